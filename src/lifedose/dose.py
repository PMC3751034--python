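"""Yearly exposures and their accumulation into effective doses.

A subject's yearly exposure factorises as E(y, i) = eps(y) * T(y) * D(y, r_i)
-- emission per vehicle-km, average vehicles per km, and the residence
transfer function.  Effective dose Z weights each year's exposure by a
biological-effectiveness factor B before summing, so that equal Z implies
an equal log-odds increment regardless of when the exposure occurred.

Four effectiveness forms are supported:

* ``B1`` constant weight (plain cumulative dose);
* ``B2`` weight inversely proportional to the squared age at disease onset
  (younger onset implies higher sensitivity per unit dose);
* ``B3`` only the peak annual exposure counts (threshold model);
* ``B4`` only the last ``k`` years before the stop year count (pure
  promoter model).

A latency period L is implemented by moving the summation stop year back
by L.  Every yearly exposure carries a provenance flag; the accumulated
dose is split into a modeled part (Z_calc) and an imputed part (Z_imp),
which the diagnostics module turns into the PDI incompleteness index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

#: Provenance flags for yearly exposures.
MODELED = "modeled"
IMPUTED_IN_AREA = "imputed_in_area"
IMPUTED_OUT_OF_AREA = "imputed_out_of_area"
SURROGATE_EARLY = "surrogate_early"
PROVENANCES = (MODELED, IMPUTED_IN_AREA, IMPUTED_OUT_OF_AREA, SURROGATE_EARLY)
#: Provenances contributing to Z_imp rather than Z_calc.
IMPUTED_FLAGS = frozenset(PROVENANCES) - {MODELED}


class DoseWarning(UserWarning):
    pass


@dataclass(frozen=True)
class YearSeries:
    """A positive annual series with optional constant pre-boundary extension.

    Used for both the emission factor eps(y) (mass per vehicle-km) and the
    traffic level T(y) (average vehicles per km).  Years before
    ``boundary_year`` return the boundary-year value, reflecting the rule
    that the emission factor is held constant before the first year with
    measured data.
    """

    values: Mapping[int, float]
    boundary_year: int | None = None

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("empty series")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("series values must be positive")

    def __getitem__(self, year: int) -> float:
        year = int(year)
        if self.boundary_year is not None and year < self.boundary_year:
            return self.values[self.boundary_year]
        try:
            return self.values[year]
        except KeyError:
            raise KeyError(f"year {year} not covered by series") from None

    def years(self) -> list[int]:
        return sorted(self.values)


# The same container serves both roles.
EmissionSeries = YearSeries
TrafficSeries = YearSeries


def series_vector(series: YearSeries, y0: int, y1: int) -> np.ndarray:
    """Dense lookup array for years y0..y1 inclusive."""
    return np.asarray([series[y] for y in range(y0, y1 + 1)], dtype=float)


def expand_intervals(start: np.ndarray, end: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Expand half-open year intervals into (row_index, year) arrays."""
    start = np.asarray(start, dtype=int)
    end = np.asarray(end, dtype=int)
    lengths = np.maximum(end - start, 0)
    idx = np.repeat(np.arange(len(start)), lengths)
    cs = np.cumsum(lengths)
    total = int(cs[-1]) if len(cs) else 0
    offsets = np.arange(total) - np.repeat(cs - lengths, lengths)
    return idx, start[idx] + offsets


@dataclass(frozen=True)
class EffectivenessModel:
    """Biological-effectiveness form with its parameters.

    ``latency`` (years) excludes exposures in the last L years before the
    stop year.  ``promoter_window`` is B4's k.  ``reference_age`` normalises
    B2 so that a subject whose onset age equals the reference age has
    weight one; it defaults (in cohort-level helpers) to the cohort mean
    onset age.
    """

    form: str = "B1"
    latency: float = 0.0
    promoter_window: int = 1
    reference_age: float = 50.0

    def __post_init__(self) -> None:
        if self.form not in ("B1", "B2", "B3", "B4"):
            raise ValueError(f"unknown effectiveness form {self.form!r}")
        if self.latency < 0:
            raise ValueError("latency must be >= 0")
        if self.promoter_window < 1:
            raise ValueError("promoter window k must be >= 1")
        if self.reference_age <= 0:
            raise ValueError("reference_age must be > 0")


@dataclass(frozen=True)
class EffectiveDose:
    subject_id: object
    form: str
    z_total: float
    z_calc: float
    z_imp: float
    relative_units: bool = False

    def __post_init__(self) -> None:
        if self.z_calc < 0 or self.z_imp < 0:
            raise ValueError("dose components must be >= 0")
        if not np.isclose(self.z_total, self.z_calc + self.z_imp,
                          rtol=1e-9, atol=1e-12):
            raise ValueError("z_total must equal z_calc + z_imp")


def b_weight(model: EffectivenessModel, age_at_exposure: float,
             age_at_onset: float, age_at_stop: float | None = None) -> float:
    """Relative-risk weight for one unit of exposure at a given age.

    For B4 the weight is 1 only when the exposure falls within the last
    ``k`` years before the stop age (defaulting to the onset age).  B3
    returns 1 here; its peak selection happens in :func:`effective_dose`.
    """
    if not 0 <= age_at_exposure <= age_at_onset:
        raise ValueError("require 0 <= age_at_exposure <= age_at_onset")
    if model.form == "B1" or model.form == "B3":
        return 1.0
    if model.form == "B2":
        if age_at_onset == 0:
            raise ValueError("B2 undefined at onset age 0")
        return (model.reference_age / age_at_onset) ** 2
    # B4: promoter window
    stop = age_at_onset if age_at_stop is None else age_at_stop
    return 1.0 if age_at_exposure > stop - model.promoter_window else 0.0


def annual_exposure(eps: float, traffic: float, d: float) -> float:
    """E = eps * T * D; linear in each factor."""
    if eps < 0 or traffic < 0 or d < 0:
        raise ValueError("annual exposure factors must be >= 0")
    return eps * traffic * d


def effective_dose(series: pd.DataFrame, model: EffectivenessModel,
                   birth_year: int, diagnosis_year: int,
                   stop_year: int | None = None) -> EffectiveDose:
    """Accumulate one subject's yearly exposures into an effective dose.

    ``series`` has columns ``year``, ``E`` and ``provenance``.  Years after
    ``stop_year - latency`` are excluded.  Under B3 the dose is the peak
    annual exposure and the peak year's provenance decides whether the
    whole dose counts as modeled or imputed.
    """
    if stop_year is None:
        stop_year = diagnosis_year
    if not birth_year <= stop_year <= diagnosis_year:
        raise ValueError("require birth_year <= stop_year <= diagnosis_year")
    sid = series["subject_id"].iloc[0] if ("subject_id" in series.columns
                                           and len(series)) else None
    cutoff = stop_year - model.latency
    sub = series[(series["year"] >= birth_year) & (series["year"] <= cutoff)]
    if len(sub) == 0:
        warnings.warn("empty exposure series: Z = 0", DoseWarning,
                      stacklevel=2)
        return EffectiveDose(sid, model.form, 0.0, 0.0, 0.0)
    e = sub["E"].to_numpy(dtype=float)
    if np.any(e < 0):
        raise ValueError("negative exposure value")
    imputed = sub["provenance"].isin(IMPUTED_FLAGS).to_numpy()
    if model.form == "B3":
        i = int(np.argmax(e))
        z = float(e[i])
        z_imp = z if imputed[i] else 0.0
        return EffectiveDose(sid, "B3", z, z - z_imp, z_imp)
    onset_age = diagnosis_year - birth_year
    ages = sub["year"].to_numpy() - birth_year
    w = np.asarray([
        b_weight(model, a, onset_age, age_at_stop=cutoff - birth_year)
        for a in ages])
    contrib = e * w
    z_imp = float(contrib[imputed].sum())
    z_calc = float(contrib[~imputed].sum())
    return EffectiveDose(sid, model.form, z_calc + z_imp, z_calc, z_imp)


def cohort_effective_doses(exposures: pd.DataFrame, subjects: pd.DataFrame,
                           model: EffectivenessModel,
                           stop_year: int | None = None) -> pd.DataFrame:
    """Vectorised :func:`effective_dose` over a cohort.

    ``exposures`` is long format (subject_id, year, E, provenance);
    ``subjects`` carries birth_year and diagnosis_year.  Returns a frame
    with columns subject_id, form, z_total, z_calc, z_imp.
    """
    sub = exposures.merge(
        subjects[["subject_id", "birth_year", "diagnosis_year"]],
        on="subject_id", how="inner")
    stop = sub["diagnosis_year"] if stop_year is None else stop_year
    cutoff = stop - model.latency
    sub = sub[(sub["year"] >= sub["birth_year"]) & (sub["year"] <= cutoff)]
    sub = sub.copy()
    stop_arr = (stop_year if stop_year is not None
                else sub["diagnosis_year"].to_numpy())
    imputed = sub["provenance"].isin(IMPUTED_FLAGS)

    if model.form == "B3":
        # peak annual exposure; provenance of the peak year decides the split
        idx = sub.groupby("subject_id")["E"].idxmax()
        peak = sub.loc[idx, ["subject_id", "E"]].copy()
        peak["imputed"] = imputed.loc[idx].to_numpy()
        out = pd.DataFrame({
            "subject_id": peak["subject_id"].to_numpy(),
            "z_total": peak["E"].to_numpy(dtype=float),
        })
        out["z_imp"] = np.where(peak["imputed"], out["z_total"], 0.0)
        out["z_calc"] = out["z_total"] - out["z_imp"]
    else:
        if model.form == "B1":
            w = np.ones(len(sub))
        elif model.form == "B2":
            onset = (sub["diagnosis_year"] - sub["birth_year"]).to_numpy(float)
            if np.any(onset == 0):
                raise ValueError("B2 undefined at onset age 0")
            w = (model.reference_age / onset) ** 2
        else:  # B4
            w = (sub["year"].to_numpy()
                 > stop_arr - model.latency - model.promoter_window)
            w = w.astype(float)
        sub["contrib"] = sub["E"].to_numpy(float) * w
        sub["contrib_imp"] = np.where(imputed, sub["contrib"], 0.0)
        g = sub.groupby("subject_id")[["contrib", "contrib_imp"]].sum()
        out = pd.DataFrame({
            "subject_id": g.index.to_numpy(),
            "z_imp": g["contrib_imp"].to_numpy(),
            "z_total": g["contrib"].to_numpy(),
        })
        out["z_calc"] = out["z_total"] - out["z_imp"]
    # subjects with no covered exposure rows accumulate zero dose
    missing = subjects.loc[~subjects["subject_id"].isin(out["subject_id"]),
                           "subject_id"]
    if len(missing):
        zeros = pd.DataFrame({"subject_id": missing.to_numpy(),
                              "z_total": 0.0, "z_imp": 0.0, "z_calc": 0.0})
        out = pd.concat([out, zeros], ignore_index=True)
    out["form"] = model.form
    cols = ["subject_id", "form", "z_total", "z_calc", "z_imp"]
    return out[cols].sort_values("subject_id").reset_index(drop=True)


def normalize_doses(doses: pd.DataFrame, reference_exposures: np.ndarray
                    ) -> pd.DataFrame:
    """Express doses in relative units: 1 = one year's cohort-mean exposure.

    ``reference_exposures`` are the cohort's annual exposures in the
    reference year (one per subject with that year covered).  Ratios
    between subjects and the Z split are preserved, so PDI is invariant.
    """
    ref = np.asarray(reference_exposures, dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size == 0 or ref.mean() <= 0:
        raise ValueError("reference-year mean exposure must be positive")
    m = ref.mean()
    out = doses.copy()
    for col in ("z_total", "z_calc", "z_imp"):
        if col in out.columns:
            out[col] = out[col] / m
    out.attrs["relative_units"] = True
    out.attrs["reference_mean"] = m
    return out
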