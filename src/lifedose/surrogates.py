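"""Group-level dose surrogates for years outside individualised coverage.

Two gaps arise in lifetime reconstruction: calendar years before the first
year with usable emission/traffic records (the *record boundary*, e.g.
1960), and in-record years a subject spent outside the study area.

* The **early surrogate** scales the boundary-year mean individualised
  dose by the ratio of regional vehicle registrations,
  ``dose(t) = V1(i) * (Vehicles(t) / Vehicles(boundary))**k1 * mean_dose``.
* The **out-of-area surrogate** keeps the temporal factors and replaces
  the unavailable residence transfer function by the cohort average,
  ``dose(t) = k2 * V2(i) * eps(t) * T(t) * <D(t)>``.

Both are individualised by mean-one lognormal variates whose variance is
calibrated to the spread of individualised doses (at the boundary year for
V1; on five-year windows for V2), separately for cases and controls, so
surrogate means and variances are consistent with the individualised data
at the boundary.  ``k1`` and ``k2`` are sensitivity knobs, both 1 by
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .dose import SURROGATE_EARLY, IMPUTED_OUT_OF_AREA

MIN_CALIBRATION_N = 10
V2_WINDOW_YEARS = 5


@dataclass(frozen=True)
class SensitivityParams:
    """k1: exponent on the registration ratio; k2: out-of-area scale."""

    k1: float = 1.0
    k2: float = 1.0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be > 0")


@dataclass(frozen=True)
class ScalerSpec:
    """Variance-matched scaling of a group-level surrogate for one arm.

    ``sigma`` parameterises the mean-one lognormal variate
    ``V = exp(sigma * xi - sigma**2 / 2)`` whose relative variance
    ``exp(sigma**2) - 1`` equals the relative variance of the arm's
    individualised boundary-year doses.
    """

    arm: str
    boundary_year: int
    mean_dose: float
    rel_variance: float
    sigma: float
    #: standard error of mean_dose; drawn per imputed dataset so Rubin's
    #: rules see the scaler's own estimation uncertainty
    mean_se: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @staticmethod
    def from_json(text: str) -> "ScalerSpec":
        return ScalerSpec(**json.loads(text))


def lognormal_sigma(rel_variance: float) -> float:
    """Sigma of a mean-one lognormal with the given relative variance.

    Solves exp(sigma^2) - 1 = CV^2, i.e. sigma^2 = ln(1 + CV^2).
    """
    if rel_variance < 0:
        raise ValueError("relative variance must be >= 0")
    return float(np.sqrt(np.log1p(rel_variance)))


def draw_mean_one(sigma: float, rng: np.random.Generator,
                  size=None) -> np.ndarray | float:
    """Mean-one lognormal draw(s); analytic mean is exactly 1 for any sigma."""
    if sigma == 0.0:
        return np.ones(size) if size is not None else 1.0
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def calibrate_scaler(boundary_doses, arm: str,
                     boundary_year: int) -> ScalerSpec:
    """Fit a mean-one variance-matched scaler from one arm's boundary doses.

    Only subjects in the given arm with a positive individualised dose in
    the boundary year enter; at least 10 are required.
    """
    d = np.asarray(boundary_doses, dtype=float)
    d = d[np.isfinite(d) & (d > 0)]
    if d.size < MIN_CALIBRATION_N:
        raise ValueError(
            f"need >= {MIN_CALIBRATION_N} positive boundary doses for arm "
            f"{arm!r}, got {d.size}")
    mean = float(d.mean())
    rel_var = float(d.var(ddof=1)) / mean ** 2
    return ScalerSpec(arm=arm, boundary_year=boundary_year, mean_dose=mean,
                      rel_variance=rel_var, sigma=lognormal_sigma(rel_var),
                      mean_se=float(d.std(ddof=1) / np.sqrt(d.size)))


def early_surrogate(birth_year: int, registrations, scaler: ScalerSpec,
                    params: SensitivityParams = SensitivityParams(),
                    v1_draw: float = 1.0,
                    start_age: int = 0) -> pd.DataFrame:
    """Pre-boundary yearly dose contributions for one subject,
    V1 * (Vehicles(t)/Vehicles(boundary))**k1 * mean boundary dose.

    Accrual runs from ``birth_year + start_age`` (default: birth) through
    the year before the boundary.  ``registrations`` maps year to regional
    vehicle registrations and must cover every needed year.
    """
    boundary = scaler.boundary_year
    first = birth_year + start_age
    years = np.arange(first, boundary)
    if len(years) == 0:
        return pd.DataFrame(columns=["year", "E", "provenance"])
    missing = [int(y) for y in years if _lookup(registrations, y) is None]
    if missing:
        raise ValueError(f"registration series missing years: {missing}")
    v_boundary = _lookup(registrations, boundary)
    if v_boundary is None or v_boundary <= 0:
        raise ValueError("registration series must cover the boundary year")
    veh = np.asarray([_lookup(registrations, y) for y in years], dtype=float)
    dose = v1_draw * (veh / v_boundary) ** params.k1 * scaler.mean_dose
    return pd.DataFrame({"year": years, "E": dose,
                         "provenance": SURROGATE_EARLY})


def _lookup(series, year):
    try:
        return series[int(year)]
    except (KeyError, IndexError):
        return None


def calibrate_v2_windows(in_area_d: pd.DataFrame, boundary_year: int,
                         stop_year: int,
                         window: int = V2_WINDOW_YEARS) -> pd.DataFrame:
    """Per-window cohort mean and relative variance of in-area D values.

    ``in_area_d`` is long format (year, D) over in-area subject-years.
    Windows are ``[boundary, boundary+window)`` and so on up to
    ``stop_year``.  A window with no in-area subjects inherits the nearest
    populated window's statistics.
    """
    starts = np.arange(boundary_year, stop_year + 1, window)
    rows = []
    for s in starts:
        e = min(s + window - 1, stop_year)
        d = in_area_d.loc[(in_area_d["year"] >= s) & (in_area_d["year"] <= e),
                          "D"].to_numpy(dtype=float)
        d = d[np.isfinite(d) & (d > 0)]
        if d.size >= 2:
            mean = float(d.mean())
            rel = float(d.var(ddof=1)) / mean ** 2
        elif d.size == 1:
            mean, rel = float(d[0]), 0.0
        else:
            mean, rel = np.nan, np.nan
        rows.append({"window_start": int(s), "window_end": int(e),
                     "mean_D": mean, "rel_variance": rel})
    out = pd.DataFrame(rows)
    if out["mean_D"].isna().any():
        if out["mean_D"].isna().all():
            raise ValueError("no in-area D values in any window")
        out = out.ffill().bfill()  # nearest populated window carries over
    out["sigma"] = [lognormal_sigma(r) for r in out["rel_variance"]]
    return out


def out_of_area_surrogate(years, eps, traffic, mean_d_by_year,
                          windows: pd.DataFrame,
                          params: SensitivityParams = SensitivityParams(),
                          v2_draws=None,
                          rng: np.random.Generator | None = None
                          ) -> pd.DataFrame:
    """Out-of-area yearly dose contributions for one subject.

    ``mean_d_by_year`` maps each year to the cohort-average transfer value
    of in-area subjects alive that year (<D(t)>).  ``v2_draws`` maps window
    start year to the subject's V2 draw; when absent it is drawn from the
    window's calibrated mean-one lognormal.
    """
    years = np.asarray(sorted(int(y) for y in years))
    if len(years) == 0:
        return pd.DataFrame(columns=["year", "E", "provenance"])
    starts = windows["window_start"].to_numpy()
    if v2_draws is None:
        if rng is None:
            rng = np.random.default_rng()
        v2_draws = {int(r.window_start): float(draw_mean_one(r.sigma, rng))
                    for r in windows.itertuples()}
    rows = []
    for y in years:
        w = starts[np.searchsorted(starts, y, side="right") - 1] \
            if y >= starts[0] else starts[0]
        v2 = v2_draws[int(w)]
        d_bar = mean_d_by_year[int(y)]
        rows.append({"year": int(y),
                     "E": params.k2 * v2 * eps[y] * traffic[y] * d_bar,
                     "provenance": IMPUTED_OUT_OF_AREA})
    return pd.DataFrame(rows)
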