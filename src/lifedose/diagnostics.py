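"""Incompleteness indices and recall-bias diagnostics.

The **PDI** (percentage of dose imputed), ``100 * Z_imp / (Z_imp + Z_calc)``,
measures how much of a subject's effective dose rests on group-level or
imputed components; the companion **PTI** is the percentage of covered
years that needed imputation.  Stratifying case-control counts by PDI and
testing independence with a Pearson chi-square probes whether imputation
burden differs by disease status -- a signature of recall bias when
residence histories come from interviews.  Additional diagnostics:
correlations of dose variants across effectiveness models under PDI caps,
the dependence of dose on year of arrival in the study area (which
out-of-area surrogates should remove), and normal-probability-plot tables
that expose the heavy right tail contributed by residences near busy
intersections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: Table-style PDI strata: {0}, (0,20), [20,40), [40,60), [60,80), [80,100].
DEFAULT_PDI_BINS = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
DEFAULT_PDI_CAPS = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
DEFAULT_BIN_LABELS = ("zero", ">0 and <20%", "20% to <40%", "40% to <60%",
                      "60% to <80%", "80% to <=100%")


def compute_pdi_pti(z_calc: float, z_imp: float, years_imputed: int,
                    years_covered: int) -> dict:
    """PDI = 100*Z_imp/(Z_imp+Z_calc); PTI = 100*imputed years/covered years.

    A subject with zero dose in both components gets PDI = 100 and a
    ``degenerate`` flag (nothing was individually modeled).
    """
    if z_calc < 0 or z_imp < 0:
        raise ValueError("dose components must be >= 0")
    total = z_calc + z_imp
    degenerate = total == 0
    pdi = 100.0 if degenerate else min(100.0 * z_imp / total, 100.0)
    pti = (100.0 * years_imputed / years_covered) if years_covered else 0.0
    return {"pdi": pdi, "pti": pti, "degenerate": degenerate}


def pdi_frame(doses: pd.DataFrame,
              exposures: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-subject PDI (and PTI when an exposure timeline is given).

    ``doses`` needs columns subject_id, z_calc, z_imp; ``exposures`` the
    long (subject_id, year, provenance) timeline.
    """
    out = doses[["subject_id"]].copy()
    total = doses["z_calc"].to_numpy(float) + doses["z_imp"].to_numpy(float)
    degenerate = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pdi = 100.0 * doses["z_imp"].to_numpy(float) / total
    out["pdi"] = np.clip(np.where(degenerate, 100.0, pdi), 0.0, 100.0)
    out["degenerate"] = degenerate
    if exposures is not None:
        from .dose import IMPUTED_FLAGS
        g = exposures.groupby("subject_id")["provenance"]
        covered = g.size()
        imput = exposures[exposures["provenance"].isin(IMPUTED_FLAGS)] \
            .groupby("subject_id").size().reindex(covered.index, fill_value=0)
        pti = (100.0 * imput / covered).rename("pti").reset_index()
        out = out.merge(pti, on="subject_id", how="left")
        out["pti"] = out["pti"].fillna(0.0)
    return out


def pdi_bin_index(pdi: np.ndarray,
                  bins: tuple = DEFAULT_PDI_BINS) -> np.ndarray:
    """Strata index: 0 for PDI == 0; else half-open bins, top bin closed."""
    pdi = np.asarray(pdi, dtype=float)
    if np.any((pdi < 0) | (pdi > 100)):
        raise ValueError("PDI outside [0, 100]")
    edges = np.asarray(bins, dtype=float)
    # strata: {0}, (0, e1), [e1, e2), ..., [e_{k-1}, 100]
    idx = np.searchsorted(edges[1:-1], pdi, side="right") + 1
    return np.where(pdi == 0.0, 0, idx)


def pdi_strata_table(pdi: np.ndarray, case: np.ndarray,
                     bins: tuple = DEFAULT_PDI_BINS,
                     labels: tuple = DEFAULT_BIN_LABELS) -> pd.DataFrame:
    """Case/control counts by PDI stratum (strata partition [0, 100])."""
    idx = pdi_bin_index(pdi, bins)
    case = np.asarray(case, dtype=int)
    n_bins = len(bins)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        rows.append({"stratum": labels[b] if b < len(labels) else str(b),
                     "controls": int(np.sum(sel & (case == 0))),
                     "cases": int(np.sum(sel & (case == 1)))})
    table = pd.DataFrame(rows)
    table["total"] = table["controls"] + table["cases"]
    return table


def chi_square_independence(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Expected counts come from the row/column margins; no continuity
    correction.  Returns (statistic, df, upper-tail p).
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row or column margin")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df, float(stats.chi2.sf(stat, df))


def dose_correlations(doses_by_form: dict[str, pd.DataFrame],
                      pdi: pd.DataFrame,
                      caps: tuple = DEFAULT_PDI_CAPS,
                      reference_form: str = "B1") -> pd.DataFrame:
    """Pearson/Spearman correlation of each dose variant against the
    reference cumulative dose, within each PDI cap.

    Each entry of ``doses_by_form`` has columns subject_id, z_total; ``pdi``
    has subject_id, pdi.  Correlations undefined under a cap (constant
    vector or fewer than 3 subjects) are reported as NaN.
    """
    ref = doses_by_form[reference_form][["subject_id", "z_total"]] \
        .rename(columns={"z_total": "z_ref"})
    rows = []
    for form, df in doses_by_form.items():
        merged = df[["subject_id", "z_total"]].merge(ref, on="subject_id") \
            .merge(pdi[["subject_id", "pdi"]], on="subject_id")
        for cap in caps:
            sub = merged[merged["pdi"] <= cap]
            x = sub["z_total"].to_numpy(float)
            y = sub["z_ref"].to_numpy(float)
            if len(sub) < 3 or np.std(x) == 0 or np.std(y) == 0:
                pear = spear = np.nan
            else:
                pear = float(stats.pearsonr(x, y).statistic)
                spear = float(stats.spearmanr(x, y).statistic)
            rows.append({"form": form, "pdi_cap": cap, "n": len(sub),
                         "pearson": pear, "spearman": spear})
    return pd.DataFrame(rows)


def dose_correlations_multi(per_imputation: list[dict[str, pd.DataFrame]],
                            pdi_per_imputation: list[pd.DataFrame],
                            caps: tuple = DEFAULT_PDI_CAPS,
                            reference_form: str = "B1") -> pd.DataFrame:
    """Mean and SD of the correlation table across M imputed datasets."""
    parts = [dose_correlations(d, p, caps, reference_form)
             for d, p in zip(per_imputation, pdi_per_imputation)]
    cat = pd.concat(parts)
    agg = cat.groupby(["form", "pdi_cap"]).agg(
        n=("n", "mean"),
        pearson_mean=("pearson", "mean"), pearson_sd=("pearson", "std"),
        spearman_mean=("spearman", "mean"), spearman_sd=("spearman", "std"),
    ).reset_index()
    return agg


def arrival_dependency(subjects: pd.DataFrame,
                       doses: pd.DataFrame) -> dict:
    """Dose-vs-arrival-year dependence, with and without the imputed part.

    Out-of-area surrogates should remove most of the artefactual negative
    correlation between the modeled dose Z_calc and year of arrival (late
    arrivers are missing pre-arrival exposure).  Returns both Pearson
    coefficients and per-arrival-decade mean doses.
    """
    merged = subjects[["subject_id", "arrival_year"]].merge(
        doses[["subject_id", "z_calc", "z_imp", "z_total"]], on="subject_id")
    arr = merged["arrival_year"].to_numpy(float)
    out = {"corr_z_calc": np.nan, "corr_z_total": np.nan}
    if np.unique(arr).size >= 2:
        for key, col in (("corr_z_calc", "z_calc"),
                         ("corr_z_total", "z_total")):
            v = merged[col].to_numpy(float)
            if np.std(v) > 0:
                out[key] = float(stats.pearsonr(v, arr).statistic)
    decade = (merged["arrival_year"] // 10 * 10).astype(int)
    out["binned_means"] = merged.assign(decade=decade).groupby("decade")[
        ["z_calc", "z_total"]].mean().reset_index()
    return out


def tail_diagnostics(doses: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Normal-probability-plot table for ln dose with a pointwise band.

    Returns one row per positive dose with the ordered ln dose, its normal
    plotting-position quantile, the pointwise ``1 - alpha`` order-statistic
    band (beta distribution of uniform order statistics, mapped through the
    fitted normal), and an ``above_band`` flag.  Location and scale of the
    reference normal are fitted robustly (median and normalised IQR) so a
    heavy upper tail cannot mask itself.
    """
    d = np.asarray(doses, dtype=float)
    n_nonpos = int(np.sum(~(d > 0) | ~np.isfinite(d)))
    d = d[np.isfinite(d) & (d > 0)]
    n = d.size
    if n < 20:
        raise ValueError("need at least 20 positive doses")
    x = np.sort(np.log(d))
    loc = np.median(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = iqr / (2.0 * stats.norm.ppf(0.75))
    if scale == 0:
        raise ValueError("degenerate dose distribution")
    i = np.arange(1, n + 1)
    pp = (i - 0.375) / (n + 0.25)  # Blom plotting positions
    q = stats.norm.ppf(pp)
    lo = loc + scale * stats.norm.ppf(stats.beta.ppf(alpha / 2, i, n - i + 1))
    hi = loc + scale * stats.norm.ppf(
        stats.beta.ppf(1 - alpha / 2, i, n - i + 1))
    table = pd.DataFrame({
        "ln_dose": x, "normal_quantile": q,
        "band_low": lo, "band_high": hi,
        "above_band": x > hi, "below_band": x < lo,
    })
    table.attrs["n_excluded_nonpositive"] = n_nonpos
    table.attrs["share_above_band"] = float(table["above_band"].mean())
    return table
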