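"""Multiple imputation of missing residence transfer values and covariates.

Residence transfer values (D) go missing when an address cannot be
geocoded.  Two imputation methods are provided:

* **interpolation** -- log-linear interpolation in time between the
  subject's nearest earlier and later residences with known D, multiplied
  by a mean-one lognormal noise draw whose sigma is the two-point lognormal
  fit ``|ln prev - ln next| / 2``.  At the start or end of a history the
  single neighbour is carried over with zero variance, so those values are
  identical across imputed datasets.
* **place** -- hot-deck sampling restricted to donors in the same small
  geographic area ("place"), conditioned on covariates including
  case-control status via predictive-mean matching (q = 5 donors): a
  linear predictor of ln D on the covariates is fit over the place's
  donors, and the imputed value is an observed donor D drawn from the five
  donors whose predictions are nearest the recipient's.  Places with fewer
  than five donors in either arm fall back on interpolation.  Because the
  method only re-uses observed values, it can reproduce non-standard
  (heavy-tailed) D distributions that no parametric family fits.

Missing covariates are completed first, by a fully-conditional-
specification loop (5 cycles; continuous variables via predictive-mean
matching, categoricals via within-arm frequency draws).  ``M`` completed
datasets are produced from independent, reproducible RNG substreams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_M = 15
PMM_DONORS = 5
MIN_ARM_POOL = 5
FCS_CYCLES = 5


class ImputationWarning(UserWarning):
    pass


class NotImputableError(ValueError):
    """Interpolation impossible: no neighbouring residence has a known D."""


@dataclass
class ImputedDataset:
    """One completed copy of the cohort."""

    m: int
    subjects: pd.DataFrame
    residences: pd.DataFrame
    seed: int
    fallback_counts: dict = field(default_factory=dict)


def interpolation_impute(prev_d: float | None, next_d: float | None,
                         frac: float, rng: np.random.Generator) -> float:
    """Impute one D by log-linear interpolation with lognormal noise.

    ``frac`` is the gap's fractional time position between the two
    neighbours (0 = at the earlier one).  With a single neighbour the
    neighbour's value is returned with zero variance.
    """
    has_prev = prev_d is not None and np.isfinite(prev_d)
    has_next = next_d is not None and np.isfinite(next_d)
    if not has_prev and not has_next:
        raise NotImputableError("no neighbouring residence with known D")
    if has_prev and has_next:
        lp, ln_ = np.log(prev_d), np.log(next_d)
        base = (1.0 - frac) * lp + frac * ln_
        sigma = abs(lp - ln_) / 2.0
    else:
        base = np.log(prev_d if has_prev else next_d)
        sigma = 0.0
    noise = 1.0 if sigma == 0.0 else rng.lognormal(-0.5 * sigma**2, sigma)
    return float(np.exp(base) * noise)


def _interpolation_frame(residences: pd.DataFrame) -> pd.DataFrame:
    """Vectorised neighbour lookup for interpolation over a cohort.

    Returns one row per missing in-area D with columns ``base_ln`` and
    ``sigma``; rows with no usable neighbour get NaN base_ln.
    """
    res = residences.sort_values(["subject_id", "start_year"]).copy()
    res["mid"] = 0.5 * (res["start_year"] + res["end_year"])
    with np.errstate(divide="ignore", invalid="ignore"):
        res["ln_d"] = np.log(res["D"].to_numpy(dtype=float))
    g = res.groupby("subject_id", sort=False)
    res["prev_ln"] = g["ln_d"].ffill()
    res["next_ln"] = g["ln_d"].bfill()
    t = res["mid"].where(res["ln_d"].notna())
    res["prev_t"] = t.groupby(res["subject_id"], sort=False).ffill()
    res["next_t"] = t.groupby(res["subject_id"], sort=False).bfill()

    miss = res[res["D"].isna() & res["in_area"]].copy()
    both = miss["prev_ln"].notna() & miss["next_ln"].notna()
    span = (miss["next_t"] - miss["prev_t"]).where(both)
    frac = ((miss["mid"] - miss["prev_t"]) / span).clip(0.0, 1.0).fillna(0.0)
    base = np.where(
        both,
        (1.0 - frac) * miss["prev_ln"] + frac * miss["next_ln"],
        miss["prev_ln"].fillna(miss["next_ln"]))
    sigma = np.where(both,
                     (miss["prev_ln"] - miss["next_ln"]).abs() / 2.0, 0.0)
    return pd.DataFrame({"base_ln": base, "sigma": sigma}, index=miss.index)


def place_impute(record: pd.Series, donors: pd.DataFrame,
                 recipient_covariates: pd.Series, covariate_cols: list[str],
                 rng: np.random.Generator) -> float | None:
    """Hot-deck PMM draw from the record's place; None if the pool is thin.

    ``donors`` holds the place's observed rows with columns ``D``, ``case``
    and the covariates.  Requires at least five donors in each arm.
    """
    if len(donors) == 0:
        return None
    arm_counts = donors["case"].value_counts()
    if (arm_counts.get(0, 0) < MIN_ARM_POOL
            or arm_counts.get(1, 0) < MIN_ARM_POOL):
        return None
    cols = [c for c in covariate_cols if c in donors.columns]
    X = donors[cols].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    y = np.log(donors["D"].to_numpy(dtype=float))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    x0 = np.concatenate(
        [[1.0], recipient_covariates[cols].to_numpy(dtype=float)])
    pred0 = float(x0 @ beta)
    preds = X @ beta
    order = np.argsort(np.abs(preds - pred0), kind="stable")
    pick = order[: min(PMM_DONORS, len(order))]
    return float(donors["D"].to_numpy()[pick[rng.integers(len(pick))]])


def _impute_d(subjects: pd.DataFrame, residences: pd.DataFrame, method: str,
              covariate_cols: list[str], rng: np.random.Generator
              ) -> tuple[pd.DataFrame, dict]:
    res = residences.copy()
    counts = {"place": 0, "interpolation": 0, "cohort_pool": 0}
    missing_idx = res.index[res["D"].isna() & res["in_area"]]
    if len(missing_idx) == 0:
        return res, counts

    interp = _interpolation_frame(res)
    observed = res.loc[res["D"].notna() & res["in_area"]]
    pool_d = observed["D"].to_numpy(dtype=float)
    filled = res["D"].copy()
    remaining = set(missing_idx)

    if method == "place":
        donors_all = observed.merge(
            subjects[["subject_id", "case"] + covariate_cols],
            on="subject_id")
        subj_cov = subjects.set_index("subject_id")
        miss = res.loc[missing_idx]
        miss = miss[miss["place_id"].notna()]
        cols = list(covariate_cols)
        # fit each place's linear predictor of ln D once, then PMM-draw
        # for every recipient in that place
        for place, recip in sorted(
                miss.groupby("place_id").groups.items(), key=lambda kv: kv[0]):
            donors = donors_all[donors_all["place_id"] == place]
            if len(donors) == 0:
                continue
            arm_counts = donors["case"].value_counts()
            if (arm_counts.get(0, 0) < MIN_ARM_POOL
                    or arm_counts.get(1, 0) < MIN_ARM_POOL):
                continue
            X = donors[cols].to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(X)), X])
            yv = np.log(donors["D"].to_numpy(dtype=float))
            beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
            preds = X @ beta
            d_obs = donors["D"].to_numpy(dtype=float)
            for idx in recip:
                sid = res.at[idx, "subject_id"]
                x0 = np.concatenate(
                    [[1.0], subj_cov.loc[sid, cols].to_numpy(dtype=float)])
                pred0 = float(x0 @ beta)
                order = np.argsort(np.abs(preds - pred0), kind="stable")
                pick = order[: min(PMM_DONORS, len(order))]
                filled.loc[idx] = float(d_obs[pick[rng.integers(len(pick))]])
                counts["place"] += 1
                remaining.discard(idx)

    for idx in sorted(remaining):
        base = interp.at[idx, "base_ln"] if idx in interp.index else np.nan
        if np.isfinite(base):
            sigma = interp.at[idx, "sigma"]
            noise = 1.0 if sigma == 0.0 else rng.lognormal(
                -0.5 * sigma**2, sigma)
            filled.loc[idx] = float(np.exp(base) * noise)
            counts["interpolation"] += 1
        elif len(pool_d):
            filled.loc[idx] = float(pool_d[rng.integers(len(pool_d))])
            counts["cohort_pool"] += 1
        else:
            raise NotImputableError("no observed D anywhere in the cohort")
    if counts["cohort_pool"]:
        warnings.warn(
            f"{counts['cohort_pool']} residences imputed from the whole-"
            "cohort donor pool (no neighbours, no usable place)",
            ImputationWarning, stacklevel=2)
    res["D"] = filled
    return res, counts


def _impute_d_interpolation_fast(residences: pd.DataFrame,
                                 rng: np.random.Generator
                                 ) -> tuple[pd.DataFrame, dict]:
    """Vectorised interpolation-only path (used when method='interpolation'
    and escalation is not needed)."""
    res = residences.copy()
    counts = {"place": 0, "interpolation": 0, "cohort_pool": 0}
    interp = _interpolation_frame(res)
    if len(interp) == 0:
        return res, counts
    ok = np.isfinite(interp["base_ln"].to_numpy())
    sig = interp["sigma"].to_numpy()
    noise = np.ones(len(interp))
    pos = ok & (sig > 0)
    noise[pos] = rng.lognormal(-0.5 * sig[pos]**2, sig[pos])
    values = np.exp(interp["base_ln"].to_numpy()) * noise
    res.loc[interp.index[ok], "D"] = values[ok]
    counts["interpolation"] = int(ok.sum())
    # escalate hopeless rows to the cohort-wide pool
    bad = interp.index[~ok]
    if len(bad):
        pool = res.loc[res["D"].notna() & res["in_area"], "D"].to_numpy()
        res.loc[bad, "D"] = pool[rng.integers(len(pool), size=len(bad))]
        counts["cohort_pool"] = len(bad)
        warnings.warn(
            f"{len(bad)} residences imputed from the whole-cohort donor "
            "pool", ImputationWarning, stacklevel=2)
    return res, counts


def _impute_covariates(subjects: pd.DataFrame, covariate_cols: list[str],
                       rng: np.random.Generator,
                       cycles: int = FCS_CYCLES) -> pd.DataFrame:
    """Fully-conditional-specification fill of missing covariates."""
    sub = subjects.copy()
    missing_cols = [c for c in covariate_cols if sub[c].isna().any()]
    if not missing_cols:
        return sub
    masks = {c: sub[c].isna().to_numpy() for c in missing_cols}
    categorical = {c: (sub[c].dtype == object
                       or str(sub[c].dtype) == "category"
                       or sub[c].dropna().isin([0, 1]).all())
                   for c in missing_cols}
    # initial fill: observed-value draws
    for c in missing_cols:
        obs = sub.loc[~masks[c], c].to_numpy()
        sub.loc[masks[c], c] = obs[rng.integers(len(obs), size=masks[c].sum())]
    for _ in range(cycles):
        for c in missing_cols:
            mask = masks[c]
            if categorical[c]:
                # conditional frequency draw within arm
                for arm, grp in sub.groupby("case"):
                    sel = mask & (sub["case"] == arm).to_numpy()
                    if not sel.any():
                        continue
                    obs = sub.loc[(~mask) & (sub["case"] == arm).to_numpy(),
                                  c].to_numpy()
                    if len(obs) == 0:
                        obs = sub.loc[~mask, c].to_numpy()
                    sub.loc[sel, c] = obs[rng.integers(len(obs),
                                                       size=sel.sum())]
            else:
                others = [o for o in covariate_cols if o != c] + ["case"]
                X = sub[others].to_numpy(dtype=float)
                X = np.column_stack([np.ones(len(X)), X])
                y = sub[c].to_numpy(dtype=float)
                beta, *_ = np.linalg.lstsq(X[~mask], y[~mask], rcond=None)
                preds = X @ beta
                obs_idx = np.flatnonzero(~mask)
                for i in np.flatnonzero(mask):
                    near = obs_idx[np.argsort(
                        np.abs(preds[obs_idx] - preds[i]),
                        kind="stable")[:PMM_DONORS]]
                    sub.iloc[i, sub.columns.get_loc(c)] = \
                        y[near[rng.integers(len(near))]]
    return sub


def _place_structures(subjects: pd.DataFrame, residences: pd.DataFrame,
                      covariate_cols: list[str]) -> dict:
    """Precompute PMM donor candidate sets per missing cell.

    Valid whenever the covariates are complete: donors, predictors and
    nearest-donor sets do not change across imputed datasets -- only the
    uniform draw among the q nearest donors does.  Returns a mapping
    ``residence index -> candidate D array`` plus interpolation/fallback
    bookkeeping for the remaining cells.
    """
    res = residences
    observed = res.loc[res["D"].notna() & res["in_area"]]
    donors_all = observed.merge(
        subjects[["subject_id", "case"] + covariate_cols], on="subject_id")
    subj_cov = subjects.set_index("subject_id")
    missing_idx = res.index[res["D"].isna() & res["in_area"]]
    miss = res.loc[missing_idx]
    miss = miss[miss["place_id"].notna()]
    cols = list(covariate_cols)
    candidates: dict[int, np.ndarray] = {}
    for place, recip in sorted(
            miss.groupby("place_id").groups.items(), key=lambda kv: kv[0]):
        donors = donors_all[donors_all["place_id"] == place]
        if len(donors) == 0:
            continue
        arm_counts = donors["case"].value_counts()
        if (arm_counts.get(0, 0) < MIN_ARM_POOL
                or arm_counts.get(1, 0) < MIN_ARM_POOL):
            continue
        X = np.column_stack([np.ones(len(donors)),
                             donors[cols].to_numpy(dtype=float)])
        yv = np.log(donors["D"].to_numpy(dtype=float))
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        preds = X @ beta
        d_obs = donors["D"].to_numpy(dtype=float)
        sids = res.loc[recip, "subject_id"].to_numpy()
        X0 = np.column_stack([np.ones(len(sids)),
                              subj_cov.loc[sids, cols].to_numpy(dtype=float)])
        pred0 = X0 @ beta
        dist = np.abs(preds[None, :] - pred0[:, None])
        order = np.argsort(dist, axis=1, kind="stable")[:, :PMM_DONORS]
        for i, idx in enumerate(recip):
            candidates[idx] = d_obs[order[i]]
    return {"candidates": candidates, "missing_idx": missing_idx}


def _impute_d_place_fast(residences: pd.DataFrame, structures: dict,
                         rng: np.random.Generator
                         ) -> tuple[pd.DataFrame, dict]:
    """Per-dataset draws from precomputed PMM candidate sets."""
    res = residences.copy()
    counts = {"place": 0, "interpolation": 0, "cohort_pool": 0}
    cand = structures["candidates"]
    for idx in sorted(cand):
        c = cand[idx]
        res.at[idx, "D"] = float(c[rng.integers(len(c))])
        counts["place"] += 1
    still = res["D"].isna() & res["in_area"]
    if still.any():
        res2, c2 = _impute_d_interpolation_fast(res, rng)
        res = res2
        counts["interpolation"] = c2["interpolation"]
        counts["cohort_pool"] = c2["cohort_pool"]
    return res, counts


def generate_imputations(subjects: pd.DataFrame, residences: pd.DataFrame,
                         M: int = DEFAULT_M, method: str = "place",
                         seed: int = 0,
                         covariate_cols: list[str] | None = None
                         ) -> list[ImputedDataset]:
    """Produce M completed datasets from independent RNG substreams.

    ``subjects`` must carry ``subject_id`` and ``case``; ``residences``
    must carry ``subject_id``, ``start_year``, ``end_year``, ``in_area``,
    ``place_id`` and ``D`` (NaN = missing).  Deterministic under
    ``(seed, M, method)``.
    """
    if M < 2:
        raise ValueError("M >= 2 required for Rubin pooling")
    if method not in ("place", "interpolation"):
        raise ValueError(f"unknown imputation method {method!r}")
    if covariate_cols is None:
        covariate_cols = [c for c in subjects.columns
                          if c.startswith("cov_")]
    streams = np.random.SeedSequence(seed).spawn(M)
    covariates_complete = not subjects[covariate_cols].isna().any().any() \
        if covariate_cols else True
    structures = None
    if method == "place" and covariates_complete:
        # donor pools and PMM candidate sets are identical across
        # imputations when the covariates are complete
        structures = _place_structures(subjects, residences, covariate_cols)
    out = []
    for m, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        sub = _impute_covariates(subjects, covariate_cols, rng)
        if method == "interpolation":
            res, counts = _impute_d_interpolation_fast(residences, rng)
        elif structures is not None:
            res, counts = _impute_d_place_fast(residences, structures, rng)
        else:
            res, counts = _impute_d(sub, residences, method,
                                    covariate_cols, rng)
        out.append(ImputedDataset(m=m, subjects=sub, residences=res,
                                  seed=int(ss.entropy), fallback_counts=counts))
    return out
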