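"""Synthetic study-area, cohort and outcome generation.

Everything the reconstruction pipeline consumes can be generated here at
desk scale: a planar road network with traffic weights and boosted
intersection zones, a case-control cohort with in-migration (a majority of
subjects arriving after the record boundary year), residence histories
anchored to a library of candidate home sites, true transfer values from
the dispersion module, interview-style missingness whose geocoding success
declines into the past, and case status drawn from the logistic risk
equation with a known dose coefficient.

Ground truth (true D histories, true doses, true case probabilities) is
kept in a separate :class:`TrueState` container that estimation code never
reads; recovery tests compare pipeline output against it.

Default rates mirror the study conditions the framework targets: ~55% of
subjects arriving after the 1960 boundary, 65% geocoding success at the
boundary (declining earlier), 80% place retention among failed geocodes,
and a 1% tail of subjects living for decades beside heavily trafficked
intersections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from .dispersion import MetSummary, RoadSegment, network_spatial_sums
from .dose import YearSeries


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 2000
    case_fraction: float = 0.5
    birth_year_range: tuple[int, int] = (1916, 1955)
    boundary_year: int = 1960
    stop_year: int = 1995
    diagnosis_year: int = 1996
    late_arrival_fraction: float = 0.55
    mean_residence_years: float = 12.0
    geocode_success_boundary: float = 0.65
    geocode_scale_years: float = 12.0
    place_retention: float = 0.80
    intersection_tail_fraction: float = 0.01
    missingness: str = "MAR"  # or "MCAR"
    mcar_rate: float = 0.40
    mar_covariate_effect: float = 0.5
    true_beta_per_sd: float = math.log(1.5)
    # network / geography
    region_km: tuple[float, float] = (20.0, 20.0)
    minor_spacing_km: float = 0.7
    n_major_roads: int = 6
    major_traffic_weight: float = 5.0
    minor_weight_sigma: float = 0.30  # lognormal spread of street volumes
    urban_field_sigma: float = 0.45   # log-scale SD of the density gradient
    urban_field_waves: int = 8
    intersection_boost: float = 3.0
    intersection_zone_m: float = 100.0
    segment_length_km: float = 0.7
    n_sites: int = 400
    n_met_months: int = 1
    place_grid: tuple[int, int] = (10, 10)
    out_of_area_like_in_area: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 50:
            raise ValueError("n_subjects must be >= 50")
        for f in (self.case_fraction, self.late_arrival_fraction,
                  self.geocode_success_boundary, self.place_retention,
                  self.intersection_tail_fraction, self.mcar_rate):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class TrueState:
    """Ground truth; estimation code must never read this."""

    residence_d: pd.DataFrame      # residence_id, true_D
    exposures: pd.DataFrame        # subject_id, year, E (true)
    z_true: pd.DataFrame           # subject_id, z_true (B1, record period)
    case_prob: pd.DataFrame        # subject_id, p
    beta: float
    intercept: float
    tail_subjects: np.ndarray


@dataclass
class Cohort:
    subjects: pd.DataFrame
    residences: pd.DataFrame
    config: CohortConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# historical series

def default_emission_series(boundary_year: int = 1960,
                            stop_year: int = 1995) -> YearSeries:
    """Relative tailpipe BaP emission factor: peak in the mid-1970s, then a
    steep decline with catalytic converters through the late 1980s."""
    years = np.arange(boundary_year, stop_year + 1)
    peak, width = 1974.0, 9.0
    rise = np.exp(-0.5 * ((years - peak) / width) ** 2)
    decline = np.where(years > 1985, np.exp(-0.10 * (years - 1985)), 1.0)
    vals = 0.25 + 1.35 * rise * decline
    return YearSeries(dict(zip(years.tolist(), vals.tolist())),
                      boundary_year=boundary_year)


def default_traffic_series(boundary_year: int = 1960,
                           stop_year: int = 1995) -> YearSeries:
    """Average vehicles per km, growing ~2.7x between 1970 and 1995."""
    years = np.arange(boundary_year, stop_year + 1)
    vals = 0.75 * np.exp(0.0397 * (years - boundary_year))
    return YearSeries(dict(zip(years.tolist(), vals.tolist())),
                      boundary_year=boundary_year)


def default_registration_series(first_year: int = 1900,
                                boundary_year: int = 1960) -> YearSeries:
    """Regional vehicle registrations, logistic growth from ~1900."""
    years = np.arange(first_year, boundary_year + 1)
    vals = 100.0 / (1.0 + np.exp(-(years - 1945) / 12.0))
    return YearSeries(dict(zip(years.tolist(), vals.tolist())))


def default_met(n_months: int = 1, background: float = 0.0
                ) -> list[MetSummary]:
    """Monthly met summaries; a mild seasonal rotation of the wind rose."""
    out = []
    base = np.array([0.20, 0.16, 0.10, 0.08, 0.10, 0.12, 0.12, 0.12])
    for m in range(n_months):
        probs = np.roll(base, m % 8)
        out.append(MetSummary(month=m + 1, sector_probs=probs,
                              sector_speeds=np.full(8, 4.0),
                              background=background))
    return out


# ---------------------------------------------------------------------------
# network

def generate_network(config: CohortConfig, seed: int
                     ) -> tuple[list[RoadSegment], np.ndarray]:
    """Grid of minor roads plus sparse major roads with intersection zones.

    Returns (segments, intersection_centres); segments within
    ``intersection_zone_m`` of a major-major crossing get
    ``intersection_boost``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    w, h = config.region_km
    segs: list[RoadSegment] = []
    field = _log_density_field(rng, config.urban_field_sigma,
                               config.urban_field_waves, w, h)

    def add_polyline(x1, y1, x2, y2, weight, prefix):
        length = float(np.hypot(x2 - x1, y2 - y1))
        n = max(1, int(np.ceil(length / config.segment_length_km)))
        xs = np.linspace(x1, x2, n + 1)
        ys = np.linspace(y1, y2, n + 1)
        for i in range(n):
            mx, my = 0.5 * (xs[i] + xs[i + 1]), 0.5 * (ys[i] + ys[i + 1])
            segs.append(RoadSegment(
                id=f"{prefix}_{len(segs)}", x1=xs[i], y1=ys[i],
                x2=xs[i + 1], y2=ys[i + 1],
                traffic_weight=weight * float(np.exp(field(mx, my)))))

    # street traffic volumes are right-skewed; each minor street carries a
    # mean-one lognormal volume
    sp = config.minor_spacing_km
    sig = config.minor_weight_sigma
    for x in np.arange(0.0, w + 1e-9, sp):
        wgt = rng.lognormal(-0.5 * sig**2, sig) if sig > 0 else 1.0
        add_polyline(x, 0.0, x, h, wgt, "minor_v")
    for y in np.arange(0.0, h + 1e-9, sp):
        wgt = rng.lognormal(-0.5 * sig**2, sig) if sig > 0 else 1.0
        add_polyline(0.0, y, w, y, wgt, "minor_h")

    majors = []
    for k in range(config.n_major_roads):
        if k % 2 == 0:  # roughly east-west
            y0, y1 = rng.uniform(0.1 * h, 0.9 * h, size=2)
            majors.append((0.0, y0, w, y1))
        else:
            x0, x1 = rng.uniform(0.1 * w, 0.9 * w, size=2)
            majors.append((x0, 0.0, x1, h))
    for (x1, y1, x2, y2) in majors:
        add_polyline(x1, y1, x2, y2, config.major_traffic_weight, "major")

    centres = _major_crossings(majors)
    if len(centres):
        zone_km = config.intersection_zone_m / 1000.0
        boosted = []
        for s in segs:
            mx = 0.5 * (s.x1 + s.x2)
            my = 0.5 * (s.y1 + s.y2)
            d = np.min(np.hypot(centres[:, 0] - mx, centres[:, 1] - my))
            if d <= zone_km:
                s = replace(s, intersection_boost=config.intersection_boost)
            boosted.append(s)
        segs = boosted
    return segs, centres


def _major_crossings(majors) -> np.ndarray:
    pts = []
    for i in range(len(majors)):
        for j in range(i + 1, len(majors)):
            p = _line_intersection(majors[i], majors[j])
            if p is not None:
                pts.append(p)
    return np.asarray(pts) if pts else np.empty((0, 2))


def _line_intersection(a, b):
    x1, y1, x2, y2 = a
    x3, y3, x4, y4 = b
    den = (x1 - x2) * (y3 - y4) - (y1 - y2) * (x3 - x4)
    if abs(den) < 1e-12:
        return None
    t = ((x1 - x3) * (y3 - y4) - (y1 - y3) * (x3 - x4)) / den
    u = ((x1 - x3) * (y1 - y2) - (y1 - y3) * (x1 - x2)) / den
    if 0.0 <= t <= 1.0 and 0.0 <= u <= 1.0:
        return (x1 + t * (x2 - x1), y1 + t * (y2 - y1))
    return None


# ---------------------------------------------------------------------------
# sites

def generate_sites(config: CohortConfig, network, centres,
                   met_by_month, seed: int) -> pd.DataFrame:
    """Candidate home sites with true transfer sums and place labels.

    A handful of sites are placed right beside boosted intersections; the
    rest are uniform over the region.  ``place_id`` comes from a
    rectangular partition of the region (~1% of area per place).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    w, h = config.region_km
    n = config.n_sites
    # ordinary homes sit off the road (block-interior setback >= 50 m);
    # without it a random site can sit on a road axis and outrank the
    # intersection tail
    xy = _setback_sites(network, rng, n, w, h, setback_m=100.0)
    n_tail_sites = max(2, n // 60)
    tail_flag = np.zeros(n, dtype=bool)
    if config.intersection_tail_fraction == 0.0:
        centres = centres[:0]  # tail off: no housing hard against crossings
    if len(centres):
        # housing beside every major-major crossing (2 candidates each);
        # the busiest of these form the intersection tail, the rest a
        # near-tail continuum
        n_cand = min(2 * len(centres), max(2 * n_tail_sites, 8))
        picks = np.arange(n_cand) % len(centres)
        r = rng.uniform(0.025, 0.060, size=n_cand)  # 25-60 m
        ang = rng.uniform(0, 2 * np.pi, size=n_cand)
        offs = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        xy[:n_cand] = np.clip(centres[picks] + offs, 0, [w, h])
    spatial = network_spatial_sums(network, xy, met_by_month)
    crossing_flag = np.zeros(n, dtype=bool)
    if len(centres):
        crossing_flag[:n_cand] = True
        top = np.argsort(spatial[:n_cand])[-n_tail_sites:]
        tail_flag[top] = True
    gx, gy = config.place_grid
    px = np.minimum((xy[:, 0] / w * gx).astype(int), gx - 1)
    py = np.minimum((xy[:, 1] / h * gy).astype(int), gy - 1)
    return pd.DataFrame({
        "site_id": np.arange(n), "x": xy[:, 0], "y": xy[:, 1],
        "true_D": spatial, "place_id": px * gy + py,
        "tail_site": tail_flag, "crossing_site": crossing_flag,
    })


def _log_density_field(rng, sigma: float, n_waves: int, w: float, h: float):
    """Smooth random log-traffic-density surface (urbanisation gradient).

    A sum of random-direction cosines; the marginal is approximately
    N(0, sigma^2), so local traffic density is approximately lognormal
    across the region.
    """
    if sigma == 0 or n_waves == 0:
        return lambda x, y: np.zeros_like(np.asarray(x, dtype=float))
    ang = rng.uniform(0, 2 * np.pi, n_waves)
    freq = rng.uniform(0.5, 1.5, n_waves) * 2 * np.pi / max(w, h)
    phase = rng.uniform(0, 2 * np.pi, n_waves)
    amp = sigma * np.sqrt(2.0 / n_waves)

    def field(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape)
        for a, f, p in zip(ang, freq, phase):
            out = out + np.cos(f * (x * np.cos(a) + y * np.sin(a)) + p)
        return amp * out

    return field


def _setback_sites(network, rng, n, w, h, setback_m=50.0):
    """Rejection-sample site positions at least ``setback_m`` from roads."""
    from .dispersion import _segment_distance_m
    out = []
    need = n
    while need > 0:
        cand = rng.uniform([0, 0], [w, h], size=(max(2 * need, 50), 2))
        dmin = np.full(len(cand), np.inf)
        for seg in network:
            dmin = np.minimum(dmin, _segment_distance_m(
                seg, cand[:, 0], cand[:, 1]))
        ok = cand[dmin >= setback_m]
        out.append(ok[:need])
        need -= len(ok[:need])
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# cohort

def generate_cohort(config: CohortConfig, seed: int,
                    network=None, met_by_month=None,
                    eps: YearSeries | None = None,
                    traffic: YearSeries | None = None,
                    sites: pd.DataFrame | None = None
                    ) -> tuple[Cohort, TrueState]:
    """Generate the observable cohort and its hidden ground truth.

    Subjects receive birth and arrival years (a configured majority
    arriving after the boundary year), residence sequences drawn from the
    site library with income-biased site choice (which links covariates to
    exposure and enables MAR missingness), true D histories from the
    dispersion module, and case status from the logistic risk equation.
    Case-control age-frequency matching is emulated by giving the
    intercept an age-stratum offset that removes the marginal age-dose
    association.
    """
    ss = np.random.SeedSequence([seed, 303])
    rng = np.random.default_rng(ss)
    if met_by_month is None:
        met_by_month = default_met(config.n_met_months)
    if sites is None:
        if network is None:
            network, centres = generate_network(config, seed)
        else:
            centres = _major_crossings([])  # external network: no tail sites
        sites = generate_sites(config, network, centres, met_by_month, seed)
    eps = eps or default_emission_series(config.boundary_year,
                                         config.stop_year)
    traffic = traffic or default_traffic_series(config.boundary_year,
                                                config.stop_year)

    n = config.n_subjects
    b0, b1 = config.birth_year_range
    birth = rng.integers(b0, b1 + 1, size=n)
    late = rng.random(n) < config.late_arrival_fraction
    arrival = np.where(
        late,
        rng.integers(config.boundary_year + 1, config.stop_year + 1, size=n),
        np.maximum(birth, rng.integers(b0, config.boundary_year + 1, size=n)))
    arrival = np.maximum(arrival, birth)

    income = rng.normal(0.0, 1.0, size=n)
    education = (rng.random(n) < special.expit(0.8 * income)).astype(int)
    smoker = rng.integers(0, 2, size=n)

    n_tail = (max(1, int(round(config.intersection_tail_fraction * n)))
              if config.intersection_tail_fraction > 0 else 0)
    tail_ids = rng.choice(n, size=n_tail, replace=False)
    is_tail = np.zeros(n, dtype=bool)
    is_tail[tail_ids] = True
    # tail subjects are long-duration residents beside busy intersections;
    # highway-adjacent housing selects for low income, which lets the
    # covariate-conditioned imputation see the tail
    arrival = np.where(is_tail,
                       np.minimum(arrival, config.boundary_year + 10),
                       arrival)
    income[is_tail] = np.minimum(income[is_tail],
                                 rng.normal(-1.2, 0.4, size=n_tail))
    education = (rng.random(n) < special.expit(0.8 * income)).astype(int)

    subjects = pd.DataFrame({
        "subject_id": np.arange(n), "birth_year": birth,
        "arrival_year": arrival, "diagnosis_year": config.diagnosis_year,
        "cov_income": income, "cov_education": education,
        "cov_smoker": smoker,
    })
    subjects["age"] = config.diagnosis_year - subjects["birth_year"]

    residences, res_true_d = _residence_histories(
        config, subjects, sites, is_tail, rng)

    exposures = _true_exposures(config, subjects, residences, res_true_d,
                                eps, traffic)
    z = exposures.groupby("subject_id")["E"].sum().rename("z_true")
    z = z.reindex(subjects["subject_id"], fill_value=0.0).reset_index()

    case, p, beta, a0 = generate_outcomes(
        z["z_true"].to_numpy(), subjects["birth_year"].to_numpy(),
        config.case_fraction, config.true_beta_per_sd,
        int(rng.integers(2 ** 31)))
    subjects["case"] = case

    true_state = TrueState(
        residence_d=res_true_d, exposures=exposures,
        z_true=z, case_prob=pd.DataFrame(
            {"subject_id": subjects["subject_id"], "p": p}),
        beta=beta, intercept=a0, tail_subjects=np.flatnonzero(is_tail))
    cohort = Cohort(subjects=subjects, residences=residences, config=config)
    cohort.sites = sites
    return cohort, true_state


def _residence_histories(config, subjects, sites, is_tail, rng):
    """Residence intervals per subject; returns (residences, true_d_frame).

    In-area residences start at the arrival year; one out-of-area record
    covers birth to arrival.  Site choice is income-biased toward low-D
    sites, tying covariates to exposure.  Tail subjects occupy a single
    intersection-adjacent site for their whole in-area period.
    """
    order = np.argsort(sites["true_D"].to_numpy())  # ascending D
    sorted_sites = sites.iloc[order].reset_index(drop=True)
    n_sites = len(sorted_sites)
    tail_pool = sites.index[sites["tail_site"]].to_numpy()
    if "crossing_site" in sites.columns:
        ordinary_d = sites.loc[~sites["crossing_site"], "true_D"].to_numpy()
    else:
        ordinary_d = sites["true_D"].to_numpy()

    rows = []
    true_d = []
    rid = 0
    for s in subjects.itertuples():
        i = s.subject_id
        start = int(s.arrival_year)
        stop = config.stop_year + 1
        if start > config.stop_year:
            start = config.stop_year  # at least one in-area year
        if is_tail[i]:
            site = sites.loc[rng.choice(tail_pool)]
            rows.append(_res_row(rid, i, start, stop, site, True))
            true_d.append((rid, float(site["true_D"])))
            rid += 1
        else:
            y = start
            while y < stop:
                dur = 1 + rng.geometric(1.0 / config.mean_residence_years)
                end = min(y + dur, stop)
                pref = special.expit(
                    0.7 * s.cov_income + 1.2 * rng.standard_normal())
                idx = min(int(pref * n_sites), n_sites - 1)
                site = sorted_sites.iloc[idx]
                rows.append(_res_row(rid, i, y, end, site, True))
                true_d.append((rid, float(site["true_D"])))
                rid += 1
                y = end
        if s.birth_year < s.arrival_year:
            # out-of-area period before arrival; truth drawn from the
            # in-area *ordinary-housing* D distribution when configured to
            # match it (intersection-adjacent housing is a feature of the
            # study area, not of out-of-area environments)
            if config.out_of_area_like_in_area:
                d_out = float(ordinary_d[rng.integers(len(ordinary_d))])
            else:
                d_out = float(sites["true_D"].median()) * 0.5
            rows.append({
                "residence_id": rid, "subject_id": i,
                "start_year": int(s.birth_year),
                "end_year": int(s.arrival_year),
                "x": np.nan, "y": np.nan, "place_id": pd.NA,
                "geocode_status": "exact", "in_area": False, "D": np.nan,
            })
            true_d.append((rid, d_out))
            rid += 1
    residences = pd.DataFrame(rows)
    residences["place_id"] = residences["place_id"].astype("object")
    res_true_d = pd.DataFrame(true_d, columns=["residence_id", "true_D"])
    return residences, res_true_d


def _res_row(rid, sid, start, end, site, in_area):
    return {
        "residence_id": rid, "subject_id": sid,
        "start_year": int(start), "end_year": int(end),
        "x": float(site["x"]), "y": float(site["y"]),
        "place_id": int(site["place_id"]), "geocode_status": "exact",
        "in_area": in_area, "D": float(site["true_D"]),
    }


def _true_exposures(config, subjects, residences, res_true_d, eps, traffic):
    """True yearly exposures over the record period (boundary..stop)."""
    from .dose import expand_intervals, series_vector

    res = residences.merge(res_true_d, on="residence_id")
    y0 = np.maximum(res["start_year"].to_numpy(), config.boundary_year)
    y1 = np.minimum(res["end_year"].to_numpy(), config.stop_year + 1)
    idx, years = expand_intervals(y0, y1)
    e = series_vector(eps, config.boundary_year,
                      config.stop_year)[years - config.boundary_year]
    return pd.DataFrame({
        "subject_id": res["subject_id"].to_numpy()[idx], "year": years,
        "E": e * res["true_D"].to_numpy()[idx],
    })


def generate_outcomes(z_true: np.ndarray, birth_year: np.ndarray,
                      case_fraction: float, beta_per_sd: float,
                      seed: int) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Case statuses from the logistic risk equation.

    ``beta_per_sd`` is the log odds ratio per SD of true dose; the raw-
    scale coefficient is ``beta_per_sd / sd(Z)``.  The intercept A is
    solved by bisection so the expected case fraction hits the target, and
    an age-stratum offset emulates frequency matching of controls to the
    case age distribution (it removes the marginal dose-age gradient from
    the case probability).
    """
    z = np.asarray(z_true, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("doses must be finite")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    sd = z.std()
    beta = beta_per_sd / sd if sd > 0 else 0.0
    # age-stratum offsets: remove E[Z | age stratum] gradient
    strata = (np.asarray(birth_year) // 5) * 5
    offsets = np.zeros(len(z))
    for s in np.unique(strata):
        sel = strata == s
        offsets[sel] = -beta * (z[sel].mean() - z.mean())

    def mean_p(a):
        return special.expit(a + beta * z + offsets).mean() - case_fraction

    lo, hi = -30.0, 30.0
    if mean_p(lo) > 0 or mean_p(hi) < 0:
        raise ValueError("target case fraction unattainable")
    a0 = float(optimize.brentq(mean_p, lo, hi, xtol=1e-10))
    p = special.expit(a0 + beta * z + offsets)
    case = (rng.random(len(z)) < p).astype(int)
    return case, p, beta, a0


# ---------------------------------------------------------------------------
# missingness

def geocode_success(year: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Geocoding success probability by calendar year (logistic curve
    anchored at the configured boundary-year success rate)."""
    anchor = special.logit(config.geocode_success_boundary)
    x = anchor + (np.asarray(year, dtype=float) - config.boundary_year) \
        / config.geocode_scale_years
    return special.expit(x)


def apply_missingness(cohort: Cohort, seed: int,
                      config: CohortConfig | None = None) -> Cohort:
    """Mask residence locations/D values interview-style.

    Masking probability per in-area residence follows the geocoding-
    success curve evaluated at the residence start year (MCAR mode uses a
    flat rate instead); under MAR it also shifts with the education
    covariate -- never with D or case status.  Among masked residences the
    configured share retains the place label (``place_only``), the rest
    become ``unknown``.
    """
    config = config or cohort.config
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    res = cohort.residences.copy()
    sub = cohort.subjects.set_index("subject_id")
    in_area = res["in_area"].to_numpy()
    years = res["start_year"].to_numpy()
    if config.missingness == "MCAR":
        p_miss = np.full(len(res), config.mcar_rate)
    else:
        logit_fail = special.logit(
            np.clip(1.0 - geocode_success(years, config), 1e-9, 1 - 1e-9))
        edu = sub.loc[res["subject_id"], "cov_education"].to_numpy(float)
        shift = config.mar_covariate_effect * (edu - edu.mean())
        p_miss = special.expit(logit_fail - shift)
    masked = (rng.random(len(res)) < p_miss) & in_area
    keep_place = rng.random(len(res)) < config.place_retention

    if masked.any():
        res.loc[masked, "D"] = np.nan
        res.loc[masked, ["x", "y"]] = np.nan
        res.loc[masked & keep_place, "geocode_status"] = "place_only"
        res.loc[masked & ~keep_place, "geocode_status"] = "unknown"
        res["place_id"] = res["place_id"].astype("object")
        res.loc[masked & ~keep_place, "place_id"] = pd.NA
    out = Cohort(subjects=cohort.subjects.copy(), residences=res,
                 config=config)
    if hasattr(cohort, "sites"):
        out.sites = cohort.sites
    return out
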