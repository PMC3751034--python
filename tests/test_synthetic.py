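"""Synthetic generator contracts: rates, matching, tail, determinism."""

import dataclasses
import inspect

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lifedose
from lifedose.synthetic import (CohortConfig, Cohort, apply_missingness,
                                default_met, generate_cohort,
                                generate_network, generate_outcomes,
                                generate_sites, geocode_success)

SMALL = CohortConfig(n_subjects=5000, n_sites=80, minor_spacing_km=3.0,
                     n_major_roads=4, region_km=(12.0, 12.0))


@pytest.fixture(scope="module")
def small_sites():
    net, cen = generate_network(SMALL, 7)
    return net, cen, generate_sites(SMALL, net, cen, default_met(1), 7)


class TestNetwork:
    def test_same_seed_identical(self):
        a, _ = generate_network(SMALL, 3)
        b, _ = generate_network(SMALL, 3)
        assert [dataclasses.astuple(s) for s in a] \
            == [dataclasses.astuple(s) for s in b]

    def test_boost_one_config_has_no_intersection_effect(self):
        cfg = dataclasses.replace(SMALL, intersection_boost=1.0)
        net, _ = generate_network(cfg, 3)
        assert all(s.intersection_boost == 1.0 for s in net)

    def test_intersection_zone_density(self):
        # generator contract: at least one zone per 10 km^2 worth of
        # major-road crossings on the default-shaped network
        cfg = CohortConfig(n_subjects=50, region_km=(20.0, 20.0))
        net, centres = generate_network(cfg, 11)
        assert len(centres) >= 20.0 * 20.0 / 10.0 / 4  # sparse majors
        assert any(s.intersection_boost > 1.0 for s in net)

    def test_boosted_segments_near_crossings_only(self):
        net, centres = generate_network(SMALL, 5)
        zone = SMALL.intersection_zone_m / 1000.0
        for s in net:
            if s.intersection_boost > 1.0:
                mx, my = 0.5 * (s.x1 + s.x2), 0.5 * (s.y1 + s.y2)
                d = np.min(np.hypot(centres[:, 0] - mx,
                                    centres[:, 1] - my))
                assert d <= zone + 1e-9


class TestCohort:
    def test_arrival_fraction_within_3pct(self, small_sites):
        *_, sites = small_sites
        cohort, _ = generate_cohort(SMALL, 21, sites=sites)
        late = (cohort.subjects["arrival_year"]
                > SMALL.boundary_year).mean()
        assert late == pytest.approx(SMALL.late_arrival_fraction, abs=0.03)

    def test_frequency_matched_age_distributions(self, small_sites):
        *_, sites = small_sites
        cohort, _ = generate_cohort(SMALL, 22, sites=sites)
        cases = cohort.subjects.loc[cohort.subjects["case"] == 1, "age"]
        controls = cohort.subjects.loc[cohort.subjects["case"] == 0, "age"]
        assert stats.ks_2samp(cases, controls).pvalue > 0.01

    def test_same_seed_identical_cohort(self, small_sites):
        *_, sites = small_sites
        a, _ = generate_cohort(SMALL, 23, sites=sites)
        b, _ = generate_cohort(SMALL, 23, sites=sites)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
        pd.testing.assert_frame_equal(a.residences, b.residences)

    def test_residence_intervals_ordered_disjoint(self, small_sites):
        *_, sites = small_sites
        cohort, _ = generate_cohort(SMALL, 24, sites=sites)
        res = cohort.residences
        assert (res["end_year"] > res["start_year"]).all()
        for _, grp in res[res["in_area"]].groupby("subject_id"):
            g = grp.sort_values("start_year")
            assert (g["start_year"].to_numpy()[1:]
                    >= g["end_year"].to_numpy()[:-1]).all()

    def test_tail_subjects_dominate_true_dose(self, study):
        truth = study["truth"]
        z = truth.z_true.set_index("subject_id")["z_true"]
        q99 = z.quantile(0.99)
        share = np.mean(z.loc[truth.tail_subjects] >= q99)
        assert share >= 0.9

    def test_true_dose_right_skewed_with_tail(self, study):
        z = study["truth"].z_true["z_true"]
        assert stats.skew(z) > 2.0

    def test_dose_lognormal_with_tail_off(self):
        cfg = dataclasses.replace(
            SMALL, n_subjects=1000, intersection_tail_fraction=0.0,
            intersection_boost=1.0)
        net, cen = generate_network(cfg, 31)
        sites = generate_sites(cfg, net, cen, default_met(1), 31)
        _, truth = generate_cohort(cfg, 31, sites=sites)
        d = sites["true_D"].to_numpy()
        sh, loc, sc = stats.lognorm.fit(d, floc=0)
        assert stats.kstest(d, "lognorm", args=(sh, loc, sc)).pvalue > 0.01


class TestOutcomes:
    def test_case_fraction_hit_by_bisection(self, rng):
        z = rng.lognormal(0, 1, 4000)
        birth = rng.integers(1920, 1955, 4000)
        case, p, beta, a0 = generate_outcomes(z, birth, 0.4, np.log(1.5), 9)
        assert p.mean() == pytest.approx(0.4, abs=1e-6)
        assert case.mean() == pytest.approx(0.4, abs=0.03)

    def test_null_beta_breaks_dose_outcome_link(self, rng):
        z = rng.lognormal(0, 1, 3000)
        birth = rng.integers(1920, 1955, 3000)
        case, *_ = generate_outcomes(z, birth, 0.5, 0.0, 10)
        quartile = pd.qcut(z, 4, labels=False)
        table = pd.crosstab(quartile, case).to_numpy()
        _, p, *_ = stats.chi2_contingency(table)[:2], None, None
        stat, pval, *_ = stats.chi2_contingency(table)
        assert pval > 0.001

    def test_large_beta_puts_top_decile_in_cases(self, rng):
        z = rng.lognormal(0, 1, 3000)
        birth = rng.integers(1920, 1955, 3000)
        case, *_ = generate_outcomes(z, birth, 0.5, 8.0, 11)
        top = z >= np.quantile(z, 0.9)
        assert case[top].mean() > 0.95

    def test_fixed_seed_identical_outcomes(self, rng):
        z = rng.lognormal(0, 1, 500)
        birth = rng.integers(1920, 1955, 500)
        a = generate_outcomes(z, birth, 0.5, np.log(1.5), 12)[0]
        b = generate_outcomes(z, birth, 0.5, np.log(1.5), 12)[0]
        assert (a == b).all()

    def test_unattainable_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_outcomes(np.array([np.inf, 1.0]),
                              np.array([1940, 1950]), 0.5, 1.0, 1)


class TestMissingness:
    def boundary_cohort(self, n=5000):
        """All in-area residences start at the boundary year."""
        rng = np.random.default_rng(3)
        subjects = pd.DataFrame({
            "subject_id": np.arange(n), "case": rng.integers(0, 2, n),
            "birth_year": 1940, "arrival_year": 1960,
            "diagnosis_year": 1996, "age": 56,
            "cov_income": rng.normal(0, 1, n),
            "cov_education": rng.integers(0, 2, n),
            "cov_smoker": rng.integers(0, 2, n),
        })
        residences = pd.DataFrame({
            "residence_id": np.arange(n), "subject_id": np.arange(n),
            "start_year": 1960, "end_year": 1996,
            "x": 1.0, "y": 1.0, "place_id": 0,
            "geocode_status": "exact", "in_area": True, "D": 1.0,
        })
        return Cohort(subjects=subjects, residences=residences,
                      config=CohortConfig(n_subjects=n))

    def test_boundary_year_masking_near_35pct(self):
        cohort = self.boundary_cohort()
        masked = apply_missingness(cohort, 17)
        rate = masked.residences["D"].isna().mean()
        assert rate == pytest.approx(0.35, abs=0.03)

    def test_place_retention_near_80pct(self):
        cohort = self.boundary_cohort()
        masked = apply_missingness(cohort, 18)
        m = masked.residences[masked.residences["D"].isna()]
        retained = (m["geocode_status"] == "place_only").mean()
        assert retained == pytest.approx(0.80, abs=0.03)
        assert m.loc[m["geocode_status"] == "unknown", "place_id"] \
            .isna().all()

    def test_zero_masking_leaves_cohort_unchanged(self):
        cohort = self.boundary_cohort(n=200)
        cfg = dataclasses.replace(cohort.config, missingness="MCAR",
                                  mcar_rate=0.0)
        masked = apply_missingness(cohort, 19, config=cfg)
        pd.testing.assert_frame_equal(masked.residences, cohort.residences)

    def test_geocode_curve_anchored_at_boundary(self):
        cfg = CohortConfig(n_subjects=50)
        assert geocode_success(np.array([1960]), cfg)[0] \
            == pytest.approx(0.65)
        curve = geocode_success(np.arange(1920, 1996), cfg)
        assert (np.diff(curve) > 0).all()

    def test_mar_depends_on_covariates_not_dose(self):
        cohort = self.boundary_cohort()
        masked = apply_missingness(cohort, 20)
        merged = masked.residences.merge(cohort.subjects, on="subject_id")
        rate_by_edu = merged.groupby("cov_education")["D"] \
            .apply(lambda s: s.isna().mean())
        assert rate_by_edu[0] > rate_by_edu[1]  # educated recall better


class TestTrueStateIsolation:
    def test_estimation_modules_never_touch_truth(self):
        estimation = ["dispersion", "dose", "surrogates", "imputation",
                      "diagnostics", "risk", "pipeline", "io", "cli"]
        for name in estimation:
            src = inspect.getsource(getattr(lifedose, name) if name != "cli"
                                    else __import__("lifedose.cli",
                                                    fromlist=["cli"]))
            assert "TrueState" not in src, name
            assert "true_D" not in src, name
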