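"""Effective-dose accumulation under the four effectiveness forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lifedose.dose import (DoseWarning, EffectiveDose, EffectivenessModel,
                           IMPUTED_IN_AREA, MODELED, YearSeries,
                           annual_exposure, b_weight, cohort_effective_doses,
                           effective_dose, expand_intervals, normalize_doses)


def series(values, provenance=None, start=1960):
    years = np.arange(start, start + len(values))
    prov = provenance or [MODELED] * len(values)
    return pd.DataFrame({"year": years, "E": values, "provenance": prov})


class TestBWeight:
    def test_constant_form_is_one(self):
        m = EffectivenessModel(form="B1")
        assert b_weight(m, 3, 50) == 1.0
        assert b_weight(m, 50, 50) == 1.0

    def test_inverse_square_onset_age(self):
        m = EffectivenessModel(form="B2", reference_age=40.0)
        assert b_weight(m, 10, 40) == 1.0
        assert b_weight(m, 10, 80) == pytest.approx(0.25)

    def test_b2_rejects_zero_onset(self):
        with pytest.raises(ValueError):
            b_weight(EffectivenessModel(form="B2"), 0, 0)

    def test_promoter_window_k1_final_year_only(self):
        m = EffectivenessModel(form="B4", promoter_window=1)
        assert b_weight(m, 50, 50, age_at_stop=50) == 1.0
        assert b_weight(m, 49, 50, age_at_stop=50) == 0.0

    def test_invalid_forms_rejected(self):
        with pytest.raises(ValueError):
            EffectivenessModel(form="B5")
        with pytest.raises(ValueError):
            EffectivenessModel(latency=-1)
        with pytest.raises(ValueError):
            EffectivenessModel(promoter_window=0)


class TestAnnualExposure:
    def test_product_decomposition(self):
        assert annual_exposure(2.0, 3.0, 0.5) == pytest.approx(3.0)

    @pytest.mark.parametrize("eps,t,d", [(0, 1, 1), (1, 0, 1), (1, 1, 0)])
    def test_any_zero_factor_nulls(self, eps, t, d):
        assert annual_exposure(eps, t, d) == 0.0

    def test_linearity_in_traffic(self):
        assert annual_exposure(1.5, 4.0, 0.2) == pytest.approx(
            2.0 * annual_exposure(1.5, 2.0, 0.2))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            annual_exposure(-1.0, 1.0, 1.0)


class TestEffectiveDose:
    def test_flat_sum_under_b1(self):
        s = series([2.0] * 10)
        d = effective_dose(s, EffectivenessModel("B1"), 1950, 1996)
        assert d.z_total == pytest.approx(20.0)

    def test_b3_takes_peak_annual_exposure(self):
        s = series([1.0, 3.0, 2.0])
        d = effective_dose(s, EffectivenessModel("B3"), 1950, 1996)
        assert d.z_total == pytest.approx(3.0)

    def test_mixed_provenance_partition(self):
        s = series([1, 1, 1, 2, 2],
                   [MODELED] * 3 + [IMPUTED_IN_AREA] * 2)
        d = effective_dose(s, EffectivenessModel("B1"), 1950, 1996)
        assert (d.z_calc, d.z_imp, d.z_total) == (3.0, 4.0, 7.0)

    def test_b3_peak_provenance_decides_split(self):
        s = series([1.0, 5.0, 2.0], [MODELED, IMPUTED_IN_AREA, MODELED])
        d = effective_dose(s, EffectivenessModel("B3"), 1950, 1996)
        assert d.z_imp == 5.0 and d.z_calc == 0.0

    def test_latency_excludes_recent_years(self):
        s = series([1.0] * 10, start=1986)  # covers 1986-1995
        m = EffectivenessModel("B1", latency=5)
        d = effective_dose(s, m, 1950, 1996, stop_year=1995)
        assert d.z_total == pytest.approx(5.0)  # only 1986-1990

    def test_latency_longer_than_span_zeroes_dose(self):
        s = series([1.0] * 10, start=1986)
        m = EffectivenessModel("B1", latency=50)
        with pytest.warns(DoseWarning):
            d = effective_dose(s, m, 1950, 1996, stop_year=1995)
        assert d.z_total == 0.0

    def test_empty_series_warns_and_zeroes(self):
        with pytest.warns(DoseWarning):
            d = effective_dose(series([]), EffectivenessModel("B1"),
                               1950, 1996)
        assert d.z_total == 0.0

    def test_split_invariant_enforced(self):
        with pytest.raises(ValueError):
            EffectiveDose("s", "B1", 5.0, 1.0, 1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0, 100.0), min_size=1, max_size=30))
    def test_b1_equals_direct_sum_and_b3_the_max(self, values):
        s = series(values)
        d1 = effective_dose(s, EffectivenessModel("B1"), 1950, 1996)
        d3 = effective_dose(s, EffectivenessModel("B3"), 1950, 1996)
        assert d1.z_total == pytest.approx(sum(values), rel=1e-9, abs=1e-9)
        assert d3.z_total == pytest.approx(max(values), rel=1e-9, abs=1e-9)


class TestCohortEffectiveDoses:
    @pytest.mark.parametrize("form", ["B1", "B2", "B3", "B4"])
    def test_matches_per_subject_oracle(self, form, rng):
        subjects = pd.DataFrame({
            "subject_id": np.arange(8),
            "birth_year": rng.integers(1920, 1950, 8),
            "diagnosis_year": 1996,
        })
        rows = []
        for sid in range(8):
            years = np.arange(1960, 1996)
            rows.append(pd.DataFrame({
                "subject_id": sid, "year": years,
                "E": rng.gamma(2.0, 1.0, len(years)),
                "provenance": rng.choice([MODELED, IMPUTED_IN_AREA],
                                         len(years)),
            }))
        exposures = pd.concat(rows, ignore_index=True)
        model = EffectivenessModel(form, latency=3, promoter_window=2,
                                   reference_age=55.0)
        table = cohort_effective_doses(exposures, subjects, model,
                                       stop_year=1995)
        for sid in range(8):
            ss = exposures[exposures["subject_id"] == sid]
            expected = effective_dose(
                ss, model, int(subjects["birth_year"][sid]), 1996,
                stop_year=1995)
            row = table[table["subject_id"] == sid].iloc[0]
            assert row["z_total"] == pytest.approx(expected.z_total,
                                                   rel=1e-9)
            assert row["z_imp"] == pytest.approx(expected.z_imp, rel=1e-9)

    def test_subject_without_exposures_gets_zero(self):
        subjects = pd.DataFrame({"subject_id": [0, 1],
                                 "birth_year": [1940, 1940],
                                 "diagnosis_year": [1996, 1996]})
        exposures = series([1.0, 2.0]).assign(subject_id=0)
        table = cohort_effective_doses(exposures, subjects,
                                       EffectivenessModel("B1"))
        assert table.loc[table["subject_id"] == 1, "z_total"].iloc[0] == 0.0


class TestNormalizeDoses:
    def test_reference_mean_maps_to_one(self):
        doses = pd.DataFrame({"subject_id": [0, 1],
                              "z_total": [4.0, 8.0],
                              "z_calc": [4.0, 6.0], "z_imp": [0.0, 2.0]})
        ref = np.array([2.0, 6.0])  # mean 4
        out = normalize_doses(doses, ref)
        assert out["z_total"].tolist() == [1.0, 2.0]

    def test_ratios_and_split_preserved(self):
        doses = pd.DataFrame({"subject_id": [0, 1],
                              "z_total": [4.0, 8.0],
                              "z_calc": [1.0, 8.0], "z_imp": [3.0, 0.0]})
        out = normalize_doses(doses, np.array([5.0]))
        assert (out["z_total"][0] / out["z_total"][1]
                == pytest.approx(0.5))
        pdi = 100 * out["z_imp"] / (out["z_imp"] + out["z_calc"])
        assert pdi[0] == pytest.approx(75.0)

    def test_renormalizing_is_idempotent(self):
        doses = pd.DataFrame({"subject_id": [0], "z_total": [3.0],
                              "z_calc": [3.0], "z_imp": [0.0]})
        once = normalize_doses(doses, np.array([3.0]))
        twice = normalize_doses(once, np.array([1.0]))
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            normalize_doses(pd.DataFrame({"z_total": [1.0]}),
                            np.array([0.0]))


class TestYearSeries:
    def test_constant_extension_below_boundary(self):
        s = YearSeries({1960: 2.0, 1961: 3.0}, boundary_year=1960)
        assert s[1900] == 2.0
        assert s[1961] == 3.0

    def test_missing_year_raises(self):
        with pytest.raises(KeyError):
            YearSeries({1960: 1.0})[1970]

    def test_positive_values_required(self):
        with pytest.raises(ValueError):
            YearSeries({1960: 0.0})


def test_expand_intervals_round_trip():
    idx, years = expand_intervals(np.array([1960, 1990]),
                                  np.array([1963, 1990]))
    assert idx.tolist() == [0, 0, 0]
    assert years.tolist() == [1960, 1961, 1962]
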