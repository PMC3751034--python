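"""PDI/PTI indices, strata tables, chi-square, correlations, tail plots."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lifedose.diagnostics import (arrival_dependency,
                                  chi_square_independence, compute_pdi_pti,
                                  dose_correlations, pdi_bin_index,
                                  pdi_frame, pdi_strata_table,
                                  tail_diagnostics)

# Reference strata counts (serialization round-trip fixture):
# controls and cases by incompleteness stratum, totals 1518/1468/2986.
STRATA_COUNTS = np.array([[267, 280], [336, 281], [164, 149],
                          [150, 137], [136, 151], [465, 470]])


def brute_force_pearson_chi2(table):
    """Direct-formula oracle: explicit loops, python floats."""
    rows = len(table)
    cols = len(table[0])
    total = float(sum(sum(r) for r in table))
    row_sums = [float(sum(r)) for r in table]
    col_sums = [float(sum(table[i][j] for i in range(rows)))
                for j in range(cols)]
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            e = row_sums[i] * col_sums[j] / total
            stat += (table[i][j] - e) ** 2 / e
    return stat


class TestPdi:
    def test_complete_case_has_zero_pdi(self):
        assert compute_pdi_pti(5.0, 0.0, 0, 10)["pdi"] == 0.0

    def test_quarter_imputed(self):
        assert compute_pdi_pti(3.0, 1.0, 2, 10)["pdi"] == pytest.approx(25.0)

    def test_pti_diverges_from_pdi(self):
        # 4 tiny imputed years among 16: PTI = 25 while PDI is small
        rec = compute_pdi_pti(16.0, 0.04, 4, 16)
        assert rec["pti"] == pytest.approx(25.0)
        assert rec["pdi"] < 1.0

    def test_degenerate_both_zero_flagged(self):
        rec = compute_pdi_pti(0.0, 0.0, 0, 5)
        assert rec["pdi"] == 100.0 and rec["degenerate"]

    def test_frame_bounds_and_equivalences(self, rng):
        doses = pd.DataFrame({
            "subject_id": np.arange(50),
            "z_calc": rng.gamma(2, 1, 50) * (rng.random(50) > 0.2),
            "z_imp": rng.gamma(2, 1, 50) * (rng.random(50) > 0.5),
        })
        out = pdi_frame(doses)
        assert out["pdi"].between(0, 100).all()
        zero = out["pdi"] == 0
        assert (zero == ((doses["z_imp"] == 0)
                         & (doses["z_calc"] > 0))).all()
        hundred = (out["pdi"] == 100) & ~out["degenerate"]
        assert (doses.loc[hundred, "z_calc"] == 0).all()


class TestStrataTable:
    def test_bin_edges_half_open_with_zero_stratum(self):
        pdi = np.array([0.0, 10.0, 20.0, 39.9, 40.0, 80.0, 100.0])
        assert pdi_bin_index(pdi).tolist() == [0, 1, 2, 2, 3, 5, 5]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pdi_bin_index(np.array([101.0]))

    def test_all_zero_pdi_in_first_bin(self):
        table = pdi_strata_table(np.zeros(30), np.tile([0, 1], 15))
        assert table["total"].iloc[0] == 30
        assert table["total"].iloc[1:].sum() == 0

    def test_published_counts_round_trip(self, tmp_path):
        table = pd.DataFrame({
            "stratum": [f"s{i}" for i in range(6)],
            "controls": STRATA_COUNTS[:, 0],
            "cases": STRATA_COUNTS[:, 1]})
        table["total"] = table["controls"] + table["cases"]
        assert table["controls"].sum() == 1518
        assert table["cases"].sum() == 1468
        assert table["total"].sum() == 2986
        path = tmp_path / "strata.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, table)


class TestChiSquare:
    def test_proportional_table_is_exact_independence(self):
        stat, df, p = chi_square_independence([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_2x2_matches_hand_oracle(self):
        table = [[10, 20], [20, 10]]
        stat, df, p = chi_square_independence(table)
        assert stat == pytest.approx(brute_force_pearson_chi2(table),
                                     abs=1e-12)
        assert df == 1

    def test_published_6x2_counts_match_oracle_and_scipy(self):
        stat, df, p = chi_square_independence(STRATA_COUNTS)
        assert stat == pytest.approx(brute_force_pearson_chi2(STRATA_COUNTS),
                                     abs=1e-10)
        s2, p2, df2, _ = stats.chi2_contingency(STRATA_COUNTS,
                                                correction=False)
        assert stat == pytest.approx(s2, rel=1e-12)
        assert p == pytest.approx(p2, rel=1e-9)
        assert df == df2 == 5

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [5, 5]])


class TestDoseCorrelations:
    def make(self, rng, n=30):
        b1 = pd.DataFrame({"subject_id": np.arange(n),
                           "z_total": rng.gamma(2, 1, n)})
        return b1

    def test_self_correlation_is_unity_at_every_cap(self, rng):
        b1 = self.make(rng)
        pdi = pd.DataFrame({"subject_id": b1["subject_id"],
                            "pdi": rng.uniform(0, 100, len(b1))})
        pdi.loc[:5, "pdi"] = 0.0
        out = dose_correlations({"B1": b1}, pdi)
        assert np.allclose(out["pearson"].dropna(), 1.0)
        assert np.allclose(out["spearman"].dropna(), 1.0)

    def test_proportional_variants_fully_correlated(self, rng):
        # constant exposure over time: peak is proportional to the sum
        b1 = self.make(rng)
        b3 = b1.assign(z_total=b1["z_total"] / 10.0)
        pdi = pd.DataFrame({"subject_id": b1["subject_id"], "pdi": 0.0})
        out = dose_correlations({"B1": b1, "B3": b3}, pdi)
        b3_rows = out[out["form"] == "B3"]
        assert np.allclose(b3_rows["pearson"], 1.0)

    def test_five_subject_fixture_matches_covariance_oracle(self):
        b1 = pd.DataFrame({"subject_id": range(5),
                           "z_total": [1.0, 2.0, 4.0, 3.0, 10.0]})
        b4 = pd.DataFrame({"subject_id": range(5),
                           "z_total": [0.5, 1.0, 1.0, 2.0, 4.0]})
        pdi = pd.DataFrame({"subject_id": range(5), "pdi": 0.0})
        out = dose_correlations({"B1": b1, "B4": b4}, pdi, caps=(100.0,))
        x = np.array([0.5, 1.0, 1.0, 2.0, 4.0])
        y = np.array([1.0, 2.0, 4.0, 3.0, 10.0])
        r = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        got = out.loc[out["form"] == "B4", "pearson"].iloc[0]
        assert got == pytest.approx(r, rel=1e-10)

    def test_constant_vector_reported_absent(self):
        b1 = pd.DataFrame({"subject_id": range(5), "z_total": 2.0})
        pdi = pd.DataFrame({"subject_id": range(5), "pdi": 0.0})
        out = dose_correlations({"B1": b1}, pdi, caps=(100.0,))
        assert np.isnan(out["pearson"]).all()


class TestArrivalDependency:
    def test_all_arrive_at_birth_correlations_identical(self, rng):
        n = 40
        subjects = pd.DataFrame({"subject_id": np.arange(n),
                                 "arrival_year": rng.integers(1930, 1960,
                                                              n)})
        z = rng.gamma(2, 1, n)
        doses = pd.DataFrame({"subject_id": np.arange(n), "z_calc": z,
                              "z_imp": 0.0, "z_total": z})
        out = arrival_dependency(subjects, doses)
        assert out["corr_z_calc"] == pytest.approx(out["corr_z_total"])

    def test_degenerate_inputs_reported_absent(self):
        subjects = pd.DataFrame({"subject_id": [0, 1],
                                 "arrival_year": [1970, 1970]})
        doses = pd.DataFrame({"subject_id": [0, 1], "z_calc": [1.0, 2.0],
                              "z_imp": [0.0, 0.0], "z_total": [1.0, 2.0]})
        out = arrival_dependency(subjects, doses)
        assert np.isnan(out["corr_z_calc"])

    def test_binned_means_by_decade(self, rng):
        subjects = pd.DataFrame({"subject_id": np.arange(20),
                                 "arrival_year": ([1955] * 10
                                                  + [1975] * 10)})
        doses = pd.DataFrame({"subject_id": np.arange(20),
                              "z_calc": [2.0] * 10 + [1.0] * 10,
                              "z_imp": 0.0,
                              "z_total": [2.0] * 10 + [1.0] * 10})
        out = arrival_dependency(subjects, doses)
        means = out["binned_means"].set_index("decade")["z_calc"]
        assert means.loc[1950] == pytest.approx(2.0)
        assert means.loc[1970] == pytest.approx(1.0)


class TestTailDiagnostics:
    def test_lognormal_sample_calibrated_band(self):
        # expected outside-share is alpha; correlated order statistics make
        # single-sample shares small and clumpy, so average over samples
        shares = []
        for k in range(60):
            x = np.random.default_rng(k).lognormal(0, 1, 400)
            t = tail_diagnostics(x)
            shares.append(t.attrs["share_above_band"]
                          + t["below_band"].mean())
        assert np.mean(shares) < 0.12

    def test_heavy_tail_flagged_at_top(self, rng):
        x = rng.lognormal(0, 0.5, 980)
        x = np.concatenate([x, np.exp(rng.normal(3.5, 0.3, 20))])
        t = tail_diagnostics(x)
        assert t.tail(20)["above_band"].all()

    def test_nonpositive_doses_excluded_and_counted(self, rng):
        x = np.concatenate([rng.lognormal(0, 1, 50), [0.0, -1.0]])
        t = tail_diagnostics(x)
        assert t.attrs["n_excluded_nonpositive"] == 2
        assert len(t) == 50

    def test_minimum_sample_size(self, rng):
        with pytest.raises(ValueError):
            tail_diagnostics(rng.lognormal(0, 1, 10))
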