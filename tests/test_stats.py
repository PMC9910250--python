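"""Comparison engines: closed-form oracles, degenerate paths, test-selection
behaviour, and Monte-Carlo properties of planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from sleepfbn import (
    compare_categorical,
    compare_independent,
    compare_longitudinal,
    compare_paired,
    percent_change,
    simulate_volumes,
    volume_region_analysis,
)
from sleepfbn.errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
    PairingError,
)


def long_table(values):
    """subjects x timepoints matrix -> long-format frame."""
    n, k = values.shape
    return pd.DataFrame({
        "subject_id": np.repeat([f"S{i}" for i in range(n)], k),
        "timepoint": np.tile([f"T{j}" for j in range(k)], n),
        "value": values.ravel(),
    })


class TestIndependent:
    def test_identical_samples_null(self):
        res = compare_independent([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_matches_pooled_variance_formula(self):
        a = np.array([12.1, 14.3, 11.8, 15.2, 13.0, 12.6])
        b = np.array([10.4, 11.9, 9.8, 12.2, 10.9])
        res = compare_independent(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p_oracle = 2 * ss.t.sf(abs(t_oracle), na + nb - 2)
        assert res.test_used.startswith("Student's t")
        assert res.statistic == pytest.approx(t_oracle, abs=1e-9)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-9)

    def test_nonnormal_data_routed_to_mann_whitney(self):
        rng = np.random.default_rng(0)
        a = np.exp(rng.normal(size=40) * 2)  # heavy-tailed
        b = np.exp(rng.normal(size=40) * 2)
        res = compare_independent(a, b)
        assert res.test_used == "Mann–Whitney U"
        assert "(" in res.descriptives[0]["summary"]  # median (Q1–Q3) style

    def test_degenerate_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            compare_independent([3.0, 3.0, 3.0], [3.0, 3.0])
        with pytest.raises(InsufficientDataError):
            compare_independent([1.0], [1.0, 2.0])

    def test_selection_is_deterministic(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=15), rng.normal(size=10)
        r1, r2 = compare_independent(a, b), compare_independent(a, b)
        assert r1.test_used == r2.test_used
        assert r1.p_value == r2.p_value

    def test_t_and_mwu_agree_for_large_normal_samples(self):
        """Decisions agree on >= 95% of 500 null simulations at large n."""
        rng = np.random.default_rng(2)
        agree = 0
        for _ in range(500):
            a, b = rng.normal(size=60), rng.normal(size=60)
            t_sig = ss.ttest_ind(a, b).pvalue < 0.05
            u_sig = ss.mannwhitneyu(a, b, alternative="two-sided").pvalue < 0.05
            agree += t_sig == u_sig
        assert agree / 500 >= 0.95

    def test_monotone_p_value_in_effect_size(self):
        """Median p over 200 shared seeds never increases with the planted shift."""
        shifts = [0.0, 0.5, 1.0, 1.5]
        medians = []
        for shift in shifts:
            ps = []
            for seed in range(200):
                rng = np.random.default_rng(seed)
                a = rng.normal(shift, 1, size=15)
                b = rng.normal(0, 1, size=10)
                ps.append(compare_independent(a, b).p_value)
            medians.append(np.median(ps))
        assert all(m1 >= m2 for m1, m2 in zip(medians, medians[1:]))


class TestPaired:
    def test_matches_closed_form_paired_t(self):
        before = np.array([10.0, 12.5, 9.8, 14.1, 11.3, 13.2, 10.9])
        after = np.array([11.2, 13.1, 10.9, 15.4, 11.1, 14.8, 12.0])
        res = compare_paired(before, after)
        diff = after - before
        t_oracle = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        assert res.test_used == "Student's t (paired)"
        assert res.statistic == pytest.approx(t_oracle, abs=1e-9)

    def test_constant_shift_is_degenerate(self):
        before = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(DegenerateDataError):
            compare_paired(before, before + 2.0)

    def test_zero_differences_are_degenerate(self):
        with pytest.raises(DegenerateDataError):
            compare_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_paired([1.0, 2.0], [1.0, 2.0, 3.0])


class TestLongitudinal:
    def test_two_timepoints_reduce_to_paired_t(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(50, 10, size=(14, 1)) + rng.normal(0, 3, size=(14, 2))
        res = compare_longitudinal(long_table(vals))
        paired = compare_paired(vals[:, 0], vals[:, 1])
        assert res.statistic == pytest.approx(paired.statistic**2, abs=1e-6)
        assert res.p_value == pytest.approx(paired.p_value, abs=1e-6)

    def test_planted_time_effect_detected(self):
        """A 1.5-within-SD monotone time trend at n = 14: power > 0.9 (500 seeds)."""
        hits = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            trend = np.linspace(0, 1.5, 5)  # in units of within-subject SD 1
            vals = rng.normal(0, 1, size=(14, 1)) + trend + rng.normal(0, 1, size=(14, 5))
            hits += compare_longitudinal(long_table(vals)).p_value < 0.05
        assert hits / 500 > 0.9

    def test_incomplete_subjects_dropped(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(6, 3))
        df = long_table(vals)
        df = df.drop(df[(df.subject_id == "S0") & (df.timepoint == "T2")].index)
        res = compare_longitudinal(df)
        assert res.n == (5,)

    def test_insufficient_subjects_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(InsufficientDataError):
            compare_longitudinal(long_table(rng.normal(size=(2, 4))))


class TestCategorical:
    def test_perfect_homogeneity(self):
        res = compare_categorical([[5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_sum_of_squares_oracle(self):
        t = np.array([[12, 8], [6, 14]])
        res = compare_categorical(t)
        expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
        chi2_oracle = ((t - expected) ** 2 / expected).sum()
        assert res.test_used == "chi-squared"
        assert res.statistic == pytest.approx(chi2_oracle, abs=1e-9)

    def test_small_expected_cells_use_fisher(self):
        res = compare_categorical([[2, 8], [7, 3]])
        assert res.test_used == "Fisher's exact"

    def test_zero_row_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_categorical([[0, 0], [5, 5]])
        with pytest.raises(InvalidInputError):
            compare_categorical(np.empty((0, 2)))


class TestPercentChange:
    def test_reference_total_volume_change(self):
        """The published whole-gray-matter means give a 1.51% increase."""
        assert percent_change(614239.25, 623498.50) == 1.51

    def test_identities(self):
        assert percent_change(10.0, 10.0) == 0.00
        assert percent_change(10.0, 20.0) == 100.00

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(InvalidInputError):
            percent_change(0.0, 5.0)


class TestVolumeAnalysis:
    def test_reports_n_per_region(self):
        table = simulate_volumes(n_subjects=9, seed=10)
        summary, results = volume_region_analysis(table)
        assert (summary["n"] == 9).all()
        assert set(results) == set(summary["region"])

    def test_planted_regional_effect_localized(self):
        """+5% planted in SOG.L: only that region's mean change lands in [4, 6]%."""
        acc = {}
        for seed in range(500):
            table = simulate_volumes(n_subjects=9, seed=seed, effect={"SOG.L": 0.05})
            summary, _ = volume_region_analysis(table)
            for _, row in summary.iterrows():
                acc.setdefault(row["region"], []).append(row["mean_percent_change"])
        means = {r: np.mean(v) for r, v in acc.items()}
        assert 4.0 <= means["SOG.L"] <= 6.0
        for region, m in means.items():
            if region not in ("SOG.L", "TOTAL"):
                assert abs(m) < 1.0, region

    def test_unpaired_subject_named(self):
        table = simulate_volumes(n_subjects=5, seed=11)
        broken = table.drop(
            table[(table.subject_id == "V03") & (table.timepoint == "6M")
                  & (table.region == "SOG.L")].index
        )
        with pytest.raises(PairingError, match="V03"):
            volume_region_analysis(broken)
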