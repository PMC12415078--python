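"""Mechanochemical statistics: joins, medians, Welch tests, correlations,
histograms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mechanospec.stats import (build_histogram, cluster_medians,
                               join_colocalized, pairwise_comparisons,
                               shift_width_correlation, welch_omnibus)


def _fits(points, nu, gamma, valid=None):
    n = len(points)
    return pd.DataFrame({"point": points, "nu_B": nu, "gamma_B": gamma,
                         "valid": valid if valid is not None else [True] * n})


def _joined(groups):
    """groups: dict cluster -> list of (nu, gamma)."""
    rows = []
    i = 0
    for c, vals in groups.items():
        for nu, ga in vals:
            rows.append({"point": i, "cluster": c, "nu_B": nu, "gamma_B": ga,
                         "blt": ga / nu})
            i += 1
    return pd.DataFrame(rows)


class TestJoin:
    def test_full_join_and_exclusions(self):
        fits = _fits(range(50), np.full(50, 5.4), np.full(50, 0.44))
        labels = pd.DataFrame({"point": range(50), "cluster": [0] * 50})
        assert len(join_colocalized(fits, labels)) == 50

        fits.loc[[3, 7, 9], "valid"] = False
        out = join_colocalized(fits, labels)
        assert len(out) == 47
        assert out.attrs["n_excluded_invalid"] == 3

    def test_row_order_independence(self, rng):
        fits = _fits(range(30), rng.normal(5.4, 0.05, 30),
                     rng.normal(0.44, 0.05, 30))
        labels = pd.DataFrame({"point": range(30),
                               "cluster": rng.integers(0, 3, 30)})
        a = join_colocalized(fits, labels)
        b = join_colocalized(fits.sample(frac=1, random_state=1),
                             labels.sample(frac=1, random_state=2))
        pd.testing.assert_frame_equal(a, b)

    def test_position_mismatch_names_offenders(self):
        fits = _fits(range(10), np.full(10, 5.4), np.full(10, 0.4))
        labels = pd.DataFrame({"point": range(2, 12), "cluster": [0] * 10})
        with pytest.raises(ValueError, match="position mismatch"):
            join_colocalized(fits, labels)


class TestMedians:
    def test_even_count_convention_and_singleton(self):
        j = _joined({0: [(5.3, 0.4), (5.4, 0.5)], 1: [(5.2, 0.33)]})
        med = cluster_medians(j)
        assert med.loc[0, "median_nu_B"] == pytest.approx(5.35)
        assert med.loc[1, "median_nu_B"] == pytest.approx(5.2)
        assert med.loc[1, "n"] == 1

    def test_blt_aggregations_both_reported(self, rng):
        nu = rng.normal(5.4, 0.1, 101)
        ga = rng.normal(0.5, 0.08, 101)
        j = _joined({0: list(zip(nu, ga))})
        med = cluster_medians(j)
        # median of per-point ratios vs ratio of medians: close but distinct
        assert med.loc[0, "median_blt"] == pytest.approx(
            np.median(ga / nu), rel=1e-12)
        assert med.loc[0, "blt_of_medians"] == pytest.approx(
            np.median(ga) / np.median(nu), rel=1e-12)


def _welch_anova_brute(groups):
    """Independent brute-force Welch ANOVA oracle, written from the
    textbook formulas without reuse of the implementation."""
    k = len(groups)
    w = [len(g) / np.var(g, ddof=1) for g in groups]
    xb = [np.mean(g) for g in groups]
    W = sum(w)
    xw = sum(wi * xi for wi, xi in zip(w, xb)) / W
    num = sum(wi * (xi - xw) ** 2 for wi, xi in zip(w, xb)) / (k - 1)
    lam = sum((1 - wi / W) ** 2 / (len(g) - 1)
              for wi, g in zip(w, groups))
    F = num / (1 + 2 * (k - 2) * lam / (k ** 2 - 1))
    df2 = (k ** 2 - 1) / (3 * lam)
    p = sps.f.sf(F, k - 1, df2)
    return F, df2, p


class TestWelch:
    def test_identical_groups_give_t_zero_p_one(self):
        j = _joined({0: [(1.0, 1), (2.0, 1), (3.0, 1)],
                     1: [(1.0, 1), (2.0, 1), (3.0, 1)]})
        res = welch_omnibus(j, "nu_B")
        assert res.test == "welch_t"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_three_group_toy_matches_brute_force(self):
        groups = [np.array([1.0, 2, 3]), np.array([1.1, 2.1, 3.1]),
                  np.array([10.0, 11, 12])]
        j = _joined({i: [(v, 1.0) for v in g] for i, g in enumerate(groups)})
        res = welch_omnibus(j, "nu_B")
        F, df2, p = _welch_anova_brute(groups)
        assert res.test == "welch_anova"
        assert res.statistic == pytest.approx(F, abs=1e-10)
        assert res.df2 == pytest.approx(df2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        # frozen values, hand-checked: F = 68.6657..., p = 8.0102e-4
        assert res.statistic == pytest.approx(68.66571428571427, abs=1e-8)
        assert res.p_value == pytest.approx(8.010183866594189e-4, abs=1e-10)

    def test_random_datasets_match_brute_force_to_1e10(self, rng):
        for _ in range(20):
            k = rng.integers(3, 6)
            groups = [rng.normal(rng.normal(0, 2), rng.uniform(0.5, 3),
                                 rng.integers(5, 30)) for _ in range(k)]
            j = _joined({i: [(v, 1.0) for v in g]
                         for i, g in enumerate(groups)})
            res = welch_omnibus(j, "nu_B")
            F, df2, p = _welch_anova_brute(groups)
            assert res.statistic == pytest.approx(F, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_large_separation_is_overwhelming(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(10, 1, 30)
        c = rng.normal(20, 1, 30)
        j = _joined({i: [(v, 1.0) for v in g]
                     for i, g in enumerate([a, b, c])})
        assert welch_omnibus(j, "nu_B").p_value < 1e-6

    def test_zero_variance_group_rejected(self):
        j = _joined({0: [(1.0, 1), (1.0, 1)], 1: [(2.0, 1), (3.0, 1)]})
        with pytest.raises(ValueError, match="zero-variance"):
            welch_omnibus(j, "nu_B")


class TestPairwise:
    def test_identical_groups_not_significant(self, rng):
        base = rng.normal(5.4, 0.05, 30)
        j = _joined({c: [(v, 1.0) for v in base + rng.normal(0, 1e-3, 30)]
                     for c in range(3)})
        pw = pairwise_comparisons(j, "nu_B")
        assert (pw["p_adjust"] > 0.5).all()
        assert (pw["method"] == "games_howell").all()

    def test_two_groups_reduce_to_welch_t(self, rng):
        j = _joined({0: [(v, 1.0) for v in rng.normal(5.3, 0.05, 20)],
                     1: [(v, 1.0) for v in rng.normal(5.5, 0.05, 20)]})
        pw = pairwise_comparisons(j, "nu_B")
        res = welch_omnibus(j, "nu_B")
        assert len(pw) == 1
        assert pw.loc[0, "p_adjust"] == pytest.approx(res.p_value, rel=1e-12)

    def test_single_outlying_group_drives_significance(self, rng):
        # two groups share a mean; the third sits 10 SDs away
        j = _joined({0: [(v, 1.0) for v in rng.normal(5.40, 0.05, 30)],
                     1: [(v, 1.0) for v in rng.normal(5.40, 0.05, 30)],
                     2: [(v, 1.0) for v in rng.normal(5.90, 0.05, 30)]})
        pw = pairwise_comparisons(j, "nu_B").set_index(["A", "B"])
        assert pw.loc[(0, 1), "p_adjust"] > 0.05
        assert pw.loc[(0, 2), "p_adjust"] < 0.05
        assert pw.loc[(1, 2), "p_adjust"] < 0.05


class TestCorrelation:
    def test_independent_width_shows_poor_correlation(self, rng):
        j = _joined({0: list(zip(rng.normal(5.4, 0.05, 500),
                                 rng.normal(0.44, 0.05, 500)))})
        out = shift_width_correlation(j)
        assert abs(out.loc[0, "r"]) < 0.2

    def test_exact_proportionality(self):
        nu = np.array([5.1, 5.2, 5.3, 5.4])
        j = _joined({0: list(zip(nu, 0.1 * nu))})
        assert shift_width_correlation(j).loc[0, "r"] == pytest.approx(1.0)
        j = _joined({0: list(zip(nu, 1.0 - 0.1 * nu))})
        assert shift_width_correlation(j).loc[0, "r"] == pytest.approx(-1.0)

    def test_zero_variance_flagged_undefined(self):
        j = _joined({0: [(5.4, 0.4), (5.4, 0.5), (5.4, 0.6)]})
        out = shift_width_correlation(j)
        assert not out.loc[0, "defined"]
        assert np.isnan(out.loc[0, "r"])


class TestHistogram:
    def test_counts_and_default_bin_width(self, rng):
        values = rng.normal(5.4, 0.1, 2000)
        h = build_histogram(values)
        assert h.n_observations == 2000
        assert np.allclose(np.diff(h.bin_edges), 0.05)
        # edges anchored at integer multiples of the bin width
        assert np.allclose(h.bin_edges / 0.05,
                           np.round(h.bin_edges / 0.05), atol=1e-9)

    def test_single_value(self):
        h = build_histogram([5.41])
        assert h.n_observations == 1
        assert h.bin_edges[0] <= 5.41 < h.bin_edges[-1]
        assert abs(h.mode_bin_center - 5.425) < 1e-9

    def test_edge_value_falls_in_right_hand_bin(self):
        h = build_histogram([5.40, 5.41], bin_width=0.05)
        # 5.40 sits exactly on an edge -> bin [5.40, 5.45)
        assert h.counts.sum() == 2
        assert h.counts[-1] == 2
        assert h.bin_edges[0] == pytest.approx(5.40)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([])
        with pytest.raises(ValueError):
            build_histogram([1.0], bin_width=0.0)
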