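"""Group comparison: ANOVA, correction, post-hoc t, summary-statistic t."""

import numpy as np
import pytest
from scipy import stats

from remcpm.connectome import edge_pair_codes, pair_code_of
from remcpm.errors import ConfigError, EmptyMaskError
from remcpm.groups import (
    anova_across_groups,
    compare_groups,
    correct_multiple,
    edge_level_anova,
    pair_strength,
    posthoc_t,
    welch_t_from_summary,
)


class TestPairStrength:
    def test_single_edge(self, toy_parcellation):
        codes = edge_pair_codes(toy_parcellation)
        e = np.flatnonzero(codes == pair_code_of(("DMN", "DMN")))[0]
        m = np.zeros(toy_parcellation.n_edges, bool)
        m[e] = True
        v = np.zeros(toy_parcellation.n_edges)
        v[e] = 0.4
        assert pair_strength(v, m, ("DMN", "DMN"), toy_parcellation) == \
            pytest.approx(0.4)

    def test_mean_of_two_edges(self, toy_parcellation):
        codes = edge_pair_codes(toy_parcellation)
        ee = np.flatnonzero(codes == pair_code_of(("DMN", "DMN")))[:2]
        m = np.zeros(toy_parcellation.n_edges, bool)
        m[ee] = True
        v = np.zeros(toy_parcellation.n_edges)
        v[ee] = [0.2, 0.6]
        assert pair_strength(v, m, ("DMN", "DMN"), toy_parcellation) == \
            pytest.approx(0.4)

    def test_matches_bruteforce_mean(self, toy_parcellation, rng):
        codes = edge_pair_codes(toy_parcellation)
        m = rng.random(toy_parcellation.n_edges) < 0.3
        X = rng.normal(size=(7, toy_parcellation.n_edges))
        sel = m & (codes == pair_code_of(("DMN", "VIS")))
        if not sel.any():
            m[np.flatnonzero(codes == pair_code_of(("DMN", "VIS")))[0]] = True
            sel = m & (codes == pair_code_of(("DMN", "VIS")))
        out = pair_strength(X, m, ("DMN", "VIS"), toy_parcellation)
        assert np.allclose(out, X[:, sel].mean(1), atol=1e-12)

    def test_empty_pair_rejected(self, toy_parcellation):
        m = np.zeros(toy_parcellation.n_edges, bool)
        m[0] = True  # a DMN-DMN edge
        with pytest.raises(EmptyMaskError):
            pair_strength(np.zeros(toy_parcellation.n_edges), m,
                          ("VIS", "SUB"), toy_parcellation)


class TestAnova:
    def test_two_groups_equals_t_squared(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(1.0, 1.0, size=15)
        F, df, p = anova_across_groups([a, b])
        t = stats.ttest_ind(a, b, equal_var=True).statistic
        assert F == pytest.approx(t * t, abs=1e-9)

    def test_degenerate_all_equal(self):
        F, df, p = anova_across_groups([np.ones(2), np.ones(2), np.ones(2)])
        assert (F, p) == (0.0, 1.0)
        assert df == (2, 3)

    def test_df_match_group_sizes(self, rng):
        groups = [rng.normal(size=n) for n in (33, 41, 36)]
        _, df, _ = anova_across_groups(groups)
        assert df == (2, 107)

    def test_type_one_error_calibrated(self):
        """Null rejection rate ~= alpha over label-permuted replicates."""
        rejections = 0
        n_rep = 400
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            v = rng.normal(size=30)
            _, _, p = anova_across_groups([v[:10], v[10:20], v[20:]])
            rejections += p < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.03

    def test_needs_two_per_group(self):
        with pytest.raises(ConfigError):
            anova_across_groups([np.ones(1), np.ones(3)])


class TestCorrection:
    def test_single_p_unchanged_bh(self):
        assert correct_multiple([0.03]) == pytest.approx([0.03])

    def test_bh_hand_applied(self):
        out = correct_multiple([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_bonferroni(self):
        assert correct_multiple([0.001] * 1 + [0.5] * 31, "bonferroni")[0] == \
            pytest.approx(0.032)

    def test_monotone_and_above_raw(self, rng):
        p = rng.random(20)
        for method in ("bh", "bonferroni"):
            q = correct_multiple(p, method)
            assert (q >= p - 1e-12).all()
            assert (q <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            correct_multiple([0.5, 1.2])


class TestPosthoc:
    def test_identical_samples(self):
        r = posthoc_t(np.arange(5.0), np.arange(5.0))
        assert (r.t, r.p, r.d_pooled) == (0.0, 1.0, 0.0)

    def test_clear_separation(self, rng):
        a = rng.normal(0, 0.01, 6)
        b = rng.normal(1, 0.01, 6)
        r = posthoc_t(a, b)
        assert abs(r.d_pooled) > 10
        assert r.p < 1e-6

    def test_welch_matches_summary_formula(self, rng):
        a = rng.normal(24.41, 6.56, 41)
        b = rng.normal(15.18, 5.31, 36)
        r = posthoc_t(a, b)
        t_sum, df_sum = welch_t_from_summary(a.mean(), a.std(ddof=1), 41,
                                             b.mean(), b.std(ddof=1), 36)
        assert r.t == pytest.approx(t_sum, abs=1e-12)
        assert r.df == pytest.approx(df_sum, abs=1e-9)

    def test_simulated_mean_t_matches_closed_form(self):
        """Welch t over simulated group draws averages to the summary value."""
        t_ref, _ = welch_t_from_summary(24.41, 6.56, 41, 15.18, 5.31, 36)
        rng = np.random.default_rng(0)
        ts = []
        for _ in range(500):
            a = rng.normal(24.41, 6.56, 41)
            b = rng.normal(15.18, 5.31, 36)
            ts.append(stats.ttest_ind(a, b, equal_var=False).statistic)
        assert abs(np.mean(ts) - t_ref) / t_ref < 0.05


class TestWelchSummary:
    def test_equal_means_zero(self):
        t, _ = welch_t_from_summary(5, 1, 10, 5, 2, 12)
        assert t == 0.0

    def test_doubling_n_scales_sqrt2(self):
        t1, _ = welch_t_from_summary(10, 2, 20, 8, 2, 30)
        t2, _ = welch_t_from_summary(10, 2, 40, 8, 2, 60)
        assert t2 == pytest.approx(np.sqrt(2) * t1)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            welch_t_from_summary(1, 0, 10, 2, 1, 10)
        with pytest.raises(ConfigError):
            welch_t_from_summary(1, 1, 1, 2, 1, 10)


class TestEdgeLevel:
    def _setup(self, toy_parcellation, shift=0.0, seed=0, n_shifted=2):
        rng = np.random.default_rng(seed)
        codes = edge_pair_codes(toy_parcellation)
        pool = np.flatnonzero(codes == pair_code_of(("DMN", "DMN")))
        m = np.zeros(toy_parcellation.n_edges, bool)
        m[pool[:6]] = True
        labels = np.array(["FS"] * 12 + ["early_dep"] * 12 + ["late_dep"] * 12)
        X = rng.normal(0, 0.1, size=(36, toy_parcellation.n_edges))
        X[labels == "late_dep"][:, pool[:n_shifted]] += 0.0  # view, no-op
        if shift:
            rows = np.flatnonzero(labels == "late_dep")
            X[np.ix_(rows, pool[:n_shifted])] += shift
        return X, m, labels

    def test_single_edge_corrected_equals_raw(self, toy_parcellation, rng):
        codes = edge_pair_codes(toy_parcellation)
        e = np.flatnonzero(codes == pair_code_of(("DMN", "DMN")))[0]
        m = np.zeros(toy_parcellation.n_edges, bool)
        m[e] = True
        labels = np.array(["FS"] * 8 + ["early_dep"] * 8 + ["late_dep"] * 8)
        X = rng.normal(size=(24, toy_parcellation.n_edges))
        table = edge_level_anova(X, m, ("DMN", "DMN"), toy_parcellation, labels)
        assert len(table) == 1
        assert table.p_corr.iloc[0] == pytest.approx(table.p.iloc[0])

    def test_shifted_edges_rank_first(self, toy_parcellation):
        wins = 0
        for seed in range(20):
            X, m, labels = self._setup(toy_parcellation, shift=0.3, seed=seed)
            table = edge_level_anova(X, m, ("DMN", "DMN"), toy_parcellation,
                                     labels)
            codes = edge_pair_codes(toy_parcellation)
            pool = np.flatnonzero(codes == pair_code_of(("DMN", "DMN")))
            top2 = set(table.edge_index.iloc[:2])
            if top2 == set(pool[:2].tolist()):
                wins += 1
        assert wins >= 18

    def test_null_false_positive_rate(self, toy_parcellation):
        total_sig = 0
        for seed in range(50):
            X, m, labels = self._setup(toy_parcellation, shift=0.0, seed=seed)
            table = edge_level_anova(X, m, ("DMN", "DMN"), toy_parcellation,
                                     labels)
            total_sig += int((table.p_corr < 0.05).sum() > 0)
        assert total_sig <= 6  # BH at q=0.05 over 50 null replicates


def test_compare_groups_pipeline(toy_parcellation, rng):
    """End-to-end pair comparison flags only the truly shifted pair."""
    codes = edge_pair_codes(toy_parcellation)
    dmn = np.flatnonzero(codes == pair_code_of(("DMN", "DMN")))[:5]
    vis = np.flatnonzero(codes == pair_code_of(("VIS", "VIS")))[:5]
    m = np.zeros(toy_parcellation.n_edges, bool)
    m[dmn] = True
    m[vis] = True
    labels = np.array(["FS"] * 15 + ["early_dep"] * 15 + ["late_dep"] * 15)
    X = rng.normal(0, 0.1, size=(45, toy_parcellation.n_edges))
    rows = np.flatnonzero(labels == "late_dep")
    X[np.ix_(rows, dmn)] -= 0.3
    res = compare_groups(X, labels, m, toy_parcellation)
    table = res.pair_table.set_index("pair")
    assert bool(table.loc["DMN-DMN", "significant"])
    assert not bool(table.loc["VIS-VIS", "significant"])
    assert "DMN-DMN" in res.posthoc
    contrast = res.posthoc["DMN-DMN"]["FS_vs_late_dep"]
    assert contrast.t > 0  # FS above the depressed late_dep group
    assert "DMN-DMN" in res.edge_tables
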