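"""Multi-level characterization: shares, contributions, regional profiles."""

import numpy as np
import pytest

from remcpm.characterize import (
    characterize,
    network_shares,
    pair_contribution,
    pair_edge_profile,
    regional_profile,
)
from remcpm.connectome import (
    edge_pair_codes,
    pair_code_of,
    parcellation_from_sizes,
    triu_pairs,
)
from remcpm.errors import EmptyMaskError
from helpers import brute_degrees


def _mask_with(parc, pairs_counts, rng=None):
    """Boolean mask holding the first k edges of each requested pair."""
    codes = edge_pair_codes(parc)
    m = np.zeros(parc.n_edges, bool)
    for pair, k in pairs_counts.items():
        pool = np.flatnonzero(codes == pair_code_of(pair))
        m[pool[:k]] = True
    return m


class TestPairProfile:
    def test_single_dmn_edge(self, toy_parcellation):
        m = _mask_with(toy_parcellation, {("DMN", "DMN"): 1})
        table, var = pair_edge_profile(m, toy_parcellation)
        assert len(table) == 55
        row = table[table.pair == "DMN-DMN"].iloc[0]
        assert row.edge_share == 1.0
        assert table.edge_share.sum() == pytest.approx(1.0)
        expected = np.zeros(55)
        expected[0] = 1.0
        assert var == pytest.approx(expected.var())

    def test_uniform_mask_shares_proportional(self, toy_parcellation):
        m = np.ones(toy_parcellation.n_edges, bool)
        table, _ = pair_edge_profile(m, toy_parcellation)
        assert table.edge_share.sum() == pytest.approx(1.0)
        sizes = toy_parcellation.network_sizes()
        # combinatorial oracle for a within pair and a between pair
        dmn = sizes["DMN"]
        expected_within = dmn * (dmn - 1) / 2 / toy_parcellation.n_edges
        assert table[table.pair == "DMN-DMN"].edge_share.iloc[0] == \
            pytest.approx(expected_within)
        expected_between = sizes["DMN"] * sizes["VIS"] / toy_parcellation.n_edges
        assert table[table.pair == "DMN-VIS"].edge_share.iloc[0] == \
            pytest.approx(expected_between)

    def test_empty_mask_rejected(self, toy_parcellation):
        with pytest.raises(EmptyMaskError):
            pair_edge_profile(np.zeros(toy_parcellation.n_edges, bool),
                              toy_parcellation)


class TestNetworkShares:
    def test_between_edge_split(self, toy_parcellation):
        m = _mask_with(toy_parcellation, {("DMN", "VIS"): 1})
        table, _ = network_shares(m, toy_parcellation)
        assert table[table.network == "DMN"].endpoint_share.iloc[0] == 0.5
        assert table[table.network == "VIS"].endpoint_share.iloc[0] == 0.5

    def test_within_edge_full_share(self, toy_parcellation):
        m = _mask_with(toy_parcellation, {("DMN", "DMN"): 1})
        table, _ = network_shares(m, toy_parcellation)
        assert table[table.network == "DMN"].endpoint_share.iloc[0] == 1.0

    def test_shares_sum_and_bruteforce(self, toy_parcellation, rng):
        m = rng.random(toy_parcellation.n_edges) < 0.2
        table, _ = network_shares(m, toy_parcellation)
        assert table.endpoint_share.sum() == pytest.approx(1.0)
        iu, ju = triu_pairs(toy_parcellation.n_nodes)
        for _, row in table.iterrows():
            brute = sum(
                (toy_parcellation.labels[iu[e]] == row.network)
                + (toy_parcellation.labels[ju[e]] == row.network)
                for e in np.flatnonzero(m))
            assert row.endpoint_count == brute


class TestContribution:
    def _cohort(self, parc, mask, beta_by_edge, n=40, seed=0, noise=0.1):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=n)
        yz = (y - y.mean()) / y.std()
        X = rng.normal(0, noise, size=(n, parc.n_edges))
        for e, b in beta_by_edge.items():
            X[:, e] += b * yz
        return X, y

    def test_single_pair_normalizes_to_one(self, toy_parcellation):
        m = _mask_with(toy_parcellation, {("DMN", "DMN"): 2})
        X, y = self._cohort(toy_parcellation, m,
                            {e: 0.3 for e in np.flatnonzero(m)})
        table, var = pair_contribution(X, y, m, toy_parcellation)
        assert len(table) == 1
        assert table.contribution_norm.iloc[0] == 1.0
        assert var == 0.0

    def test_equal_beta_pairs_symmetric(self, toy_parcellation):
        m = _mask_with(toy_parcellation, {("DMN", "DMN"): 3, ("VIS", "VIS"): 3})
        diffs = []
        for seed in range(8):
            X, y = self._cohort(toy_parcellation, m,
                                {e: 0.2 for e in np.flatnonzero(m)}, seed=seed)
            table, _ = pair_contribution(X, y, m, toy_parcellation)
            vals = table.set_index("pair").contribution_norm
            diffs.append(abs(vals["DMN-DMN"] - vals["VIS-VIS"]))
        assert np.mean(diffs) < 0.1

    def test_planted_pair_dominates_null_pair(self, toy_parcellation):
        m = _mask_with(toy_parcellation, {("DMN", "DMN"): 3, ("CON", "CON"): 3})
        wins = 0
        for seed in range(20):
            planted = np.flatnonzero(
                m & (edge_pair_codes(toy_parcellation) == pair_code_of(("DMN", "DMN"))))
            X, y = self._cohort(toy_parcellation, m,
                                {e: 0.3 for e in planted}, seed=seed)
            table, _ = pair_contribution(X, y, m, toy_parcellation)
            vals = table.set_index("pair").contribution_r
            if vals["DMN-DMN"] > vals["CON-CON"]:
                wins += 1
        assert wins >= 19


class TestRegional:
    def test_isolated_node_zero(self, toy_parcellation, rng):
        m = _mask_with(toy_parcellation, {("DMN", "DMN"): 1})
        X = rng.normal(size=(12, toy_parcellation.n_edges))
        y = rng.normal(size=12)
        table, _ = regional_profile(X, y, m, toy_parcellation)
        idle = table[table.degree == 0]
        assert (idle.contribution_r == 0).all()

    def test_star_mask_degrees(self, toy_parcellation, rng):
        iu, ju = triu_pairs(toy_parcellation.n_nodes)
        hub = 0
        spokes = [1, 2, 3, 4]
        m = np.zeros(toy_parcellation.n_edges, bool)
        for s in spokes:
            m[np.flatnonzero((iu == hub) & (ju == s))[0]] = True
        X = rng.normal(size=(12, toy_parcellation.n_edges))
        y = rng.normal(size=12)
        table, _ = regional_profile(X, y, m, toy_parcellation)
        assert table.degree.iloc[hub] == len(spokes)
        assert all(table.degree.iloc[s] == 1 for s in spokes)
        assert table.degree.sum() == 2 * m.sum()

    def test_degrees_match_bruteforce(self, toy_parcellation, rng):
        m = rng.random(toy_parcellation.n_edges) < 0.25
        X = rng.normal(size=(10, toy_parcellation.n_edges))
        y = rng.normal(size=10)
        table, _ = regional_profile(X, y, m, toy_parcellation)
        assert np.array_equal(table.degree.to_numpy(),
                              brute_degrees(m, toy_parcellation.n_nodes))

    def test_noiseless_similarity_is_one(self, toy_parcellation):
        """Two equal-beta pairs, no noise: degree and contribution profiles
        both split nodes into {in mask, out of mask}, so their correlation is 1."""
        m = _mask_with(toy_parcellation, {("DMN", "DMN"): 1, ("VIS", "VIS"): 1})
        rng = np.random.default_rng(0)
        y = rng.normal(size=15)
        yz = (y - y.mean()) / y.std()
        X = np.zeros((15, toy_parcellation.n_edges))
        X[:, np.flatnonzero(m)] = 0.3 * yz[:, None]
        table, sim = regional_profile(X, y, m, toy_parcellation)
        assert sim == pytest.approx(1.0)

    def test_node_permutation_equivariance(self, rng):
        parc = parcellation_from_sizes({"DMN": 4, "VIS": 4})
        n = parc.n_nodes
        m = rng.random(parc.n_edges) < 0.4
        if not m.any():
            m[0] = True
        X = rng.normal(size=(10, parc.n_edges))
        y = rng.normal(size=10)
        table, _ = regional_profile(X, y, m, parc)
        perm = rng.permutation(n)
        # permute nodes: rebuild mask/edges under the permuted node order
        from remcpm.connectome import Parcellation, devectorize, vectorize

        Mz = [devectorize(X[s])[np.ix_(perm, perm)] for s in range(10)]
        Xp = np.stack([vectorize(mz) for mz in Mz])
        mp = vectorize(devectorize(m.astype(float))[np.ix_(perm, perm)]) > 0.5
        parc_p = Parcellation(labels=parc.labels[perm])
        table_p, _ = regional_profile(Xp, y, mp, parc_p)
        assert np.array_equal(table_p.degree.to_numpy(),
                              table.degree.to_numpy()[perm])
        assert np.allclose(table_p.contribution_r.to_numpy(),
                           table.contribution_r.to_numpy()[perm], atol=1e-12)


def test_full_report_conservation(ten_net_parcellation, rng):
    parc = ten_net_parcellation
    m = rng.random(parc.n_edges) < 0.05
    X = rng.normal(size=(20, parc.n_edges))
    y = rng.normal(size=20)
    report = characterize(X, y, m, parc)
    assert report.pair_table.edge_share.sum() == pytest.approx(1.0)
    assert report.pair_table.edge_count.sum() == m.sum()
    assert report.node_table.degree.sum() == 2 * m.sum()
    assert report.network_table.endpoint_share.sum() == pytest.approx(1.0)
    active = report.pair_table.contribution_norm.dropna()
    assert active.sum() == pytest.approx(1.0)
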