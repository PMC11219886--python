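"""Multi-level characterization of a consensus connectome.

Three levels of description for the edge set a predictive model retains:

* network pairs (55 unordered pairs): edge counts, normalized edge shares,
  and correlation-based contributions;
* large-scale networks (10): endpoint shares and contributions;
* regions (nodes): consensus degree and contribution, plus the
  degree-contribution similarity.

"Contribution" of a unit (pair / network / node) is the absolute Pearson
correlation between behavior and the per-subject sum of the unit's
consensus-edge strengths.  "Normalized" always means divide-by-total so
each distribution sums to one; reported variances are population variances
(divide by count) of those normalized distributions.  Pairs without
consensus edges are excluded from the contribution normalization but kept
(as zero) in the edge-share distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .connectome import (
    NETWORKS,
    Parcellation,
    all_network_pairs,
    edge_pair_codes,
    pair_code_of,
    pair_label,
    triu_pairs,
)
from .errors import ConstantBehaviorError, EmptyMaskError


@dataclass
class CharacterizationReport:
    """Tables and scalars of the multi-level profile."""

    pair_table: pd.DataFrame       # 55 rows: pair, edge_count, edge_share, contribution
    network_table: pd.DataFrame    # 10 rows: network, endpoint_share, contribution
    node_table: pd.DataFrame       # per node: degree, contribution
    edge_share_variance: float
    pair_contribution_variance: float
    network_share_variance: float
    network_contribution_variance: float
    similarity_r: float

    def to_dict(self) -> Dict:
        return {
            "edge_share_variance": self.edge_share_variance,
            "pair_contribution_variance": self.pair_contribution_variance,
            "network_share_variance": self.network_share_variance,
            "network_contribution_variance": self.network_contribution_variance,
            "similarity_r": self.similarity_r,
            "pair_table": self.pair_table.to_dict(orient="records"),
            "network_table": self.network_table.to_dict(orient="records"),
            "node_table": self.node_table.to_dict(orient="records"),
        }


def _as_bool_mask(mask) -> np.ndarray:
    m = getattr(mask, "combined", mask)
    return np.asarray(m, dtype=bool)


def pair_edge_profile(mask, p: Parcellation) -> Tuple[pd.DataFrame, float]:
    """Edge counts and normalized shares per network pair, plus variance.

    Returns a 55-row table (every possible pair, zeros included) and the
    population variance of the normalized share distribution.
    """
    m = _as_bool_mask(mask)
    if not m.any():
        raise EmptyMaskError("consensus mask is empty")
    codes = edge_pair_codes(p)
    pairs = all_network_pairs()
    counts = np.array([int((codes[m] == pair_code_of(q)).sum()) for q in pairs])
    total = counts.sum()
    shares = counts / total
    table = pd.DataFrame({
        "pair": [pair_label(q) for q in pairs],
        "edge_count": counts,
        "edge_share": shares,
    })
    return table, float(shares.var())


def pair_contribution(edges: np.ndarray, behavior: np.ndarray, mask,
                      p: Parcellation) -> Tuple[pd.DataFrame, float]:
    """Absolute behavior correlation of each pair's summed strengths.

    Only pairs holding at least one consensus edge contribute; their
    normalized contributions sum to one.
    """
    m = _as_bool_mask(mask)
    X = np.asarray(edges, float)
    y = np.asarray(behavior, float)
    if y.size < 3:
        raise ConstantBehaviorError("need >=3 subjects")
    if y.std() == 0:
        raise ConstantBehaviorError("behavior has zero variance")
    if not m.any():
        raise EmptyMaskError("consensus mask is empty")
    codes = edge_pair_codes(p)
    rows = []
    for q in all_network_pairs():
        sel = m & (codes == pair_code_of(q))
        if not sel.any():
            continue
        strength = X[:, sel].sum(axis=1)
        r = 0.0 if strength.std() == 0 else abs(float(np.corrcoef(strength, y)[0, 1]))
        rows.append({"pair": pair_label(q), "edge_count": int(sel.sum()),
                     "contribution_r": r})
    table = pd.DataFrame(rows)
    total = table["contribution_r"].sum()
    table["contribution_norm"] = (
        table["contribution_r"] / total if total > 0 else 0.0)
    return table, float(np.asarray(table["contribution_norm"]).var())


def network_shares(mask, p: Parcellation) -> Tuple[pd.DataFrame, float]:
    """Share of consensus-edge endpoints per large-scale network."""
    m = _as_bool_mask(mask)
    if not m.any():
        raise EmptyMaskError("consensus mask is empty")
    iu, ju = triu_pairs(p.n_nodes)
    ends = np.concatenate([p.labels[iu[m]], p.labels[ju[m]]])
    total = ends.size  # = 2 x consensus edge count
    counts = np.array([int((ends == net).sum()) for net in NETWORKS])
    shares = counts / total
    table = pd.DataFrame({"network": list(NETWORKS),
                          "endpoint_count": counts,
                          "endpoint_share": shares})
    return table, float(shares.var())


def network_contribution(edges: np.ndarray, behavior: np.ndarray, mask,
                         p: Parcellation) -> Tuple[pd.DataFrame, float]:
    """Contribution per network from its incident consensus edges."""
    m = _as_bool_mask(mask)
    X = np.asarray(edges, float)
    y = np.asarray(behavior, float)
    iu, ju = triu_pairs(p.n_nodes)
    rows = []
    for net in NETWORKS:
        sel = m & ((p.labels[iu] == net) | (p.labels[ju] == net))
        if not sel.any():
            rows.append({"network": net, "contribution_r": 0.0, "incident": 0})
            continue
        strength = X[:, sel].sum(axis=1)
        r = 0.0 if strength.std() == 0 else abs(float(np.corrcoef(strength, y)[0, 1]))
        rows.append({"network": net, "contribution_r": r, "incident": int(sel.sum())})
    table = pd.DataFrame(rows)
    active = table["incident"] > 0
    total = table.loc[active, "contribution_r"].sum()
    table["contribution_norm"] = 0.0
    if total > 0:
        table.loc[active, "contribution_norm"] = (
            table.loc[active, "contribution_r"] / total)
    var = float(np.asarray(table.loc[active, "contribution_norm"]).var()) if active.any() else 0.0
    return table, var


def regional_profile(edges: np.ndarray, behavior: np.ndarray, mask,
                     p: Parcellation) -> Tuple[pd.DataFrame, float]:
    """Per-node consensus degree, contribution, and their similarity.

    Degree counts consensus edges incident to the node (so degrees sum to
    twice the consensus edge count); contribution is the absolute behavior
    correlation of the node's summed incident strengths (zero for isolated
    nodes).  similarity_r is the Pearson correlation of the two profiles
    over all nodes.
    """
    m = _as_bool_mask(mask)
    X = np.asarray(edges, float)
    y = np.asarray(behavior, float)
    n = p.n_nodes
    iu, ju = triu_pairs(n)
    degree = np.zeros(n, dtype=int)
    np.add.at(degree, iu[m], 1)
    np.add.at(degree, ju[m], 1)
    contribution = np.zeros(n)
    sel_edges = np.flatnonzero(m)
    for node in np.flatnonzero(degree):
        incident = sel_edges[(iu[sel_edges] == node) | (ju[sel_edges] == node)]
        strength = X[:, incident].sum(axis=1)
        if strength.std() > 0 and y.std() > 0:
            contribution[node] = abs(float(np.corrcoef(strength, y)[0, 1]))
    if degree.std() > 0 and contribution.std() > 0:
        sim = float(np.corrcoef(degree, contribution)[0, 1])
    else:
        sim = float("nan")
    table = pd.DataFrame({
        "node": np.arange(n),
        "network": p.labels,
        "degree": degree,
        "contribution_r": contribution,
    })
    return table, sim


def characterize(edges: np.ndarray, behavior: np.ndarray, mask,
                 p: Parcellation) -> CharacterizationReport:
    """Full multi-level report for one consensus mask."""
    pair_tab, share_var = pair_edge_profile(mask, p)
    contrib_tab, contrib_var = pair_contribution(edges, behavior, mask, p)
    pair_tab = pair_tab.merge(
        contrib_tab[["pair", "contribution_r", "contribution_norm"]],
        on="pair", how="left")
    net_tab, net_share_var = network_shares(mask, p)
    netc_tab, net_contrib_var = network_contribution(edges, behavior, mask, p)
    net_tab = net_tab.merge(
        netc_tab[["network", "contribution_r", "contribution_norm"]], on="network")
    node_tab, sim = regional_profile(edges, behavior, mask, p)
    return CharacterizationReport(
        pair_table=pair_tab,
        network_table=net_tab,
        node_table=node_tab,
        edge_share_variance=share_var,
        pair_contribution_variance=contrib_var,
        network_share_variance=net_share_var,
        network_contribution_variance=net_contrib_var,
        similarity_r=sim,
    )
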