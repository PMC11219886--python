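"""Three-group comparison of connectome-restricted connectivity.

Per-subject strength of a network pair is the mean Fisher-z over the
pair's consensus edges (mean rather than sum, so pairs with different edge
counts are comparable).  Pairs are compared across groups with one-way
fixed-effects ANOVA, corrected across pairs (BH-FDR by default, Bonferroni
available); pairs surviving correction get Welch post-hoc contrasts with
Cohen's d and an edge-level ANOVA follow-up corrected within the pair.

Summary-statistic Welch t utilities support comparisons from published
mean +/- SD tables without raw data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectome import (
    Parcellation,
    all_network_pairs,
    edge_pair_codes,
    pair_code_of,
    pair_label,
)
from .errors import ConfigError, EmptyMaskError

logger = logging.getLogger(__name__)


@dataclass
class PosthocResult:
    """Welch two-sample contrast with both Cohen's d conventions."""

    t: float
    df: float
    p: float
    d_pooled: float   # mean difference / pooled SD
    d_from_t: float   # t / sqrt(nA + nB)
    n: int


@dataclass
class GroupComparisonResult:
    pair_table: pd.DataFrame                       # per-pair F, df, p, p_corr
    posthoc: Dict[str, Dict[str, PosthocResult]]   # pair -> contrast -> result
    edge_tables: Dict[str, pd.DataFrame]           # pair -> per-edge ANOVA
    correction: str
    alpha: float

    def to_dict(self) -> Dict:
        return {
            "correction": self.correction,
            "alpha": self.alpha,
            "pair_table": self.pair_table.to_dict(orient="records"),
            "posthoc": {
                pair: {c: vars(res) for c, res in contrasts.items()}
                for pair, contrasts in self.posthoc.items()
            },
            "edge_tables": {k: v.to_dict(orient="records")
                            for k, v in self.edge_tables.items()},
        }


def _as_bool_mask(mask) -> np.ndarray:
    m = getattr(mask, "combined", mask)
    return np.asarray(m, dtype=bool)


def pair_strength(edges: np.ndarray, mask, pair: Tuple[str, str],
                  p: Parcellation) -> np.ndarray:
    """Mean consensus-edge z for one network pair, per subject.

    ``edges`` may be a single edge vector or a subjects x edges matrix.
    """
    m = _as_bool_mask(mask)
    codes = edge_pair_codes(p)
    sel = m & (codes == pair_code_of(pair))
    if not sel.any():
        raise EmptyMaskError(f"pair {pair_label(pair)} has no consensus edges")
    X = np.atleast_2d(np.asarray(edges, float))
    out = X[:, sel].mean(axis=1)
    return out[0] if np.asarray(edges).ndim == 1 else out


def anova_across_groups(values_by_group: Sequence[np.ndarray]
                        ) -> Tuple[float, Tuple[int, int], float]:
    """One-way fixed-effects ANOVA; returns (F, (df1, df2), p).

    Fully degenerate input (all values identical) is reported as F = 0,
    p = 1 rather than NaN, and logged.
    """
    groups = [np.asarray(v, float) for v in values_by_group]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ConfigError("need >=2 groups with >=2 subjects each")
    k = len(groups)
    N = sum(g.size for g in groups)
    df = (k - 1, N - k)
    allv = np.concatenate(groups)
    if allv.std() == 0:
        logger.info("degenerate ANOVA (all values equal): F=0, p=1")
        return 0.0, df, 1.0
    F, p = stats.f_oneway(*groups)
    F = float(F)
    p = float(p)
    if not np.isfinite(F):
        # zero within-group variance with distinct means
        return float("inf"), df, 0.0
    return F, df, p


def correct_multiple(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """BH-FDR (default) or Bonferroni corrected p-values."""
    p = np.asarray(pvalues, float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ConfigError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    if method in ("bh", "fdr_bh"):
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    raise ConfigError(f"unknown correction method {method!r}")


def posthoc_t(values_a: np.ndarray, values_b: np.ndarray,
              equal_var: bool = False) -> PosthocResult:
    """Welch (default) or pooled two-sample t with Cohen's d.

    Both d conventions are reported: the pooled-SD standardized mean
    difference, and t/sqrt(N) (both appear in the applied literature and
    are not interchangeable).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("each group needs >=2 subjects")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return PosthocResult(t=0.0, df=float(a.size + b.size - 2), p=1.0,
                             d_pooled=0.0, d_from_t=0.0, n=a.size + b.size)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    na, nb = a.size, b.size
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                 / (na + nb - 2))
    d_pooled = float((a.mean() - b.mean()) / sp) if sp > 0 else float("inf")
    return PosthocResult(t=t, df=df, p=p, d_pooled=d_pooled,
                         d_from_t=t / np.sqrt(na + nb), n=na + nb)


def welch_t_from_summary(mean_a: float, sd_a: float, n_a: int,
                         mean_b: float, sd_b: float, n_b: int
                         ) -> Tuple[float, float]:
    """Welch t and Welch-Satterthwaite df from summary statistics.

    t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b).
    """
    if sd_a <= 0 or sd_b <= 0:
        raise ConfigError("SDs must be > 0")
    if n_a < 2 or n_b < 2:
        raise ConfigError("ns must be >= 2")
    va = sd_a**2 / n_a
    vb = sd_b**2 / n_b
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(t), float(df)


def edge_level_anova(edges: np.ndarray, mask, pair: Tuple[str, str],
                     p: Parcellation, group_labels: Sequence[str],
                     correction: str = "bh") -> pd.DataFrame:
    """Per-edge one-way ANOVA within a pair's consensus edges.

    Correction is applied within the pair's edge family.
    """
    m = _as_bool_mask(mask)
    codes = edge_pair_codes(p)
    sel = np.flatnonzero(m & (codes == pair_code_of(pair)))
    if sel.size == 0:
        raise EmptyMaskError(f"pair {pair_label(pair)} has no consensus edges")
    X = np.asarray(edges, float)
    labels = np.asarray(group_labels)
    uniq = [g for g in ("FS", "early_dep", "late_dep") if (labels == g).any()]
    rows = []
    for e in sel:
        vals = [X[labels == g, e] for g in uniq]
        F, df, pv = anova_across_groups(vals)
        rows.append({"edge_index": int(e), "F": F, "df1": df[0], "df2": df[1],
                     "p": pv})
    table = pd.DataFrame(rows)
    table["p_corr"] = correct_multiple(table["p"].to_numpy(), correction)
    return table.sort_values("F", ascending=False).reset_index(drop=True)


def compare_groups(edges: np.ndarray, group_labels: Sequence[str], mask,
                   p: Parcellation, correction: str = "bh",
                   alpha: float = 0.05,
                   run_edge_level: bool = True) -> GroupComparisonResult:
    """Pair-level group comparison over the consensus connectome.

    Tests every network pair holding at least one consensus edge; pairs
    surviving correction (gatekeeping) get post-hoc contrasts and the
    edge-level follow-up.
    """
    m = _as_bool_mask(mask)
    codes = edge_pair_codes(p)
    labels = np.asarray(group_labels)
    uniq = [g for g in ("FS", "early_dep", "late_dep") if (labels == g).any()]
    X = np.asarray(edges, float)
    rows = []
    strengths: Dict[str, np.ndarray] = {}
    for q in all_network_pairs():
        sel = m & (codes == pair_code_of(q))
        if not sel.any():
            continue
        s = X[:, sel].mean(axis=1)
        strengths[pair_label(q)] = s
        F, df, pv = anova_across_groups([s[labels == g] for g in uniq])
        rows.append({"pair": pair_label(q), "n_edges": int(sel.sum()),
                     "F": F, "df1": df[0], "df2": df[1], "p": pv})
    if not rows:
        raise EmptyMaskError("no network pair holds a consensus edge")
    table = pd.DataFrame(rows)
    table["p_corr"] = correct_multiple(table["p"].to_numpy(), correction)
    table["significant"] = table["p_corr"] < alpha
    posthoc: Dict[str, Dict[str, PosthocResult]] = {}
    edge_tables: Dict[str, pd.DataFrame] = {}
    for _, row in table[table["significant"]].iterrows():
        name = row["pair"]
        s = strengths[name]
        contrasts = {}
        for i, ga in enumerate(uniq):
            for gb in uniq[i + 1:]:
                contrasts[f"{ga}_vs_{gb}"] = posthoc_t(s[labels == ga],
                                                       s[labels == gb])
        posthoc[name] = contrasts
        if run_edge_level:
            a, b = name.split("-")
            edge_tables[name] = edge_level_anova(X, mask, (a, b), p, labels,
                                                 correction)
    return GroupComparisonResult(pair_table=table.reset_index(drop=True),
                                 posthoc=posthoc, edge_tables=edge_tables,
                                 correction=correction, alpha=alpha)
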