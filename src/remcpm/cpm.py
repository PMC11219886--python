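"""Connectome-based predictive modeling (CPM) of a behavioral score.

CPM relates whole-brain functional connectivity to a behavior (here REM
sleep duration) under leave-one-out cross-validation:

1. On each training fold, correlate every edge with behavior; edges with
   r > 0 and two-sided p below ``selection_alpha`` form the positive mask,
   edges with r < 0 the negative mask.
2. For each subject, sum the Fisher-z edge weights over each mask — the
   positive-strength and negative-strength features.
3. Fit ordinary least squares on the training subjects (one model per tail
   plus a combined two-feature model) and predict the held-out subject.
4. Score the model as r_obs = Pearson r(cross-validated predictions,
   observed behavior); significance comes from rerunning the entire
   pipeline, per-fold selection included, on permuted behavior:
   p = (1 + #{r_perm >= r_obs}) / (n_permutations + 1), one-tailed.

The per-fold correlations use exact leave-one-out downdates of the full
cross-products, which is algebraically identical to recomputing each fold
from scratch (tests verify this against a brute-force oracle) but makes
1000-permutation tests affordable.

Folds whose training mask is empty predict the training behavior mean
(logged) so weak-signal data never aborts the cross-validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats

from .errors import ConfigError, ConstantBehaviorError

logger = logging.getLogger(__name__)

MODELS = ("positive", "negative", "combined")


@dataclass
class CPMConfig:
    """Knobs of the CPM pipeline.

    selection_alpha
        Per-edge two-sided correlation p-value threshold for mask entry.
    tails
        Which tails to report ("positive", "negative", "both"); all three
        models are always computed, this only selects the headline.
    n_permutations
        Label permutations for the significance test.
    consensus_fraction
        Fraction of folds an edge must be selected in (same sign) to enter
        the consensus connectome; 1.0 = intersection of all folds.
    """

    selection_alpha: float = 0.01
    tails: str = "both"
    n_permutations: int = 1000
    consensus_fraction: float = 1.0
    seed: int = 0
    covariates: Optional[np.ndarray] = None  # accepted, not regressed (no-op hook)

    def __post_init__(self) -> None:
        if not (0.0 < self.selection_alpha < 1.0):
            raise ConfigError("selection_alpha must be in (0, 1)")
        if not (0.0 < self.consensus_fraction <= 1.0):
            raise ConfigError("consensus_fraction must be in (0, 1]")
        if self.n_permutations < 100:
            raise ConfigError("n_permutations must be >= 100")
        if self.tails not in ("positive", "negative", "both"):
            raise ConfigError("tails must be positive, negative or both")
        if self.covariates is not None:
            logger.warning("covariate regression is a no-op hook in this release")


@dataclass
class EdgeMask:
    """Disjoint positive- and negative-tail edge indicators."""

    positive: np.ndarray
    negative: np.ndarray

    def __post_init__(self) -> None:
        self.positive = np.asarray(self.positive, dtype=bool)
        self.negative = np.asarray(self.negative, dtype=bool)
        if self.positive.shape != self.negative.shape:
            raise ConfigError("positive/negative masks must share shape")
        if (self.positive & self.negative).any():
            raise ConfigError("positive and negative masks must be disjoint")

    @property
    def combined(self) -> np.ndarray:
        return self.positive | self.negative

    @property
    def n_edges(self) -> int:
        return int(self.positive.size)


@dataclass
class CPMResult:
    """Cross-validated predictions and everything needed downstream."""

    predictions: Dict[str, np.ndarray]
    r_obs: Dict[str, float]
    fold_positive: np.ndarray  # folds x edges boolean
    fold_negative: np.ndarray
    consensus_mask: EdgeMask
    config: CPMConfig
    p_perm: Optional[Dict[str, float]] = None

    @property
    def n_subjects(self) -> int:
        return int(self.fold_positive.shape[0])


def critical_r(n_samples: int, alpha: float) -> float:
    """|r| threshold equivalent to a two-sided Pearson p < alpha at n samples."""
    df = n_samples - 2
    if df <= 0:
        raise ConfigError("need at least 3 samples for edge selection")
    tcrit = stats.t.isf(alpha / 2.0, df)
    return float(tcrit / math.sqrt(tcrit * tcrit + df))


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        logger.info("degenerate correlation (constant input) reported as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def select_edges(train_edges: np.ndarray, train_behavior: np.ndarray,
                 alpha: float = 0.01) -> EdgeMask:
    """Mask edges whose behavior correlation passes two-sided p < alpha.

    Positive mask: r > 0 and p < alpha; negative mask: r < 0 and p < alpha.
    """
    X = np.asarray(train_edges, float)
    y = np.asarray(train_behavior, float)
    n = y.size
    if n < 3:
        raise ConfigError("need >=3 training subjects")
    if y.std() == 0:
        raise ConstantBehaviorError("behavior has zero variance")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    num = Xc.T @ yc
    den = np.sqrt((Xc * Xc).sum(axis=0) * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.maximum(den, np.finfo(float).tiny), 0.0)
    rc = critical_r(n, alpha)
    return EdgeMask(positive=r > rc, negative=r < -rc)


def strength_features(subject_edges: np.ndarray, mask: EdgeMask) -> Tuple[float, float]:
    """Sum of the subject's edge z-values over each tail of a mask."""
    v = np.asarray(subject_edges, float)
    if v.shape[-1] != mask.n_edges:
        raise ConfigError("mask dimensioned to a different edge count")
    return float(v[..., mask.positive].sum(-1)), float(v[..., mask.negative].sum(-1))


def _predict_single(f: np.ndarray, y: np.ndarray, i: int, m: int,
                    sy: float) -> float:
    """OLS y ~ a + b*f on all subjects but i; predict subject i."""
    fi = f[i]
    sf = f.sum() - fi
    sff = float(f @ f) - fi * fi
    sfy = float(f @ y) - fi * y[i]
    varf = sff - sf * sf / m
    if varf <= 1e-12:
        return sy / m
    slope = (sfy - sf * sy / m) / varf
    intercept = (sy - slope * sf) / m
    return intercept + slope * fi


def _predict_combined(fp: np.ndarray, fn: np.ndarray, y: np.ndarray, i: int,
                      m: int, sy: float) -> float:
    """Two-feature OLS on the training rows; least-squares on singularity."""
    fpi, fni, yi = fp[i], fn[i], y[i]
    sfp = fp.sum() - fpi
    sfn = fn.sum() - fni
    spp = float(fp @ fp) - fpi * fpi
    snn = float(fn @ fn) - fni * fni
    spn = float(fp @ fn) - fpi * fni
    spy = float(fp @ y) - fpi * yi
    sny = float(fn @ y) - fni * yi
    A = np.array([[m, sfp, sfn], [sfp, spp, spn], [sfn, spn, snn]])
    b = np.array([sy, spy, sny])
    try:
        coef = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        coef = np.linalg.lstsq(A, b, rcond=None)[0]
    if not np.isfinite(coef).all():
        return sy / m
    return float(coef[0] + coef[1] * fpi + coef[2] * fni)


def _loocv_core(X: np.ndarray, y: np.ndarray, alpha: float,
                keep_masks: bool,
                sums: Optional[Tuple[np.ndarray, np.ndarray]] = None):
    """One full LOOCV pass: per-fold selection, features, OLS prediction.

    Returns (predictions dict, fold_pos, fold_neg); the fold masks are None
    unless ``keep_masks``.  ``sums`` may carry precomputed (Sx, Sxx) column
    sums to amortize work across permutation replicates.
    """
    n, E = X.shape
    if sums is None:
        Sx = X.sum(axis=0)
        Sxx = (X * X).sum(axis=0)
    else:
        Sx, Sxx = sums
    Sxy = X.T @ y
    Sy = float(y.sum())
    Syy = float(y @ y)
    m = n - 1
    rc = critical_r(m, alpha)
    tiny = np.finfo(float).tiny
    preds = {k: np.empty(n) for k in MODELS}
    fold_pos = np.zeros((n, E), dtype=bool) if keep_masks else None
    fold_neg = np.zeros((n, E), dtype=bool) if keep_masks else None
    empty_folds = 0
    for i in range(n):
        xi = X[i]
        yi = y[i]
        sx = Sx - xi
        sxy = Sxy - xi * yi
        sy = Sy - yi
        cov = sxy - sx * (sy / m)
        varx = (Sxx - xi * xi) - sx * (sx / m)
        # training-behavior variance scale (syy - sy^2/m)
        vary = Syy - yi * yi - sy * sy / m
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.sqrt(np.maximum(varx * vary, 0.0))
            r = np.where(denom > 0, cov / np.maximum(denom, tiny), 0.0)
        pos = r > rc
        neg = r < -rc
        if keep_masks:
            fold_pos[i] = pos
            fold_neg[i] = neg
        has_pos = pos.any()
        has_neg = neg.any()
        fp = X[:, pos].sum(axis=1) if has_pos else None
        fn = X[:, neg].sum(axis=1) if has_neg else None
        if has_pos:
            preds["positive"][i] = _predict_single(fp, y, i, m, sy)
        else:
            preds["positive"][i] = sy / m
            empty_folds += 1
        if has_neg:
            preds["negative"][i] = _predict_single(fn, y, i, m, sy)
        else:
            preds["negative"][i] = sy / m
        if has_pos and has_neg:
            preds["combined"][i] = _predict_combined(fp, fn, y, i, m, sy)
        elif has_pos:
            preds["combined"][i] = preds["positive"][i]
        elif has_neg:
            preds["combined"][i] = preds["negative"][i]
        else:
            preds["combined"][i] = sy / m
    if empty_folds:
        logger.info("%d/%d folds had an empty positive mask (mean predicted)",
                    empty_folds, n)
    return preds, fold_pos, fold_neg


def consensus_from_folds(fold_pos: np.ndarray, fold_neg: np.ndarray,
                         fraction: float) -> EdgeMask:
    n_folds = fold_pos.shape[0]
    need = fraction * n_folds - 1e-9
    pos = fold_pos.sum(axis=0) >= max(need, 1e-9)
    neg = fold_neg.sum(axis=0) >= max(need, 1e-9)
    both = pos & neg  # can only happen at tiny fractions; break toward neither
    if both.any():
        pos = pos & ~both
        neg = neg & ~both
    return EdgeMask(positive=pos, negative=neg)


def fit_predict_loocv(edges: np.ndarray, behavior: np.ndarray,
                      config: Optional[CPMConfig] = None) -> CPMResult:
    """Run the full LOOCV CPM pipeline.

    ``edges`` is subjects x edges (Fisher-z); ``behavior`` the score to
    predict.  Returns per-fold masks, cross-validated predictions and
    observed-vs-predicted r per model, plus the consensus connectome.
    """
    config = config or CPMConfig()
    X = np.asarray(edges, float)
    y = np.asarray(behavior, float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ConfigError("edges must be subjects x edges matching behavior")
    if y.size < 10:
        raise ConfigError("need >=10 subjects for LOOCV")
    if y.std() == 0:
        raise ConstantBehaviorError("behavior has zero variance")
    preds, fold_pos, fold_neg = _loocv_core(X, y, config.selection_alpha, True)
    r_obs = {k: _safe_pearson(preds[k], y) for k in MODELS}
    consensus = consensus_from_folds(fold_pos, fold_neg, config.consensus_fraction)
    return CPMResult(
        predictions=preds,
        r_obs=r_obs,
        fold_positive=fold_pos,
        fold_negative=fold_neg,
        consensus_mask=consensus,
        config=config,
    )


def permutation_test(edges: np.ndarray, behavior: np.ndarray,
                     config: Optional[CPMConfig] = None,
                     result: Optional[CPMResult] = None) -> Dict[str, float]:
    """One-tailed permutation p per model, rerunning per-fold selection.

    p = (1 + #{r_perm >= r_obs}) / (n_permutations + 1), reproducible from
    ``config.seed``.  When a precomputed ``result`` is supplied its r_obs
    is reused (and p_perm is written back onto it).
    """
    config = config or CPMConfig()
    X = np.asarray(edges, float)
    y = np.asarray(behavior, float)
    if result is None:
        result = fit_predict_loocv(X, y, config)
    rng = np.random.default_rng(config.seed)
    Sx = X.sum(axis=0)
    Sxx = (X * X).sum(axis=0)
    counts = {k: 0 for k in MODELS}
    n = y.size
    for _ in range(config.n_permutations):
        yp = y[rng.permutation(n)]
        preds, _, _ = _loocv_core(X, yp, config.selection_alpha, False, (Sx, Sxx))
        for k in MODELS:
            if _safe_pearson(preds[k], yp) >= result.r_obs[k]:
                counts[k] += 1
    p = {k: (1.0 + counts[k]) / (config.n_permutations + 1.0) for k in MODELS}
    result.p_perm = p
    return p


def consensus_connectome(result: CPMResult, fraction: Optional[float] = None) -> EdgeMask:
    """Edges selected with the same sign in >= fraction of LOOCV folds."""
    if fraction is None:
        fraction = result.config.consensus_fraction
    if not (0.0 < fraction <= 1.0):
        raise ConfigError("fraction must be in (0, 1]")
    return consensus_from_folds(result.fold_positive, result.fold_negative, fraction)
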