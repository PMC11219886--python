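"""Synthetic split-night cohorts with planted connectome-behavior signal.

The generator emulates the study design the downstream analysis assumes:

* three sleep schedules — full sleep (FS, in bed 23:00-08:00), early-night
  deprivation (early_dep, sleeps 03:00-07:30) and late-night deprivation
  (late_dep, sleeps 23:00-03:30);
* hypnograms built from ~90-minute NREM/REM cycles whose REM fraction
  ramps up across the night (anchored to clock time, so the late-night
  sleepers get the REM-rich cycles), with a sleep-onset latency, brief
  awakenings and a short terminal wake;
* per-group REM-duration laws on the scale of an overnight-lab sample
  (defaults back-computed from group TST x REM%); each drawn duration is
  reconciled with the subject's hypnogram by resampling REM epochs so the
  scored duration matches the draw to within one epoch;
* Fisher-z connectivity edge vectors = a network-structured baseline
  (within- vs between-network correlation levels) + beta x standardized
  REM duration on a planted edge set + independent Gaussian edge noise,
  optionally with a group-level depression of the planted DMN-DMN edges
  in the late-deprivation group.

Everything is reproducible from ``CohortConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .connectome import (
    NETWORKS,
    Parcellation,
    devectorize,
    edge_pair_codes,
    n_edges_for,
    pair_code_of,
    parcellation_from_sizes,
    triu_pairs,
)
from .errors import ConfigError, UnknownGroupError
from .sleep import Hypnogram, rem_metrics, score_sleep_parameters

logger = logging.getLogger(__name__)

GROUPS: Tuple[str, ...] = ("FS", "early_dep", "late_dep")

#: In-bed windows (lights_off, lights_on) per group.
SCHEDULES: Dict[str, Tuple[str, str]] = {
    "FS": ("23:00", "08:00"),
    "early_dep": ("03:00", "07:30"),
    "late_dep": ("23:00", "03:30"),
}

#: Default REM-duration (minutes) mean/SD per group, back-computed from
#: group-level TST x REM-percentage summaries (approximations; see docs).
DEFAULT_REM_MEAN_SD: Dict[str, Tuple[float, float]] = {
    "FS": (102.2, 28.6),
    "early_dep": (61.3, 16.5),
    "late_dep": (38.2, 13.4),
}

#: Default 227-node split across the ten networks (DMN-heavy, as in the
#: cortical/subcortical template family the node count comes from).
DEFAULT_NETWORK_SIZES: Dict[str, int] = {
    "DMN": 58, "VIS": 31, "FPN": 24, "DAN": 11, "VAN": 9,
    "SAN": 18, "CON": 14, "AUD": 13, "SMN": 36, "SUB": 13,
}

#: Network pairs that host the default planted edges, with edge counts.
DEFAULT_PLANTED_COMPOSITION: Dict[Tuple[str, str], int] = {
    ("DMN", "DMN"): 14,
    ("DMN", "VIS"): 10,
    ("VIS", "SUB"): 8,
    ("CON", "CON"): 8,
}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_per_group: Dict[str, int] = field(
        default_factory=lambda: {"FS": 36, "early_dep": 41, "late_dep": 36})
    rem_mean_sd: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REM_MEAN_SD))
    n_nodes: int = 227
    network_sizes: Optional[Dict[str, int]] = None
    planted_edges: Optional[Sequence[Tuple[int, int]]] = None
    n_planted: int = 40
    beta: float = 0.1
    edge_noise_sd: float = 0.1
    rho_within: float = 0.3
    rho_between: float = 0.1
    n_timepoints: int = 230
    dmn_group_delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise UnknownGroupError(f"unknown group {g!r}")
            if n <= 0:
                raise ConfigError("group sizes must be > 0")
        for g, (mu, sd) in self.rem_mean_sd.items():
            if sd <= 0:
                raise ConfigError("REM duration SDs must be > 0")
        if not (0.0 <= self.rho_between <= self.rho_within < 1.0):
            raise ConfigError("need 0 <= rho_between <= rho_within < 1")
        if self.edge_noise_sd <= 0:
            raise ConfigError("edge_noise_sd must be > 0")
        if self.network_sizes is None:
            self.network_sizes = _scaled_network_sizes(self.n_nodes)
        if sum(self.network_sizes.values()) != self.n_nodes:
            raise ConfigError("network_sizes must sum to n_nodes")
        if self.planted_edges is not None:
            seen = set()
            for (a, b) in self.planted_edges:
                if a == b or not (0 <= a < self.n_nodes and 0 <= b < self.n_nodes):
                    raise ConfigError(f"planted edge ({a},{b}) out of node range")
                key = (min(a, b), max(a, b))
                if key in seen:
                    raise ConfigError(f"planted edge ({a},{b}) duplicated")
                seen.add(key)


def _scaled_network_sizes(n_nodes: int) -> Dict[str, int]:
    """Scale the default 227-node network split to any node count."""
    if n_nodes == 227:
        return dict(DEFAULT_NETWORK_SIZES)
    total = sum(DEFAULT_NETWORK_SIZES.values())
    sizes = {k: max(1, int(round(v * n_nodes / total)))
             for k, v in DEFAULT_NETWORK_SIZES.items()}
    # fix rounding drift on the largest networks
    order = sorted(sizes, key=sizes.get, reverse=True)
    i = 0
    while sum(sizes.values()) != n_nodes:
        k = order[i % len(order)]
        sizes[k] += 1 if sum(sizes.values()) < n_nodes else -1
        if sizes[k] == 0:
            sizes[k] = 1
        i += 1
    return sizes


@dataclass
class SubjectRecord:
    """One simulated participant."""

    subject_id: str
    group: str
    hypnogram: Hypnogram
    rem_duration_min: float
    rem_proportion_pct: float
    edges: np.ndarray  # canonical upper-triangle Fisher-z edge vector

    @property
    def connectivity(self) -> np.ndarray:
        """Dense symmetric Fisher-z matrix (materialized on demand)."""
        return devectorize(self.edges)


@dataclass
class Cohort:
    """Generated cohort plus the objects downstream stages need."""

    subjects: List[SubjectRecord]
    parcellation: Parcellation
    planted_edges: np.ndarray  # edge indices into the canonical vectorization
    config: CohortConfig

    @property
    def edge_matrix(self) -> np.ndarray:
        return np.stack([s.edges for s in self.subjects])

    @property
    def behavior(self) -> np.ndarray:
        return np.array([s.rem_duration_min for s in self.subjects])

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def behavior_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "subject_id": [s.subject_id for s in self.subjects],
            "group": [s.group for s in self.subjects],
            "rem_duration_min": [s.rem_duration_min for s in self.subjects],
            "rem_proportion_pct": [s.rem_proportion_pct for s in self.subjects],
        })


def _clock_minutes(clock: str) -> int:
    h, m = clock.split(":")
    return int(h) * 60 + int(m)


def _rem_fraction(hours_since_2300: float) -> float:
    """Circadian REM pressure: ~10% of a cycle early, ~35% late night."""
    return 0.10 + 0.25 * float(np.clip((hours_since_2300 - 0.75) / 6.0, 0.0, 1.0))


def _n3_fraction(hours_since_2300: float) -> float:
    """Slow-wave pressure declines across the night."""
    return 0.32 - 0.24 * float(np.clip(hours_since_2300 / 7.0, 0.0, 1.0))


def generate_hypnogram(group: str, config: Optional[CohortConfig] = None,
                       rng: Optional[np.random.Generator] = None,
                       subject_id: str = "") -> Hypnogram:
    """Semi-Markov cycle hypnogram for one subject of a schedule group.

    Sleep is organized in ~90-minute cycles (N1 -> N2 -> N3 -> N2 -> REM);
    the REM share of each cycle follows the circadian ramp, so late-night
    epochs are REM-dominant regardless of when the group goes to bed.
    """
    if group not in SCHEDULES:
        raise UnknownGroupError(f"unknown group {group!r}")
    config = config or CohortConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    start, end = SCHEDULES[group]
    span_min = (_clock_minutes(end) - _clock_minutes(start)) % (24 * 60)
    n_ep = int(span_min * 2)
    t0 = (_clock_minutes(start) - _clock_minutes("23:00")) % (24 * 60)

    stages: List[str] = []
    latency_min = float(np.clip(rng.normal(8.0, 4.0), 1.0, 25.0))
    stages.extend(["W"] * int(round(latency_min * 2)))
    while len(stages) < n_ep:
        cyc_len = int(np.clip(rng.normal(180, 15), 150, 210))
        mid_h = (t0 + (len(stages) + cyc_len / 2) * 0.5) / 60.0
        f_rem = _rem_fraction(mid_h)
        f_n3 = _n3_fraction(mid_h)
        r_ep = int(round(f_rem * cyc_len))
        n3_ep = int(round(f_n3 * cyc_len))
        n1_ep = int(round(0.05 * cyc_len))
        n2_ep = max(cyc_len - r_ep - n3_ep - n1_ep, 0)
        block = (["N1"] * n1_ep + ["N2"] * (n2_ep // 2) + ["N3"] * n3_ep
                 + ["N2"] * (n2_ep - n2_ep // 2) + ["R"] * r_ep)
        if rng.random() < 0.6:  # brief awakening somewhere in the cycle
            w = int(rng.integers(1, 7))
            pos = int(rng.integers(0, max(len(block) - 1, 1)))
            block[pos:pos] = ["W"] * w
        stages.extend(block)
    stages = stages[:n_ep]
    for k in range(int(rng.integers(0, 8))):  # short terminal wake
        idx = n_ep - 1 - k
        if idx >= 0:
            stages[idx] = "W"
    return Hypnogram(subject_id=subject_id, lights_off=start,
                     stages=np.array(stages), epoch_length_s=30.0)


def _retarget_rem(stages: np.ndarray, target_epochs: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Resample REM epochs so the R count equals ``target_epochs`` exactly.

    Only sleep epochs are relabeled (TST is preserved).  REM runs are grown
    at their boundaries when more REM is needed and trimmed when less is,
    keeping the cycle structure plausible.
    """
    st = stages.copy()
    asleep = st != "W"
    n_sleep = int(asleep.sum())
    target = int(np.clip(target_epochs, 0, n_sleep))
    is_r = st == "R"
    if target > 0 and not is_r.any():
        # seed one REM epoch late in the sleep period
        sleep_idx = np.flatnonzero(asleep)
        st[sleep_idx[int(0.75 * (len(sleep_idx) - 1))]] = "R"
        is_r = st == "R"
    while int(is_r.sum()) < target:
        r_idx = np.flatnonzero(is_r)
        left = r_idx - 1
        right = r_idx + 1
        cand = np.concatenate([left[left >= 0], right[right < st.size]])
        cand = np.unique(cand)
        cand = cand[(st[cand] != "R") & (st[cand] != "W")]
        need = target - int(is_r.sum())
        if cand.size == 0:  # grow from scratch among any sleep epochs
            cand = np.flatnonzero(asleep & ~is_r)
            cand = rng.permutation(cand)
        take = cand[:need]
        st[take] = "R"
        is_r = st == "R"
    while int(is_r.sum()) > target:
        r_idx = np.flatnonzero(is_r)
        # trim run boundaries (first epoch of each run) first
        run_starts = r_idx[np.concatenate([[True], np.diff(r_idx) > 1])]
        need = int(is_r.sum()) - target
        take = run_starts[:need] if run_starts.size else r_idx[:need]
        st[take] = "N2"
        is_r = st == "R"
    return st


def default_planted_edges(parc: Parcellation, rng: np.random.Generator,
                          n_planted: int = 40) -> np.ndarray:
    """Planted edge indices spread over DMN-DMN, DMN-VIS, VIS-SUB, CON-CON.

    Edge counts per pair follow :data:`DEFAULT_PLANTED_COMPOSITION`,
    rescaled when ``n_planted`` differs from 40.
    """
    codes = edge_pair_codes(parc)
    comp = DEFAULT_PLANTED_COMPOSITION
    total = sum(comp.values())
    chosen: List[int] = []
    items = list(comp.items())
    for i, (pair, count) in enumerate(items):
        k = int(round(count * n_planted / total))
        if i == len(items) - 1:
            k = n_planted - len(chosen)
        pool = np.flatnonzero(codes == pair_code_of(pair))
        if pool.size < k:
            raise ConfigError(
                f"parcellation too small: pair {pair} has {pool.size} edges, need {k}")
        chosen.extend(rng.choice(pool, size=k, replace=False).tolist())
    return np.sort(np.array(chosen, dtype=int))


def planted_beta_for_r2(r2: float, noise_sd: float, n_planted: int = 40,
                        level: str = "edge") -> float:
    """Closed-form beta for a target population R² of the planted signal.

    level="edge": each planted edge individually has R² = r2 against the
    standardized behavior, i.e. beta = noise_sd * sqrt(r2 / (1 - r2)).
    level="feature": the *sum* over the planted set has R² = r2, i.e.
    beta = noise_sd * sqrt(r2 / ((1 - r2) * n_planted)).
    """
    if not (0.0 < r2 < 1.0):
        raise ConfigError("r2 must be in (0, 1)")
    if level == "edge":
        return noise_sd * float(np.sqrt(r2 / (1.0 - r2)))
    if level == "feature":
        return noise_sd * float(np.sqrt(r2 / ((1.0 - r2) * n_planted)))
    raise ConfigError("level must be 'edge' or 'feature'")


def generate_cohort(config: Optional[CohortConfig] = None) -> Cohort:
    """Generate a full cohort: hypnograms, behavior, and edge vectors."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    parc = parcellation_from_sizes(config.network_sizes)
    E = parc.n_edges

    if config.planted_edges is not None:
        iu, ju = triu_pairs(config.n_nodes)
        pos = {(int(a), int(b)): e for e, (a, b) in enumerate(zip(iu, ju))}
        planted = np.sort(np.array(
            [pos[(min(a, b), max(a, b))] for a, b in config.planted_edges], dtype=int))
    else:
        planted = default_planted_edges(parc, rng, config.n_planted)

    subjects: List[SubjectRecord] = []
    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        mu, sd = config.rem_mean_sd[group]
        for k in range(n):
            sid = f"{group}_{k:03d}"
            h = generate_hypnogram(group, config, rng, subject_id=sid)
            params = score_sleep_parameters(h)
            target_min = float(np.clip(rng.normal(mu, sd), 5.0,
                                       0.9 * max(params.tst_min, 10.0)))
            st = _retarget_rem(h.stages, int(round(target_min * 2)), rng)
            h = Hypnogram(subject_id=sid, lights_off=h.lights_off, stages=st,
                          epoch_length_s=h.epoch_length_s)
            dur, prop = rem_metrics(h)
            subjects.append(SubjectRecord(
                subject_id=sid, group=group, hypnogram=h,
                rem_duration_min=dur, rem_proportion_pct=prop,
                edges=np.empty(0),
            ))

    durations = np.array([s.rem_duration_min for s in subjects])
    z_y = (durations - durations.mean()) / durations.std()

    codes = edge_pair_codes(parc)
    iu, ju = triu_pairs(config.n_nodes)
    within = parc.labels[iu] == parc.labels[ju]
    base = np.where(within, np.arctanh(config.rho_within),
                    np.arctanh(config.rho_between))
    dmn_planted = planted[codes[planted] == pair_code_of(("DMN", "DMN"))]

    for s, zy in zip(subjects, z_y):
        edges = base.copy()
        edges[planted] += config.beta * zy
        if config.dmn_group_delta and s.group == "late_dep":
            edges[dmn_planted] -= config.dmn_group_delta
        edges += rng.normal(0.0, config.edge_noise_sd, size=E)
        s.edges = edges

    return Cohort(subjects=subjects, parcellation=parc,
                  planted_edges=planted, config=config)


def realize_timeseries(target: np.ndarray, n_timepoints: int,
                       rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Sample node time series whose correlation back-transforms the target.

    ``target`` is a Fisher-z connectivity matrix; its tanh back-transform
    (unit diagonal) is repaired to the nearest positive-definite
    correlation matrix by eigenvalue clipping when needed (logged), then
    ``n_timepoints`` multivariate-normal draws are taken.
    """
    rng = rng if rng is not None else np.random.default_rng()
    z = np.asarray(target, float)
    C = np.tanh(z)
    np.fill_diagonal(C, 1.0)
    n = C.shape[0]
    if n_timepoints < n + 1:
        logger.warning(
            "n_timepoints=%d < n_nodes+1=%d: downstream FC will be rank-deficient",
            n_timepoints, n + 1)
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    if w.min() < 1e-10:
        logger.info("correlation target not positive definite "
                    "(min eigenvalue %.3e); clipped", w.min())
        w = np.clip(w, 1e-10, None)
        C = (V * w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        w, V = np.linalg.eigh((C + C.T) / 2.0)
        w = np.clip(w, 1e-12, None)
    L = V * np.sqrt(w)
    return (L @ rng.standard_normal((n, int(n_timepoints))))
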