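"""End-to-end orchestration: simulate -> score -> cpm -> characterize -> groups.

Every stage writes a JSON/CSV artifact embedding the seed, a config echo
and the package version; a stage failure aborts with a :class:`StageError`
naming the stage so the CLI can exit non-zero with a useful message.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import io as rio
from .characterize import characterize
from .cpm import CPMConfig, fit_predict_loocv, permutation_test
from .errors import RemcpmError, StageError
from .groups import compare_groups
from .sleep import group_summary, score_sleep_parameters, summarize_parameters
from .synthetic import CohortConfig, generate_cohort, realize_timeseries

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and knobs for a full pipeline run."""

    out_dir: str = "remcpm_run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cpm: CPMConfig = field(default_factory=CPMConfig)
    correction: str = "bh"
    alpha: float = 0.05
    split_clock: str = "03:30"
    emit_timeseries: bool = False
    run_permutations: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        cpm = CPMConfig(**raw.pop("cpm", {}))
        return cls(cohort=cohort, cpm=cpm, **raw)

    def echo(self) -> Dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # volatile path; keeps rerun artifacts identical
        if d["cohort"].get("planted_edges") is not None:
            d["cohort"]["planted_edges"] = [list(e) for e in d["cohort"]["planted_edges"]]
        d["cpm"].pop("covariates", None)
        return d


def write_cohort(cohort, out_dir, emit_timeseries: bool = False,
                 n_timepoints: Optional[int] = None,
                 seed: Optional[int] = None) -> Dict:
    """Materialize a cohort on disk (behavior CSV, TSV/CSV per subject)."""
    out = Path(out_dir)
    (out / "hypnograms").mkdir(parents=True, exist_ok=True)
    (out / "fc").mkdir(exist_ok=True)
    rio.write_behavior(cohort.behavior_frame(), out / "behavior.csv")
    rio.write_parcellation(cohort.parcellation, out / "parcellation.tsv")
    paths = {"behavior": "behavior.csv", "parcellation": "parcellation.tsv",
             "hypnograms": [], "fc": [], "timeseries": []}
    rng = np.random.default_rng(seed)
    if emit_timeseries:
        (out / "timeseries").mkdir(exist_ok=True)
    for s in cohort.subjects:
        hp = out / "hypnograms" / f"{s.subject_id}.tsv"
        rio.write_hypnogram(s.hypnogram, hp)
        paths["hypnograms"].append(str(hp.relative_to(out)))
        fp = out / "fc" / f"{s.subject_id}.csv"
        rio.write_matrix(s.connectivity, fp)
        paths["fc"].append(str(fp.relative_to(out)))
        if emit_timeseries:
            T = n_timepoints or cohort.config.n_timepoints
            ts = realize_timeseries(s.connectivity, T, rng)
            tp = out / "timeseries" / f"{s.subject_id}.csv"
            np.savetxt(tp, ts, fmt="%.6f", delimiter=",")
            paths["timeseries"].append(str(tp.relative_to(out)))
    manifest = rio.provenance(seed, dataclasses.asdict(cohort.config))
    manifest["files"] = paths
    rio.write_json(manifest, out / "manifest.json")
    return manifest


def run_pipeline(config: RunConfig) -> Dict[str, str]:
    """Execute the full synthetic-cohort pipeline; returns artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, str] = {}

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        _stage("simulate")
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        cohort = generate_cohort(cohort_cfg)
        write_cohort(cohort, out / "cohort", seed=config.seed,
                     emit_timeseries=config.emit_timeseries)
        artifacts["cohort"] = str(out / "cohort")
    except RemcpmError as exc:
        raise StageError("simulate", str(exc)) from exc

    try:
        _stage("score-sleep")
        rows = [(s.subject_id, s.group, score_sleep_parameters(s.hypnogram))
                for s in cohort.subjects]
        frame = summarize_parameters(rows)
        frame.to_csv(out / "sleep_parameters.csv", index=False)
        group_summary(frame).to_csv(out / "sleep_group_summary.csv")
        artifacts["sleep"] = str(out / "sleep_parameters.csv")
    except RemcpmError as exc:
        raise StageError("score-sleep", str(exc)) from exc

    try:
        _stage("cpm")
        cpm_cfg = dataclasses.replace(config.cpm, seed=config.seed)
        X = cohort.edge_matrix
        y = cohort.behavior
        result = fit_predict_loocv(X, y, cpm_cfg)
        if config.run_permutations:
            permutation_test(X, y, cpm_cfg, result)
        payload = rio.provenance(config.seed, config.echo())
        payload.update({
            "r_obs": result.r_obs,
            "p_perm": result.p_perm,
            "n_subjects": result.n_subjects,
            "consensus_positive": np.flatnonzero(result.consensus_mask.positive),
            "consensus_negative": np.flatnonzero(result.consensus_mask.negative),
        })
        rio.write_json(payload, out / "cpm_result.json")
        artifacts["cpm"] = str(out / "cpm_result.json")
    except RemcpmError as exc:
        raise StageError("cpm", str(exc)) from exc

    try:
        _stage("characterize")
        mask = result.consensus_mask
        if mask.combined.any():
            report = characterize(X, y, mask, cohort.parcellation)
            payload = rio.provenance(config.seed, config.echo())
            payload["report"] = report.to_dict()
            rio.write_json(payload, out / "characterization.json")
            artifacts["characterization"] = str(out / "characterization.json")
        else:
            logger.warning("consensus mask empty; characterization skipped")
    except RemcpmError as exc:
        raise StageError("characterize", str(exc)) from exc

    try:
        _stage("group-compare")
        if mask.combined.any():
            cmp = compare_groups(X, cohort.groups, mask, cohort.parcellation,
                                 correction=config.correction, alpha=config.alpha)
            payload = rio.provenance(config.seed, config.echo())
            payload["groups"] = cmp.to_dict()
            rio.write_json(payload, out / "group_comparison.json")
            artifacts["groups"] = str(out / "group_comparison.json")
    except RemcpmError as exc:
        raise StageError("group-compare", str(exc)) from exc

    return artifacts
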