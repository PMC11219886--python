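"""Plain-text file formats: hypnogram TSV, matrix/behavior CSV, parcellation.

All formats are diffable text.  Readers validate aggressively and raise
named errors that identify the offending line or cell; writers round-trip
exactly with the readers.

Hypnogram TSV dialect::

    # subject_id=FS_000
    # lights_off=23:00
    # epoch_length_s=30
    epoch_index<TAB>stage
    0<TAB>W
    1<TAB>N1
    ...

FC matrices are dense n x n CSV without header; the parcellation is a
two-column TSV ``node_id<TAB>network``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from .connectome import NETWORKS, Parcellation
from .errors import (
    AsymmetryError,
    BehaviorTableError,
    HypnogramFormatError,
    MatrixFormatError,
    UnknownStageError,
)
from .sleep import STAGES, Hypnogram

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_REQUIRED_META = ("subject_id", "lights_off", "epoch_length_s")

#: Matrices with asymmetry below this are silently symmetrized (logged).
ASYMMETRY_TOL = 1e-6

GROUP_LABELS = ("FS", "early_dep", "late_dep")


def write_hypnogram(h: Hypnogram, path: PathLike) -> None:
    path = Path(path)
    lines = [
        f"# subject_id={h.subject_id}",
        f"# lights_off={h.lights_off}",
        f"# epoch_length_s={h.epoch_length_s:g}",
        "epoch_index\tstage",
    ]
    lines.extend(f"{i}\t{s}" for i, s in enumerate(h.stages))
    path.write_text("\n".join(lines) + "\n")


def read_hypnogram(path: PathLike) -> Hypnogram:
    """Parse a hypnogram TSV; tolerant of CRLF, strict about content."""
    path = Path(path)
    meta: Dict[str, str] = {}
    stages = []
    expected_idx = 0
    header_seen = False
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise HypnogramFormatError(
                        f"{path.name}:{lineno}: metadata line without key=value")
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line.strip() != "epoch_index\tstage":
                    raise HypnogramFormatError(
                        f"{path.name}:{lineno}: expected header 'epoch_index\\tstage'")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise HypnogramFormatError(
                    f"{path.name}:{lineno}: expected two tab-separated fields")
            try:
                idx = int(parts[0])
            except ValueError:
                raise HypnogramFormatError(
                    f"{path.name}:{lineno}: non-integer epoch index {parts[0]!r}")
            if idx != expected_idx:
                raise HypnogramFormatError(
                    f"{path.name}:{lineno}: non-contiguous epoch index "
                    f"{idx} (expected {expected_idx})")
            stage = parts[1].strip()
            if stage not in STAGES:
                raise UnknownStageError(
                    f"{path.name}:{lineno}: unknown stage {stage!r}")
            stages.append(stage)
            expected_idx += 1
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise HypnogramFormatError(
            f"{path.name}: missing metadata {', '.join(missing)}")
    if not stages:
        raise HypnogramFormatError(f"{path.name}: no epochs")
    return Hypnogram(
        subject_id=meta["subject_id"],
        lights_off=meta["lights_off"],
        stages=np.array(stages),
        epoch_length_s=float(meta["epoch_length_s"]),
    )


def write_matrix(z: np.ndarray, path: PathLike) -> None:
    np.savetxt(path, np.asarray(z, float), fmt="%.6f", delimiter=",")


def read_matrix(path: PathLike, n_expected: Optional[int] = None) -> np.ndarray:
    """Dense CSV connectivity matrix; symmetrized within tolerance."""
    path = Path(path)
    try:
        z = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise MatrixFormatError(f"{path.name}: non-numeric cell ({exc})") from exc
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise MatrixFormatError(f"{path.name}: expected square matrix, got {z.shape}")
    if n_expected is not None and z.shape[0] != n_expected:
        raise MatrixFormatError(
            f"{path.name}: dimension {z.shape[0]} != parcellation size {n_expected}")
    asym = float(np.abs(z - z.T).max(initial=0.0))
    if asym > ASYMMETRY_TOL:
        raise AsymmetryError(
            f"{path.name}: asymmetry {asym:.3g} exceeds tolerance {ASYMMETRY_TOL:g}")
    if asym > 0:
        logger.info("%s: asymmetry %.3g symmetrized", path.name, asym)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return z


def write_parcellation(p: Parcellation, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\tnetwork\n")
        for i, label in enumerate(p.labels):
            fh.write(f"{i}\t{label}\n")


def read_parcellation(path: PathLike) -> Parcellation:
    frame = pd.read_csv(path, sep="\t")
    if not {"node_id", "network"}.issubset(frame.columns):
        raise MatrixFormatError(f"{Path(path).name}: need node_id and network columns")
    frame = frame.sort_values("node_id")
    if not (frame["node_id"].to_numpy() == np.arange(len(frame))).all():
        raise MatrixFormatError(
            f"{Path(path).name}: node_id must be 0-based and contiguous")
    return Parcellation(labels=frame["network"].str.strip().to_numpy())


def read_behavior(path: PathLike) -> pd.DataFrame:
    """Behavior table with subject_id, group, rem_duration_min.

    Group labels are whitespace-trimmed (logged when normalization fires);
    duplicate subjects and unknown labels are rejected.
    """
    frame = pd.read_csv(path)
    required = {"subject_id", "group", "rem_duration_min"}
    missing = required - set(frame.columns)
    if missing:
        raise BehaviorTableError(f"missing columns: {', '.join(sorted(missing))}")
    frame["subject_id"] = frame["subject_id"].astype(str).str.strip()
    raw_groups = frame["group"].astype(str)
    trimmed = raw_groups.str.strip()
    if (raw_groups != trimmed).any():
        logger.info("behavior table: trimmed whitespace from group labels")
    frame["group"] = trimmed
    dup = frame["subject_id"].duplicated()
    if dup.any():
        raise BehaviorTableError(
            f"duplicate subject_id {frame.loc[dup, 'subject_id'].iloc[0]!r}")
    bad = ~frame["group"].isin(GROUP_LABELS)
    if bad.any():
        raise BehaviorTableError(
            f"unknown group label {frame.loc[bad, 'group'].iloc[0]!r}")
    if not np.issubdtype(frame["rem_duration_min"].dtype, np.number):
        raise BehaviorTableError("rem_duration_min must be numeric")
    return frame


def write_behavior(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, index=False, float_format="%.6f")


def write_json(obj: Dict, path: PathLike) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_default) + "\n")


def provenance(seed: Optional[int], config_echo: Dict) -> Dict:
    from . import __version__

    return {"seed": seed, "version": f"remcpm {__version__}",
            "config": config_echo}
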