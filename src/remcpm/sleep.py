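"""Hypnogram container and polysomnography-style sleep parameters.

A hypnogram is the epoch-by-epoch sequence of manually scored sleep stages
(AASM alphabet W/N1/N2/N3/R, 30-second epochs by default) anchored at a
lights-off clock time.  From it we derive the standard sleep parameters:

* TST   total sleep time: minutes spent in any of N1/N2/N3/R
* SL    sleep latency: minutes from lights-off to the first sleep epoch
* WASO  wake after sleep onset: wake minutes strictly between sleep onset
        and the final sleep epoch (terminal wake is excluded so that
        TIB = TST + SL + WASO + terminal wake holds exactly)
* SE    sleep efficiency: TST / time in bed (lights-off to lights-on)
* stage percentages: share of TST per stage

plus the two REM metrics used for brain-behavior modeling, REM duration
(minutes in R) and REM proportion (percent of TST).

Definitions the scoring literature leaves open (onset = first non-wake
epoch, SE denominator = full recording span) are fixed here and documented
in docs/methods.md.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Tuple

import numpy as np

from .errors import HypnogramError, SplitError

logger = logging.getLogger(__name__)

#: AASM stage alphabet; anything else is rejected at construction/parse time.
STAGES: Tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

_SLEEP_STAGES = frozenset({"N1", "N2", "N3", "R"})


def _clock_to_minutes(clock: str) -> int:
    try:
        hh, mm = clock.split(":")
        h, m = int(hh), int(mm)
    except ValueError as exc:  # pragma: no cover - defensive
        raise HypnogramError(f"bad clock time {clock!r}, expected HH:MM") from exc
    if not (0 <= h < 24 and 0 <= m < 60):
        raise HypnogramError(f"bad clock time {clock!r}")
    return 60 * h + m


def _minutes_to_clock(minutes: float) -> str:
    minutes = int(round(minutes)) % (24 * 60)
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


@dataclass
class Hypnogram:
    """Scored stage sequence for one recording.

    Parameters
    ----------
    subject_id
        Free-form identifier.
    lights_off
        Clock time "HH:MM" at which the recording (time in bed) starts.
    stages
        Ordered stage symbols, one per epoch, each in :data:`STAGES`.
    epoch_length_s
        Epoch duration in seconds (30 by convention).
    """

    subject_id: str
    lights_off: str
    stages: np.ndarray
    epoch_length_s: float = 30.0

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="U2")
        if self.stages.size == 0:
            raise HypnogramError("empty stage sequence")
        if self.epoch_length_s <= 0:
            raise HypnogramError("epoch_length_s must be > 0")
        bad = ~np.isin(self.stages, STAGES)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise HypnogramError(
                f"unknown stage {self.stages[idx]!r} at epoch {idx}"
            )
        _clock_to_minutes(self.lights_off)  # validate format

    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    @property
    def epoch_min(self) -> float:
        return self.epoch_length_s / 60.0

    @property
    def span_min(self) -> float:
        """Time in bed in minutes (lights-off to lights-on)."""
        return self.n_epochs * self.epoch_min

    @property
    def lights_on(self) -> str:
        return _minutes_to_clock(_clock_to_minutes(self.lights_off) + self.span_min)


@dataclass(frozen=True)
class SleepParameters:
    """Scored summary of one night.  NaN marks undefined values (TST = 0)."""

    tst_min: float
    sl_min: float
    waso_min: float
    se_frac: float
    pct_n1: float
    pct_n2: float
    pct_n3: float
    pct_rem: float
    rem_duration_min: float
    tib_min: float = field(default=float("nan"))
    terminal_wake_min: float = field(default=float("nan"))


def score_sleep_parameters(h: Hypnogram) -> SleepParameters:
    """Compute TST, SL, WASO, SE, stage percentages and REM duration.

    An all-wake recording yields TST = 0 with the stage percentages and
    SL/WASO reported as NaN (missing), never as zero percentages.
    """
    epm = h.epoch_min
    asleep = np.isin(h.stages, tuple(_SLEEP_STAGES))
    tib = h.n_epochs * epm
    if not asleep.any():
        nan = float("nan")
        return SleepParameters(
            tst_min=0.0, sl_min=nan, waso_min=nan, se_frac=0.0,
            pct_n1=nan, pct_n2=nan, pct_n3=nan, pct_rem=nan,
            rem_duration_min=0.0, tib_min=tib, terminal_wake_min=nan,
        )
    onset = int(np.flatnonzero(asleep)[0])
    last = int(np.flatnonzero(asleep)[-1])
    n_sleep = int(asleep.sum())
    tst = n_sleep * epm
    sl = onset * epm
    waso = float((~asleep[onset : last + 1]).sum()) * epm
    terminal = (h.n_epochs - 1 - last) * epm
    counts = {s: int((h.stages == s).sum()) for s in ("N1", "N2", "N3", "R")}
    pct = {s: 100.0 * c / n_sleep for s, c in counts.items()}
    return SleepParameters(
        tst_min=tst,
        sl_min=sl,
        waso_min=waso,
        se_frac=tst / tib,
        pct_n1=pct["N1"],
        pct_n2=pct["N2"],
        pct_n3=pct["N3"],
        pct_rem=pct["R"],
        rem_duration_min=counts["R"] * epm,
        tib_min=tib,
        terminal_wake_min=terminal,
    )


def rem_metrics(h: Hypnogram) -> Tuple[float, float]:
    """REM duration (minutes) and REM proportion (percent of TST).

    Returns (NaN, NaN) when the recording contains no sleep.
    """
    p = score_sleep_parameters(h)
    if p.tst_min == 0:
        return float("nan"), float("nan")
    return p.rem_duration_min, 100.0 * p.rem_duration_min / p.tst_min


def segment(h: Hypnogram, split_clock: str) -> Tuple[Hypnogram, Hypnogram]:
    """Split a hypnogram at a clock time into (early, late) halves.

    The split is snapped to the nearest epoch boundary (logged when it is
    not already aligned); concatenating the two outputs reproduces the
    input, and the late half carries the split as its lights-off.
    """
    offset = (_clock_to_minutes(split_clock) - _clock_to_minutes(h.lights_off)) % (24 * 60)
    k_exact = offset / h.epoch_min
    k = int(round(k_exact))
    if abs(k_exact - k) > 1e-9:
        logger.info(
            "split %s not on an epoch boundary; snapped to epoch %d", split_clock, k
        )
    if k <= 0 or k >= h.n_epochs:
        raise SplitError(
            f"split {split_clock} outside recording window "
            f"({h.lights_off}-{h.lights_on}) or degenerate"
        )
    snapped = _minutes_to_clock(_clock_to_minutes(h.lights_off) + k * h.epoch_min)
    early = replace(h, subject_id=h.subject_id, stages=h.stages[:k].copy())
    late = Hypnogram(
        subject_id=h.subject_id,
        lights_off=snapped,
        stages=h.stages[k:].copy(),
        epoch_length_s=h.epoch_length_s,
    )
    return early, late


def summarize_parameters(rows: Iterable[Tuple[str, str, SleepParameters]]):
    """Assemble per-subject sleep parameters into a tidy table.

    ``rows`` yields (subject_id, group, SleepParameters).  Returns a pandas
    DataFrame with one row per subject; use ``.groupby('group')`` for a
    Table-1-like mean +/- SD summary.
    """
    import pandas as pd

    records = []
    for subject_id, group, p in rows:
        rec = {"subject_id": subject_id, "group": group}
        rec.update({k: getattr(p, k) for k in (
            "tst_min", "sl_min", "waso_min", "se_frac",
            "pct_n1", "pct_n2", "pct_n3", "pct_rem", "rem_duration_min",
        )})
        records.append(rec)
    return pd.DataFrame.from_records(records)


def group_summary(frame) -> "object":
    """Mean +/- SD per group for every numeric sleep parameter column."""
    numeric = frame.drop(columns=["subject_id"]).groupby("group")
    mean = numeric.mean().add_suffix("_mean")
    sd = numeric.std(ddof=1).add_suffix("_sd")
    return mean.join(sd)
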