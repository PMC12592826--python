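"""Core domain containers shared across the pipeline.

All times are seconds from recording start; bins and epochs are half-open
intervals ``[start, end)``.
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np


class StageCode(enum.Enum):
    """Sleep stage labels.

    LIGHT aggregates NREM stages 1-2, DEEP is NREM stage 3 (slow-wave
    sleep); REM and WAKE are their own states.
    """

    WAKE = "WAKE"
    LIGHT = "LIGHT"
    DEEP = "DEEP"
    REM = "REM"


STAGES: tuple[StageCode, ...] = (
    StageCode.WAKE,
    StageCode.LIGHT,
    StageCode.DEEP,
    StageCode.REM,
)

#: AASM / R&K numeric stage codes as found in scored hypnogram exports.
RAW_STAGE_MAP: dict[int, StageCode] = {
    0: StageCode.WAKE,
    1: StageCode.LIGHT,
    2: StageCode.LIGHT,
    3: StageCode.DEEP,
    4: StageCode.DEEP,  # R&K stage 4 folds into slow-wave sleep
    5: StageCode.REM,
}


class EventKind(enum.Enum):
    """Scored polysomnographic event categories."""

    OSA = "OSA"
    CSA = "CSA"
    HYPOPNEA = "HYPOPNEA"
    AROUSAL = "AROUSAL"


#: Kinds pooled into the single sleep-disordered-breathing indicator.
SDB_KINDS = frozenset({EventKind.OSA, EventKind.CSA, EventKind.HYPOPNEA})


@dataclass(frozen=True)
class Hypnogram:
    """Epoch-coded sleep-stage sequence.

    Parameters
    ----------
    stages : sequence of StageCode
        One stage per epoch.
    epoch_length : float
        Epoch duration in seconds (30 s for standard scoring).
    start_time : float
        Time of the first epoch's start, seconds from recording start.
    """

    stages: tuple[StageCode, ...]
    epoch_length: float = 30.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if not all(isinstance(s, StageCode) for s in self.stages):
            raise ValueError("stages must be StageCode values")
        object.__setattr__(self, "stages", tuple(self.stages))

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return self.epoch_length * self.n_epochs

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def stage_at(self, t: float | np.ndarray) -> StageCode | np.ndarray:
        """Stage of the epoch containing time ``t`` (vectorised)."""
        t_arr = np.asarray(t)
        idx = np.floor((t_arr - self.start_time) / self.epoch_length)
        idx = np.clip(idx.astype(int), 0, self.n_epochs - 1)
        if t_arr.ndim == 0:
            return self.stages[int(idx)]
        arr = np.empty(len(self.stages), dtype=object)
        arr[:] = self.stages
        return arr[idx]

    def seconds_in_stage(self, stage: StageCode) -> float:
        return self.epoch_length * sum(s is stage for s in self.stages)

    def sleep_window(self) -> tuple[float, float] | None:
        """``[start, end)`` span from first to last scored sleep epoch.

        Interior wake is included. ``None`` if no sleep epoch exists.
        """
        sleep_idx = [i for i, s in enumerate(self.stages) if s is not StageCode.WAKE]
        if not sleep_idx:
            return None
        lo = self.start_time + sleep_idx[0] * self.epoch_length
        hi = self.start_time + (sleep_idx[-1] + 1) * self.epoch_length
        return lo, hi


@dataclass(frozen=True)
class EventInterval:
    """A scored SDB or arousal interval, ``[start, end)`` seconds."""

    start: float
    end: float
    kind: EventKind

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"event end ({self.end}) must exceed start ({self.start})")
        if not isinstance(self.kind, EventKind):
            raise ValueError("kind must be an EventKind")


def merge_intervals(events: list[EventInterval]) -> list[EventInterval]:
    """Merge overlapping or touching same-kind intervals; sort by start."""
    out: list[EventInterval] = []
    for kind in EventKind:
        same = sorted((e for e in events if e.kind is kind), key=lambda e: e.start)
        for ev in same:
            if out_k := [e for e in out if e.kind is kind]:
                last = out_k[-1]
                if ev.start <= last.end:
                    out[out.index(last)] = EventInterval(
                        last.start, max(last.end, ev.end), kind
                    )
                    continue
            out.append(ev)
    return sorted(out, key=lambda e: (e.start, e.kind.value))


@dataclass
class RRSeries:
    """Beat times and the R-R interval ending at each beat.

    ``rr[i]`` is the interval between beat ``i-1`` and beat ``i`` when both
    were retained; after quality editing some pairs are not adjacent
    detections and are dropped rather than reinterpreted.
    """

    beat_time: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        self.beat_time = np.asarray(self.beat_time, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.beat_time.shape != self.rr.shape:
            raise ValueError("beat_time and rr must have equal length")
        if self.beat_time.size and np.any(np.diff(self.beat_time) <= 0):
            raise ValueError("beat_time must be strictly increasing")
        if np.any(self.rr <= 0):
            raise ValueError("rr intervals must be positive")

    def __len__(self) -> int:
        return self.beat_time.size

    @property
    def span(self) -> float:
        return float(self.beat_time[-1]) if len(self) else 0.0


@dataclass
class BaselineTrack:
    """Per-window baseline R-R over fixed, non-overlapping tiles."""

    window_start: np.ndarray  # start of each window, s
    window_length: float  # s
    baseline_rr: np.ndarray  # mean R-R within each window, s

    def baseline_at(self, t: float | np.ndarray) -> np.ndarray:
        idx = np.floor((np.asarray(t, dtype=float) - self.window_start[0]) / self.window_length)
        idx = np.clip(idx.astype(int), 0, len(self.baseline_rr) - 1)
        return self.baseline_rr[idx]


@dataclass(frozen=True)
class NAAEpisode:
    """One detected arrhythmia-avalanche episode."""

    onset_time: float
    end_time: float
    onset_beat_index: int
    end_beat_index: int
    baseline_rr: float
    min_rr: float
    n_beats: int
    truncated: bool = False


@dataclass
class NAAEventTrain:
    """Ordered avalanche onsets: the point process being modelled."""

    onsets: np.ndarray
    episodes: list[NAAEpisode] = field(default_factory=list)
    recording_span: float = 0.0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.episodes and len(self.episodes) != self.onsets.size:
            raise ValueError("one onset per episode")

    def __len__(self) -> int:
        return self.onsets.size


@dataclass
class ECGRecord:
    """Raw single-lead ECG samples."""

    sample_rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sample_rate


@dataclass
class QualityMask:
    """Per-segment GOOD/BAD flags covering the full recording."""

    segment_length: float
    flags: np.ndarray  # bool: True = GOOD
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    def good_at(self, t: float | np.ndarray) -> np.ndarray:
        idx = np.floor((np.asarray(t, dtype=float) - self.start_time) / self.segment_length)
        idx = np.clip(idx.astype(int), 0, self.flags.size - 1)
        return self.flags[idx]


class ConfigurationError(ValueError):
    """Invalid simulation or analysis configuration."""


class ValidationError(ValueError):
    """Input files or bundles failed cross-validation."""


def _warn(msg: str) -> None:
    warnings.warn(msg, UserWarning, stacklevel=3)
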