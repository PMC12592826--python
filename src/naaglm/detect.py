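"""Detection of nocturnal arrhythmia avalanche episodes from R-R series.

An avalanche is a transient run of shortened R-R intervals: the episode
opens at the first beat whose interval falls more than 30% below the
local baseline (the mean R-R in the enclosing fixed 10-min window) and
closes at the first later beat that has recovered to 90% of that same
baseline.  Single-beat episodes are allowed.  The baseline is frozen at
onset so an episode that crosses a window boundary keeps one consistent
recovery target.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .types import (
    STAGES,
    BaselineTrack,
    Hypnogram,
    NAAEpisode,
    NAAEventTrain,
    RRSeries,
    StageCode,
    _warn,
)


def compute_baselines(
    rr: RRSeries,
    window_s: float = 600.0,
    min_partial_beats: int = 30,
    start_time: float = 0.0,
) -> BaselineTrack:
    """Mean R-R in fixed, non-overlapping windows tiling the recording.

    The final partial window uses its own mean only if it holds at least
    ``min_partial_beats`` beats, otherwise it inherits the previous
    window's baseline; an interior empty window likewise inherits.  An
    empty first window is an error (no baseline to inherit).
    """
    if len(rr) == 0:
        raise ValueError("empty R-R series")
    span = rr.beat_time[-1] - start_time
    n_win = max(int(np.ceil(span / window_s)), 1)
    starts = start_time + window_s * np.arange(n_win)
    idx = np.clip(
        np.floor((rr.beat_time - start_time) / window_s).astype(int), 0, n_win - 1
    )
    baselines = np.empty(n_win)
    prev = np.nan
    for w in range(n_win):
        vals = rr.rr[idx == w]
        is_partial = starts[w] + window_s > start_time + span
        if vals.size == 0 or (is_partial and vals.size < min_partial_beats and w > 0):
            if w == 0 and vals.size == 0:
                raise ValueError("first baseline window contains no beats")
            baselines[w] = prev
        else:
            baselines[w] = float(vals.mean())
        prev = baselines[w]
    return BaselineTrack(starts, window_s, baselines)


def detect_episodes(
    rr: RRSeries,
    baselines: BaselineTrack,
    drop_fraction: float = 0.30,
    recovery_fraction: float = 0.90,
) -> NAAEventTrain:
    """Scan beats in order and extract avalanche episodes.

    Detection is scale-invariant: rescaling all intervals and baselines
    by a common factor leaves the episode set unchanged.
    """
    base_at = baselines.baseline_at(rr.beat_time)
    episodes: list[NAAEpisode] = []
    onsets: list[float] = []
    i, n = 0, len(rr)
    while i < n:
        if rr.rr[i] < (1.0 - drop_fraction) * base_at[i]:
            base = float(base_at[i])  # frozen for the whole episode
            j = i + 1
            while j < n and rr.rr[j] < recovery_fraction * base:
                j += 1
            truncated = j >= n
            j_end = min(j, n - 1)
            seg = rr.rr[i : j_end + 1]
            episodes.append(
                NAAEpisode(
                    onset_time=float(rr.beat_time[i]),
                    end_time=float(rr.beat_time[j_end]),
                    onset_beat_index=i,
                    end_beat_index=j_end,
                    baseline_rr=base,
                    min_rr=float(seg.min()),
                    n_beats=j_end - i + 1,
                    truncated=truncated,
                )
            )
            onsets.append(float(rr.beat_time[i]))
            if truncated:
                _warn("episode still open at end of recording; closed at last beat")
            i = j_end + 1
        else:
            i += 1
    return NAAEventTrain(np.array(onsets), episodes, recording_span=rr.span)


class AvalancheDetector(BaseEstimator):
    """Baseline tracking plus episode scanning as one transformer.

    Parameters mirror :func:`compute_baselines` / :func:`detect_episodes`.
    """

    def __init__(
        self,
        window_s: float = 600.0,
        drop_fraction: float = 0.30,
        recovery_fraction: float = 0.90,
        min_partial_beats: int = 30,
    ) -> None:
        self.window_s = window_s
        self.drop_fraction = drop_fraction
        self.recovery_fraction = recovery_fraction
        self.min_partial_beats = min_partial_beats

    def detect(self, rr: RRSeries) -> NAAEventTrain:
        self.baselines_ = compute_baselines(
            rr, self.window_s, self.min_partial_beats
        )
        return detect_episodes(
            rr, self.baselines_, self.drop_fraction, self.recovery_fraction
        )

    transform = detect


def stage_rates(
    train: NAAEventTrain, hypnogram: Hypnogram
) -> dict[StageCode | str, float | None]:
    """Avalanche onsets per hour by sleep stage, plus the overall rate.

    A stage with zero occupancy has an undefined rate, reported as None.
    """
    out: dict[StageCode | str, float | None] = {}
    onset_stages = (
        hypnogram.stage_at(train.onsets) if len(train) else np.array([], dtype=object)
    )
    for s in STAGES:
        hours = hypnogram.seconds_in_stage(s) / 3600.0
        if hours == 0.0:
            out[s] = None
            continue
        count = int(np.sum(onset_stages == s)) if len(train) else 0
        out[s] = count / hours
    total_h = hypnogram.duration / 3600.0
    out["overall"] = len(train) / total_h if total_h > 0 else None
    return out


def stage_counts(
    train: NAAEventTrain, hypnogram: Hypnogram
) -> dict[StageCode, tuple[int, float]]:
    """(onset count, exposure hours) per stage; raw material for cohort tests."""
    onset_stages = (
        hypnogram.stage_at(train.onsets) if len(train) else np.array([], dtype=object)
    )
    return {
        s: (
            int(np.sum(onset_stages == s)) if len(train) else 0,
            hypnogram.seconds_in_stage(s) / 3600.0,
        )
        for s in STAGES
    }
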