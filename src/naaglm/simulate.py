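"""Synthetic overnight recordings with known ground truth.

Every downstream stage (detection, GLM fitting, feature extraction,
goodness of fit, cohort statistics) is validated against recordings
generated here: a semi-Markov hypnogram, stage-conditional SDB/arousal
interval processes, an avalanche event train drawn forward from a known
point-process GLM, an R-R series with each avalanche embedded as a
>= 30% interval drop recovering to 90% of baseline, and optionally a
clean synthetic ECG with known R-peak times.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .spline import HISTORY_WINDOW_S
from .types import (
    SDB_KINDS,
    STAGES,
    ConfigurationError,
    ECGRecord,
    EventInterval,
    EventKind,
    Hypnogram,
    NAAEventTrain,
    RRSeries,
    StageCode,
    merge_intervals,
    _warn,
)

_W, _L, _D, _R = StageCode.WAKE, StageCode.LIGHT, StageCode.DEEP, StageCode.REM

#: Embedded (jump-chain) stage transition probabilities, row-stochastic,
#: zero diagonal; dwell times are drawn separately.
DEFAULT_TRANSITIONS: dict[StageCode, dict[StageCode, float]] = {
    _W: {_W: 0.0, _L: 0.9, _D: 0.0, _R: 0.1},
    _L: {_W: 0.15, _L: 0.0, _D: 0.5, _R: 0.35},
    _D: {_W: 0.1, _L: 0.8, _D: 0.0, _R: 0.1},
    _R: {_W: 0.3, _L: 0.7, _D: 0.0, _R: 0.0},
}

#: Mean stage dwell in 30-s epochs (geometric dwell distribution).
DEFAULT_DWELL_EPOCHS: dict[StageCode, float] = {_W: 10.0, _L: 20.0, _D: 10.0, _R: 14.0}

#: Stage-conditional event onset rates, events per hour of stage time.
DEFAULT_SDB_RATES: dict[StageCode, float] = {_W: 2.0, _L: 25.0, _D: 8.0, _R: 20.0}
DEFAULT_AROUSAL_RATES: dict[StageCode, float] = {_W: 5.0, _L: 18.0, _D: 6.0, _R: 15.0}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic-night generator.

    Durations are seconds; rates events/hour of stage time.  Event
    durations are lognormal with the given median and log-SD.  The
    avalanche depth must be at least 0.30 of baseline so embedded
    episodes satisfy the detection rule.
    """

    duration_s: float = 28_800.0
    epoch_length: float = 30.0
    start_stage: StageCode = StageCode.WAKE
    transitions: dict[StageCode, dict[StageCode, float]] = field(
        default_factory=lambda: {s: dict(r) for s, r in DEFAULT_TRANSITIONS.items()}
    )
    dwell_epochs: dict[StageCode, float] = field(
        default_factory=lambda: dict(DEFAULT_DWELL_EPOCHS)
    )
    sdb_rate_per_h: dict[StageCode, float] = field(
        default_factory=lambda: dict(DEFAULT_SDB_RATES)
    )
    arousal_rate_per_h: dict[StageCode, float] = field(
        default_factory=lambda: dict(DEFAULT_AROUSAL_RATES)
    )
    sdb_duration_median_s: float = 20.0
    sdb_duration_log_sd: float = 0.4
    arousal_duration_median_s: float = 10.0
    arousal_duration_log_sd: float = 0.4
    sdb_kind_mix: tuple[float, float, float] = (0.70, 0.25, 0.05)  # OSA, HYP, CSA
    baseline_rr_s: float = 1.0
    rr_jitter_frac: float = 0.02
    naa_depth_fraction: float = 0.35
    naa_recovery_fraction: float = 0.90
    naa_plateau_beats: int = 4
    bin_width_s: float = 1.0

    def __post_init__(self) -> None:
        if self.naa_depth_fraction < 0.30:
            raise ConfigurationError(
                "naa_depth_fraction must be >= 0.30 for detectable avalanches"
            )
        if self.baseline_rr_s <= 0:
            raise ConfigurationError("baseline_rr_s must be positive")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth GLM generating the avalanche train.

    ``stage_log_rates`` are log intensities per bin; ``history_curve``
    maps lag (s) to the log modulation and is zero beyond the 120-s
    history window (enforced on evaluation).
    """

    stage_log_rates: dict[StageCode, float]
    beta_sdb: float = 0.0
    beta_ar: float = 0.0
    history_curve: Callable[[float], float] | None = None
    bin_width: float = 1.0

    def log_modulation(self, lag: float) -> float:
        if self.history_curve is None or lag > HISTORY_WINDOW_S or lag < 0:
            return 0.0
        return float(self.history_curve(lag))

    @classmethod
    def from_rates_per_hour(
        cls,
        stage_rates_per_h: dict[StageCode, float],
        beta_sdb: float = 0.0,
        beta_ar: float = 0.0,
        history_curve: Callable[[float], float] | None = None,
        bin_width: float = 1.0,
    ) -> "TrueModel":
        logs = {
            s: float(np.log(r * bin_width / 3600.0))
            for s, r in stage_rates_per_h.items()
        }
        return cls(logs, beta_sdb, beta_ar, history_curve, bin_width)


def gaussian_bump(peak: float = 2.0, peak_lag_s: float = 15.0, width_s: float = 5.0):
    """Log-modulation curve whose exp is a Gaussian bump above 1.

    The modulation peaks at ``peak`` at ``peak_lag_s`` and relaxes to 1
    away from it; negligible by the 120-s window edge for the default
    width.
    """

    def curve(lag: float) -> float:
        return float(
            np.log1p((peak - 1.0) * np.exp(-0.5 * ((lag - peak_lag_s) / width_s) ** 2))
        )

    return curve


def hard_refractory(refractory_s: float, then: Callable[[float], float] | None = None):
    """Log-modulation of -inf (zero rate) below ``refractory_s``."""

    def curve(lag: float) -> float:
        if lag < refractory_s:
            return -np.inf
        return float(then(lag)) if then is not None else 0.0

    return curve


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# --------------------------------------------------------------- hypnogram
def simulate_hypnogram(config: SimConfig, seed=None) -> Hypnogram:
    """Semi-Markov stage sequence in fixed epochs.

    Dwell in each visited stage is geometric with the configured mean
    (in epochs); the next stage follows the embedded transition row.
    """
    rng = _rng(seed)
    n_epochs = int(np.floor(config.duration_s / config.epoch_length))
    if n_epochs < 1:
        raise ConfigurationError("duration must cover at least one epoch")
    P = np.array(
        [[config.transitions[a].get(b, 0.0) for b in STAGES] for a in STAGES]
    )
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
        raise ConfigurationError("transition matrix rows must be stochastic")
    stages: list[StageCode] = []
    state = config.start_stage
    while len(stages) < n_epochs:
        mean_dwell = max(float(config.dwell_epochs[state]), 1.0)
        dwell = int(rng.geometric(1.0 / mean_dwell))
        stages.extend([state] * min(dwell, n_epochs - len(stages)))
        state = STAGES[rng.choice(len(STAGES), p=P[STAGES.index(state)])]
    return Hypnogram(tuple(stages), config.epoch_length, 0.0)


def stationary_occupancy(config: SimConfig) -> dict[StageCode, float]:
    """Long-run epoch occupancy of the configured semi-Markov chain.

    Computed from the embedded chain's stationary vector (left
    eigenvector of the transition matrix) weighted by mean dwell.
    """
    P = np.array(
        [[config.transitions[a].get(b, 0.0) for b in STAGES] for a in STAGES]
    )
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    dwell = np.array([config.dwell_epochs[s] for s in STAGES], dtype=float)
    occ = pi * dwell
    occ /= occ.sum()
    return dict(zip(STAGES, occ))


# ----------------------------------------------------------------- events
def simulate_event_intervals(
    hypnogram: Hypnogram, config: SimConfig, seed=None
) -> list[EventInterval]:
    """Stage-conditional Poisson onsets with lognormal durations.

    Overlapping same-kind intervals are merged; SDB onsets are assigned
    OSA/hypopnea/CSA kinds by the configured mix.
    """
    rng = _rng(seed)
    for rates in (config.sdb_rate_per_h, config.arousal_rate_per_h):
        if any(r < 0 for r in rates.values()):
            raise ConfigurationError("event rates must be non-negative")
    events: list[EventInterval] = []
    epoch_h = hypnogram.epoch_length / 3600.0
    sdb_kinds = (EventKind.OSA, EventKind.HYPOPNEA, EventKind.CSA)
    for e, stage in enumerate(hypnogram.stages):
        t0 = hypnogram.start_time + e * hypnogram.epoch_length
        for rates, is_sdb in ((config.sdb_rate_per_h, True),
                              (config.arousal_rate_per_h, False)):
            lam = rates.get(stage, 0.0) * epoch_h
            for _ in range(rng.poisson(lam)):
                onset = t0 + rng.uniform(0.0, hypnogram.epoch_length)
                if is_sdb:
                    dur = rng.lognormal(
                        np.log(config.sdb_duration_median_s), config.sdb_duration_log_sd
                    )
                    kind = sdb_kinds[rng.choice(3, p=np.array(config.sdb_kind_mix))]
                else:
                    dur = rng.lognormal(
                        np.log(config.arousal_duration_median_s),
                        config.arousal_duration_log_sd,
                    )
                    kind = EventKind.AROUSAL
                end = min(onset + dur, hypnogram.end_time)
                if end > onset:
                    events.append(EventInterval(onset, end, kind))
    return merge_intervals(events)


# ------------------------------------------------------------- NAA train
def simulate_naa_events(
    true_model: TrueModel,
    hypnogram: Hypnogram,
    events: list[EventInterval],
    seed=None,
) -> NAAEventTrain:
    """Forward-simulate the avalanche train from the ground-truth GLM.

    Per bin a Bernoulli draw with p = min(1, exp(linear predictor)); the
    linear predictor combines the stage log rate, the SDB/arousal
    indicators, and the history curve at the lag since the last drawn
    event.  Event times are recorded at bin midpoints.
    """
    from .glm import _interval_indicator  # local import to avoid a cycle

    rng = _rng(seed)
    w = true_model.bin_width
    n_bins = int(np.floor(hypnogram.duration / w))
    bin_start = hypnogram.start_time + w * np.arange(n_bins)
    mid = bin_start + w / 2.0
    stages = hypnogram.stage_at(mid)
    eta = np.array([true_model.stage_log_rates[s] for s in stages])
    eta += true_model.beta_sdb * _interval_indicator(events, SDB_KINDS, bin_start, w)
    eta += true_model.beta_ar * _interval_indicator(
        events, {EventKind.AROUSAL}, bin_start, w
    )
    # history modulation depends only on the whole-bin lag to the last
    # event (event times sit at bin midpoints), so it can be tabulated
    max_lag_bins = int(np.floor(HISTORY_WINDOW_S / w))
    hist_table = np.array(
        [true_model.log_modulation(d * w) for d in range(1, max_lag_bins + 1)]
    )
    u = rng.random(n_bins)
    onsets: list[float] = []
    last_bin = -(10 ** 9)
    warned = False
    for i in range(n_bins):
        e = eta[i]
        d = i - last_bin
        if 1 <= d <= max_lag_bins:
            e = e + hist_table[d - 1]
        p = np.exp(e)
        if p > 0.5 and not warned:
            _warn("per-bin event probability exceeded 0.5; Bernoulli "
                  "approximation of the point process degrades")
            warned = True
        if u[i] < min(p, 1.0):
            onsets.append(mid[i])
            last_bin = i
    return NAAEventTrain(np.array(onsets), recording_span=hypnogram.duration)


def true_intensity(
    true_model: TrueModel,
    hypnogram: Hypnogram,
    events: list[EventInterval],
    train: NAAEventTrain,
    window: tuple[float, float] | None = None,
):
    """Per-bin ground-truth conditional intensity given a realised train.

    Mirrors the forward simulation's linear predictor (stage, SDB,
    arousal, history at the lag since the last onset before the bin), so
    it can drive time-rescaling calibration checks without fitting.
    """
    from .glm import IntensitySeries, _interval_indicator

    w = true_model.bin_width
    lo, hi = window or (hypnogram.start_time, hypnogram.end_time)
    n_bins = int(np.floor((hi - lo) / w))
    bin_start = lo + w * np.arange(n_bins)
    mid = bin_start + w / 2.0
    stages = hypnogram.stage_at(mid)
    eta = np.array([true_model.stage_log_rates[s] for s in stages])
    eta += true_model.beta_sdb * _interval_indicator(events, SDB_KINDS, bin_start, w)
    eta += true_model.beta_ar * _interval_indicator(
        events, {EventKind.AROUSAL}, bin_start, w
    )
    onsets = train.onsets
    if onsets.size:
        last = np.searchsorted(onsets, bin_start, side="left") - 1
        lag = np.where(last >= 0, mid - onsets[np.clip(last, 0, None)], np.inf)
    else:
        lag = np.full(n_bins, np.inf)
    hist = np.array([true_model.log_modulation(l) if np.isfinite(l) else 0.0
                     for l in lag])
    return IntensitySeries(bin_start, w, np.exp(eta + hist))


# -------------------------------------------------------------- R-R series
@dataclass
class SimulatedRR:
    """R-R series with the embedded-avalanche ground truth."""

    rr: RRSeries
    embedded_onsets: np.ndarray  # beat time of the first full-depth beat
    n_skipped: int = 0


def simulate_rr_series(
    naa: NAAEventTrain,
    config: SimConfig,
    seed=None,
    depth_fraction: float | None = None,
) -> SimulatedRR:
    """Embed each avalanche in a jittered constant-baseline R-R series.

    Morphology: three descending beats to (1 - depth) x baseline, a
    plateau of ``naa_plateau_beats`` beats at full depth, then a two-beat
    recovery ending at 0.95 x baseline (above the 0.90 recovery
    threshold).  The recorded embedded onset is the first full-depth
    beat.  Onsets arriving before the previous avalanche has recovered
    are skipped with a warning.

    ``depth_fraction`` overrides the configured depth, e.g. to embed
    sub-threshold dips as a detector negative control.
    """
    rng = _rng(seed)
    b = config.baseline_rr_s
    d = depth_fraction if depth_fraction is not None else config.naa_depth_fraction
    span = naa.recording_span or (naa.onsets[-1] + 60.0 if len(naa) else 600.0)
    shape = (
        [1 - d / 3.0, 1 - 2 * d / 3.0]
        + [1 - d] * config.naa_plateau_beats
        + [1 - d / 2.0, 0.95]
    )
    onset_pos = 2  # index of the first full-depth beat within `shape`
    pending = list(naa.onsets)
    beat_t: list[float] = []
    rr: list[float] = []
    embedded: list[float] = []
    t = 0.0
    n_skipped = 0
    while t < span:
        if pending and t + b >= pending[0]:
            onset = pending.pop(0)
            if t > onset:  # still inside/too close to the previous avalanche
                n_skipped += 1
                continue
            for k, frac in enumerate(shape):
                iv = b * frac
                t += iv
                beat_t.append(t)
                rr.append(iv)
                if k == onset_pos:
                    embedded.append(t)
        else:
            iv = b * (1.0 + config.rr_jitter_frac * rng.standard_normal())
            iv = max(iv, 0.5 * b)
            t += iv
            beat_t.append(t)
            rr.append(iv)
    if n_skipped:
        _warn(f"skipped {n_skipped} avalanche(s) arriving before recovery")
    return SimulatedRR(
        RRSeries(np.array(beat_t), np.array(rr)), np.array(embedded), n_skipped
    )


# ------------------------------------------------------------------- ECG
@dataclass
class SimulatedECG:
    """Synthetic ECG with its true R-peak times."""

    ecg: ECGRecord
    r_peaks: np.ndarray


def simulate_ecg(
    rr: RRSeries,
    sample_rate: float = 256.0,
    seed=None,
    noise_sd: float = 0.0,
    qrs_sigma_s: float = 0.01,
) -> SimulatedECG:
    """Template ECG: one Gaussian QRS complex per beat, optional noise."""
    rng = _rng(seed)
    if sample_rate < 128.0:
        raise ConfigurationError("sample_rate must be >= 128 Hz")
    beats = rr.beat_time
    if beats.size == 0:
        raise ValueError("R-R series has no beats")
    width = 6.0 * qrs_sigma_s
    if beats.size > 1 and np.min(np.diff(beats)) < width:
        raise ValueError("beat interval shorter than the QRS template width")
    t_end = beats[-1] + 0.5
    t = np.arange(0.0, t_end, 1.0 / sample_rate)
    x = np.zeros_like(t)
    for bt in beats:
        lo = np.searchsorted(t, bt - width)
        hi = np.searchsorted(t, bt + width)
        x[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - bt) / qrs_sigma_s) ** 2)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(t.size)
    return SimulatedECG(ECGRecord(sample_rate, x), beats.copy())


# --------------------------------------------------------------- full night
@dataclass
class SimulatedNight:
    """A complete synthetic recording with all ground truth attached."""

    config: SimConfig
    true_model: TrueModel
    hypnogram: Hypnogram
    events: list[EventInterval]
    train: NAAEventTrain
    rr: SimulatedRR


def simulate_night(
    config: SimConfig, true_model: TrueModel, seed=None
) -> SimulatedNight:
    """Hypnogram -> scored events -> avalanche train -> R-R series."""
    rng = _rng(seed)
    hyp = simulate_hypnogram(config, rng)
    events = simulate_event_intervals(hyp, config, rng)
    train = simulate_naa_events(true_model, hyp, events, rng)
    rr = simulate_rr_series(train, config, rng)
    return SimulatedNight(config, true_model, hyp, events, train, rr)
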