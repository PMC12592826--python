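"""Goodness of fit by the time-rescaling theorem and the KS statistic.

If the fitted conditional intensity is correct, the rescaled waiting
times z_j = Lambda(t_j) - Lambda(t_{j-1}) between consecutive events are
unit-exponential, so u_j = 1 - exp(-z_j) are i.i.d. Uniform(0, 1).  The
KS statistic compares the empirical distribution of the u_j against the
uniform CDF; the model passes for a recording when the statistic falls
below the sample-size-dependent 5% critical value.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kstwo

from .glm import IntensitySeries
from .types import NAAEventTrain, _warn


@dataclass
class KSResult:
    """KS comparison of rescaled event times against Uniform(0, 1)."""

    ks_stat: float
    threshold: float
    n_events: int
    passed: bool
    rescaled: np.ndarray


def time_rescale(
    intensity: IntensitySeries,
    train: NAAEventTrain,
    jitter: bool = True,
    seed=None,
) -> np.ndarray:
    """Uniform-scale rescaled inter-event values u_j.

    The cumulative intensity is the running sum of per-bin intensities,
    interpolated linearly within bins.  Because events live in discrete
    bins, each event time is by default de-discretised with a uniform
    jitter inside its bin before rescaling; the first waiting time is
    measured from the start of the intensity series.
    """
    lo = float(intensity.bin_start[0])
    hi = float(intensity.bin_start[-1] + intensity.bin_width)
    onsets = train.onsets[(train.onsets >= lo) & (train.onsets < hi)]
    if onsets.size < 2:
        _warn("fewer than two onsets in the intensity window; "
              "no rescaled intervals")
        return np.array([])
    t = onsets.astype(float).copy()
    if jitter:
        rng = np.random.default_rng(seed)
        bins = np.floor((t - lo) / intensity.bin_width)
        t = lo + (bins + rng.random(t.size)) * intensity.bin_width
        t.sort()
    cum = intensity.cumulative_at(np.concatenate([[lo], t]))
    z = np.diff(cum)
    return 1.0 - np.exp(-z)


def ks_threshold(n: int, alpha: float = 0.05) -> float:
    """Critical D-value at level ``alpha`` for sample size ``n``.

    Exact finite-n two-sided distribution for n < 35, the classical
    asymptotic c(alpha)/sqrt(n) beyond (1.358/sqrt(n) at 5%).
    """
    if n < 1:
        raise ValueError("need at least one rescaled value")
    if n < 35:
        return float(kstwo.ppf(1.0 - alpha, n))
    return float(np.sqrt(-0.5 * np.log(alpha / 2.0)) / np.sqrt(n))


def ks_statistic(rescaled: np.ndarray, alpha: float = 0.05) -> KSResult:
    """Two-sided KS statistic of the rescaled values vs Uniform(0, 1)."""
    u = np.sort(np.asarray(rescaled, dtype=float))
    n = u.size
    if n < 1:
        raise ValueError("need at least one rescaled value")
    i = np.arange(1, n + 1)
    d = np.maximum(np.abs(u - i / n), np.abs(u - (i - 1) / n)).max()
    thr = ks_threshold(n, alpha)
    return KSResult(float(d), thr, n, bool(d < thr), u)


def ks_test(
    intensity: IntensitySeries,
    train: NAAEventTrain,
    alpha: float = 0.05,
    jitter: bool = True,
    seed=None,
) -> KSResult:
    """Time-rescale then apply the KS uniformity test."""
    u = time_rescale(intensity, train, jitter=jitter, seed=seed)
    if u.size == 0:
        return KSResult(np.nan, np.nan, 0, False, u)
    return ks_statistic(u, alpha)
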