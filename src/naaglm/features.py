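"""History-modulation curve and its clinical summary features.

The fitted history filter is summarised as a multiplicative modulation
curve exp(g(lag)' h) over lag 0-120 s with pointwise 95% delta-method
bounds, from which five features are read off: the refractory period,
the increased-propensity (IP) period duration, and the IP peak height,
lag, and width.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .glm import PointProcessGLM
from .spline import HISTORY_WINDOW_S, HistoryBasis
from .types import _warn

Z95 = float(norm.ppf(0.975))


@dataclass
class ModulationCurve:
    """Multiplicative history effect with 95% pointwise bounds."""

    lag: np.ndarray
    modulation: np.ndarray
    lcb: np.ndarray | None
    ucb: np.ndarray | None

    @property
    def step(self) -> float:
        return float(self.lag[1] - self.lag[0])


@dataclass
class HistoryFeatures:
    """Five summary features of the history-modulation curve.

    All values in seconds except ``ip_peak_height`` (dimensionless
    multiplier); NaN when the defining confidence bound is unavailable.
    """

    refractory_s: float
    ip_duration_s: float
    ip_peak_height: float
    ip_peak_lag_s: float
    ip_peak_width_s: float

    def as_dict(self) -> dict[str, float]:
        return {
            "refractory_s": self.refractory_s,
            "ip_duration_s": self.ip_duration_s,
            "ip_peak_height": self.ip_peak_height,
            "ip_peak_lag_s": self.ip_peak_lag_s,
            "ip_peak_width_s": self.ip_peak_width_s,
        }


def modulation_curve(
    fit: PointProcessGLM,
    basis: HistoryBasis | None = None,
    grid_step: float = 0.1,
) -> ModulationCurve:
    """Evaluate exp(g' h) with delta-method bounds on a fixed lag grid.

    Bounds are exp(g'h +/- 1.96 sqrt(g' Sigma_h g)) with Sigma_h the
    history block of the coefficient covariance; if that block is not
    positive semi-definite the bounds are reported missing and the curve
    alone is returned.
    """
    if basis is None:
        basis = fit.basis_
    lag = np.arange(0.0, HISTORY_WINDOW_S + grid_step / 2.0, grid_step)
    G = basis.evaluate(lag)
    h = fit.history_coef_
    curve = np.exp(G @ h)
    sigma = fit.history_covariance_
    var = np.einsum("ij,jk,ik->i", G, sigma, G)
    if np.any(var < -1e-10) or not np.all(np.isfinite(var)):
        _warn("history covariance block not positive semi-definite; "
              "confidence bounds omitted")
        return ModulationCurve(lag, curve, None, None)
    half = Z95 * np.sqrt(np.clip(var, 0.0, None))
    return ModulationCurve(lag, curve, np.exp(G @ h - half), np.exp(G @ h + half))


def _first_run_length(lag: np.ndarray, below: np.ndarray) -> float:
    """Length of the maximal run of True starting at index 0."""
    if not below[0]:
        return 0.0
    stop = np.argmin(below) if not below.all() else below.size - 1
    if below.all():
        return float(lag[-1] - lag[0])
    return float(lag[stop] - lag[0])


def extract_features(
    curve: ModulationCurve, width_mode: str = "half_prominence"
) -> HistoryFeatures:
    """Read the five summary features off a modulation curve.

    * refractory: span from lag 0 while the upper bound stays below 1
      (0 if the upper bound starts at or above 1);
    * IP duration: length of the first contiguous run where the lower
      bound is at or above 1, ending at the first lag where it falls
      strictly below 1;
    * peak height / lag: maximum modulation and its (first) argmax;
    * peak width: full width of the region around the peak where the
      modulation stays above half the peak's prominence over the
      neutral level 1 (``width_mode="half_height"`` uses 0.5 x peak
      instead).
    """
    m = curve.modulation
    lag = curve.lag
    peak_i = int(np.argmax(m))
    peak = float(m[peak_i])
    peak_lag = float(lag[peak_i])

    if width_mode == "half_prominence":
        level = 1.0 + (peak - 1.0) / 2.0
    elif width_mode == "half_height":
        level = peak / 2.0
    else:
        raise ValueError("width_mode must be 'half_prominence' or 'half_height'")
    if peak <= 1.0 and width_mode == "half_prominence":
        width = 0.0
    else:
        above = m >= level
        left = peak_i
        while left > 0 and above[left - 1]:
            left -= 1
        right = peak_i
        while right < m.size - 1 and above[right + 1]:
            right += 1
        width = float(lag[right] - lag[left])

    if curve.ucb is None or curve.lcb is None:
        refractory = np.nan
        ip_dur = np.nan
    else:
        refractory = _first_run_length(lag, curve.ucb < 1.0)
        qual = curve.lcb >= 1.0
        if not qual.any():
            ip_dur = 0.0
        else:
            start = int(np.argmax(qual))
            rest = qual[start:]
            end = start + (int(np.argmin(rest)) if not rest.all() else rest.size - 1)
            ip_dur = float(lag[end] - lag[start])

    return HistoryFeatures(refractory, ip_dur, peak, peak_lag, width)
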