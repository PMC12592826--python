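"""Cardinal-spline basis for the event-history filter.

The history dependence of the avalanche rate is modelled as a smooth
function of the lag since the last event, expanded in a cardinal
(Catmull-Rom family) spline basis over the 120-s history window.  Each
basis function :math:`g_k` is a piecewise cubic that interpolates knot
coefficients: with coefficients equal to target values at the knots, the
curve passes through those values exactly, and the curve is C1 on the
window.

Convention
----------
On each knot interval the curve is the cubic Hermite interpolant with
knot tangents

    m_i = 2 * tension * (y_{i+1} - y_{i-1}) / (t_{i+1} - t_{i-1})

so tension 0.5 reproduces the classic Catmull-Rom slope on non-uniform
knots.  Phantom boundary knots at -5 s and +130 s supply the endpoint
derivatives; their values are linearly extrapolated from the adjacent
real knots, which makes the boundary tangent the one-sided difference
slope.  Outside [0, 120] s the basis is identically zero (no history
influence beyond the window).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import NAAEventTrain, _warn

HISTORY_WINDOW_S = 120.0
#: Knots used when an event train is too sparse to estimate p10 spacing.
FALLBACK_KNOTS = (0.0, 5.0, 15.0, 30.0, 50.0, 80.0, 100.0, 120.0)
BOUNDARY_KNOTS = (-5.0, 130.0)


def _hermite_weights(u: np.ndarray) -> tuple[np.ndarray, ...]:
    """Cubic Hermite shape functions h00, h10, h01, h11 at u in [0, 1]."""
    u2 = u * u
    u3 = u2 * u
    return (
        2 * u3 - 3 * u2 + 1,
        u3 - 2 * u2 + u,
        -2 * u3 + 3 * u2,
        u3 - u2,
    )


@dataclass
class HistoryBasis:
    """Cardinal-spline basis over lag since the last avalanche.

    Parameters
    ----------
    knots : array of float
        Strictly increasing knot lags in [0, 120] s; one basis function
        (and one model coefficient) per knot.
    tension : float
        Cardinal tension; 0.5 gives Catmull-Rom tangents.
    """

    knots: np.ndarray
    tension: float = 0.5
    boundary: tuple[float, float] = BOUNDARY_KNOTS
    _tangent_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.size < 2:
            raise ValueError("need at least two knots")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.knots[0] < 0 or self.knots[-1] > HISTORY_WINDOW_S:
            raise ValueError("knots must lie within [0, 120] s")
        self._tangent_matrix = self._build_tangents()

    @property
    def K(self) -> int:
        return self.knots.size

    def _build_tangents(self) -> np.ndarray:
        """K x K matrix mapping knot coefficients y to knot tangents m."""
        t = self.knots
        K = self.K
        s2 = 2.0 * self.tension
        T = np.zeros((K, K))
        for i in range(1, K - 1):
            c = s2 / (t[i + 1] - t[i - 1])
            T[i, i + 1] += c
            T[i, i - 1] -= c
        # Boundary tangents: phantom knots at -5 / +130 s hold linearly
        # extrapolated values, which collapses the centred difference to
        # the one-sided slope (scaled by 2 * tension).
        c0 = s2 / (t[1] - t[0])
        T[0, 1] += c0
        T[0, 0] -= c0
        cK = s2 / (t[-1] - t[-2])
        T[-1, -1] += cK
        T[-1, -2] -= cK
        return T

    def evaluate(self, lags: np.ndarray | float) -> np.ndarray:
        """Basis matrix at the given lags.

        Returns shape ``(n, K)`` (or ``(K,)`` for a scalar lag); rows are
        zero for lags outside [0, 120] s.
        """
        lag = np.atleast_1d(np.asarray(lags, dtype=float))
        out = np.zeros((lag.size, self.K))
        t = self.knots
        inside = (lag >= t[0]) & (lag <= t[-1])
        if np.any(inside):
            x = lag[inside]
            seg = np.clip(np.searchsorted(t, x, side="right") - 1, 0, self.K - 2)
            dt = t[seg + 1] - t[seg]
            u = (x - t[seg]) / dt
            h00, h10, h01, h11 = _hermite_weights(u)
            rows = np.zeros((x.size, self.K))
            idx = np.arange(x.size)
            rows[idx, seg] += h00
            rows[idx, seg + 1] += h01
            rows += (h10 * dt)[:, None] * self._tangent_matrix[seg]
            rows += (h11 * dt)[:, None] * self._tangent_matrix[seg + 1]
            out[inside] = rows
        return out if np.ndim(lags) else out[0]

    def curve(self, coef: np.ndarray, lags: np.ndarray) -> np.ndarray:
        """Spline value g(lag) . coef at the given lags."""
        return self.evaluate(np.atleast_1d(lags)) @ np.asarray(coef, dtype=float)


def build_history_basis(
    event_train: NAAEventTrain | np.ndarray | None,
    tension: float = 0.5,
    n_inner: int = 5,
    spacing: str = "linear",
) -> HistoryBasis:
    """Place knots from the observed inter-event interval distribution.

    Interior knots sit at 0, then ``n_inner`` knots between the 10th
    percentile of inter-event intervals and 80 s, then 100 and 120 s.
    With fewer than two events the percentile is undefined and the fixed
    fallback grid is used.
    """
    onsets = event_train.onsets if isinstance(event_train, NAAEventTrain) else event_train
    if onsets is None or len(onsets) < 2:
        return HistoryBasis(np.array(FALLBACK_KNOTS), tension=tension)
    intervals = np.diff(np.asarray(onsets, dtype=float))
    lo = float(np.percentile(intervals, 10))
    if lo >= 80.0:
        _warn(
            f"10th percentile of inter-event intervals ({lo:.1f} s) is >= 80 s; "
            "compressing inner knots to the fallback spacing"
        )
        lo = FALLBACK_KNOTS[1]
    lo = max(lo, 1.0)  # keep the first inner knot clear of the 0-s knot
    if spacing == "log":
        inner = np.geomspace(lo, 80.0, n_inner)
    elif spacing == "linear":
        inner = np.linspace(lo, 80.0, n_inner)
    else:
        raise ValueError("spacing must be 'linear' or 'log'")
    knots = np.concatenate([[0.0], inner, [100.0, HISTORY_WINDOW_S]])
    return HistoryBasis(knots, tension=tension)
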