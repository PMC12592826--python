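"""Discrete-time point-process GLM of avalanche occurrence.

Time is discretised into short bins (default 1 s).  Per bin the event
indicator ``y_t`` follows a Bernoulli law with log-link probability

    log p_t = sum_s beta_s I_s(t) + beta_SDB I_SDB(t) + beta_Ar I_Ar(t)
              + sum_k h_k g_k(lag_t)

where the four sleep-stage indicators partition time (no separate
intercept), the SDB/arousal indicators mark bins overlapped by scored
events, and ``g_k`` is the cardinal-spline history basis evaluated at the
lag since the most recent prior avalanche (zero if none within 120 s).
At realistic rates (tens of events per hour, 1-s bins) ``p_t`` is a few
per mille and the Bernoulli model is numerically indistinguishable from
the Poisson reading of the conditional intensity.

The likelihood is maximised by Newton's method with step halving, which
for this model coincides with iteratively reweighted least squares on
the zero-event rows; the covariance is the inverse observed information
at the optimum.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .spline import HISTORY_WINDOW_S, HistoryBasis, build_history_basis
from .types import (
    SDB_KINDS,
    STAGES,
    EventInterval,
    EventKind,
    Hypnogram,
    NAAEventTrain,
    StageCode,
    _warn,
)

STAGE_COLUMNS = tuple(f"I_{s.value}" for s in STAGES)
SDB_COLUMN = "I_SDB"
AROUSAL_COLUMN = "I_AR"


@dataclass
class DesignMatrix:
    """Binned covariates and event indicators for one recording."""

    bin_start: np.ndarray  # seconds, left edge of each bin
    bin_width: float
    y: np.ndarray  # 0/1 event indicator per bin
    X: np.ndarray  # (n_bins, 6 + K) covariates
    column_names: tuple[str, ...]
    include: np.ndarray  # bool: rows entering the likelihood (burn-in excluded)
    basis: HistoryBasis | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be 0/1: at most one event per bin "
                             "(reduce bin_width)")
        stage_block = self.X[:, : len(STAGE_COLUMNS)]
        if not np.allclose(stage_block.sum(axis=1), 1.0):
            raise ValueError("stage indicator columns must sum to 1 in every bin")

    @property
    def n_bins(self) -> int:
        return self.y.size

    @property
    def n_events(self) -> int:
        return int(self.y[self.include].sum())

    @property
    def history_columns(self) -> list[int]:
        return [i for i, c in enumerate(self.column_names) if c.startswith("G_")]


def _interval_indicator(
    events: list[EventInterval],
    kinds: frozenset[EventKind] | set[EventKind],
    bin_start: np.ndarray,
    bin_width: float,
    pad: float = 0.0,
) -> np.ndarray:
    """1 where a bin overlaps any event of the given kinds (optionally padded)."""
    n = bin_start.size
    ind = np.zeros(n)
    t0 = bin_start[0]
    for ev in events:
        if ev.kind not in kinds:
            continue
        lo, hi = ev.start - pad, ev.end + pad
        i0 = max(int(np.floor((lo - t0) / bin_width)), 0)
        i1 = min(int(np.ceil((hi - t0) / bin_width)), n)
        if hi > t0 and i0 < n:
            ind[i0:i1] = 1.0
    return ind


def build_design(
    train: NAAEventTrain,
    hypnogram: Hypnogram,
    events: list[EventInterval],
    basis: HistoryBasis,
    bin_width: float = 1.0,
    burn_in_s: float = HISTORY_WINDOW_S,
    window: tuple[float, float] | None = None,
    sdb_pad_s: float = 0.0,
) -> DesignMatrix:
    """Assemble the binned design for one recording.

    The analysis window defaults to the span from the first to the last
    scored sleep epoch (interior wake included); its first ``burn_in_s``
    seconds are kept in the matrix but excluded from the likelihood so
    the history filter starts from an unbiased state.  Bins are
    half-open ``[start, start + bin_width)``; an onset on an edge belongs
    to the bin on its right.
    """
    if bin_width > 2.0:
        raise ValueError("bin_width must be <= 2 s to keep bins single-event")
    if window is None:
        window = hypnogram.sleep_window() or (hypnogram.start_time, hypnogram.end_time)
    lo, hi = window
    n_bins = int(np.floor((hi - lo) / bin_width))
    if n_bins < 1:
        raise ValueError("analysis window shorter than one bin")
    bin_start = lo + bin_width * np.arange(n_bins)
    mid = bin_start + bin_width / 2.0

    onsets = train.onsets
    y = np.zeros(n_bins)
    in_win = (onsets >= lo) & (onsets < lo + n_bins * bin_width)
    idx = np.floor((onsets[in_win] - lo) / bin_width).astype(int)
    uniq, counts = np.unique(idx, return_counts=True)
    if np.any(counts > 1):
        raise ValueError("two onsets fall in one bin; reduce bin_width")
    y[uniq] = 1.0

    stages = np.array([hypnogram.stage_at(t) for t in mid], dtype=object)
    stage_block = np.column_stack([(stages == s).astype(float) for s in STAGES])
    i_sdb = _interval_indicator(events, SDB_KINDS, bin_start, bin_width, sdb_pad_s)
    i_ar = _interval_indicator(events, {EventKind.AROUSAL}, bin_start, bin_width)

    # history: lag from bin midpoint to the most recent onset before the bin
    if onsets.size:
        last = np.searchsorted(onsets, bin_start, side="left") - 1
        lag = np.where(last >= 0, mid - onsets[np.clip(last, 0, None)], np.inf)
    else:
        lag = np.full(n_bins, np.inf)
    G = basis.evaluate(lag)

    X = np.column_stack([stage_block, i_sdb, i_ar, G])
    names = STAGE_COLUMNS + (SDB_COLUMN, AROUSAL_COLUMN) + tuple(
        f"G_{k}" for k in range(basis.K)
    )
    include = bin_start >= lo + burn_in_s
    return DesignMatrix(bin_start, bin_width, y, X, names, include, basis)


@dataclass
class IntensitySeries:
    """Per-bin conditional intensity (expected events per bin)."""

    bin_start: np.ndarray
    bin_width: float
    lam: np.ndarray

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """Edges and running-sum cumulative intensity Lambda at the edges."""
        edges = np.append(self.bin_start, self.bin_start[-1] + self.bin_width)
        return edges, np.concatenate([[0.0], np.cumsum(self.lam)])

    def cumulative_at(self, t: np.ndarray | float) -> np.ndarray:
        edges, cum = self.cumulative()
        return np.interp(np.asarray(t, dtype=float), edges, cum)


class PointProcessGLM(BaseEstimator):
    """Bernoulli point-process GLM with log link and spline history filter.

    Parameters
    ----------
    bin_width : float
        Discretisation step, seconds.  1 s keeps the per-bin event
        probability small at observed avalanche rates.
    burn_in_s : float
        Initial span of the analysis window excluded from the
        likelihood (history initialisation), seconds.
    tension : float
        Cardinal-spline tension of the history basis.
    knot_spacing : {"linear", "log"}
        How the five inner knots are spread between the p10 inter-event
        interval and 80 s.
    ridge : float
        L2 penalty on all coefficients; 0 means none.  On a singular or
        diverging fit a fallback ridge of 1e-4 is applied and the fit is
        flagged ``regularized_``.
    tol, max_iter : float, int
        Newton convergence: relative log-likelihood change below ``tol``
        or ``max_iter`` iterations.
    min_events : int
        Below this many events (after burn-in) the fit is flagged
        ``reliable_ = False``.
    sdb_pad_s : float
        Symmetric padding of scored SDB intervals before computing the
        overlap indicator.

    Attributes
    ----------
    coef_ : ndarray
        Maximum-likelihood coefficients for the retained columns.
    covariance_ : ndarray
        Inverse observed information at the optimum.
    log_likelihood_, converged_, n_iter_, n_events_, n_bins_ : fit diagnostics.
    """

    _FALLBACK_RIDGE = 1e-4

    def __init__(
        self,
        bin_width: float = 1.0,
        burn_in_s: float = HISTORY_WINDOW_S,
        tension: float = 0.5,
        knot_spacing: str = "linear",
        ridge: float = 0.0,
        tol: float = 1e-8,
        max_iter: int = 100,
        min_events: int = 5,
        sdb_pad_s: float = 0.0,
    ) -> None:
        self.bin_width = bin_width
        self.burn_in_s = burn_in_s
        self.tension = tension
        self.knot_spacing = knot_spacing
        self.ridge = ridge
        self.tol = tol
        self.max_iter = max_iter
        self.min_events = min_events
        self.sdb_pad_s = sdb_pad_s

    # ---------------------------------------------------------------- fit
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        column_names: tuple[str, ...] | None = None,
    ) -> "PointProcessGLM":
        """Maximise the Bernoulli log-link likelihood on raw arrays."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ValueError("X must be (n, p) and y (n,) with matching n")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("y must be binary")
        names = tuple(column_names) if column_names else tuple(
            f"x{i}" for i in range(X.shape[1])
        )

        keep = ~np.all(X == 0.0, axis=0)
        if not keep.all():
            dropped = [n for n, k in zip(names, keep) if not k]
            _warn(f"dropping all-zero covariate columns: {dropped}")
        self.dropped_columns_ = tuple(n for n, k in zip(names, keep) if not k)
        self.column_names_ = tuple(n for n, k in zip(names, keep) if k)
        Xk = X[:, keep]

        self.n_bins_ = y.size
        self.n_events_ = int(y.sum())
        self.reliable_ = self.n_events_ >= self.min_events
        if not self.reliable_:
            _warn(f"only {self.n_events_} events; fit flagged unreliable")

        theta, info = self._newton(Xk, y, self.ridge)
        self.regularized_ = False
        if not info["ok"]:
            theta, info = self._newton(Xk, y, max(self.ridge, self._FALLBACK_RIDGE))
            self.regularized_ = True
            _warn("fit required fallback ridge regularisation")
        self.coef_ = theta
        self.converged_ = info["converged"]
        self.n_iter_ = info["n_iter"]
        self.log_likelihood_ = info["ll"]
        self.covariance_ = info["cov"]
        return self

    def fit_design(self, design: DesignMatrix) -> "PointProcessGLM":
        """Fit on a prebuilt :class:`DesignMatrix` (burn-in rows excluded)."""
        self.design_ = design
        self.basis_ = design.basis
        m = design.include
        return self.fit(design.X[m], design.y[m], design.column_names)

    def fit_night(
        self,
        train: NAAEventTrain,
        hypnogram: Hypnogram,
        events: list[EventInterval],
        basis: HistoryBasis | None = None,
        window: tuple[float, float] | None = None,
    ) -> "PointProcessGLM":
        """Build the history basis and design for one night, then fit."""
        if basis is None:
            basis = build_history_basis(
                train, tension=self.tension, spacing=self.knot_spacing
            )
        design = build_design(
            train,
            hypnogram,
            events,
            basis,
            bin_width=self.bin_width,
            burn_in_s=self.burn_in_s,
            window=window,
            sdb_pad_s=self.sdb_pad_s,
        )
        return self.fit_design(design)

    # ------------------------------------------------------------ internals
    @staticmethod
    def _loglik(eta: np.ndarray, y: np.ndarray, theta: np.ndarray, ridge: float) -> float:
        if np.any(eta[y == 0.0] >= 0.0):
            return -np.inf
        ll = float(eta[y == 1.0].sum() + np.log1p(-np.exp(eta[y == 0.0])).sum())
        if ridge:
            ll -= 0.5 * ridge * float(theta @ theta)
        return ll

    def _newton(self, X: np.ndarray, y: np.ndarray, ridge: float) -> tuple[np.ndarray, dict]:
        n, p = X.shape
        rate = (y.sum() + 0.5) / (n + 1.0)
        # start near the constant-rate model: eta ~ log(rate) everywhere
        # (for the stage one-hot block this sets every stage to log(rate))
        theta = np.zeros(p)
        for margin in (0.0, 1.0, 2.0, 4.0):
            cand = np.linalg.lstsq(
                X, np.full(n, np.log(rate) - margin), rcond=None
            )[0]
            if np.all((X @ cand)[y == 0.0] < 0.0):
                theta = cand
                break
        ll = self._loglik(X @ theta, y, theta, ridge)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = X @ theta
            zero = y == 0.0
            pz = np.exp(eta[zero])
            g = np.ones(n)
            g[zero] = -pz / (1.0 - pz)
            grad = X.T @ g - ridge * theta
            w = np.zeros(n)
            w[zero] = pz / (1.0 - pz) ** 2
            H = X.T @ (X * w[:, None]) + ridge * np.eye(p)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                return theta, {"ok": False, "converged": False, "n_iter": it,
                               "ll": ll, "cov": np.full((p, p), np.nan)}
            # step halving keeps the log-likelihood non-decreasing
            alpha, new_ll = 1.0, -np.inf
            for _ in range(40):
                cand = theta + alpha * step
                new_ll = self._loglik(X @ cand, y, cand, ridge)
                if new_ll >= ll:
                    break
                alpha /= 2.0
            if not np.isfinite(new_ll) or new_ll < ll:
                return theta, {"ok": False, "converged": False, "n_iter": it,
                               "ll": ll, "cov": np.full((p, p), np.nan)}
            theta = theta + alpha * step
            if abs(new_ll - ll) <= self.tol * (abs(ll) + 1.0):
                ll = new_ll
                converged = True
                break
            ll = new_ll
        eta = X @ theta
        zero = y == 0.0
        pz = np.exp(eta[zero])
        w = np.zeros(n)
        w[zero] = pz / (1.0 - pz) ** 2
        H = X.T @ (X * w[:, None]) + ridge * np.eye(X.shape[1])
        try:
            cov = np.linalg.inv(H)
            cov = (cov + cov.T) / 2.0
            ok = True
        except np.linalg.LinAlgError:
            cov = np.full((X.shape[1],) * 2, np.nan)
            ok = False
        if not np.all(np.isfinite(theta)):
            ok = False
        return theta, {"ok": ok, "converged": converged, "n_iter": it,
                       "ll": ll, "cov": cov}

    # ------------------------------------------------------------ accessors
    def _index(self, name: str) -> int | None:
        try:
            return self.column_names_.index(name)
        except ValueError:
            return None

    def coefficient(self, name: str) -> float:
        i = self._index(name)
        return float(self.coef_[i]) if i is not None else np.nan

    def coefficient_se(self, name: str) -> float:
        i = self._index(name)
        return float(np.sqrt(self.covariance_[i, i])) if i is not None else np.nan

    @property
    def stage_log_rates_(self) -> dict[StageCode, float]:
        return {s: self.coefficient(f"I_{s.value}") for s in STAGES}

    @property
    def sdb_multiplier_(self) -> float:
        """exp(beta_SDB): rate ratio while an SDB event overlaps the bin."""
        return float(np.exp(self.coefficient(SDB_COLUMN)))

    @property
    def arousal_multiplier_(self) -> float:
        return float(np.exp(self.coefficient(AROUSAL_COLUMN)))

    @property
    def history_coef_(self) -> np.ndarray:
        idx = [i for i, c in enumerate(self.column_names_) if c.startswith("G_")]
        return self.coef_[idx]

    @property
    def history_covariance_(self) -> np.ndarray:
        idx = [i for i, c in enumerate(self.column_names_) if c.startswith("G_")]
        return self.covariance_[np.ix_(idx, idx)]

    # ------------------------------------------------------------- predict
    def predict_intensity(self, design: DesignMatrix | np.ndarray) -> IntensitySeries:
        """Conditional intensity exp(x theta) per bin of the design."""
        if isinstance(design, DesignMatrix):
            cols = [i for i, c in enumerate(design.column_names)
                    if c in self.column_names_]
            if tuple(design.column_names[i] for i in cols) != self.column_names_:
                raise ValueError("design columns do not match the fitted model")
            lam = np.exp(design.X[:, cols] @ self.coef_)
            return IntensitySeries(design.bin_start, design.bin_width, lam)
        X = np.asarray(design, dtype=float)
        if X.shape[1] != self.coef_.size:
            raise ValueError("design columns do not match the fitted model")
        lam = np.exp(X @ self.coef_)
        return IntensitySeries(np.arange(X.shape[0], dtype=float), 1.0, lam)


def fit_glm(design: DesignMatrix, **params) -> PointProcessGLM:
    """Thin functional wrapper over :class:`PointProcessGLM`."""
    return PointProcessGLM(**params).fit_design(design)


def predict_intensity(fit: PointProcessGLM, design: DesignMatrix) -> IntensitySeries:
    return fit.predict_intensity(design)
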