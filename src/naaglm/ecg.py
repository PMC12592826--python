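"""Single-lead ECG processing: R-peak detection, quality screening, R-R.

QRS detection follows the classic Pan-Tompkins stages — 5-15 Hz
band-pass, derivative, squaring, 150-ms moving-window integration, and
adaptive dual thresholds with search-back and a 200-ms refractory
period.  Segment quality is screened with a small set of signal quality
indices (two-detector agreement, flatline fraction, saturation
fraction, kurtosis) before intervals are formed.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks
from scipy.stats import kurtosis
from sklearn.base import BaseEstimator

from .types import ECGRecord, QualityMask, RRSeries, _warn

REFRACTORY_S = 0.200
INTEGRATION_WINDOW_S = 0.150
SEARCHBACK_FACTOR = 1.66


class PanTompkinsDetector(BaseEstimator):
    """Pan-Tompkins QRS detector with the canonical constants.

    Band edges 5-15 Hz, 150-ms integration window, threshold updates
    0.125/0.875 (0.25/0.75 on search-back), search-back when no QRS is
    found within 1.66 x the running R-R average, 200-ms refractory.
    The band-pass is applied zero-phase so detected fiducials need no
    group-delay correction; the R time is refined to the absolute
    band-passed maximum near each accepted integrator peak.
    """

    def __init__(
        self,
        band: tuple[float, float] = (5.0, 15.0),
        order: int = 3,
        refractory_s: float = REFRACTORY_S,
        integration_window_s: float = INTEGRATION_WINDOW_S,
        searchback_factor: float = SEARCHBACK_FACTOR,
    ) -> None:
        self.band = band
        self.order = order
        self.refractory_s = refractory_s
        self.integration_window_s = integration_window_s
        self.searchback_factor = searchback_factor

    # stages ------------------------------------------------------------
    def _preprocess(self, ecg: ECGRecord) -> tuple[np.ndarray, np.ndarray]:
        fs = ecg.sample_rate
        nyq = fs / 2.0
        b, a = butter(self.order, [self.band[0] / nyq, self.band[1] / nyq], "band")
        filtered = filtfilt(b, a, ecg.samples)
        deriv = np.gradient(filtered) * fs
        squared = deriv**2
        n_int = max(int(round(self.integration_window_s * fs)), 1)
        mwi = np.convolve(squared, np.ones(n_int) / n_int, mode="same")
        return filtered, mwi

    def detect(self, ecg: ECGRecord) -> np.ndarray:
        """Strictly increasing R-peak times, seconds."""
        if ecg.duration < 10.0:
            raise ValueError("recording must be at least 10 s")
        if ecg.sample_rate < 128.0:
            raise ValueError("sample_rate must be >= 128 Hz")
        if np.ptp(ecg.samples) == 0.0:
            _warn("flatline ECG input; no peaks detected")
            return np.array([])
        fs = ecg.sample_rate
        filtered, mwi = self._preprocess(ecg)
        refr = int(round(self.refractory_s * fs))
        cand, _ = find_peaks(mwi, distance=refr)
        if cand.size == 0:
            _warn("no candidate peaks in integrated signal")
            return np.array([])

        # adaptive dual thresholds on the integrated signal
        learn = mwi[: int(2.0 * fs)]
        spki = 0.25 * float(learn.max())
        npki = 0.5 * float(learn.mean())
        qrs: list[int] = []
        rr_avg = None
        recent: list[float] = []
        k = 0
        while k < cand.size:
            i = cand[k]
            thr1 = npki + 0.25 * (spki - npki)
            if mwi[i] > thr1:
                accept = True
            else:
                accept = False
                # search-back: look for a missed beat at half threshold
                if qrs and rr_avg is not None and (
                    i - qrs[-1] > self.searchback_factor * rr_avg * fs
                ):
                    window = [c for c in cand[: k + 1]
                              if qrs[-1] + refr <= c <= i and mwi[c] > 0.5 * thr1]
                    if window:
                        j = max(window, key=lambda c: mwi[c])
                        qrs.append(j)
                        spki = 0.25 * mwi[j] + 0.75 * spki
                        recent.append((qrs[-1] - qrs[-2]) / fs)
                        rr_avg = float(np.mean(recent[-8:]))
            if accept:
                if not qrs or i - qrs[-1] >= refr:
                    if qrs:
                        recent.append((i - qrs[-1]) / fs)
                        rr_avg = float(np.mean(recent[-8:]))
                    qrs.append(i)
                    spki = 0.125 * mwi[i] + 0.875 * spki
            else:
                npki = 0.125 * mwi[i] + 0.875 * npki
            k += 1
        if not qrs:
            _warn("no peaks exceeded the adaptive threshold")
            return np.array([])

        # refine each fiducial to the band-passed extremum nearby
        half = int(round(0.075 * fs))
        times = []
        for i in qrs:
            lo, hi = max(i - half, 0), min(i + half + 1, filtered.size)
            times.append(ecg.start_time + (lo + int(np.argmax(np.abs(filtered[lo:hi])))) / fs)
        times = np.array(sorted(set(times)))
        # refinement may pull neighbours together; re-impose refractory
        keep = np.concatenate([[True], np.diff(times) >= self.refractory_s])
        return times[keep]

    transform = detect


def detect_r_peaks(ecg: ECGRecord, **params) -> np.ndarray:
    """Functional wrapper over :class:`PanTompkinsDetector`."""
    return PanTompkinsDetector(**params).detect(ecg)


def _longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    if mask.size == 0:
        return 0
    padded = np.concatenate([[0], mask.astype(int), [0]])
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max()) if starts.size else 0


def _amplitude_detector(x: np.ndarray, fs: float) -> np.ndarray:
    """Simple second QRS detector: prominent maxima above 0.5 x robust max."""
    scale = np.percentile(np.abs(x - np.median(x)), 99.5)
    if scale <= 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(
        np.abs(x - np.median(x)),
        height=0.5 * scale,
        distance=int(round(REFRACTORY_S * fs)),
    )
    return peaks


def assess_quality(
    ecg: ECGRecord,
    segment_s: float = 10.0,
    bsqi_threshold: float = 0.8,
    flatline_max_fraction: float = 0.2,
    saturation_max_fraction: float = 0.2,
    min_kurtosis: float = 2.0,
) -> QualityMask:
    """Per-segment GOOD/BAD screening from combined signal quality indices.

    A segment is GOOD when (i) two independent QRS detectors agree
    (bSQI >= threshold, matches within 150 ms), (ii) the flatline and
    amplitude-saturation fractions are small, and (iii) the excess
    kurtosis indicates spiky QRS-dominated content.  Degenerate segments
    are BAD, never errors.
    """
    if ecg.samples.size == 0:
        raise ValueError("empty ECG record")
    fs = ecg.sample_rate
    n_seg = max(int(np.ceil(ecg.duration / segment_s)), 1)
    seg_len = int(round(segment_s * fs))
    flags = np.zeros(n_seg, dtype=bool)
    global_scale = np.ptp(ecg.samples)
    lo_sat, hi_sat = ecg.samples.min(), ecg.samples.max()
    pt = PanTompkinsDetector()
    for s in range(n_seg):
        x = ecg.samples[s * seg_len : (s + 1) * seg_len]
        if x.size < seg_len and s > 0:  # trailing partial: too short to judge
            flags[s] = flags[s - 1]
            continue
        if np.ptp(x) == 0.0:
            flags[s] = False
            continue
        # flatline: longest constant run as a fraction of the segment
        # (an isoelectric baseline between beats breaks at every QRS)
        const = np.abs(np.diff(x)) < 1e-9 * max(global_scale, 1e-12)
        flat = _longest_run(const) / x.size
        # saturation: sustained dwelling near the extreme deviation,
        # as produced by amplifier clipping
        dev = np.abs(x - np.median(x))
        sat = float(np.mean(dev >= 0.98 * dev.max())) if dev.max() > 0 else 1.0
        kur = kurtosis(x)
        try:
            seg_rec = ECGRecord(fs, x)
            a = pt.detect(seg_rec) if x.size >= 10 * fs else np.array([])
        except ValueError:
            a = np.array([])
        b = _amplitude_detector(x, fs) / fs
        n_match = 0
        if a.size and b.size:
            for t in a:
                if np.min(np.abs(b - t)) <= 0.15:
                    n_match += 1
        denom = a.size + b.size - n_match
        bsqi = n_match / denom if denom > 0 else 0.0
        flags[s] = (
            bsqi >= bsqi_threshold
            and flat < flatline_max_fraction
            and sat < saturation_max_fraction
            and kur >= min_kurtosis
        )
    return QualityMask(segment_s, flags, ecg.start_time)


def rr_from_peaks(
    peaks: np.ndarray,
    mask: QualityMask | None = None,
    min_rr_s: float = 0.3,
    max_rr_s: float = 3.0,
) -> RRSeries:
    """Form R-R intervals, dropping low-quality and implausible beats.

    An interval is kept only if both endpoint beats lie in GOOD
    segments and its length falls inside the plausibility bounds; the
    number of intervals removed by the plausibility filter is reported
    in a warning.
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size and np.any(np.diff(peaks) <= 0):
        raise ValueError("peaks must be strictly increasing")
    rr = np.diff(peaks)
    t = peaks[1:]
    keep = np.ones(rr.size, dtype=bool)
    if mask is not None:
        good = mask.good_at(peaks)
        keep &= good[1:] & good[:-1]
    plaus = (rr >= min_rr_s) & (rr <= max_rr_s)
    n_implausible = int(np.sum(keep & ~plaus))
    if n_implausible:
        _warn(f"dropped {n_implausible} physiologically implausible interval(s)")
    keep &= plaus
    if np.sum(keep) < 1 or peaks.size < 2:
        raise ValueError("fewer than two usable peaks survive quality editing")
    return RRSeries(t[keep], rr[keep])
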