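"""Raw-channel conditioning: QRS detection, RR series, downsampling.

ECG goes through a Pan–Tompkins-style detector (band-pass 5–15 Hz,
derivative, squaring, 150-ms moving integration, adaptive thresholding
with a 200-ms refractory period). SKT and EDA are downsampled to a
working rate of 50 Hz and then low-pass filtered (2nd-order Butterworth,
zero-phase) to remove noise; an anti-alias FIR always precedes decimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sig

from .signals import SignalRecord

REFRACTORY_S = 0.200
RR_VALID_MS = (300.0, 2000.0)


@dataclass
class RPeakSeries:
    """Detected R-peak times in seconds (strictly increasing)."""

    peak_times: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")


@dataclass
class RRSeries:
    """RR intervals (ms) with a validity mask for physiologic range."""

    intervals_ms: np.ndarray
    midpoint_times_s: np.ndarray
    valid: np.ndarray

    @property
    def usable(self) -> np.ndarray:
        return self.intervals_ms[self.valid]

    def within(self, t_start: float, t_stop: float) -> "RRSeries":
        """Sub-series whose interval midpoints fall in [t_start, t_stop)."""
        m = (self.midpoint_times_s >= t_start) & (self.midpoint_times_s < t_stop)
        return RRSeries(self.intervals_ms[m], self.midpoint_times_s[m], self.valid[m])


def detect_r_peaks(ecg: SignalRecord, fs: float | None = None) -> RPeakSeries:
    """Pan–Tompkins-style QRS detection; one peak per complex.

    Raises ``ValueError`` on a flat (zero-variance) trace.
    """
    if ecg.channel != "ECG":
        raise ValueError("detect_r_peaks expects an ECG channel")
    fs = ecg.fs if fs is None else fs
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    x = ecg.samples
    if np.ptp(x) == 0:
        raise ValueError("no QRS detected: flat signal")

    sos = sig.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sig.sosfiltfilt(sos, x)
    squared = np.gradient(bp) ** 2
    win = max(int(round(0.150 * fs)), 1)
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sig.find_peaks(integrated, distance=refractory)
    if cand.size == 0:
        raise ValueError("no QRS detected")

    # adaptive running thresholds on the integrated signal
    spki = float(np.max(integrated[: min(len(integrated), int(2 * fs))])) * 0.5
    npki = float(np.mean(integrated[: min(len(integrated), int(2 * fs))])) * 0.5
    accepted = []
    for c in cand:
        thr = npki + 0.25 * (spki - npki)
        if integrated[c] > thr:
            accepted.append(c)
            spki = 0.125 * integrated[c] + 0.875 * spki
        else:
            npki = 0.125 * integrated[c] + 0.875 * npki
    if not accepted:
        raise ValueError("no QRS detected")

    # snap each accepted candidate to the raw-signal maximum nearby
    half = int(round(0.100 * fs))
    peaks = []
    for c in accepted:
        lo, hi = max(c - half, 0), min(c + half + 1, len(x))
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)

    # refractory pass: among peaks closer than 200 ms keep the taller one
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < refractory:
            if x[p] > x[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    return RPeakSeries(peak_times=np.asarray(kept) / fs, fs=fs)


def rr_from_peaks(peaks: RPeakSeries) -> RRSeries:
    """Successive peak differences in ms; intervals outside 300–2000 ms are flagged."""
    t = peaks.peak_times
    if len(t) < 2:
        raise ValueError("need at least 2 peaks to form RR intervals")
    rr = np.diff(t) * 1000.0
    mid = (t[:-1] + t[1:]) / 2.0
    valid = (rr >= RR_VALID_MS[0]) & (rr <= RR_VALID_MS[1])
    return RRSeries(intervals_ms=rr, midpoint_times_s=mid, valid=valid)


def downsample_lowpass(
    record: SignalRecord, target_fs: float = 50.0, cutoff_hz: float = 1.0
) -> SignalRecord:
    """Anti-alias, decimate to ``target_fs``, then zero-phase Butterworth low-pass."""
    if target_fs >= record.fs:
        raise ValueError("target_fs must be below the source rate")
    if cutoff_hz >= target_fs / 2:
        raise ValueError("cutoff must be below the target Nyquist frequency")
    frac = Fraction(target_fs / record.fs).limit_denominator(10000)
    y = sig.resample_poly(record.samples, frac.numerator, frac.denominator, padtype="line")
    sos = sig.butter(2, cutoff_hz, btype="lowpass", fs=target_fs, output="sos")
    y = sig.sosfiltfilt(sos, y)
    return SignalRecord(
        channel=record.channel,
        fs=target_fs,
        samples=y,
        units=record.units,
        subject_id=record.subject_id,
        condition=record.condition,
    )
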