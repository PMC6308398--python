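"""Windowed feature extraction: 16 features per 5-minute window.

Nine ECG features (time- and frequency-domain heart-rate variability),
two skin-temperature features, and five electrodermal-activity features
computed from a wavelet tonic/phasic split. Windows slide in 30-s steps;
the last 100 windows of each condition are retained as representative
vectors, on the assumption that the emotion is fully induced only late
in the stimulus. Each feature is then min-max normalized to [0, 1] per
subject over the pooled rows of both conditions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import interpolate
from scipy import signal as sig

from .preprocess import RRSeries, detect_r_peaks, downsample_lowpass, rr_from_peaks
from .signals import CONDITIONS, Recording

log = logging.getLogger(__name__)

FEATURE_NAMES = [
    "MeanHRV", "SDNN", "RMSSD", "NN50", "pNN50",
    "LF_HF", "TP", "nHF", "nLF",
    "MeanSKT", "SDSKT",
    "ZC_EDAP", "SD_EDAP", "Mean_EDAT", "SD_EDAT", "Amp_EDAT",
]
META_COLUMNS = ["subject_id", "condition", "window_index"]

LABELS = {"basic": 0, "negative": 1}

# HRV spectral bands (Hz)
BAND_TP = (0.003, 0.4)
BAND_LF = (0.04, 0.15)
BAND_HF = (0.15, 0.4)

EDA_DWT_FS = 32.0      # working rate so the level-10 approximation spans 0–0.015625 Hz
EDA_DWT_LEVEL = 10
EDA_WAVELET = "db3"

TACHO_FS = 4.0         # uniform tachogram resampling rate


class WindowFeatureError(ValueError):
    """A window whose features cannot be computed (flagged and skipped)."""


@dataclass
class WindowSpec:
    """Sliding-window layout: 5-min windows, 30-s step, keep the last 100."""

    length_s: float = 300.0
    step_s: float = 30.0
    selection_count: int = 100

    def __post_init__(self) -> None:
        if self.step_s > self.length_s:
            raise ValueError("step_s must not exceed length_s")
        if self.length_s <= 0 or self.step_s <= 0 or self.selection_count < 1:
            raise ValueError("window parameters must be positive")


def slide_windows(
    duration_s: float, spec: WindowSpec, select: bool = True
) -> list[tuple[float, float]]:
    """(start, stop) ranges stepping by ``step_s``; optionally keep the last
    ``selection_count`` windows."""
    if duration_s < spec.length_s:
        raise ValueError("recording shorter than one window")
    n = int(np.floor((duration_s - spec.length_s) / spec.step_s)) + 1
    windows = [(i * spec.step_s, i * spec.step_s + spec.length_s) for i in range(n)]
    if select:
        if spec.selection_count > n:
            raise ValueError(f"selection_count={spec.selection_count} exceeds {n} windows")
        windows = windows[-spec.selection_count:]
    return windows


def hrv_time_features(rr_ms: np.ndarray) -> dict[str, float]:
    """Mean HRV, SDNN, RMSSD, NN50, pNN50 from usable RR intervals (ms).

    MeanHRV is the arithmetic mean of the intervals; SDNN the sample SD;
    RMSSD the root mean square of the N−1 successive differences; NN50
    counts absolute successive differences above 50 ms and pNN50 is that
    count divided by the number of intervals, in percent.
    """
    rr = np.asarray(rr_ms, dtype=float)
    n = rr.size
    if n < 2:
        raise WindowFeatureError("need at least 2 RR intervals")
    mean = rr.mean()
    sdnn = float(np.sqrt(np.sum((rr - mean) ** 2) / (n - 1)))
    d = np.diff(rr)
    rmssd = float(np.sqrt(np.sum(d**2) / (n - 1)))
    nn50 = int(np.sum(np.abs(d) > 50.0))
    return {
        "MeanHRV": float(mean),
        "SDNN": sdnn,
        "RMSSD": rmssd,
        "NN50": nn50,
        "pNN50": 100.0 * nn50 / n,
    }


def hrv_freq_features(rr: RRSeries) -> dict[str, float]:
    """LF/HF ratio, total power and normalized band powers of the RR tachogram.

    The tachogram is cubic-interpolated onto a uniform 4-Hz grid, its PSD
    estimated by Welch (256-sample Hann segments, 50% overlap) and band
    powers integrated by the trapezoidal rule over TP 0.003–0.4 Hz,
    LF 0.04–0.15 Hz and HF 0.15–0.4 Hz.
    """
    t = rr.midpoint_times_s[rr.valid]
    y = rr.usable
    if y.size < 4:
        raise WindowFeatureError("too few RR intervals for spectral estimation")
    grid = np.arange(t[0], t[-1], 1.0 / TACHO_FS)
    tacho = interpolate.CubicSpline(t, y)(grid)
    nperseg = min(256, len(tacho))
    f, psd = sig.welch(tacho, fs=TACHO_FS, window="hann", nperseg=nperseg)

    def band_power(lo: float, hi: float) -> float:
        m = (f >= lo) & (f <= hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], f[m]))

    tp = band_power(*BAND_TP)
    lf = band_power(*BAND_LF)
    hf = band_power(*BAND_HF)
    if hf == 0.0 or lf + hf == 0.0:
        raise WindowFeatureError("zero HF power: LF/HF undefined")
    return {"LF_HF": lf / hf, "TP": tp, "nHF": hf / (lf + hf), "nLF": lf / (lf + hf)}


def skt_features(skt_window: np.ndarray) -> dict[str, float]:
    """Mean and sample standard deviation of windowed skin temperature."""
    x = np.asarray(skt_window, dtype=float)
    if x.size == 0:
        raise WindowFeatureError("empty SKT window")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return {"MeanSKT": float(x.mean()), "SDSKT": sd}


def eda_decompose(eda_window: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Split EDA into tonic and phasic components via a db3 wavelet.

    The window is resampled to 32 Hz so the level-10 approximation band
    spans 0–0.015625 Hz; the tonic component is the reconstruction from
    the approximation coefficients alone, and the phasic component is the
    residual (so tonic + phasic reproduces the resampled input exactly).
    Returns (tonic, phasic) at 32 Hz.
    """
    x = np.asarray(eda_window, dtype=float)
    if fs != EDA_DWT_FS:
        from fractions import Fraction

        frac = Fraction(EDA_DWT_FS / fs).limit_denominator(10000)
        x = sig.resample_poly(x, frac.numerator, frac.denominator, padtype="line")
    if x.size < 2**EDA_DWT_LEVEL:
        raise WindowFeatureError(
            f"window too short for level-{EDA_DWT_LEVEL} decomposition "
            f"(need {2**EDA_DWT_LEVEL} samples at {EDA_DWT_FS:g} Hz)"
        )
    coeffs = pywt.wavedec(x, EDA_WAVELET, level=EDA_DWT_LEVEL, mode="symmetric")
    approx_only = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    tonic = pywt.waverec(approx_only, EDA_WAVELET, mode="symmetric")[: x.size]
    return tonic, x - tonic


def _zero_crossings(x: np.ndarray) -> int:
    """Strict sign changes; zero samples attach to the previous sign."""
    s = np.sign(x)
    s = s[s != 0]  # a zero sample keeps the previous sign, so it never adds a change
    return int(np.sum(s[1:] != s[:-1]))


def eda_features(tonic: np.ndarray, phasic: np.ndarray) -> dict[str, float]:
    """Zero crossings and SD of the phasic component; mean, SD and
    peak-to-peak amplitude of the tonic component."""
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return {
        "ZC_EDAP": _zero_crossings(np.asarray(phasic, dtype=float)),
        "SD_EDAP": sd(phasic),
        "Mean_EDAT": float(np.mean(tonic)),
        "SD_EDAT": sd(tonic),
        "Amp_EDAT": float(np.max(tonic) - np.min(tonic)),
    }


def _window_slice(samples: np.ndarray, fs: float, t0: float, t1: float) -> np.ndarray:
    return samples[int(round(t0 * fs)): int(round(t1 * fs))]


def extract_condition_features(
    rec: Recording, spec: WindowSpec | None = None, select: bool = True
) -> pd.DataFrame:
    """Feature vectors for every retained window of one recording."""
    spec = spec or WindowSpec()
    rr = rr_from_peaks(detect_r_peaks(rec["ECG"]))
    skt = downsample_lowpass(rec["SKT"])
    eda = downsample_lowpass(rec["EDA"])
    duration = min(rec["ECG"].duration_s, skt.duration_s, eda.duration_s)
    rows = []
    for w_idx, (t0, t1) in enumerate(slide_windows(duration, spec, select=select)):
        try:
            rr_w = rr.within(t0, t1)
            feats = hrv_time_features(rr_w.usable)
            feats.update(hrv_freq_features(rr_w))
            feats.update(skt_features(_window_slice(skt.samples, skt.fs, t0, t1)))
            tonic, phasic = eda_decompose(_window_slice(eda.samples, eda.fs, t0, t1), eda.fs)
            feats.update(eda_features(tonic, phasic))
        except WindowFeatureError as exc:
            log.warning("window %d [%.0f, %.0f)s skipped: %s", w_idx, t0, t1, exc)
            continue
        feats["subject_id"] = rec.subject_id
        feats["condition"] = rec.condition
        feats["window_index"] = w_idx
        rows.append(feats)
    if not rows:
        raise ValueError("no usable windows in recording")
    return pd.DataFrame(rows)[FEATURE_NAMES + META_COLUMNS]


def build_feature_matrix(
    recordings: dict[str, Recording], spec: WindowSpec | None = None
) -> pd.DataFrame:
    """Stacked feature matrix for one subject's basic and negative recordings."""
    missing = [c for c in CONDITIONS if c not in recordings]
    if missing:
        raise ValueError(f"missing condition(s): {missing}")
    frames = [extract_condition_features(recordings[c], spec) for c in CONDITIONS]
    df = pd.concat(frames, ignore_index=True)
    df["label"] = df["condition"].map(LABELS)
    return df


def labels_of(matrix: pd.DataFrame) -> np.ndarray:
    if "label" in matrix.columns:
        return matrix["label"].to_numpy()
    return matrix["condition"].map(LABELS).to_numpy()


def normalize_minmax(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Min-max normalize every feature column to [0, 1] over all rows.

    Returns the normalized matrix and a bounds frame (rows ``min``/``max``
    per feature) for inverse mapping. A constant column carries no scale
    information and is set to 0.5 with a warning.
    """
    out = matrix.copy()
    bounds = pd.DataFrame(index=["min", "max"], columns=FEATURE_NAMES, dtype=float)
    for name in FEATURE_NAMES:
        col = matrix[name].to_numpy(dtype=float)
        lo, hi = float(np.min(col)), float(np.max(col))
        bounds.loc["min", name] = lo
        bounds.loc["max", name] = hi
        if hi == lo:
            warnings.warn(f"feature {name!r} is constant; normalized to 0.5", stacklevel=2)
            out[name] = 0.5
        else:
            out[name] = (col - lo) / (hi - lo)
    return out, bounds


def denormalize(matrix: pd.DataFrame, bounds: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`normalize_minmax` using the stored bounds."""
    out = matrix.copy()
    for name in FEATURE_NAMES:
        lo, hi = bounds.loc["min", name], bounds.loc["max", name]
        out[name] = matrix[name] * (hi - lo) + lo
    return out
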