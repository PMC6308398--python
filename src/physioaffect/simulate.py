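"""Seedable two-condition synthetic recordings (ECG, SKT, EDA).

The generator emulates the autonomic signature of induced negative
emotion relative to a neutral baseline: shorter RR intervals (higher
heart rate), more frequent and larger skin-conductance responses, a
higher and faster-rising tonic conductance level, and a slowly falling
skin temperature. Magnitudes are package defaults chosen for clear
class separability — no quantitative effect sizes exist for this
protocol — and every one of them is a constructor argument.

All channels are synthesized at 1 kHz, mirroring a typical laboratory
acquisition rate; downsampling happens in :mod:`physioaffect.preprocess`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .signals import CONDITIONS, Recording, SignalRecord

RR_BOUNDS_MS = (300.0, 2000.0)


def _per_condition(basic: float, negative: float) -> dict[str, float]:
    return {"basic": basic, "negative": negative}


@dataclass
class SimParams:
    """Simulation parameters; per-condition values are {condition: value} dicts."""

    duration_s: float = 3600.0
    ecg_fs: float = 1000.0
    skt_fs: float = 1000.0
    eda_fs: float = 1000.0
    # RR interval distribution (ms): negative emotion shortens intervals.
    rr_mean_ms: dict = field(default_factory=lambda: _per_condition(850.0, 740.0))
    rr_sd_ms: dict = field(default_factory=lambda: _per_condition(55.0, 40.0))
    # EDA: SCR events per minute, SCR amplitude and tonic level/drift (µS).
    scr_rate_per_min: dict = field(default_factory=lambda: _per_condition(2.0, 8.0))
    scr_amplitude_uS: dict = field(default_factory=lambda: _per_condition(0.3, 0.6))
    tonic_level_uS: dict = field(default_factory=lambda: _per_condition(4.0, 8.0))
    tonic_drift_uS_per_min: dict = field(default_factory=lambda: _per_condition(0.005, 0.03))
    # SKT baseline (°C): negative emotion cools the skin.
    skt_base_C: dict = field(default_factory=lambda: _per_condition(33.5, 33.0))
    skt_drift_C_per_min: dict = field(default_factory=lambda: _per_condition(0.0, -0.01))
    # additive Gaussian noise SD per channel (mV / °C / µS)
    noise_sd: dict = field(
        default_factory=lambda: {"ECG": 0.05, "SKT": 0.01, "EDA": 0.02}
    )
    # SCR kernel: difference of exponentials, fast rise / slow decay
    scr_tau_rise_s: float = 0.75
    scr_tau_decay_s: float = 4.0
    ecg_r_amplitude_mV: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for fs in (self.ecg_fs, self.skt_fs, self.eda_fs):
            if fs <= 0:
                raise ValueError("sampling rates must be positive")
        for cond in CONDITIONS:
            if not RR_BOUNDS_MS[0] <= self.rr_mean_ms[cond] <= RR_BOUNDS_MS[1]:
                raise ValueError(f"rr_mean_ms[{cond}] outside {RR_BOUNDS_MS}")
            if self.rr_sd_ms[cond] < 0:
                raise ValueError("rr_sd_ms must be non-negative")
            if self.scr_rate_per_min[cond] < 0:
                raise ValueError("scr_rate_per_min must be non-negative")
            if self.scr_amplitude_uS[cond] <= 0:
                raise ValueError("scr_amplitude_uS must be positive")
            if self.tonic_level_uS[cond] < 0:
                raise ValueError("tonic_level_uS must be non-negative")
        for sd in self.noise_sd.values():
            if sd < 0:
                raise ValueError("noise_sd must be non-negative")


def _rng(seed, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


def simulate_rr_series(
    params: SimParams, condition: str, seed: int | None = None
) -> np.ndarray:
    """Draw i.i.d. truncated-normal RR intervals (ms) covering ``duration_s``.

    Intervals are normal with the condition's (mean, SD), truncated to the
    physiological range 300–2000 ms; a zero SD yields a constant train.
    """
    params.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    mean = params.rr_mean_ms[condition]
    sd = params.rr_sd_ms[condition]
    if sd < 0:
        raise ValueError("rr_sd_ms must be non-negative")
    rng = _rng(params.seed if seed is None else seed, 1)
    total_ms = params.duration_s * 1000.0
    # over-draw in blocks until the cumulative sum covers the recording
    n_guess = int(total_ms / mean * 1.2) + 16
    chunks: list[np.ndarray] = []
    covered = 0.0
    lo, hi = RR_BOUNDS_MS
    while covered < total_ms:
        if sd == 0:
            block = np.full(n_guess, mean)
        else:
            a, b = (lo - mean) / sd, (hi - mean) / sd
            block = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n_guess, random_state=rng)
        chunks.append(block)
        covered += block.sum()
    rr = np.concatenate(chunks)
    keep = np.searchsorted(np.cumsum(rr), total_ms) + 1
    return rr[:keep]


def _beat_template(fs: float, amplitude: float) -> tuple[np.ndarray, int]:
    """Gaussian R-spike (σ = 8 ms, support ±30 ms); returns (waveform, peak offset)."""
    sigma = 0.008 * fs
    half = int(round(0.030 * fs))
    t = np.arange(-half, half + 1)
    return amplitude * np.exp(-0.5 * (t / sigma) ** 2), half


def simulate_ecg(
    rr_series: Sequence[float],
    fs: float = 1000.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    r_amplitude: float = 1.0,
) -> SignalRecord:
    """Place an R-spike template at each cumulative RR time plus Gaussian noise.

    With ``noise_sd = 0`` the sample argmax of every beat sits exactly at
    ``round(cumsum(rr) * fs / 1000)``.
    """
    rr = np.asarray(rr_series, dtype=float)
    if rr.size == 0:
        raise ValueError("rr_series is empty")
    if fs < 100:
        raise ValueError("fs < 100 Hz cannot resolve the R spike")
    if r_amplitude < 5 * noise_sd:
        raise ValueError("R amplitude must be at least 5x the noise SD")
    beat_idx = np.round(np.cumsum(rr) * fs / 1000.0).astype(int)
    n = beat_idx[-1] + int(round(0.5 * fs)) + 1
    template, half = _beat_template(fs, r_amplitude)
    x = np.zeros(n)
    for b in beat_idx:
        lo = max(b - half, 0)
        hi = min(b + half + 1, n)
        x[lo:hi] += template[lo - (b - half) : hi - (b - half)]
    if noise_sd > 0:
        x += _rng(seed, 2).normal(0.0, noise_sd, size=n)
    return SignalRecord(channel="ECG", fs=fs, samples=x, units="mV")


def _scr_kernel(fs: float, tau_rise: float, tau_decay: float, amplitude: float) -> np.ndarray:
    t = np.arange(0, 6 * tau_decay, 1.0 / fs)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return amplitude * k / k.max()


def scr_event_times(
    rng: np.random.Generator, rate_per_min: float, duration_s: float
) -> np.ndarray:
    """Homogeneous-Poisson SCR onset times (s): Poisson count, uniform placement."""
    if rate_per_min <= 0:
        return np.empty(0)
    n_events = rng.poisson(rate_per_min * duration_s / 60.0)
    return np.sort(rng.uniform(0.0, duration_s, size=n_events))


def simulate_eda(
    params: SimParams,
    condition: str,
    fs: float | None = None,
    seed: int | None = None,
    duration_s: float | None = None,
) -> SignalRecord:
    """Tonic level + drift, Poisson-timed SCR transients, Gaussian noise, clipped at 0."""
    params.validate()
    fs = params.eda_fs if fs is None else fs
    duration_s = params.duration_s if duration_s is None else duration_s
    rng = _rng(params.seed if seed is None else seed, 3)
    n = int(round(duration_s * fs))
    t_min = np.arange(n) / fs / 60.0
    tonic = params.tonic_level_uS[condition] + params.tonic_drift_uS_per_min[condition] * t_min
    x = tonic.copy()
    events = scr_event_times(rng, params.scr_rate_per_min[condition], duration_s)
    if events.size:
        kernel = _scr_kernel(
            fs, params.scr_tau_rise_s, params.scr_tau_decay_s, params.scr_amplitude_uS[condition]
        )
        for e in np.floor(events * fs).astype(int):
            hi = min(e + len(kernel), n)
            x[e:hi] += kernel[: hi - e]
    sd = params.noise_sd["EDA"]
    if sd > 0:
        x += rng.normal(0.0, sd, size=n)
    return SignalRecord(
        channel="EDA", fs=fs, samples=np.clip(x, 0.0, None), units="uS", condition=condition
    )


def simulate_skt(
    params: SimParams,
    condition: str,
    fs: float | None = None,
    seed: int | None = None,
    duration_s: float | None = None,
) -> SignalRecord:
    """Baseline temperature plus linear drift plus low-amplitude noise."""
    params.validate()
    fs = params.skt_fs if fs is None else fs
    duration_s = params.duration_s if duration_s is None else duration_s
    n = int(round(duration_s * fs))
    t_min = np.arange(n) / fs / 60.0
    x = params.skt_base_C[condition] + params.skt_drift_C_per_min[condition] * t_min
    sd = params.noise_sd["SKT"]
    if sd > 0:
        x = x + _rng(params.seed if seed is None else seed, 4).normal(0.0, sd, size=n)
    return SignalRecord(channel="SKT", fs=fs, samples=x, units="degC", condition=condition)


def simulate_recording(
    params: SimParams, subject_id: str = "S01", condition: str = "basic"
) -> Recording:
    """All three channels of one session, with per-channel seed streams."""
    params.validate()
    cond_idx = CONDITIONS.index(condition)
    base = int(params.seed) * 4 + cond_idx
    rr = simulate_rr_series(params, condition, seed=base)
    ecg = simulate_ecg(
        rr,
        fs=params.ecg_fs,
        noise_sd=params.noise_sd["ECG"],
        seed=base,
        r_amplitude=params.ecg_r_amplitude_mV,
    )
    # trim/pad ECG to the nominal duration so all channels align
    n_ecg = int(round(params.duration_s * params.ecg_fs))
    samples = ecg.samples[:n_ecg]
    if len(samples) < n_ecg:
        samples = np.pad(samples, (0, n_ecg - len(samples)))
    ecg = SignalRecord(channel="ECG", fs=params.ecg_fs, samples=samples, units="mV")
    eda = simulate_eda(params, condition, seed=base)
    skt = simulate_skt(params, condition, seed=base)
    rec = Recording(subject_id=subject_id, condition=condition)
    for r in (ecg, skt, eda):
        r.subject_id = subject_id
        r.condition = condition
        rec.channels[r.channel] = r
    return rec


def simulate_subject(params: SimParams, subject_id: str = "S01") -> dict[str, Recording]:
    """Both conditions for one subject: {'basic': Recording, 'negative': Recording}."""
    return {c: simulate_recording(params, subject_id, c) for c in CONDITIONS}
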