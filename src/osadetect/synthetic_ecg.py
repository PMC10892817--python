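"""Synthetic labeled single-lead ECG with apnea-like heart-rate dynamics.

The generator emulates the one ECG correlate that separates apneic from
normal minutes most robustly: the cyclical variation of heart rate.  Minutes
labeled ``A`` carry a slow bradycardia-tachycardia oscillation of the RR
interval (default 45 s period, 15% depth, the 30-60 s band reported for
obstructive events); minutes labeled ``N`` carry ordinary respiratory sinus
arrhythmia (default 0.25 Hz, 5% depth).  Beats are rendered as a fixed
sum-of-Gaussians P-QRS-T template placed at the cumulative RR times, plus
sinusoidal baseline wander and white noise.

This is a test-bench signal, not a physiologically validated simulator: beat
morphology does not change during events, and no respiration or SpO2 channel
is modeled.  Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg_io import EcgRecord
from .errors import ValidationError


@dataclass
class SynthParams:
    """Generator settings (times in seconds, amplitudes in mV)."""

    fs: float = 100.0
    mean_hr: float = 70.0            # beats/min
    rsa_freq: float = 0.25           # respiratory modulation, Hz
    rsa_depth: float = 0.05          # fractional RR modulation (normal minutes)
    cvhr_period_s: float = 45.0      # apnea cycle length, 30-60 s band
    cvhr_depth: float = 0.15         # fractional RR modulation (apnea minutes)
    rr_jitter: float = 0.01          # multiplicative beat-to-beat noise
    noise_sd: float = 0.05           # additive Gaussian noise, mV
    baseline_wander_amp: float = 0.1  # mV
    baseline_wander_freq: float = 0.3  # Hz
    hr_spread: float = 0.1           # per-record uniform HR variation (+-10%)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if not 30 <= self.mean_hr <= 200:
            raise ValidationError("mean_hr must lie in [30, 200] bpm")
        if not 0 <= self.cvhr_depth <= 0.5:
            raise ValidationError("cvhr_depth must lie in [0, 0.5]")
        if not 30 <= self.cvhr_period_s <= 60:
            raise ValidationError("cvhr_period_s must lie in [30, 60] s")


@dataclass
class BeatTemplate:
    """Sum-of-Gaussians beat: (amplitude mV, center offset s, width s) per bump."""

    bumps: tuple = (
        (0.15, -0.22, 0.030),   # P
        (-0.15, -0.035, 0.012),  # Q
        (1.20, 0.0, 0.013),     # R
        (-0.25, 0.030, 0.013),  # S
        (0.35, 0.30, 0.060),    # T
    )

    def __post_init__(self) -> None:
        # the bump at the template origin is the R wave; it must dominate
        r_amp, _, _ = min(self.bumps, key=lambda bump: abs(bump[1]))
        if r_amp <= 0 or r_amp < max(abs(a) for a, _, _ in self.bumps):
            raise ValidationError(
                "the R bump (center nearest 0) must have the largest amplitude")
        self.span = max(abs(c) + 4 * w for _, c, w in self.bumps)

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the template at offsets ``t`` (seconds from the R peak)."""
        out = np.zeros_like(t, dtype=np.float64)
        for amp, center, width in self.bumps:
            out += amp * np.exp(-((t - center) ** 2) / (2 * width ** 2))
        return out


def _rr_sequence(minutes: int, labels: list[str], params: SynthParams,
                 rng: np.random.Generator, mean_hr: float | None = None
                 ) -> np.ndarray:
    """Sequential RR intervals covering ``minutes`` of signal.

    At each beat the modulation is evaluated at the current time: RSA always,
    the slow cyclic term only inside minutes labeled ``A``.
    """
    hr = mean_hr if mean_hr is not None else params.mean_hr
    base = 60.0 / hr
    rsa_phase = rng.uniform(0, 2 * np.pi)
    cvhr_phase = rng.uniform(0, 2 * np.pi)
    total = minutes * 60.0
    rr, t = [], 0.0
    while t < total:
        minute = min(int(t // 60.0), minutes - 1)
        mod = params.rsa_depth * np.sin(
            2 * np.pi * params.rsa_freq * t + rsa_phase)
        if labels[minute] == "A":
            mod += params.cvhr_depth * np.sin(
                2 * np.pi * t / params.cvhr_period_s + cvhr_phase)
        interval = base * (1.0 + mod) * (1.0 + params.rr_jitter * rng.normal())
        interval = max(interval, 0.2)    # physiological floor
        rr.append(interval)
        t += interval
    return np.asarray(rr)


def synth_rr_series(minutes: int, label: str, params: SynthParams | None = None,
                    seed: int | None = None) -> np.ndarray:
    """RR intervals (s) for a constant-label stretch of ``minutes`` minutes."""
    params = params or SynthParams()
    if minutes < 1:
        raise ValidationError("minutes must be >= 1")
    if label not in ("N", "A"):
        raise ValidationError(f"label must be 'N' or 'A', got {label!r}")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    return _rr_sequence(minutes, [label] * minutes, params, rng)


def synth_ecg_from_rr(rr: np.ndarray, template: BeatTemplate | None = None,
                      params: SynthParams | None = None,
                      seed: int | None = None) -> np.ndarray:
    """Render RR intervals as sampled ECG (mV).

    Beats sit at the cumulative RR times; output length is
    ``round(sum(rr) * fs)`` samples.  Baseline wander and noise amplitudes
    come from ``params``.
    """
    params = params or SynthParams()
    template = template or BeatTemplate()
    rr = np.asarray(rr, dtype=np.float64)
    if rr.size == 0 or np.any(rr <= 0):
        raise ValidationError("RR intervals must be positive and non-empty")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    fs = params.fs
    n = int(round(rr.sum() * fs))
    x = np.zeros(n)
    beat_times = np.cumsum(rr)
    half = template.span
    for bt in beat_times:
        lo = max(int(np.floor((bt - half) * fs)), 0)
        hi = min(int(np.ceil((bt + half) * fs)) + 1, n)
        if lo >= hi:
            continue
        t = np.arange(lo, hi) / fs - bt
        x[lo:hi] += template.waveform(t)
    tt = np.arange(n) / fs
    if params.baseline_wander_amp > 0:
        x += params.baseline_wander_amp * np.sin(
            2 * np.pi * params.baseline_wander_freq * tt
            + rng.uniform(0, 2 * np.pi))
    if params.noise_sd > 0:
        x += params.noise_sd * rng.standard_normal(n)
    return x


def _label_runs(minutes: int, apnea_fraction: float,
                rng: np.random.Generator) -> list[str]:
    """Per-minute labels in contiguous runs with an exact A-minute count."""
    n_a = int(round(minutes * apnea_fraction))
    n_n = minutes - n_a
    labels: list[str] = []
    state = "A" if (n_n == 0 or (n_a > 0 and rng.random() < apnea_fraction)) \
        else "N"
    while len(labels) < minutes:
        remaining = n_a if state == "A" else n_n
        if remaining == 0:
            state = "N" if state == "A" else "A"
            continue
        run = min(int(rng.integers(2, 7)), remaining)
        labels.extend([state] * run)
        if state == "A":
            n_a -= run
        else:
            n_n -= run
        state = "N" if state == "A" else "A"
    return labels


def generate_dataset(n_records: int, minutes_per_record: int,
                     apnea_fraction: float, seed: int,
                     params: SynthParams | None = None,
                     template: BeatTemplate | None = None) -> list[EcgRecord]:
    """Generate a fully labeled synthetic dataset.

    Apnea minutes come in contiguous multi-minute episodes; each record's
    A-minute count equals ``round(minutes * apnea_fraction)``.  Per-record
    mean heart rate varies uniformly within ``+-hr_spread`` around
    ``params.mean_hr`` so records are not clones of one another.
    """
    params = params or SynthParams()
    template = template or BeatTemplate()
    if n_records < 1 or minutes_per_record < 1:
        raise ValidationError("counts must be >= 1")
    if not 0.0 <= apnea_fraction <= 1.0:
        raise ValidationError("apnea_fraction must lie in [0, 1]")
    root = np.random.SeedSequence(seed)
    records = []
    for i, child in enumerate(root.spawn(n_records)):
        rng = np.random.default_rng(child)
        labels = _label_runs(minutes_per_record, apnea_fraction, rng)
        hr = params.mean_hr * rng.uniform(1 - params.hr_spread,
                                          1 + params.hr_spread)
        rr = _rr_sequence(minutes_per_record, labels, params, rng, mean_hr=hr)
        beat_seed = int(rng.integers(0, 2 ** 31 - 1))
        samples = synth_ecg_from_rr(rr, template, params, seed=beat_seed)
        want = int(round(minutes_per_record * 60 * params.fs))
        if len(samples) < want:          # pad the sub-beat remainder
            samples = np.pad(samples, (0, want - len(samples)))
        records.append(EcgRecord(record_id=f"syn{i:03d}",
                                 samples=samples[:want],
                                 fs=params.fs, labels=labels))
    return records
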