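"""Synthetic trial generator with known ground truth.

Each trial emulates one repetition of the focal task: a minimum-jerk shoulder
flexion of ~90 deg and seven EMG channels built as band-limited Gaussian
carriers (20-500 Hz) amplitude-modulated by phase-locked envelopes, on top of
a band-limited noise floor.  The envelope levels are calibrated in closed
loop against the analysis pipeline's own noise model so that the *expected*
normalized intensity recovered for each (condition, phase, muscle) equals the
programmed amplitude, whose per-trial draws follow the published
condition x phase x muscle mean/SD table.

Two ingredients make the calibration well-posed:

* a dedicated normalization burst (unit envelope, ~170 ms) placed in the
  post-movement hold phase, outside all analysis windows, which realizes the
  repetition-maximum RMS the intensity normalization divides by;
* a carrier/noise scale model computed once per configuration (the processed
  RMS per unit envelope, and the expected maximum moving RMS of the burst
  including its extreme-value bias), cached and fully deterministic.

A trial-level multiplicative gain (log-normal, mean 1) on the postural-muscle
phase envelopes induces cross-phase amplitude correlations across trials; it
is recoverable precisely because the normalization burst is *not* scaled by
it (a gain on the whole channel would cancel out of the intensity, which is
scale-invariant per channel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .io import (HEIGHTS, MUSCLES, PHASES, POSTURAL_MUSCLES, VISIONS,
                 TrialRecording, write_trial)
from .preprocess import process_emg

#: Published mean +- SD of normalized muscle activity (%MAXIMUM), by
#: (height, vision) -> phase -> muscle -> (mean, sd).
PUBLISHED_AMPLITUDES: dict[tuple[str, str], dict[str, dict[str, tuple[float, float]]]] = {
    ("floor", "open"): {
        "APA": {"AD": (56.0, 21.8), "LE": (35.0, 10.8), "RA": (15.6, 6.6),
                "RF": (47.7, 11.4), "BF": (52.5, 16.7), "TA": (1.7, 1.2), "GL": (35.5, 29.7)},
        "OPA": {"AD": (66.4, 18.1), "LE": (73.6, 15.6), "RA": (71.4, 8.3),
                "RF": (65.9, 8.1), "BF": (66.8, 11.6), "TA": (78.3, 9.8), "GL": (73.4, 12.6)},
        "CPA": {"AD": (48.3, 15.4), "LE": (57.2, 15.5), "RA": (62.1, 10.1),
                "RF": (55.5, 10.6), "BF": (56.7, 16.7), "TA": (47.0, 10.9), "GL": (46.4, 10.7)},
    },
    ("floor", "closed"): {
        "APA": {"AD": (63.6, 31.3), "LE": (35.1, 11.0), "RA": (15.2, 8.0),
                "RF": (54.4, 45.8), "BF": (54.6, 14.9), "TA": (1.7, 1.1), "GL": (30.9, 27.4)},
        "OPA": {"AD": (66.7, 19.3), "LE": (73.6, 15.6), "RA": (70.2, 7.4),
                "RF": (67.3, 10.3), "BF": (65.0, 11.7), "TA": (76.4, 11.0), "GL": (70.8, 11.0)},
        "CPA": {"AD": (46.3, 16.7), "LE": (59.2, 16.6), "RA": (62.3, 8.8),
                "RF": (54.8, 11.2), "BF": (53.5, 14.3), "TA": (46.5, 12.6), "GL": (48.2, 12.0)},
    },
    ("elevated", "open"): {
        "APA": {"AD": (51.2, 18.0), "LE": (35.2, 9.3), "RA": (19.8, 9.5),
                "RF": (49.9, 11.5), "BF": (54.1, 15.4), "TA": (1.8, 1.2), "GL": (29.8, 25.2)},
        "OPA": {"AD": (65.3, 15.7), "LE": (66.5, 8.8), "RA": (70.1, 9.4),
                "RF": (63.5, 8.5), "BF": (66.6, 10.8), "TA": (76.4, 10.8), "GL": (84.9, 21.1)},
        "CPA": {"AD": (52.5, 13.5), "LE": (57.8, 12.3), "RA": (59.5, 9.3),
                "RF": (55.6, 11.1), "BF": (56.3, 14.2), "TA": (50.3, 12.4), "GL": (47.4, 10.1)},
    },
    ("elevated", "closed"): {
        "APA": {"AD": (52.4, 28.2), "LE": (35.0, 8.7), "RA": (17.8, 7.6),
                "RF": (51.3, 12.3), "BF": (54.2, 16.6), "TA": (2.4, 2.3), "GL": (29.4, 25.4)},
        "OPA": {"AD": (67.2, 14.6), "LE": (71.2, 12.2), "RA": (72.3, 8.5),
                "RF": (67.2, 15.6), "BF": (66.9, 12.5), "TA": (77.9, 10.5), "GL": (73.2, 13.4)},
        "CPA": {"AD": (52.1, 17.0), "LE": (60.1, 15.0), "RA": (61.7, 8.2),
                "RF": (57.1, 11.1), "BF": (55.2, 13.4), "TA": (47.9, 12.0), "GL": (51.1, 10.9)},
    },
}

#: Default mean burst onsets relative to movement onset (ms).  The source
#: study reports latencies only graphically, so these are free parameters:
#: the focal AD leads, postural muscles span roughly -80..+40 ms.  Muscles
#: with a large anticipatory amplitude share must start early for the stated
#: world to be self-consistent (a late onset would require an envelope spike
#: exceeding the repetition maximum to reach the window-average amplitude).
DEFAULT_LATENCIES_MS: dict[str, float] = {
    "AD": -120.0, "LE": -80.0, "BF": -70.0, "RF": -60.0,
    "GL": -50.0, "RA": -30.0, "TA": 20.0,
}

ALL_CONDITIONS: tuple[tuple[str, str], ...] = tuple(
    (h, v) for h in HEIGHTS for v in VISIONS)

#: Intensity cannot exceed 100/0.95; draws are clipped here (see docs).
AMPLITUDE_CEILING = 105.0


def flat_amplitude_table(mean: float, sd: float,
                         conditions=ALL_CONDITIONS) -> dict:
    """Uniform amplitude table (every condition/phase/muscle identical).

    Used for null-effect calibration experiments (e.g. ANOVA type-I rate).
    """
    return {c: {p: {m: (mean, sd) for m in MUSCLES} for p in PHASES}
            for c in conditions}


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated world of the synthetic experiment.

    Defaults reproduce the study's design: 8 subjects x 10 repetitions in each
    of the four (height, vision) conditions -> 80 trials per condition, 1 kHz
    sampling, ~90 deg minimum-jerk shoulder flexion of 500 ms, and phase
    amplitudes drawn from the published table.
    """

    fs_hz: float = 1000.0
    trial_duration_ms: float = 4000.0
    n_subjects: int = 8
    n_reps: int = 10
    conditions: tuple[tuple[str, str], ...] = ALL_CONDITIONS
    amplitude_table: dict = field(default_factory=lambda: PUBLISHED_AMPLITUDES)
    latency_table: dict = field(default_factory=lambda: dict(DEFAULT_LATENCIES_MS))
    latency_jitter_ms: float = 10.0
    t0_ms: float = 1000.0
    t0_jitter_ms: float = 100.0
    movement_duration_ms: float = 500.0
    movement_amplitude_deg: float = 90.0
    noise_floor: float = 1.0          # %MAX read by a silent channel
    shared_gain_sd: float = 0.1       # sd of the trial-level log-normal gain
    gain_groups: tuple[tuple[str, ...], ...] = (("APA", "OPA", "CPA"),)
    gain_per_muscle: bool = False
    angle_noise_deg: float = 0.0
    emg_band_lo_hz: float = 20.0      # acquisition high-pass (upper edge = Nyquist)
    emg_lowpass_hz: float = 200.0     # envelope low-pass the pipeline applies
    filter_order: int = 4
    ramp_ms: float = 25.0
    peak_plateau_ms: float = 120.0
    peak_offset_ms: float = 400.0     # normalization burst start after movement end
    norm_window_ms: float = 100.0
    norm_fraction: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, phases in self.amplitude_table.items():
            for phase, muscles in phases.items():
                if phase not in PHASES:
                    raise KeyError(f"unknown phase key {phase!r} in amplitude table")
                for m, (mean, sd) in muscles.items():
                    if m not in MUSCLES:
                        raise KeyError(f"unknown muscle key {m!r} in amplitude table")
                    if not 0.0 <= mean <= 100.0:
                        raise ValueError(
                            f"amplitude mean {mean} for {cond}/{phase}/{m} outside [0, 100]")
                    if sd < 0:
                        raise ValueError(f"negative amplitude sd for {cond}/{phase}/{m}")
        for m in self.latency_table:
            if m not in MUSCLES:
                raise KeyError(f"unknown muscle key {m!r} in latency table")
        if not 0 < self.emg_band_lo_hz < self.fs_hz / 2:
            raise ValueError("EMG band must lie below Nyquist")
        if self.t0_ms + self.movement_duration_ms >= self.trial_duration_ms:
            raise ValueError("movement extends past the end of the trial")

    @property
    def n_trials(self) -> int:
        return self.n_subjects * self.n_reps * len(self.conditions)


@dataclass(frozen=True)
class GroundTruth:
    """Per-trial truth: events, burst onsets, programmed amplitudes, gains.

    ``programmed`` holds the effective per-trial amplitude (base draw x gain,
    clipped at the intensity ceiling) -- the value the pipeline's normalized
    intensity is calibrated to recover in expectation.
    """

    trial_id: str
    t0_ms: float
    tf_ms: float
    onsets_ms: dict[str, float]
    programmed: dict[tuple[str, str], float]
    base_amplitude: dict[tuple[str, str], float]
    gains: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if not self.tf_ms > self.t0_ms:
            raise ValueError("tf must exceed t0")
        if any(v < 0 for v in self.programmed.values()):
            raise ValueError("programmed amplitudes must be nonnegative")


def kinematic_profile(t0_ms: float, duration_ms: float, amplitude_deg: float,
                      fs_hz: float, trial_duration_ms: float) -> np.ndarray:
    """Minimum-jerk shoulder-flexion angle trace (degrees).

    theta(s) = A (10 s^3 - 15 s^4 + 6 s^5) with s the normalized movement
    time: 0 deg before onset, ``amplitude_deg`` after ``t0 + duration``,
    smooth (continuous acceleration) in between with peak velocity at the
    movement midpoint and a biphasic acceleration profile.
    """
    if duration_ms <= 0:
        raise ValueError("movement duration must be positive")
    if t0_ms + duration_ms >= trial_duration_ms:
        raise ValueError("movement extends past the end of the trial")
    n = int(round(trial_duration_ms * fs_hz / 1000.0))
    t = np.arange(n) * 1000.0 / fs_hz
    s = np.clip((t - t0_ms) / duration_ms, 0.0, 1.0)
    return amplitude_deg * (10 * s**3 - 15 * s**4 + 6 * s**5)


# ---------------------------------------------------------------------------
# Carrier/noise scale model


def _highpass_sos(fs: float, lo_hz: float, order: int):
    return signal.butter(order, lo_hz, btype="high", fs=fs, output="sos")


def _filtfilt_noise_gain(sos: np.ndarray, fs: float) -> float:
    """Std of zero-phase-filtered unit white noise: sqrt(mean |H|^4) over frequency."""
    _, h = signal.sosfreqz(sos, worN=8192, fs=fs)
    return float(np.sqrt(np.mean(np.abs(h) ** 4)))


def _band_carrier(rng: np.random.Generator, n: int, fs: float, lo_hz: float,
                  order: int) -> np.ndarray:
    """Unit-variance (in expectation) band-limited Gaussian carrier."""
    sos = _highpass_sos(fs, lo_hz, order)
    gain = _cached_noise_gain(round(fs, 6), round(lo_hz, 6), order)
    return signal.sosfiltfilt(sos, rng.standard_normal(n)) / gain


@lru_cache(maxsize=32)
def _cached_noise_gain(fs: float, lo_hz: float, order: int) -> float:
    return _filtfilt_noise_gain(_highpass_sos(fs, lo_hz, order), fs)


def _smooth_ramp_kernel(fs: float, ramp_ms: float) -> np.ndarray:
    n = max(3, 2 * int(round(ramp_ms * fs / 1000.0)) + 1)
    k = np.hanning(n)
    return k / k.sum()


def _peak_envelope(n: int, fs: float, start_ms: float, plateau_ms: float,
                   ramp_ms: float, level: float = 1.0) -> np.ndarray:
    env = np.zeros(n)
    i0 = int(round(start_ms * fs / 1000.0))
    i1 = int(round((start_ms + plateau_ms + 2 * ramp_ms) * fs / 1000.0))
    env[i0:i1] = level
    return np.convolve(env, _smooth_ramp_kernel(fs, ramp_ms), mode="same")


@lru_cache(maxsize=16)
def _carrier_scale_model(fs: float, band_lo: float, lp_cutoff: float, order: int,
                         noise_sd: float, window_ms: float, peak_plateau_ms: float,
                         ramp_ms: float) -> tuple[float, float]:
    """(rho, kappa): processed-RMS per unit envelope, and expected
    normalization denominator in envelope units.

    rho is the RMS of the processed (demeaned, rectified, low-passed) carrier
    at constant unit envelope.  kappa is E[max moving-window RMS] of the
    processed normalization burst (unit plateau + noise floor), divided by
    rho; it includes both the sqrt(1 + noise^2) quadrature term and the
    extreme-value bias of taking a maximum over overlapping windows.  Both
    are estimated once per configuration from a fixed-seed Monte Carlo of the
    noise model (they are properties of the carrier band and filters, not of
    any particular trial) and cached.
    """
    rng = np.random.default_rng(np.random.SeedSequence(987654321))
    pad_ms = 300.0
    # rho: long constant plateau
    n = int(round(2000.0 * fs / 1000.0))
    trim = int(round(pad_ms * fs / 1000.0))
    vals = []
    for _ in range(8):
        c = _band_carrier(rng, n, fs, band_lo, order)
        nz = noise_sd * _band_carrier(rng, n, fs, band_lo, order)
        proc = process_emg(c + nz, fs, lp_cutoff, order)
        vals.append(np.sqrt(np.mean(proc[trim:-trim] ** 2)))
    rho = float(np.mean(vals))

    # kappa: normalization burst, max moving RMS
    seg_ms = 2 * pad_ms + peak_plateau_ms + 2 * ramp_ms + 2 * window_ms
    n = int(round(seg_ms * fs / 1000.0))
    env = _peak_envelope(n, fs, pad_ms, peak_plateau_ms, ramp_ms)
    w = int(round(window_ms * fs / 1000.0))
    maxima = []
    for _ in range(128):
        c = _band_carrier(rng, n, fs, band_lo, order)
        nz = noise_sd * _band_carrier(rng, n, fs, band_lo, order)
        proc = process_emg(env * c + nz, fs, lp_cutoff, order)
        csum = np.concatenate(([0.0], np.cumsum(proc * proc)))
        maxima.append(np.sqrt(((csum[w:] - csum[:-w]) / w).max()))
    kappa = float(np.mean(maxima)) / rho
    return rho, kappa


def _scale_model(config: GeneratorConfig) -> tuple[float, float, float]:
    """(rho, kappa, sigma_n) for a configuration; sigma_n in envelope units."""
    sigma0 = config.norm_fraction * config.noise_floor / 100.0
    rho, kappa = _carrier_scale_model(
        round(config.fs_hz, 6), round(config.emg_band_lo_hz, 6),
        round(config.emg_lowpass_hz, 6), config.filter_order,
        round(sigma0, 9), round(config.norm_window_ms, 6),
        round(config.peak_plateau_ms, 6), round(config.ramp_ms, 6))
    sigma_n = config.norm_fraction * kappa * config.noise_floor / 100.0
    return rho, kappa, sigma_n


# ---------------------------------------------------------------------------
# Envelope construction


def _ramped_steps(n: int, bounds: list[int], levels: list[float],
                  ramp_n: int) -> np.ndarray:
    """Piecewise-constant envelope with half-cosine ramps at the boundaries.

    ``bounds`` are the internal boundaries between ``len(levels)`` segments
    (segment j spans [bounds[j-1], bounds[j])).  Each ramp is placed entirely
    inside the segment with the *higher* level, so a quiet window never
    inherits spill-over activity from a loud neighbour.
    """
    e = np.zeros(n)
    edges = [0] + list(bounds) + [n]
    for j, lvl in enumerate(levels):
        e[edges[j]:edges[j + 1]] = lvl
    for j in range(len(levels) - 1):
        lo, hi = levels[j], levels[j + 1]
        if lo == hi:
            continue
        b = edges[j + 1]
        seg_len = (edges[j + 2] - b) if hi > lo else (b - edges[j])
        r = min(ramp_n, max(seg_len // 2, 1))
        u = (1.0 - np.cos(np.pi * np.arange(1, r + 1) / r)) / 2.0
        if hi > lo:       # rise inside the following (higher) segment
            e[b:b + r] = lo + (hi - lo) * u
        else:             # fall inside the preceding (higher) segment
            e[b - r:b] = lo + (hi - lo) * u[::-1]
    return e


def _calibrated_envelope(config: GeneratorConfig, n: int, t0: float, tf: float,
                         onset_ms: float, targets: dict[str, float],
                         sigma_n: float, kappa: float) -> np.ndarray:
    """Phase envelope whose windowed mean square matches the intensity targets.

    ``targets`` maps phase -> programmed amplitude (%MAX).  The required
    window mean square is ((fraction * kappa * a / 100)^2 - sigma_n^2)+ ; the
    envelope is plateaus over the active segment of each phase (APA activity
    starts at the muscle's burst onset, not at the window edge) joined by
    25-ms half-cosine ramps, refined by a short fixed-point loop so the
    ramps do not bias the windowed mean square.
    """
    fs = config.fs_hz
    to_idx = lambda ms: int(round(ms * fs / 1000.0))
    windows = {
        "APA": (to_idx(t0 - 200.0), to_idx(t0 + 50.0)),
        "OPA": (to_idx(t0 + 50.0), to_idx(tf)),
        "CPA": (to_idx(tf), to_idx(tf + 250.0)),
    }
    onset_idx = min(to_idx(t0 + onset_ms), windows["APA"][1] - to_idx(10.0))
    onset_idx = max(onset_idx, 0)
    target_ms = {}
    for p in PHASES:
        a = targets.get(p, 0.0)
        goal = (config.norm_fraction * kappa * a / 100.0) ** 2 - sigma_n ** 2
        target_ms[p] = max(goal, 0.0)

    # A stronger anticipatory burst must start earlier: the plateau level is
    # capped just below the normalization burst, so when the drawn APA
    # amplitude cannot be reached over [onset, t0+50) at that cap the onset
    # is advanced (never before the window start) to enlarge the active
    # fraction.  The adjusted onset is returned and recorded as ground truth.
    cap = 0.95
    w0, w1 = windows["APA"]
    if target_ms["APA"] > 0:
        frac_needed = min(target_ms["APA"] / cap ** 2, 1.0)
        latest = w1 - int(math.ceil(frac_needed * (w1 - w0)))
        onset_idx = min(onset_idx, max(latest, w0))

    levels = {}
    for p in PHASES:
        w0, w1 = windows[p]
        a0 = onset_idx if p == "APA" else w0
        frac = (w1 - a0) / max(w1 - w0, 1)
        levels[p] = math.sqrt(target_ms[p] / frac) if target_ms[p] > 0 and frac > 0 else 0.0

    ramp_n = max(1, to_idx(config.ramp_ms))
    bounds = [onset_idx, windows["APA"][1], windows["OPA"][1], windows["CPA"][1]]
    env = np.zeros(n)
    for _ in range(8):
        env = _ramped_steps(n, bounds, [0.0, levels["APA"], levels["OPA"],
                                        levels["CPA"], 0.0], ramp_n)
        converged = True
        for p in PHASES:
            if target_ms[p] <= 0 or levels[p] <= 0:
                continue
            w0, w1 = windows[p]
            got = float(np.mean(env[w0:w1] ** 2))
            if got <= 0:
                continue
            adj = math.sqrt(min(max(target_ms[p] / got, 0.25), 4.0))
            if abs(adj - 1.0) > 1e-3:
                converged = False
            levels[p] *= adj
        if converged:
            break
    onset_used_ms = onset_idx * 1000.0 / fs
    return env, onset_used_ms


# ---------------------------------------------------------------------------
# Trial and dataset generation


def _amplitude_sigma(mean: float, sd: float, gain_sd: float, gained: bool) -> float:
    """Base-draw SD so that base x gain has the published total SD."""
    if not gained or gain_sd <= 0:
        return sd
    var = (sd ** 2 - (gain_sd * mean) ** 2) / (1.0 + gain_sd ** 2)
    return math.sqrt(max(var, (0.02 * mean) ** 2))


def _draw_amplitude(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gamma draw with given mean/sd (support >= 0, exact mean)."""
    if mean <= 0:
        return 0.0
    if sd <= 0:
        return mean
    shape = (mean / sd) ** 2
    return float(rng.gamma(shape, sd ** 2 / mean))


def generate_trial(config: GeneratorConfig, condition: tuple[str, str],
                   subject_id: int, rep_id: int,
                   seed: int | None = None) -> tuple[TrialRecording, GroundTruth]:
    """Generate one trial and its ground truth.

    The random stream is a pure function of (seed, condition, subject, rep)
    via a counter-based seed sequence, so any subset of the dataset can be
    regenerated independently and identical inputs are bit-reproducible.
    """
    condition = tuple(condition)
    if condition not in config.conditions:
        raise ValueError(f"condition {condition!r} not in the configured grid")
    if condition not in config.amplitude_table:
        raise KeyError(f"no amplitude entry for condition {condition!r}")
    seed = config.seed if seed is None else seed
    cond_idx = config.conditions.index(condition)
    ss = np.random.SeedSequence([abs(int(seed)), cond_idx, int(subject_id), int(rep_id)])
    rng = np.random.default_rng(ss)

    fs = config.fs_hz
    n = int(round(config.trial_duration_ms * fs / 1000.0))
    rho, kappa, sigma_n = _scale_model(config)

    # --- events and onsets
    jitter = rng.uniform(-config.t0_jitter_ms, config.t0_jitter_ms)
    t0 = config.t0_ms + jitter
    tf = t0 + config.movement_duration_ms
    peak_start = tf + config.peak_offset_ms
    peak_end = peak_start + config.peak_plateau_ms + 2 * config.ramp_ms
    if peak_end + 50.0 > config.trial_duration_ms:
        raise ValueError("trial too short for the post-movement normalization burst")
    onsets = {m: t0 + config.latency_table.get(m, 0.0)
              + rng.normal(0.0, config.latency_jitter_ms) for m in MUSCLES}

    # --- trial gains (log-normal, mean 1), per phase group
    gains: dict[tuple[str, str], float] = {(m, p): 1.0 for m in MUSCLES for p in PHASES}
    s = config.shared_gain_sd
    if s > 0:
        sig = math.sqrt(math.log1p(s * s))
        for group in config.gain_groups:
            if config.gain_per_muscle:
                for m in POSTURAL_MUSCLES:
                    g = float(rng.lognormal(-sig * sig / 2.0, sig))
                    for p in group:
                        gains[(m, p)] = g
            else:
                g = float(rng.lognormal(-sig * sig / 2.0, sig))
                for m in POSTURAL_MUSCLES:
                    for p in group:
                        gains[(m, p)] = g

    # --- programmed amplitudes
    table = config.amplitude_table[condition]
    base: dict[tuple[str, str], float] = {}
    programmed: dict[tuple[str, str], float] = {}
    for m in MUSCLES:
        for p in PHASES:
            if m not in table[p]:
                raise KeyError(f"no amplitude entry for muscle {m!r} in phase {p!r}")
            mean, sd = table[p][m]
            gained = m in POSTURAL_MUSCLES and s > 0
            b = _draw_amplitude(rng, mean, _amplitude_sigma(mean, sd, s, gained))
            base[(m, p)] = b
            programmed[(m, p)] = min(b * gains[(m, p)], AMPLITUDE_CEILING)

    # --- kinematics
    angle = kinematic_profile(t0, config.movement_duration_ms,
                              config.movement_amplitude_deg, fs,
                              config.trial_duration_ms)
    if config.angle_noise_deg > 0:
        angle = angle + rng.normal(0.0, config.angle_noise_deg, n)

    # --- EMG channels
    peak_env = _peak_envelope(n, fs, peak_start, config.peak_plateau_ms,
                              config.ramp_ms)
    emg: dict[str, np.ndarray] = {}
    for m in MUSCLES:
        targets = {p: programmed[(m, p)] for p in PHASES}
        env, onset_used = _calibrated_envelope(config, n, t0, tf, onsets[m] - t0,
                                               targets, sigma_n, kappa)
        onsets[m] = onset_used
        env = np.maximum(env, peak_env)
        carrier = _band_carrier(rng, n, fs, config.emg_band_lo_hz, config.filter_order)
        noise = _band_carrier(rng, n, fs, config.emg_band_lo_hz, config.filter_order)
        emg[m] = env * carrier + sigma_n * noise

    rec = TrialRecording(
        time_ms=np.arange(n) * 1000.0 / fs, angle_deg=angle, emg=emg, fs_hz=fs,
        subject=int(subject_id), rep=int(rep_id),
        height=condition[0], vision=condition[1], processing_state="raw")
    truth = GroundTruth(
        trial_id=rec.trial_id(), t0_ms=t0, tf_ms=tf, onsets_ms=onsets,
        programmed=programmed, base_amplitude=base, gains=gains)
    return rec, truth


def generate_dataset(config: GeneratorConfig, seed: int | None = None
                     ) -> tuple[list[TrialRecording], list[GroundTruth]]:
    """Generate the full trial grid (subjects x reps x conditions) in memory."""
    trials, truths = [], []
    for condition in config.conditions:
        for subject in range(1, config.n_subjects + 1):
            for rep in range(1, config.n_reps + 1):
                rec, truth = generate_trial(config, condition, subject, rep, seed)
                trials.append(rec)
                truths.append(truth)
    return trials, truths


def truth_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    """Long-format ground-truth table (one row per trial x muscle x phase)."""
    rows = []
    for t in truths:
        for m in MUSCLES:
            for p in PHASES:
                rows.append({
                    "trial_id": t.trial_id, "t0_ms": t.t0_ms, "tf_ms": t.tf_ms,
                    "muscle": m, "phase": p, "onset_ms": t.onsets_ms[m],
                    "programmed": t.programmed[(m, p)],
                    "base_amplitude": t.base_amplitude[(m, p)],
                    "gain": t.gains[(m, p)],
                })
    return pd.DataFrame(rows)


def write_dataset(config: GeneratorConfig, outdir: str | Path,
                  seed: int | None = None, overwrite: bool = False) -> Path:
    """Generate and write the dataset: trial TSVs + sidecars + ground truth.

    Refuses to clobber an existing ground-truth table unless ``overwrite``.
    """
    outdir = Path(outdir)
    gt_path = outdir / "ground_truth.tsv"
    if gt_path.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite {gt_path} (pass overwrite=True)")
    trials, truths = generate_dataset(config, seed)
    trial_dir = outdir / "trials"
    for rec in trials:
        write_trial(trial_dir, rec, overwrite=overwrite)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_frame(truths).to_csv(gt_path, sep="\t", index=False, float_format="%.8g")
    return gt_path


def small_config(**overrides) -> GeneratorConfig:
    """A reduced configuration for tests and smoke runs (2 subjects x 2 reps)."""
    defaults = dict(n_subjects=2, n_reps=2, trial_duration_ms=2400.0,
                    t0_ms=800.0, t0_jitter_ms=50.0)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)
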