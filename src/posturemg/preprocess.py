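"""Signal conditioning.

EMG: mean removal, full-wave rectification, 4th-order Butterworth low-pass at
200 Hz.  Shoulder angle: 4th-order Butterworth low-pass at 20 Hz.  Both
filters are applied zero-phase (forward-backward) because epoch timing is the
core of the analysis and any phase lag would bias every window; the effective
stopband attenuation therefore doubles relative to a single pass.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .io import MUSCLES, TrialRecording

EMG_LOWPASS_HZ = 200.0
ANGLE_LOWPASS_HZ = 20.0
FILTER_ORDER = 4


def butterworth_lowpass(x: np.ndarray, cutoff_hz: float, fs: float,
                        order: int = FILTER_ORDER) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward and backward).

    Parameters
    ----------
    x : array
        Signal sampled uniformly at ``fs``.
    cutoff_hz : float
        -3 dB cutoff of the single-pass filter; must lie in (0, fs/2).
    fs : float
        Sampling rate in Hz.
    order : int
        Filter order of the single pass (default 4).

    Returns
    -------
    array
        Filtered signal, same length as ``x``.  DC gain is exactly 1.
    """
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie strictly between 0 and Nyquist ({fs / 2} Hz)")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, float))


def process_emg(x: np.ndarray, fs: float, cutoff_hz: float = EMG_LOWPASS_HZ,
                order: int = FILTER_ORDER) -> np.ndarray:
    """Condition one raw EMG channel: demean, rectify, low-pass, clip at zero.

    Rectified EMG is conceptually nonnegative; the small negative ripple the
    low-pass filter can introduce is clipped to 0 so downstream RMS values
    measure activity only.
    """
    x = np.asarray(x, float)
    rectified = np.abs(x - x.mean())
    return np.clip(butterworth_lowpass(rectified, cutoff_hz, fs, order), 0.0, None)


def process_angle(x: np.ndarray, fs: float, cutoff_hz: float = ANGLE_LOWPASS_HZ,
                  order: int = FILTER_ORDER) -> np.ndarray:
    """Low-pass filter the shoulder-angle channel (default 20 Hz, order 4)."""
    return butterworth_lowpass(x, cutoff_hz, fs, order)


def process_trial(rec: TrialRecording, emg_cutoff_hz: float = EMG_LOWPASS_HZ,
                  angle_cutoff_hz: float = ANGLE_LOWPASS_HZ,
                  order: int = FILTER_ORDER) -> TrialRecording:
    """Return a processed copy of a raw trial (all channels conditioned)."""
    if rec.processing_state == "processed":
        return rec
    emg = {m: process_emg(rec.emg[m], rec.fs_hz, emg_cutoff_hz, order) for m in MUSCLES}
    angle = process_angle(rec.angle_deg, rec.fs_hz, angle_cutoff_hz, order)
    return rec.with_channels(angle, emg, "processed")
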