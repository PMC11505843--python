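"""Movement-event detection and APA/OPA/CPA epoch construction.

The focal movement's onset ``t0`` and end ``tf`` are found from the shoulder
angle's second derivative (angular acceleration).  The three analysis epochs
partition [t0-200, tf+250) ms into half-open, contiguous windows:

* APA  (anticipatory): [t0-200, t0+50)
* OPA  (online):       [t0+50, tf)
* CPA  (compensatory): [tf, tf+250)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

APA_PRE_MS = 200.0    # APA starts this long before movement onset
APA_POST_MS = 50.0    # APA/OPA boundary after movement onset
CPA_LEN_MS = 250.0    # CPA duration after movement end


class NoMovementError(ValueError):
    """Raised when no supra-threshold acceleration excursion is found."""


class EpochBoundsError(ValueError):
    """Raised when an epoch would fall outside the recorded trial."""


@dataclass(frozen=True)
class MovementEvents:
    """Detected movement onset/end plus detection metadata."""

    t0_ms: float
    tf_ms: float
    threshold: float
    baseline_ms: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.t0_ms < self.tf_ms:
            raise ValueError("movement onset must precede movement end")


@dataclass(frozen=True)
class EpochWindows:
    """The three half-open analysis windows, in ms and in sample indices."""

    apa_ms: tuple[float, float]
    opa_ms: tuple[float, float]
    cpa_ms: tuple[float, float]
    fs_hz: float

    def window_ms(self, phase: str) -> tuple[float, float]:
        return {"APA": self.apa_ms, "OPA": self.opa_ms, "CPA": self.cpa_ms}[phase]

    def slice_(self, phase: str) -> slice:
        """Half-open sample-index slice for a phase (0-based, ms -> samples)."""
        start, end = self.window_ms(phase)
        return slice(int(round(start * self.fs_hz / 1000.0)),
                     int(round(end * self.fs_hz / 1000.0)))


def angular_acceleration(angle_deg: np.ndarray, fs: float) -> np.ndarray:
    """Angular acceleration (deg/s^2) by double central differencing.

    Interior points use central differences (exact for quadratics); the two
    endpoints fall back to one-sided differences.  The angle should already be
    low-pass filtered (20 Hz) -- double differentiation amplifies noise by
    (2*pi*f)^2.
    """
    angle_deg = np.asarray(angle_deg, float)
    if angle_deg.size < 3:
        raise ValueError("need at least 3 samples to differentiate twice")
    dt = 1.0 / fs
    return np.gradient(np.gradient(angle_deg, dt), dt)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where ``mask`` is True."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def detect_events(acc: np.ndarray, fs: float,
                  baseline_ms: tuple[float, float] = (0.0, 500.0),
                  k: float = 3.0, sustain_ms: float = 25.0,
                  quiet_ms: float = 200.0, rel_floor: float = 0.05) -> MovementEvents:
    """Detect movement onset/end from the acceleration trace.

    The threshold is ``T = mean(|acc|) + k*std(|acc|)`` over the baseline
    window, floored at ``rel_floor * max(|acc|)`` so that detection remains
    well-posed on noiseless kinematics (where the baseline statistics vanish
    to machine precision).  ``t0`` is the first sample whose next ``sustain_ms``
    stay above threshold; ``tf`` is the last sample of the final
    supra-threshold excursion that is followed by at least ``quiet_ms`` below
    threshold (or by the end of the trial).
    """
    acc = np.abs(np.asarray(acc, float))
    b0 = int(round(baseline_ms[0] * fs / 1000.0))
    b1 = int(round(baseline_ms[1] * fs / 1000.0))
    if b1 - b0 < int(0.1 * fs):
        raise ValueError("baseline window must span at least 100 ms")
    base = acc[b0:b1]
    threshold = float(base.mean() + k * base.std()) if base.size else 0.0
    threshold = max(threshold, rel_floor * float(acc.max(initial=0.0)))
    if threshold <= 0:
        raise NoMovementError("no movement detected (flat trace)")

    above = acc > threshold
    sustain_n = max(1, int(round(sustain_ms * fs / 1000.0)))
    quiet_n = max(1, int(round(quiet_ms * fs / 1000.0)))

    runs = [(s, e) for s, e in _runs_above(above) if s >= b1]
    runs = [(s, e) for s, e in runs if e - s >= sustain_n]
    if not runs:
        raise NoMovementError("no movement detected (no sustained excursion)")
    t0_idx = runs[0][0]

    # tf: end of the last excursion in the movement's excursion train, where a
    # gap of >= quiet_ms (or trial end) terminates the train.
    tf_idx = None
    all_runs = [(s, e) for s, e in _runs_above(above) if s >= t0_idx]
    for i, (s, e) in enumerate(all_runs):
        nxt = all_runs[i + 1][0] if i + 1 < len(all_runs) else above.size + quiet_n
        if nxt - e >= quiet_n:
            tf_idx = e - 1  # last supra-threshold sample of the train
            break
    if tf_idx is None:
        tf_idx = all_runs[-1][1] - 1

    return MovementEvents(
        t0_ms=t0_idx * 1000.0 / fs,
        tf_ms=tf_idx * 1000.0 / fs,
        threshold=threshold,
        baseline_ms=(float(baseline_ms[0]), float(baseline_ms[1])),
    )


def build_epochs(events: MovementEvents, n_samples: int, fs: float,
                 pre_ms: float = APA_PRE_MS, post_ms: float = APA_POST_MS,
                 cpa_ms: float = CPA_LEN_MS) -> EpochWindows:
    """Build the APA/OPA/CPA windows around detected events.

    Raises :class:`EpochBoundsError` naming the offending epoch when a window
    would extend outside the trial, and rejects degenerate movements where the
    OPA window would be empty (tf <= t0 + post_ms).
    """
    t0, tf = events.t0_ms, events.tf_ms
    duration_ms = n_samples * 1000.0 / fs
    apa = (t0 - pre_ms, t0 + post_ms)
    opa = (t0 + post_ms, tf)
    cpa = (tf, tf + cpa_ms)
    if apa[0] < 0:
        raise EpochBoundsError("APA window starts before the trial (insufficient pre-movement data)")
    if cpa[1] > duration_ms:
        raise EpochBoundsError("CPA window extends past the end of the trial")
    if opa[1] <= opa[0]:
        raise EpochBoundsError("OPA window is empty (movement end too close to onset)")
    return EpochWindows(apa_ms=apa, opa_ms=opa, cpa_ms=cpa, fs_hz=fs)


def events_record(events: MovementEvents, epochs: EpochWindows) -> dict:
    """JSON-serializable per-trial event record."""
    return {
        "t0_ms": events.t0_ms,
        "tf_ms": events.tf_ms,
        "threshold": events.threshold,
        "baseline_ms": list(events.baseline_ms),
        "apa": list(epochs.apa_ms),
        "opa": list(epochs.opa_ms),
        "cpa": list(epochs.cpa_ms),
    }
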