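"""Trial container and plain-text I/O.

A trial is one repetition of the focal task: a uniform 1-kHz time base, one
shoulder-angle channel (degrees) and seven surface-EMG channels, plus the
condition metadata (support height, vision, subject, repetition).  Trials are
stored as TSV with a JSON metadata sidecar so every artifact in the pipeline
is human-readable text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Recording montage, in fixed column order.  AD is the focal mover (anterior
#: deltoid); the remaining six are the postural trunk/leg muscles.
MUSCLES: tuple[str, ...] = ("AD", "LE", "RA", "RF", "BF", "TA", "GL")
POSTURAL_MUSCLES: tuple[str, ...] = MUSCLES[1:]

PHASES: tuple[str, ...] = ("APA", "OPA", "CPA")
HEIGHTS: tuple[str, ...] = ("floor", "elevated")
VISIONS: tuple[str, ...] = ("open", "closed")

#: Agonist/antagonist pairing per joint, agonist first.  These are the only
#: flexor/extensor pairs available in the montage; the R and C indices are
#: invariant under swapping the pair members.
JOINT_PAIRS: dict[str, tuple[str, str]] = {
    "hip": ("RA", "LE"),
    "knee": ("RF", "BF"),
    "ankle": ("TA", "GL"),
}


@dataclass
class TrialRecording:
    """One trial: time base, shoulder angle, and the seven EMG channels.

    ``emg`` maps muscle name -> 1-D array, all the same length as ``time_ms``.
    ``processing_state`` is ``"raw"`` as generated/acquired or ``"processed"``
    after mean removal, rectification and low-pass filtering.
    """

    time_ms: np.ndarray
    angle_deg: np.ndarray
    emg: dict[str, np.ndarray]
    fs_hz: float
    subject: int
    rep: int
    height: str
    vision: str
    processing_state: str = "raw"

    def __post_init__(self) -> None:
        n = self.time_ms.size
        if self.angle_deg.size != n:
            raise ValueError("angle channel length does not match time base")
        for name, ch in self.emg.items():
            if ch.size != n:
                raise ValueError(f"EMG channel {name!r} length does not match time base")
        if self.height not in HEIGHTS:
            raise ValueError(f"unknown height {self.height!r}")
        if self.vision not in VISIONS:
            raise ValueError(f"unknown vision {self.vision!r}")

    @property
    def n_samples(self) -> int:
        return self.time_ms.size

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.fs_hz

    @property
    def condition(self) -> tuple[str, str]:
        return (self.height, self.vision)

    def with_channels(self, angle_deg: np.ndarray, emg: dict[str, np.ndarray],
                      processing_state: str) -> "TrialRecording":
        return replace(self, angle_deg=angle_deg, emg=emg,
                       processing_state=processing_state)

    def trial_id(self) -> str:
        return f"{self.height}_{self.vision}_s{self.subject:02d}_r{self.rep:02d}"


def trial_frame(rec: TrialRecording) -> pd.DataFrame:
    """Tabular view of a trial: time_ms, angle_deg, then one EMG column per muscle."""
    data = {"time_ms": rec.time_ms, "angle_deg": rec.angle_deg}
    for m in MUSCLES:
        data[m] = rec.emg[m]
    return pd.DataFrame(data)


def write_trial(directory: str | Path, rec: TrialRecording,
                overwrite: bool = False) -> Path:
    """Write ``<trial_id>.tsv`` plus ``<trial_id>.json`` sidecar; return the TSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = rec.trial_id()
    tsv = directory / f"{base}.tsv"
    if tsv.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite {tsv} (pass overwrite=True)")
    trial_frame(rec).to_csv(tsv, sep="\t", index=False, float_format="%.8g")
    sidecar = {
        "subject": rec.subject,
        "rep": rec.rep,
        "height": rec.height,
        "vision": rec.vision,
        "fs_hz": rec.fs_hz,
        "processing_state": rec.processing_state,
    }
    (directory / f"{base}.json").write_text(json.dumps(sidecar, indent=1))
    return tsv


def read_trial(tsv_path: str | Path) -> TrialRecording:
    """Read a trial TSV and its JSON sidecar back into a :class:`TrialRecording`."""
    tsv_path = Path(tsv_path)
    meta = json.loads(tsv_path.with_suffix(".json").read_text())
    df = pd.read_csv(tsv_path, sep="\t")
    return TrialRecording(
        time_ms=df["time_ms"].to_numpy(float),
        angle_deg=df["angle_deg"].to_numpy(float),
        emg={m: df[m].to_numpy(float) for m in MUSCLES},
        fs_hz=float(meta["fs_hz"]),
        subject=int(meta["subject"]),
        rep=int(meta["rep"]),
        height=meta["height"],
        vision=meta["vision"],
        processing_state=meta.get("processing_state", "raw"),
    )


def list_trials(directory: str | Path) -> list[Path]:
    """All trial TSVs in a directory, sorted by trial id."""
    return sorted(Path(directory).glob("*_s??_r??.tsv"))
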