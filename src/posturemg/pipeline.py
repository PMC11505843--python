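"""End-to-end orchestration: simulate -> preprocess -> segment -> metrics ->
synergy -> stats, with a single reproducibility seed and a manifest.

Every constant of the analysis (filter cutoffs, epoch offsets, the 0.95
normalization fraction, latency thresholds, the 75% variance threshold) lives
in :class:`PipelineConfig` with the published value as default; overrides are
recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import MUSCLES, PHASES, TrialRecording
from .metrics import compute_activity, compute_joint_indices
from .preprocess import process_trial
from .segmentation import (EpochBoundsError, NoMovementError,
                           angular_acceleration, build_epochs, detect_events,
                           events_record)
from .simulate import GeneratorConfig, generate_dataset, truth_frame, write_dataset
from .stats import anova, correlation_table, tukey_hsd
from .synergy import build_matrix, extract_synergies, min_components, pca

log = logging.getLogger("posturemg")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the full analysis, with published values as defaults."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    emg_lowpass_hz: float = 200.0
    angle_lowpass_hz: float = 20.0
    filter_order: int = 4
    apa_pre_ms: float = 200.0
    apa_post_ms: float = 50.0
    cpa_len_ms: float = 250.0
    norm_fraction: float = 0.95
    max_rms_mode: str = "moving"
    latency_rule: str = "3mu+3sigma"
    detection_k: float = 3.0
    detection_sustain_ms: float = 25.0
    detection_quiet_ms: float = 200.0
    detection_rel_floor: float = 0.05
    detection_baseline_ms: tuple[float, float] = (0.0, 500.0)
    synergy_components: int = 3
    variance_threshold: float = 0.75
    run_stats: bool = True
    write_trials: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        gen = d["generator"]
        gen["conditions"] = [list(c) for c in gen["conditions"]]
        gen["amplitude_table"] = {
            f"{h}/{v}": {p: {m: list(ms) for m, ms in mus.items()}
                         for p, mus in phases.items()}
            for (h, v), phases in self.generator.amplitude_table.items()}
        gen["gain_groups"] = [list(g) for g in gen["gain_groups"]]
        d["detection_baseline_ms"] = list(self.detection_baseline_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = dict(d.pop("generator", {}))
        if "conditions" in gen:
            gen["conditions"] = tuple(tuple(c) for c in gen["conditions"])
        if "amplitude_table" in gen:
            gen["amplitude_table"] = {
                tuple(k.split("/")): {p: {m: tuple(ms) for m, ms in mus.items()}
                                      for p, mus in phases.items()}
                for k, phases in gen["amplitude_table"].items()}
        if "gain_groups" in gen:
            gen["gain_groups"] = tuple(tuple(g) for g in gen["gain_groups"])
        if "detection_baseline_ms" in d:
            d["detection_baseline_ms"] = tuple(d["detection_baseline_ms"])
        return cls(generator=GeneratorConfig(**gen), **d)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from YAML (missing keys take defaults)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


class StageError(RuntimeError):
    """An error in a named pipeline stage (original exception chained)."""

    def __init__(self, stage: str, exc: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")


def _segment_trial(rec: TrialRecording, config: PipelineConfig):
    acc = angular_acceleration(rec.angle_deg, rec.fs_hz)
    events = detect_events(
        acc, rec.fs_hz, baseline_ms=config.detection_baseline_ms,
        k=config.detection_k, sustain_ms=config.detection_sustain_ms,
        quiet_ms=config.detection_quiet_ms, rel_floor=config.detection_rel_floor)
    epochs = build_epochs(events, rec.n_samples, rec.fs_hz,
                          pre_ms=config.apa_pre_ms, post_ms=config.apa_post_ms,
                          cpa_ms=config.cpa_len_ms)
    return events, epochs


def analyze_trials(trials: list[TrialRecording], config: PipelineConfig):
    """Preprocess, segment and measure a list of raw trials.

    Returns (processed, events, epochs, activity, indices, skipped) where
    ``skipped`` lists (trial_id, reason) for trials without usable events.
    """
    processed, all_events, all_epochs, act_frames, skipped = [], [], [], [], []
    for rec in trials:
        proc = process_trial(rec, config.emg_lowpass_hz, config.angle_lowpass_hz,
                             config.filter_order)
        try:
            events, epochs = _segment_trial(proc, config)
        except (NoMovementError, EpochBoundsError) as exc:
            log.warning("skipping trial %s: %s", rec.trial_id(), exc)
            skipped.append((rec.trial_id(), str(exc)))
            continue
        processed.append(proc)
        all_events.append(events)
        all_epochs.append(epochs)
        act_frames.append(compute_activity(
            proc, events, epochs, fraction=config.norm_fraction,
            max_rms_mode=config.max_rms_mode, latency_rule=config.latency_rule))
    if not act_frames:
        raise RuntimeError("no trial produced usable movement events")
    activity = pd.concat(act_frames, ignore_index=True)
    indices = compute_joint_indices(activity)
    return processed, all_events, all_epochs, activity, indices, skipped


def trial_variance_table(processed: list[TrialRecording], epochs_list,
                         threshold: float = 0.75) -> pd.DataFrame:
    """Per-trial, per-phase PC variance fractions and minimum-component count.

    Each trial's epoch (samples x 7 muscles, z-scored within the trial) gets
    its own PCA; this is the trial-level replication used by the variance and
    dimensionality ANOVAs.
    """
    rows = []
    for rec, epochs in zip(processed, epochs_list):
        for phase in PHASES:
            sl = epochs.slice_(phase)
            x = np.column_stack([rec.emg[m][sl] for m in MUSCLES])
            std = x.std(axis=0)
            if (std == 0).any():
                continue
            x = (x - x.mean(axis=0)) / std
            _, fractions = pca(x)
            rows.append({
                "trial_id": rec.trial_id(), "subject": rec.subject, "rep": rec.rep,
                "height": rec.height, "vision": rec.vision, "phase": phase,
                "pc1": fractions[0], "pc2": fractions[1], "pc3": fractions[2],
                "n_components": min_components(fractions, threshold),
            })
    return pd.DataFrame(rows)


def pooled_synergies(processed: list[TrialRecording], epochs_list,
                     config: PipelineConfig):
    """One decomposition per condition x phase, pooled across trials."""
    synergy_rows, variance_rows = [], []
    conditions = sorted({rec.condition for rec in processed})
    for cond in conditions:
        idx = [i for i, rec in enumerate(processed) if rec.condition == cond]
        recs = [processed[i] for i in idx]
        wins = [epochs_list[i] for i in idx]
        for phase in PHASES:
            x = build_matrix(recs, wins, phase)
            dec = extract_synergies(x, config.synergy_components, seed=config.seed)
            for pc, frac in enumerate(dec.pc_variance_fractions, start=1):
                variance_rows.append({"height": cond[0], "vision": cond[1],
                                      "phase": phase, "pc": pc, "fraction": frac})
            for comp in range(dec.n_retained):
                for j, m in enumerate(MUSCLES):
                    synergy_rows.append({
                        "height": cond[0], "vision": cond[1], "phase": phase,
                        "component": comp + 1, "muscle": m,
                        "weight": dec.synergy_weights[j, comp]})
    return pd.DataFrame(synergy_rows), pd.DataFrame(variance_rows)


def run_statistics(activity: pd.DataFrame, indices: pd.DataFrame,
                   trial_var: pd.DataFrame) -> dict:
    """The study's comparison families (a)-(e) plus the correlation analysis."""
    report: dict = {"note": "no multiple-testing correction across families",
                    "alpha": 0.05}
    report["a_intensity"] = anova(activity, "intensity",
                                  ["muscle", "height", "vision", "phase"],
                                  interactions=False)
    report["a_phase_tukey"] = {
        m: tukey_hsd(activity[activity["muscle"] == m], "intensity", "phase")
        .to_dict(orient="records")
        for m in MUSCLES}
    lat = activity.drop_duplicates(["trial_id", "muscle"]).dropna(subset=["latency_ms"])
    report["b_latency_defined_fraction"] = float(
        activity.drop_duplicates(["trial_id", "muscle"])["latency_ms"].notna().mean())
    if lat["muscle"].nunique() >= 2:
        report["b_latency"] = anova(lat, "latency_ms", ["muscle"], interactions=False)
    for name, col in (("c_r_index", "r"), ("c_c_index", "c")):
        report[name] = anova(indices, col, ["joint", "height", "vision", "phase"],
                             interactions=False)
    for pc in ("pc1", "pc2", "pc3"):
        report[f"d_variance_{pc}"] = anova(trial_var, pc,
                                           ["height", "vision", "phase"],
                                           interactions=False)
    report["e_min_components"] = anova(trial_var, "n_components",
                                       ["height", "vision", "phase"],
                                       interactions=False)
    corr = correlation_table(activity)
    report["correlation"] = corr.to_dict(orient="records")
    return report


def _render_report_md(stats_report: dict) -> str:
    lines = ["# Pipeline statistics report", ""]
    for key in ("a_intensity", "b_latency", "c_r_index", "c_c_index",
                "d_variance_pc1", "d_variance_pc2", "d_variance_pc3",
                "e_min_components"):
        if key not in stats_report:
            continue
        lines.append(f"## {key}")
        for term, res in stats_report[key]["terms"].items():
            d1, d2 = res["df"]
            lines.append(f"- {term}: F({d1:.0f}, {d2:.0f}) = {res['F']:.2f}, "
                         f"p = {res['p']:.4g}")
        lines.append("")
    lines.append("## Cross-phase correlations (n = 7 muscles)")
    for row in stats_report.get("correlation", []):
        lines.append(f"- {row['height']}/{row['vision']} "
                     f"{row['phase_a']}-{row['phase_b']}: R^2 = {row['r2']:.2f}, "
                     f"p = {row['p']:.3f}")
    lines.append("")
    lines.append(f"Note: {stats_report.get('note', '')}")
    return "\n".join(lines)


def _hash_outputs(outdir: Path) -> dict[str, str]:
    hashes = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json" and path.suffix in (
                ".tsv", ".json", ".md", ".yaml"):
            hashes[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    return hashes


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 skip_stats: bool = False) -> dict:
    """Run the full pipeline and write all outputs; returns the manifest dict.

    On a stage failure a ``.partial`` marker naming the stage is left in the
    output directory and a :class:`StageError` is raised; outputs written by
    earlier stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partial = outdir / ".partial"
    stage = "simulate"
    try:
        partial.write_text(stage)
        gen = dataclasses.replace(config.generator, seed=config.seed)
        if config.write_trials:
            write_dataset(gen, outdir, overwrite=True)
            trials, truths = generate_dataset(gen)
        else:
            trials, truths = generate_dataset(gen)
            truth_frame(truths).to_csv(outdir / "ground_truth.tsv", sep="\t",
                                       index=False, float_format="%.8g")

        stage = "preprocess/segment/metrics"
        partial.write_text(stage)
        processed, events, epochs, activity, indices, skipped = analyze_trials(
            trials, config)
        evdir = outdir / "events"
        evdir.mkdir(exist_ok=True)
        for rec, ev, ep in zip(processed, events, epochs):
            (evdir / f"{rec.trial_id()}.json").write_text(
                json.dumps(events_record(ev, ep), indent=1))
        activity.to_csv(outdir / "activity.tsv", sep="\t", index=False,
                        float_format="%.8g")
        indices.to_csv(outdir / "indices.tsv", sep="\t", index=False,
                       float_format="%.8g")

        stage = "synergy"
        partial.write_text(stage)
        synergies, variance = pooled_synergies(processed, epochs, config)
        synergies.to_csv(outdir / "synergies.tsv", sep="\t", index=False,
                         float_format="%.8g")
        variance.to_csv(outdir / "variance.tsv", sep="\t", index=False,
                        float_format="%.8g")
        trial_var = trial_variance_table(processed, epochs,
                                         config.variance_threshold)
        trial_var.to_csv(outdir / "trial_variance.tsv", sep="\t", index=False,
                         float_format="%.8g")

        if config.run_stats and not skip_stats:
            stage = "stats"
            partial.write_text(stage)
            report = run_statistics(activity, indices, trial_var)
            (outdir / "stats_report.json").write_text(
                json.dumps(report, indent=1, default=float))
            (outdir / "report.md").write_text(_render_report_md(report))

        stage = "manifest"
        config_dict = config.to_dict()
        config_json = json.dumps(config_dict, sort_keys=True)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "numpy": np.__version__,
            "n_trials": len(trials),
            "n_skipped": len(skipped),
            "skipped": skipped,
            "outputs_sha256": _hash_outputs(outdir),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        partial.unlink(missing_ok=True)
        return manifest
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
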