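"""Generator tests: kinematics, determinism, dataset shape, calibration."""

import numpy as np
import pandas as pd
import pytest

from posturemg.io import MUSCLES, PHASES, POSTURAL_MUSCLES
from posturemg.pipeline import PipelineConfig, analyze_trials
from posturemg.simulate import (GeneratorConfig, flat_amplitude_table,
                                generate_dataset, generate_trial,
                                kinematic_profile, small_config, truth_frame,
                                write_dataset)

FS = 1000.0


class TestKinematicProfile:
    def test_boundary_conditions(self):
        ang = kinematic_profile(1000, 500, 90, FS, 4000)
        assert ang[999] == 0.0
        assert ang[1500] == pytest.approx(90.0)
        assert ang[-1] == pytest.approx(90.0)

    def test_peak_velocity_at_midpoint(self):
        ang = kinematic_profile(1000, 500, 90, FS, 4000)
        vel = np.gradient(ang)
        assert abs(int(np.argmax(vel)) - 1250) <= 1

    def test_movement_past_trial_end_rejected(self):
        with pytest.raises(ValueError):
            kinematic_profile(3800, 500, 90, FS, 4000)
        with pytest.raises(ValueError):
            kinematic_profile(1000, -10, 90, FS, 4000)


class TestGenerateTrial:
    def test_same_seed_bit_identical(self):
        cfg = small_config()
        a, _ = generate_trial(cfg, ("floor", "open"), 1, 1, seed=3)
        b, _ = generate_trial(cfg, ("floor", "open"), 1, 1, seed=3)
        assert np.array_equal(a.angle_deg, b.angle_deg)
        for m in MUSCLES:
            assert np.array_equal(a.emg[m], b.emg[m])

    def test_different_seed_differs(self):
        cfg = small_config()
        a, _ = generate_trial(cfg, ("floor", "open"), 1, 1, seed=3)
        b, _ = generate_trial(cfg, ("floor", "open"), 1, 1, seed=4)
        assert not np.array_equal(a.emg["TA"], b.emg["TA"])

    def test_condition_outside_grid_rejected(self):
        cfg = small_config(conditions=(("floor", "open"),))
        with pytest.raises(ValueError):
            generate_trial(cfg, ("elevated", "closed"), 1, 1)

    def test_unknown_table_keys_rejected_by_name(self):
        bad = flat_amplitude_table(50, 5)
        bad[("floor", "open")]["APA"]["XX"] = (10, 1)
        with pytest.raises(KeyError, match="XX"):
            GeneratorConfig(amplitude_table=bad)
        bad2 = {("floor", "open"): {"NOTAPHASE": {"AD": (10, 1)}}}
        with pytest.raises(KeyError, match="NOTAPHASE"):
            GeneratorConfig(amplitude_table=bad2)

    def test_amplitude_mean_bounds_enforced(self):
        with pytest.raises(ValueError):
            GeneratorConfig(amplitude_table=flat_amplitude_table(120.0, 5))

    def test_ground_truth_invariants(self, analyzed):
        for truth in analyzed["truths"]:
            assert truth.tf_ms > truth.t0_ms
            assert all(v >= 0 for v in truth.programmed.values())


class TestGenerateDataset:
    def test_trial_count_grid(self):
        cfg = small_config(n_subjects=2, n_reps=3)
        trials, truths = generate_dataset(cfg, seed=0)
        assert len(trials) == 2 * 3 * 4
        assert len(truths) == len(trials)

    def test_default_config_shape(self):
        cfg = GeneratorConfig()
        assert cfg.n_trials == 320
        assert cfg.n_subjects * cfg.n_reps == 80
        assert cfg.fs_hz == 1000.0

    def test_write_dataset_files_and_overwrite_guard(self, tmp_path):
        cfg = small_config(n_subjects=1, n_reps=2, conditions=(("floor", "open"),))
        write_dataset(cfg, tmp_path, seed=0)
        tsvs = list((tmp_path / "trials").glob("*.tsv"))
        sidecars = list((tmp_path / "trials").glob("*.json"))
        assert len(tsvs) == 2 and len(sidecars) == 2
        assert (tmp_path / "ground_truth.tsv").exists()
        with pytest.raises(FileExistsError):
            write_dataset(cfg, tmp_path, seed=0)

    def test_truth_table_rows(self):
        cfg = small_config(n_subjects=1, n_reps=1, conditions=(("floor", "open"),))
        _, truths = generate_dataset(cfg, seed=0)
        frame = truth_frame(truths)
        assert len(frame) == len(MUSCLES) * len(PHASES)


class TestCalibration:
    def test_ta_silent_in_apa_loud_in_opa(self, analyzed):
        """TA programmed near the noise floor anticipatorily, large online."""
        act = analyzed["activity"]
        ta = act[(act.muscle == "TA") & (act.height == "floor")]
        assert ta[ta.phase == "APA"]["intensity"].mean() < 5.0
        assert ta[ta.phase == "OPA"]["intensity"].mean() > 60.0

    def test_opa_largest_for_postural_muscles(self, analyzed):
        means = analyzed["activity"].groupby(["muscle", "phase"])["intensity"].mean()
        for m in POSTURAL_MUSCLES:
            assert means[m, "OPA"] > means[m, "APA"]
            assert means[m, "OPA"] > means[m, "CPA"]

    def test_recovered_tracks_programmed(self, analyzed):
        prog = pd.concat([
            pd.DataFrame([{"trial_id": t.trial_id, "muscle": m, "phase": p,
                           "programmed": t.programmed[(m, p)]}
                          for m in MUSCLES for p in PHASES])
            for t in analyzed["truths"]])
        merged = analyzed["activity"].merge(prog, on=["trial_id", "muscle", "phase"])
        dev = (merged.groupby(["muscle", "phase"])
               .apply(lambda g: g.intensity.mean() - g.programmed.mean(),
                      include_groups=False))
        assert dev.abs().max() < 5.0

    def test_latency_recovered_for_early_strong_muscles(self, analyzed):
        # LE bursts ~80 ms before movement onset at ~35 %MAX: detectable.
        act = analyzed["activity"].drop_duplicates(["trial_id", "muscle"])
        truths = {t.trial_id: t for t in analyzed["truths"]}
        le = act[act.muscle == "LE"].dropna(subset=["latency_ms"])
        assert len(le) >= 0.8 * len(truths)
        for _, row in le.iterrows():
            true_lat = truths[row.trial_id].onsets_ms["LE"] - truths[row.trial_id].t0_ms
            assert row.latency_ms >= true_lat - 5.0   # cannot fire early
            assert row.latency_ms <= true_lat + 30.0  # fires on the rising ramp


class TestSharedGain:
    def _cfg(self, gain_sd):
        return small_config(
            n_subjects=3, n_reps=10, conditions=(("floor", "open"),),
            amplitude_table=flat_amplitude_table(50, 5, (("floor", "open"),)),
            shared_gain_sd=gain_sd)

    @staticmethod
    def _phase_corr(act, muscle="LE"):
        piv = act[act.muscle == muscle].pivot_table(
            index="trial_id", columns="phase", values="intensity")
        return float(np.corrcoef(piv["APA"], piv["OPA"])[0, 1])

    def test_zero_gain_programmed_amplitudes_uncorrelated(self):
        # With the gain off, the generator draws phases independently.
        trials, truths = generate_dataset(self._cfg(0.0), seed=21)
        apa = [t.programmed[("LE", "APA")] for t in truths]
        opa = [t.programmed[("LE", "OPA")] for t in truths]
        assert abs(np.corrcoef(apa, opa)[0, 1]) < 0.25

    def test_gain_raises_recovered_cross_phase_correlation(self):
        # Recovered intensities carry a residual within-repetition coupling
        # even at zero gain (all phases share the repetition-maximum
        # denominator); the shared gain must raise the correlation well
        # beyond that floor.
        trials, _ = generate_dataset(self._cfg(0.0), seed=21)
        _, _, _, act0, _, _ = analyze_trials(trials, PipelineConfig())
        trials, _ = generate_dataset(self._cfg(0.3), seed=21)
        _, _, _, act3, _, _ = analyze_trials(trials, PipelineConfig())
        r0 = self._phase_corr(act0)
        r3 = self._phase_corr(act3)
        assert r3 > 0.75
        assert r3 > r0 + 0.2
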