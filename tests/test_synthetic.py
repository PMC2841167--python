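"""Synthetic data generator: determinism, scanpath statistics, sample
round trips through the parser, and experiment design counts."""

import numpy as np
import pytest

from oculomap.events import parse_events
from oculomap.spotlight import DEFAULT_LAYOUT
from oculomap.synthetic import (
    NOSE_PROFILE,
    WC_PROFILE,
    ExperimentDesign,
    ObserverProfile,
    make_face_image,
    plan_to_events,
    sample_scanpath,
    simulate_experiment,
    synthesize_trial_samples,
)


class TestDeterminism:
    def test_face_image_reproducible(self):
        assert np.array_equal(make_face_image(seed=42), make_face_image(seed=42))

    def test_scanpath_reproducible(self):
        p1 = sample_scanpath(WC_PROFILE, seed=42)
        p2 = sample_scanpath(WC_PROFILE, seed=42)
        assert [(s.kind, s.duration_ms, s.x0, s.y0) for s in p1.steps] == [
            (s.kind, s.duration_ms, s.x0, s.y0) for s in p2.steps
        ]

    def test_samples_reproducible(self):
        plan = sample_scanpath(WC_PROFILE, duration_ms=1000, seed=1)
        r1 = synthesize_trial_samples(plan, seed=9)
        r2 = synthesize_trial_samples(plan, seed=9)
        assert np.array_equal(r1.x, r2.x) and np.array_equal(r1.pupil, r2.pupil,
                                                             equal_nan=True)

    def test_experiment_reproducible(self):
        design = ExperimentDesign(n_learn=2, n_recog=4, blocks_per_race=1)
        cohorts = {"a": (2, WC_PROFILE), "b": (2, NOSE_PROFILE)}
        e1 = simulate_experiment(design, cohorts, 8.0, seed=5)
        e2 = simulate_experiment(design, cohorts, 8.0, seed=5)
        assert e1.trials.equals(e2.trials)


class TestFaceImages:
    def test_gray_level_range(self):
        img = make_face_image(seed=0)
        assert img.min() >= 1.0 and img.max() <= 256.0

    def test_landmarks_darker_than_surrounding_oval(self):
        img = make_face_image(seed=3)
        for lm in DEFAULT_LAYOUT.values():
            surround = img[int(lm.y) - 45:int(lm.y) + 45, int(lm.x) - 45:int(lm.x) + 45]
            assert img[int(lm.y), int(lm.x)] < np.median(surround)


class TestScanpaths:
    def test_degenerate_profile_fixates_single_landmark(self):
        prof = ObserverProfile(landmark_weights={"nose": 1.0}, spread_deg=1e-9)
        plan = sample_scanpath(prof, seed=0)
        nose = DEFAULT_LAYOUT["nose"]
        for s in plan.steps:
            if s.kind == "fixation":
                assert np.hypot(s.x0 - nose.x, s.y0 - nose.y) < 1e-3

    def test_eye_time_fraction_of_default_profile(self):
        """Eye-landmark fixation time matches the mixture expectation."""
        def eye_frac(plan):
            tot = eye = 0.0
            for s in plan.steps:
                if s.kind != "fixation":
                    continue
                tot += s.duration_ms
                d = {k: np.hypot(s.x0 - lm.x, s.y0 - lm.y)
                     for k, lm in DEFAULT_LAYOUT.items()}
                if min(d, key=d.get) in ("left_eye", "right_eye"):
                    eye += s.duration_ms
            return eye / tot

        fr = np.mean([eye_frac(sample_scanpath(WC_PROFILE, seed=i)) for i in range(150)])
        assert 0.60 <= fr <= 0.80

    def test_fixations_per_ten_seconds(self):
        counts = [len(plan_to_events(sample_scanpath(WC_PROFILE, seed=i)).fixations)
                  for i in range(150)]
        assert 20 <= np.mean(counts) <= 35

    def test_plan_spans_requested_duration(self):
        plan = sample_scanpath(WC_PROFILE, duration_ms=4000, seed=2)
        assert plan.duration_ms == pytest.approx(4000.0)


class TestSampleRoundTrip:
    def test_single_fixation_plan(self):
        from oculomap.synthetic import ScanPlan, ScanStep

        plan = ScanPlan([ScanStep("fixation", 500, 100, 100, 100, 100)])
        seq = parse_events(synthesize_trial_samples(plan, seed=0))
        assert [e.kind for e in seq] == ["fixation"]
        assert len(seq.saccades) == 0

    def test_planted_blink_recovered(self):
        from oculomap.synthetic import ScanPlan, ScanStep

        plan = ScanPlan([
            ScanStep("fixation", 300, 100, 100, 100, 100),
            ScanStep("blink", 50, 100, 100, 100, 100),
            ScanStep("fixation", 300, 100, 100, 100, 100),
        ])
        seq = parse_events(synthesize_trial_samples(plan, seed=0))
        assert len(seq.blinks) == 1

    def test_fixation_count_and_centroids_recovered(self):
        """Planted plans with detectable saccades and >= 60 ms fixations
        come back from the parser with the exact fixation count and
        centroids within 0.2 deg, in at least 95% of trials."""
        good = total = 0
        for i in range(120):
            plan = sample_scanpath(WC_PROFILE, duration_ms=3000, seed=i)
            truth = plan_to_events(plan)
            if any(f.duration < 60 for f in truth.fixations):
                continue
            amps = [np.hypot(s.x1 - s.x0, s.y1 - s.y0) / 25.0
                    for s in plan.steps if s.kind == "saccade"]
            if amps and min(amps) < 0.25:  # sub-resolution corrective saccades
                continue
            seq = parse_events(synthesize_trial_samples(plan, noise_deg=0.05,
                                                        seed=1000 + i))
            total += 1
            tf, rf = truth.fixations, seq.fixations
            if len(tf) == len(rf) and max(
                np.hypot(a.x - b.x, a.y - b.y) / 25.0 for a, b in zip(tf, rf)
            ) <= 0.2:
                good += 1
        assert total >= 50
        assert good / total >= 0.95

    def test_saccade_peak_velocity_exceeds_three_thresholds(self):
        """Rendered saccades of >= 1 deg reach >= 90 deg/s peak velocity."""
        from oculomap.events import compute_kinematics
        from oculomap.synthetic import ScanPlan, ScanStep, _saccade_duration_ms

        for amp_deg in (1.0, 3.0, 8.0):
            d = _saccade_duration_ms(amp_deg)
            plan = ScanPlan([
                ScanStep("fixation", 200, 100, 100, 100, 100),
                ScanStep("saccade", d, 100, 100, 100 + amp_deg * 25, 100),
                ScanStep("fixation", 200, 100 + amp_deg * 25, 100,
                         100 + amp_deg * 25, 100),
            ])
            rec = synthesize_trial_samples(plan, noise_deg=0.0, seed=0)
            vel, _ = compute_kinematics(rec)
            assert np.nanmax(vel) >= 3 * 30.0


class TestExperiment:
    def test_recognition_block_counts(self):
        design = ExperimentDesign()
        cohorts = {"a": (2, WC_PROFILE)}
        exp = simulate_experiment(design, cohorts, 8.0, seed=0)
        rec = exp.trials[(exp.trials.phase == "recognition")]
        per_block = rec.groupby(["observer", "race", "block"])
        for _, sub in per_block:
            assert len(sub) == 28
            assert sub.is_old.sum() == 14

    def test_design_invariant_rejects_mismatched_counts(self):
        with pytest.raises(ValueError):
            ExperimentDesign(n_learn=14, n_recog=20)

    def test_chance_accuracy_in_2deg_condition(self):
        design = ExperimentDesign()
        cohorts = {"a": (5, WC_PROFILE), "b": (5, WC_PROFILE)}
        exp = simulate_experiment(design, cohorts, 2.0, seed=1)
        rec = exp.trials[exp.trials.phase == "recognition"]
        assert rec.correct.mean() == pytest.approx(0.50, abs=0.05)

    def test_accuracy_and_rt_monotone_in_aperture(self):
        design = ExperimentDesign(n_learn=7, n_recog=14, blocks_per_race=1)
        cohorts = {"a": (4, WC_PROFILE)}
        accs, rts = [], []
        for ap in (2.0, 5.0, 8.0):
            exp = simulate_experiment(design, cohorts, ap, seed=2)
            rec = exp.trials[exp.trials.phase == "recognition"]
            accs.append(rec.correct.mean())
            rts.append(rec.rt_ms.mean())
        assert accs[0] < accs[1] < accs[2]
        assert rts[0] > rts[1] > rts[2]
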