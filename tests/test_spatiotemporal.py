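"""Step locations, step length/width, cadence, walking speed, and the 2-8 m
measurement window."""
import dataclasses

import numpy as np
import pytest

from fesgait import events, spatiotemporal as sp, synthetic
from fesgait.core import SIDES, GaitEventSet, TrajectoryTrial


def _loc(side, ap, ml, t0, t1=None):
    return sp.StepLocation(side=side, ap_cm=ap, ml_cm=ml,
                           interval=(t0, t1 if t1 is not None else t0 + 0.4))


def _spine_trial(x, fs=30.0):
    n = x.size
    t = np.arange(n) / fs
    zero = np.zeros(n)
    spine = np.column_stack([x, zero, np.ones(n)])
    return TrajectoryTrial(
        time=t, points={"spine_base": spine, "ankle_L": spine.copy(),
                        "ankle_R": spine.copy()},
        sampling_rate=fs,
    )


class TestStepLocations:
    def test_stationary_ankle_median(self):
        fs = 30.0
        n = 60
        t = np.arange(n) / fs
        ankle = np.column_stack([np.full(n, 3.0), np.full(n, 0.05),
                                 np.zeros(n)])
        spine = np.column_stack([t, np.zeros(n), np.ones(n)])
        trial = TrajectoryTrial(
            time=t,
            points={"spine_base": spine, "ankle_R": ankle,
                    "ankle_L": ankle + np.array([0.3, 0.1, 0.0])},
            sampling_rate=fs,
        )
        ev = GaitEventSet(
            contacts={"right": np.array([0.0, 1.5]),
                      "left": np.array([0.75])},
            offs={"right": np.array([1.0]),
                  "left": np.array([0.3, 1.7])},
        )
        locs = sp.step_locations(trial, ev)
        right = [l for l in locs if l.side == "right"]
        assert right[0].ap_cm == pytest.approx(300.0)
        assert right[0].ml_cm == pytest.approx(5.0)

    def test_median_robust_to_outlier(self):
        assert np.median([299.0, 300.0, 320.0]) == 300.0  # the rule in use
        # and through the pipeline: one outlier sample does not move the
        # location because it is a per-interval median
        fs = 30.0
        n = 90
        t = np.arange(n) / fs
        x = np.full(n, 3.0)
        x[40] = 3.2  # single-sample glitch inside the support window
        ankle = np.column_stack([x, np.zeros(n), np.zeros(n)])
        spine = np.column_stack([t * 0.5, np.zeros(n), np.ones(n)])
        trial = TrajectoryTrial(
            time=t, points={"spine_base": spine, "ankle_R": ankle,
                            "ankle_L": ankle}, sampling_rate=fs,
        )
        ev = GaitEventSet(
            contacts={"right": np.array([0.5, 2.5]), "left": np.array([1.8])},
            offs={"right": np.array([2.0]), "left": np.array([1.0, 2.8])},
        )
        loc = [l for l in sp.step_locations(trial, ev) if l.side == "right"][0]
        assert loc.ap_cm == pytest.approx(300.0)

    def test_zero_noise_locations_match_constructed_footfalls(
        self, noiseless_trial
    ):
        locs = sp.step_locations(noiseless_trial.trajectories,
                                 noiseless_trial.events_truth)
        truth = noiseless_trial.truth["footfalls"]
        for side in SIDES:
            want = truth[side]
            got = [l for l in locs if l.side == side]
            assert len(got) >= len(want) - 1
            for l in got:
                best = min(want, key=lambda w: abs(w["t_start"] - l.interval[0]))
                assert l.ap_cm == pytest.approx(best["ap_cm"], abs=0.5)
                assert l.ml_cm == pytest.approx(best["ml_cm"], abs=0.5)


class TestStepLengthWidth:
    def test_arithmetic(self):
        locs = [_loc("left", 200.0, 10.0, 0.0), _loc("right", 250.0, -5.0, 0.6)]
        steps = sp.step_length_width(locs)
        assert steps[0]["length_cm"] == pytest.approx(50.0)
        assert steps[0]["width_cm"] == pytest.approx(15.0)

    def test_identical_locations_give_zero(self):
        locs = [_loc("left", 200.0, 10.0, 0.0), _loc("right", 200.0, 10.0, 0.6)]
        steps = sp.step_length_width(locs)
        assert steps[0]["length_cm"] == 0.0
        assert steps[0]["width_cm"] == 0.0

    def test_same_side_pair_skipped(self, caplog):
        locs = [_loc("left", 200.0, 10.0, 0.0), _loc("left", 220.0, 10.0, 0.6),
                _loc("right", 260.0, -5.0, 1.2)]
        steps = sp.step_length_width(locs)
        assert len(steps) == 1
        assert steps[0]["length_cm"] == pytest.approx(40.0)

    def test_backward_step_flagged_not_clamped(self):
        locs = [_loc("left", 200.0, 10.0, 0.0), _loc("right", 190.0, -5.0, 0.6)]
        steps = sp.step_length_width(locs)
        assert steps[0]["length_cm"] == pytest.approx(-10.0)
        assert steps[0]["backward"]

    def test_asymmetry_recovered(self):
        """Profile with +10 cm right-minus-left asymmetry: right steps ~55 cm,
        left ~45 cm, over several seeds."""
        right_means, left_means = [], []
        for seed in range(6):
            p = synthetic.GaitProfile(
                walking_speed=1.0, step_length_mean=50.0, cadence=120.0,
                step_length_asymmetry=10.0, stance_fraction=0.65,
                noise_sd_trajectory=0.3, seed=seed,
            )
            trial, _, _ = synthetic.generate_trajectories(p)
            est = events.detect_events(trial)
            steps = sp.step_length_width(sp.step_locations(trial, est))
            right_means.append(np.mean([s["length_cm"] for s in steps
                                        if s["side"] == "right"]))
            left_means.append(np.mean([s["length_cm"] for s in steps
                                       if s["side"] == "left"]))
        assert np.mean(right_means) == pytest.approx(55.0, abs=2.0)
        assert np.mean(left_means) == pytest.approx(45.0, abs=2.0)


class TestCadence:
    def test_eleven_contacts_over_six_seconds(self):
        ev = GaitEventSet(
            contacts={"right": np.arange(0.0, 6.1, 1.2),
                      "left": np.arange(0.6, 6.1, 1.2)},
            offs={"right": np.arange(0.7, 6.0, 1.2),
                  "left": np.arange(1.3, 6.0, 1.2)},
        )
        assert ev.pooled_contacts().size == 11
        assert sp.cadence(ev) == pytest.approx(100.0)

    def test_two_contacts_one_second_apart(self):
        ev = GaitEventSet(contacts={"right": np.array([0.0]),
                                    "left": np.array([1.0])},
                          offs={"right": np.array([0.6]), "left": np.array([])})
        assert sp.cadence(ev) == pytest.approx(60.0)

    def test_fewer_than_two_contacts_raises(self):
        ev = GaitEventSet(contacts={"right": np.array([0.0]),
                                    "left": np.array([])},
                          offs={"right": np.array([]), "left": np.array([])})
        with pytest.raises(ValueError, match="at least two"):
            sp.cadence(ev)

    def test_synthetic_cadence_recovered(self, noiseless_trial):
        assert sp.cadence(noiseless_trial.events_truth) == pytest.approx(
            noiseless_trial.profile.cadence, abs=2.0
        )


class TestWalkingSpeed:
    def test_constant_speed(self):
        trial = _spine_trial(np.arange(330) / 30.0)  # 1 m/s for 11 s
        assert sp.walking_speed(trial) == pytest.approx(1.0)

    def test_window_excludes_slow_segment(self):
        fs = 30.0
        t = np.arange(0, 12, 1 / fs)
        x = np.where(t < 4.0, 0.5 * t, 2.0 + (t - 4.0) * 1.0)  # 2 m at t=4
        trial = _spine_trial(x)
        assert sp.walking_speed(trial) == pytest.approx(1.0)

    def test_not_traversed_raises(self):
        trial = _spine_trial(np.linspace(0.0, 5.0, 200))
        with pytest.raises(ValueError, match="not fully traversed"):
            sp.walking_speed(trial)

    def test_synthetic_speed_within_tolerance(self, recovery_trials):
        for profile, trial, _, _ in recovery_trials[:10]:
            assert sp.walking_speed(trial) == pytest.approx(
                profile.walking_speed, abs=0.02
            )


class TestSummary:
    def test_diff_of_identical_summaries_is_zero(self, noiseless_trial):
        est = events.detect_events(noiseless_trial.trajectories)
        s = sp.summarize(noiseless_trial.trajectories, est)
        d = sp.diff_summaries(s, s)
        assert all(v == 0.0 for v in d.values())

    def test_diff_tracks_speed_change(self):
        def summary(speed, cadence):
            p = synthetic.GaitProfile(
                walking_speed=speed, cadence=cadence,
                step_length_mean=speed * 6000 / cadence,
                noise_sd_trajectory=0.0, seed=4,
            )
            trial, _, _ = synthetic.generate_trajectories(p)
            return sp.summarize(trial, events.detect_events(trial))

        d = sp.diff_summaries(summary(0.6, 95.0), summary(0.5, 90.0))
        assert d["walking_speed_ms"] == pytest.approx(0.1, abs=0.01)

    def test_parameter_recovery_bias(self, recovery_trials):
        """Bias of each spatiotemporal estimate < 5% of the profile value."""
        rel = {k: [] for k in ("length", "width", "cadence", "speed")}
        for profile, trial, _, _ in recovery_trials:
            est = events.detect_events(trial)
            s = sp.summarize(trial, est)
            rel["length"].append(
                (s.step_length_mean_cm - profile.step_length_mean)
                / profile.step_length_mean)
            rel["width"].append(
                (s.step_width_mean_cm - profile.step_width_mean)
                / profile.step_width_mean)
            rel["cadence"].append(
                (s.cadence_spm - profile.cadence) / profile.cadence)
            rel["speed"].append(
                (s.walking_speed_ms - profile.walking_speed)
                / profile.walking_speed)
        for k, v in rel.items():
            assert abs(np.mean(v)) < 0.05, k

    def test_internal_consistency_speed_vs_step_rate(self, recovery_trials):
        for profile, trial, _, _ in recovery_trials[:10]:
            s = sp.summarize(trial, events.detect_events(trial))
            implied = s.step_length_mean_cm / 100.0 * s.cadence_spm / 60.0
            assert implied == pytest.approx(s.walking_speed_ms, rel=0.10)

    def test_samples_outside_window_do_not_change_summary(self,
                                                          noiseless_profile):
        """Extending the recording beyond the 8 m line leaves the windowed
        summary unchanged."""
        p = dataclasses.replace(noiseless_profile, walkway_length=10.0)
        trial, _, _ = synthetic.generate_trajectories(p)
        longer, _, _ = synthetic.generate_trajectories(
            dataclasses.replace(p, walkway_length=12.0)
        )
        s1 = sp.summarize(trial, events.detect_events(trial))
        s2 = sp.summarize(longer, events.detect_events(longer))
        assert s2.walking_speed_ms == pytest.approx(s1.walking_speed_ms,
                                                    abs=1e-6)
        assert s2.cadence_spm == pytest.approx(s1.cadence_spm, abs=1e-6)
        assert s2.step_length_mean_cm == pytest.approx(
            s1.step_length_mean_cm, abs=1e-6)
        assert s2.n_steps == s1.n_steps
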