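"""Synthetic experiment generator: design, behaviour, EEG, on-disk dialect."""

import numpy as np
import pandas as pd
import pytest

import reachadapt as ra
from reachadapt import timefreq
from reachadapt.synthgen import DatasetFormatError, EVENT_LABELS


class TestDesign:
    def test_full_study_has_2880_trial_slots(self, full_design):
        assert len(full_design.trials) == 2880

    def test_single_subject_has_360_slots(self):
        d = ra.make_design(1, seed=1)
        assert len(d.trials) == 360
        assert set(d.trials.task) == {"visual", "memory"}

    def test_each_task_has_180_trials_in_6_blocks_of_30(self, full_design):
        sub = full_design.trials[
            (full_design.trials.subject == "S01") & (full_design.trials.task == "visual")
        ]
        assert len(sub) == 180
        assert sub.groupby("block_index").size().tolist() == [30] * 6

    def test_seeded_determinism(self):
        d1 = ra.make_design(8, seed=1)
        d2 = ra.make_design(8, seed=1)
        pd.testing.assert_frame_equal(d1.trials, d2.trials)

    def test_target_angles_uniform_range(self, full_design):
        ang = full_design.trials.target_angle_deg
        assert ang.min() >= -10.0 and ang.max() <= 10.0
        assert abs(ang.mean()) < 0.5

    def test_rotation_zero_outside_adaptation(self, full_design):
        t = full_design.trials
        assert (t.loc[t.block_role != "adaptation", "rotation_deg"] == 0.0).all()

    def test_nonpositive_subject_count_rejected(self):
        with pytest.raises(ValueError):
            ra.make_design(0, seed=1)


class TestBehavior:
    def test_errorfree_learner_reaches_straight(self):
        d = ra.make_design(2, seed=3, trials_per_block=5, rotation_increment=0.0)
        learner = ra.LearnerParams(motor_noise_sd=0.0, x1=0.0)
        trials, _ = ra.simulate_behavior(d, learner, inject_outliers=0)
        assert np.allclose(trials.hand_angle_true_deg, 0.0)

    def test_noiseless_angles_satisfy_state_space_recursion(self):
        d = ra.make_design(1, seed=3)
        learner = ra.LearnerParams(A_true=0.9, B_true=0.25, motor_noise_sd=0.0)
        trials, _ = ra.simulate_behavior(d, learner, inject_outliers=0)
        sub = trials[trials.task == "visual"].sort_values("trial_overall")
        x = sub.hand_angle_true_deg.to_numpy()
        r = sub.rotation_deg.to_numpy()
        assert np.allclose(x[1:], 0.9 * x[:-1] + 0.25 * (r[:-1] - x[:-1]), atol=1e-12)

    def test_task_reaction_time_contrast(self, full_behavior):
        trials, _ = full_behavior
        m = trials.groupby("task")["rt_true_s"].mean()
        assert m["memory"] - m["visual"] == pytest.approx(0.10, abs=0.01)

    def test_trajectories_sampled_at_60hz_reaching_80mm(self, full_behavior):
        trials, traj = full_behavior
        one = traj[(traj.subject == "S01") & (traj.task == "visual") & (traj.trial_overall == 7)]
        dt = np.diff(one.t_s.to_numpy())
        assert np.allclose(dt, 1.0 / 60.0, atol=1e-9)
        assert np.hypot(one.x_mm, one.y_mm).max() >= 80.0

    def test_event_ordering_within_trial(self, full_behavior):
        trials, _ = full_behavior
        assert (trials.t_go_s >= trials.t_target_on_s).all()
        assert (trials.t_reach_onset_s > trials.t_go_s).all()
        assert (trials.t_feedback_s > trials.t_reach_onset_s).all()

    def test_memory_task_delays_the_go_signal(self, full_behavior):
        trials, _ = full_behavior
        gap = trials.t_go_s - trials.t_target_on_s
        assert np.allclose(gap[trials.task == "visual"], 0.0)
        assert np.allclose(gap[trials.task == "memory"], 2.2)

    def test_seeded_determinism(self):
        d = ra.make_design(2, seed=5, trials_per_block=3)
        t1, tr1 = ra.simulate_behavior(d)
        t2, tr2 = ra.simulate_behavior(d)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(tr1, tr2)


@pytest.fixture(scope="module")
def small_eeg():
    d = ra.make_design(2, seed=7, trials_per_block=2)
    trials, _ = ra.simulate_behavior(d, inject_outliers=0)
    params = ra.EEGParams(channels=("Fz", "C3", "P3", "Pz", "P4"), fs=500.0)
    return d, trials, params, ra.simulate_eeg(d, trials, params)


class TestEEG:
    def test_one_recording_per_subject_and_task(self, small_eeg):
        d, _, _, recs = small_eeg
        assert len(recs) == d.n_subjects * 2

    def test_four_markers_per_trial(self, small_eeg):
        d, _, _, recs = small_eeg
        for rec in recs.values():
            assert len(rec.markers) == 4 * d.n_trials_per_task
            assert set(rec.markers.label) == set(EVENT_LABELS)

    def test_every_event_has_epoch_margin(self, small_eeg):
        _, _, _, recs = small_eeg
        for rec in recs.values():
            s = rec.markers["sample"]
            assert (s >= 2 * rec.fs).all()
            assert (s <= rec.data.shape[1] - 2 * rec.fs).all()

    def test_effect_channels_must_exist(self):
        with pytest.raises(ValueError):
            ra.EEGParams(channels=("Fz", "C3"))  # default effects need parietal rows

    def test_seeded_determinism(self, small_eeg):
        d, trials, params, recs = small_eeg
        again = ra.simulate_eeg(d, trials, params)
        key = ("S01", "visual")
        assert np.array_equal(recs[key].data, again[key].data)
        pd.testing.assert_frame_equal(recs[key].markers, again[key].markers)

    def test_configured_db_difference_is_recovered(self):
        # Pipeline round trip: +3 dB parietal delta after feedback.
        diffs = []
        for seed in (11, 12, 13, 14):
            d = ra.make_design(4, seed=seed, trials_per_block=5)
            trials, _ = ra.simulate_behavior(d, inject_outliers=0)
            params = ra.EEGParams(channels=("P3", "Pz", "P4"), effects=(
                ra.EEGEffect(band=(1.0, 4.0), channels=("P3", "Pz", "P4"),
                             align="feedback", window=(0.0, 1.0), db_difference=3.0),
            ))
            recs = ra.simulate_eeg(d, trials, params)
            per_task = {"visual": [], "memory": []}
            for (_, task), rec in recs.items():
                rec = timefreq.preprocess_raw(rec)
                ep = timefreq.epoch_by_event(rec, "feedback")
                db = timefreq.db_normalize(timefreq.morlet_tfr(ep))
                bp = timefreq.band_average(
                    db, electrode_groups={"parietal": ("P3", "Pz", "P4")}
                )
                sel = bp[(bp.band == "delta") & (bp.time_ms >= 0) & (bp.time_ms <= 1000)]
                per_task[task].append(sel["value"].mean())
            diffs.append(np.mean(per_task["visual"]) - np.mean(per_task["memory"]))
        assert np.mean(diffs) == pytest.approx(3.0, abs=0.5)


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    d = ra.make_design(2, seed=9, trials_per_block=2)
    trials, traj = ra.simulate_behavior(d, inject_outliers=0)
    params = ra.EEGParams(channels=("Fz", "C3", "P3", "Pz", "P4"))
    recs = ra.simulate_eeg(d, trials, params)
    out = tmp_path_factory.mktemp("ds")
    ra.write_dataset(out, trials, traj, recs)
    return out, trials, traj, recs


class TestDatasetRoundTrip:
    def test_tables_round_trip_exactly(self, dataset):
        out, trials, traj, _ = dataset
        trials2, traj2, _ = ra.read_dataset(out, load_eeg=False)
        pd.testing.assert_frame_equal(trials, trials2, check_exact=True)
        pd.testing.assert_frame_equal(traj, traj2, check_exact=True)

    def test_signals_round_trip_to_float32(self, dataset):
        out, _, _, recs = dataset
        _, _, recs2 = ra.read_dataset(out)
        key = ("S02", "memory")
        assert recs2[key].channels == recs[key].channels
        assert np.allclose(recs2[key].data, recs[key].data, atol=1e-4)
        pd.testing.assert_frame_equal(recs2[key].markers, recs[key].markers)

    def test_file_inventory(self, dataset):
        out, *_ = dataset
        assert (out / "trials.csv").exists()
        assert (out / "events.csv").exists()
        # one signal + sidecar pair per subject x task
        assert len(list((out / "eeg").glob("*.f32"))) == 4
        assert len(list((out / "eeg").glob("*.sidecar.txt"))) == 4

    def test_corrupt_marker_row_names_the_line(self, dataset, tmp_path):
        out, *_ = dataset
        import shutil

        dst = tmp_path / "corrupt"
        shutil.copytree(out, dst)
        sidecar = sorted((dst / "eeg").glob("*.sidecar.txt"))[0]
        lines = sidecar.read_text().splitlines()
        lines[10] = "feedback,not_a_number"
        sidecar.write_text("\n".join(lines) + "\n")
        with pytest.raises(DatasetFormatError, match=r"sidecar\.txt:11"):
            ra.read_dataset(dst)

    def test_truncated_signal_file_detected(self, dataset, tmp_path):
        out, *_ = dataset
        import shutil

        dst = tmp_path / "trunc"
        shutil.copytree(out, dst)
        f32 = sorted((dst / "eeg").glob("*.f32"))[0]
        f32.write_bytes(f32.read_bytes()[:-100])
        with pytest.raises(DatasetFormatError, match="truncated"):
            ra.read_dataset(dst)
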