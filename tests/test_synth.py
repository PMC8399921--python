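"""Generator self-consistency: determinism, cadence closure, fatigue hooks."""

import numpy as np
import pytest

import fieldfatigue as ff
from fieldfatigue.labelling import cadence_from_zero_crossings, classify_activity
from fieldfatigue.prep import baseline_correct_ecg
from fieldfatigue.synth import count_r_peaks, synth_ecg, synth_gait_accel


def test_session_is_deterministic_under_fixed_seed():
    cfg = ff.ProtocolConfig(n_laps=1, seed=11)
    a = ff.generate_session(cfg)
    b = ff.generate_session(ff.ProtocolConfig(n_laps=1, seed=11))
    assert a.accel.tobytes() == b.accel.tobytes()
    assert a.ecg.tobytes() == b.ecg.tobytes()
    assert a.gps.equals(b.gps)
    assert a.test_scores.equals(b.test_scores)


def test_two_lap_schedule_has_two_seated_blocks():
    cfg = ff.ProtocolConfig(n_laps=2, seed=7)
    s = ff.generate_session(cfg)
    sit = (s.truth["activity"] == "sit").to_numpy()
    n_blocks = int(np.sum(np.diff(sit.astype(int)) == 1) + sit[0])
    assert n_blocks == 2
    assert 3600 < s.duration_s < 9000  # two self-paced hourly cycles


def test_default_trajectory_monotone_and_bounded():
    cfg = ff.ProtocolConfig(n_laps=3, seed=0)
    s = ff.generate_session(cfg)
    f = s.truth["fatigue"].to_numpy()
    assert f[-1] >= f[0]
    assert s.trajectory.is_monotone
    assert np.all((f >= 0) & (f <= 1))


def test_stream_lengths_match_rates():
    cfg = ff.ProtocolConfig(n_laps=1, seed=5)
    s = ff.generate_session(cfg)
    assert abs(s.accel.shape[0] - s.duration_s * 100) <= 1
    assert abs(s.ecg.shape[0] - s.duration_s * 250) <= 1
    assert len(s.gps) == s.duration_s


@pytest.mark.parametrize("activity,surface,cadence", [
    ("run", "dirt", 160.0),
    ("walk", "tarseal", 110.0),
    ("run", "boulders", 170.0),
])
def test_gait_cadence_closure(activity, surface, cadence):
    x = synth_gait_accel(activity, surface, cadence, 0.0, 60.0, rng=2)
    est = cadence_from_zero_crossings(x[:, 0], 100.0)
    mid = est[5:-5]
    assert np.all(np.abs(mid - cadence) <= 2.0)
    expected = "walk" if 100 < cadence < 150 else "run"
    assert all(classify_activity(c) == expected for c in mid)


def test_peak_amplitude_strictly_decreases_with_fatigue():
    fresh = synth_gait_accel("run", "dirt", 160.0, 0.0, 30.0, rng=4)[:, 0]
    tired = synth_gait_accel("run", "dirt", 160.0, 0.9, 30.0, rng=4)[:, 0]
    # same seed -> same step layout; compare mean per-step peaks
    step = int(round(100 * 60 / 160))
    n = (len(fresh) // step) * step
    pf = fresh[:n].reshape(-1, step).max(axis=1)
    pt = tired[:n].reshape(-1, step).max(axis=1)
    assert pt.mean() < pf.mean()
    assert np.mean(pt < pf) > 0.95


def test_gait_input_validation():
    with pytest.raises(ValueError):
        synth_gait_accel("run", "dirt", 40.0, 0.0, 10.0, rng=0)
    with pytest.raises(ValueError):
        synth_gait_accel("run", "lava", 120.0, 0.0, 10.0, rng=0)
    with pytest.raises(ValueError):
        synth_gait_accel("obstacle", "dirt", 120.0, 0.0, 10.0, rng=0)


def test_ecg_rate_self_consistency():
    ecg = synth_ecg(60.0, 60.0, rng=1)
    corrected = baseline_correct_ecg(ecg)
    assert abs(count_r_peaks(corrected) - 60) <= 1


def test_ecg_without_wander_is_nearly_untouched_by_correction():
    ecg = synth_ecg(70.0, 30.0, rng=0, wander_amp_mv=0.0, noise_sd_mv=0.0)
    corrected = baseline_correct_ecg(ecg)
    qrs_ptp = np.ptp(ecg)
    assert np.max(np.abs(corrected - ecg)) <= 0.1 * qrs_ptp


def test_ecg_validation_and_determinism():
    with pytest.raises(ValueError):
        synth_ecg(250.0, 10.0, rng=0)
    a = synth_ecg(80.0, 10.0, rng=9)
    b = synth_ecg(80.0, 10.0, rng=9)
    assert np.array_equal(a, b)


def test_noiseless_scores_are_affine_in_fatigue():
    traj = ff.FatigueTrajectory.linear(7200.0, 0.0, 0.6)
    sched = [(600.0 * i, "post_physical") for i in range(1, 12)]
    table = ff.synth_test_scores(traj, sched, rng=0, noise_scale=0.0)
    series = ff.TestSeries.from_table(table, "ftt_dominant")
    assert ff.sensitivity_r2(series) == pytest.approx(1.0)


def test_empty_test_schedule_rejected():
    traj = ff.FatigueTrajectory.linear(100.0)
    with pytest.raises(ValueError):
        ff.synth_test_scores(traj, [], rng=0)


def test_trajectory_validation():
    with pytest.raises(ValueError):
        ff.FatigueTrajectory(t=[0, 1], f=[0.0, 1.5])
    with pytest.raises(ValueError):
        ff.generate_session(
            ff.ProtocolConfig(n_laps=2, seed=0),
            trajectory=ff.FatigueTrajectory.linear(100.0),  # too short
        )
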