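"""Generator properties: determinism, planted effects, artifact injection."""

import numpy as np
import pytest
from scipy import signal as sig
from scipy import stats

from gaitstab.io_formats import EEGRecording
from gaitstab.synth import (ArtifactSpec, SessionConfig, channel_groups,
                            default_band_effects, generate_session,
                            inject_artifacts)


def band_power(x, fs, band):
    f, p = sig.welch(x, fs=fs, nperseg=int(4 * fs))
    m = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(p[m], f[m]))


def test_identical_seed_and_config_give_bit_identical_sessions(small_config):
    a = generate_session(small_config, "STROOP", 1)
    b = generate_session(small_config, "STROOP", 1)
    assert np.array_equal(a.eeg.data, b.eeg.data)
    assert np.array_equal(a.heel_z_right.values, b.heel_z_right.values)
    assert np.array_equal(a.grf_left.values, b.grf_left.values)
    assert np.array_equal(a.true_events["right"], b.true_events["right"])


def test_rejects_invalid_configuration():
    with pytest.raises(ValueError):
        SessionConfig(trial_duration=-1.0)
    with pytest.raises(ValueError):
        SessionConfig(sampling_rate_eeg=0.0)
    effects = default_band_effects()
    effects["NW"]["beta"] = -0.5
    with pytest.raises(ValueError):
        SessionConfig(band_effects=effects)


def test_event_structure(small_session, small_config):
    for side in ("right", "left"):
        ev = small_session.true_events[side]
        gaps = np.diff(ev)
        assert np.all(gaps > 0)
        sd = small_config.stride_cv_stable * small_config.stride_mean
        assert np.all(np.abs(gaps - small_config.stride_mean) < 5 * sd)
    n = small_session.eeg.n_samples
    assert n == int(small_config.trial_duration
                    * small_config.sampling_rate_eeg)


def test_heel_minima_at_true_events(small_config):
    """Noiseless heel height has its local minima on the event times."""
    cfg = SessionConfig(**{**small_config.__dict__, "heel_noise_mm": 0.0})
    s = generate_session(cfg, "NW", 1)
    dt = 1.0 / cfg.sampling_rate_mocap
    h = s.heel_z_right.values
    for ev in s.true_events["right"]:
        i = int(round(ev * cfg.sampling_rate_mocap))
        lo, hi = max(i - 15, 0), min(i + 16, len(h))
        assert abs(s.heel_z_right.time[lo + np.argmin(h[lo:hi])] - ev) <= dt


def test_grf_zero_in_swing_and_rising_at_heel_strike(small_session):
    grf = small_session.grf_right
    fs = grf.sampling_rate
    for ev in small_session.true_events["right"][1:-1]:
        i = int(round(ev * fs))
        # shortly before the strike the foot is in swing (near zero force)
        assert np.all(grf.values[i - 10:i - 2] < 20.0)
        # shortly after, force is far above threshold
        assert grf.values[i + 10] > 100.0


def test_null_band_effects_equalize_beta_power():
    """With all band factors 1, beta power is equal across conditions."""
    effects = {c: {"alpha": 1.0, "beta": 1.0, "theta": 1.0}
               for c in ("NW", "STROOP", "COM", "MLP")}
    p_nw, p_mlp = [], []
    for seed in range(20):
        cfg = SessionConfig(trial_duration=30.0, sampling_rate_eeg=250.0,
                            n_channels=16, band_effects=effects, seed=seed)
        for cond, store in (("NW", p_nw), ("MLP", p_mlp)):
            s = generate_session(cfg, cond, 0)
            cz = s.eeg.channel_labels.index("Cz")
            store.append(band_power(s.eeg.data[cz], 250.0, (12, 30)))
    assert stats.ttest_ind(p_nw, p_mlp).pvalue > 0.01


def test_planted_beta_factor_recovered_by_welch():
    """Default unstable beta factor 0.7 shows up as a ~0.7 power ratio."""
    ratios = []
    for seed in range(10):
        cfg = SessionConfig(trial_duration=60.0, sampling_rate_eeg=500.0,
                            n_channels=64, seed=seed)
        nw = generate_session(cfg, "NW", 0)
        mlp = generate_session(cfg, "MLP", 0)
        cz = nw.eeg.channel_labels.index("Cz")
        ratios.append(band_power(mlp.eeg.data[cz], 500.0, (12, 30))
                      / band_power(nw.eeg.data[cz], 500.0, (12, 30)))
    assert abs(np.mean(ratios) - 0.7) < 0.1


def test_inject_artifacts_zero_rates_is_identity(small_session):
    spec = ArtifactSpec()
    out = inject_artifacts(small_session.eeg, spec, seed=0)
    assert np.array_equal(out.data, small_session.eeg.data)


def test_inject_artifacts_does_not_modify_input(small_session):
    before = small_session.eeg.data.copy()
    inject_artifacts(small_session.eeg,
                     ArtifactSpec(blink_rate=0.5, line_amplitude=10.0),
                     seed=1)
    assert np.array_equal(small_session.eeg.data, before)


def test_line_noise_power_increment_matches_analytic_value():
    """Adding a sinusoid of amplitude a raises total power by a^2/2."""
    fs, dur, a = 250.0, 60.0, 8.0
    rec = EEGRecording(np.zeros((4, int(fs * dur))), fs,
                       ["Fp1", "Cz", "Pz", "Oz"])
    out = inject_artifacts(rec, ArtifactSpec(line_amplitude=a), seed=2)
    for ch in range(4):
        f, p = sig.welch(out.data[ch], fs=fs, nperseg=int(4 * fs))
        m = (f >= 55) & (f <= 65)
        power = np.trapezoid(p[m], f[m])
        assert abs(power - a**2 / 2) / (a**2 / 2) < 0.05


def test_blink_count_is_poisson_with_expected_rate():
    """0.2 blinks/s over 300 s gives 60 +- 15 recorded blink events."""
    fs = 100.0
    rec = EEGRecording(np.zeros((2, int(fs * 300))), fs, ["Fp1", "Fp2"])
    out = inject_artifacts(rec, ArtifactSpec(blink_rate=0.2), seed=3)
    n = len(out.metadata["artifacts"]["blink_times"])
    assert 45 <= n <= 75


def test_blink_timestamps_match_waveform_peaks():
    fs = 250.0
    rec = EEGRecording(np.zeros((2, int(fs * 120))), fs, ["Fp1", "Oz"])
    out = inject_artifacts(rec, ArtifactSpec(blink_rate=0.1), seed=4)
    for bt in out.metadata["artifacts"]["blink_times"]:
        i0 = int(bt * fs)
        window = out.data[0, i0:i0 + int(0.3 * fs)]
        assert window.max() > 100.0  # frontal amplitude present
    assert np.abs(out.data[1]).max() == 0.0  # occipital untouched


def test_channel_groups_cover_expected_montage_regions():
    from gaitstab.synth import CHANNEL_LABELS_64
    groups = channel_groups(CHANNEL_LABELS_64)
    assert CHANNEL_LABELS_64.index("Cz") in groups["sensorimotor"]
    assert CHANNEL_LABELS_64.index("Oz") in groups["posterior"]
    assert CHANNEL_LABELS_64.index("Fz") in groups["frontal_midline"]
    assert len(set(CHANNEL_LABELS_64)) == 64
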