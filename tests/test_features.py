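"""Feature correctness against brute-force oracles, plus invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from gaitstab.features import (FEATURE_NAMES, FeatureConfig,
                               build_feature_vector, entropy_features,
                               extract_features, hjorth, max_wavelet_level,
                               time_domain_features, wavelet_energies,
                               wavelet_features)
from gaitstab.segmentation import NormalizedCycle


def test_time_domain_trivial_examples():
    const = time_domain_features(np.full(10, -2.5))
    assert const["mad"] == 0 and const["variance"] == 0 and const["aac"] == 0
    assert const["rms"] == pytest.approx(2.5)

    x = np.array([1.0, 2.0, 3.0])
    td = time_domain_features(x)
    assert td["mean"] == pytest.approx(2.0)
    assert td["mad"] == pytest.approx(2.0 / 3.0)
    assert td["rms"] == pytest.approx(np.sqrt(14.0 / 3.0))


def test_gaussian_moments(rng):
    x = rng.standard_normal(100_000)
    td = time_domain_features(x)
    assert abs(td["skewness"]) < 0.1
    assert abs(td["kurtosis"] - 3.0) < 0.1


def test_hjorth_activity_is_variance(rng):
    x = rng.standard_normal(500)
    act, _, _ = hjorth(x)
    assert act == pytest.approx(np.var(x), rel=1e-12)


def test_hjorth_sinusoid_complexity_is_one():
    t = np.arange(4000) / 1000.0
    _, _, comp = hjorth(np.sin(2 * np.pi * 5.0 * t))
    assert comp == pytest.approx(1.0, rel=0.01)


def test_hjorth_matches_bruteforce_on_white_noise(rng):
    x = rng.standard_normal(100_000)
    mine = hjorth(x)
    ref = oracles.hjorth(list(x))
    for m, r in zip(mine, ref):
        assert m == pytest.approx(r, rel=1e-12)


def test_shannon_entropy_degenerate_and_uniform():
    assert entropy_features(np.full(50, 1.0))["shannon_entropy"] == 0.0
    x = np.repeat(np.arange(16.0), 10) + 0.0001
    assert entropy_features(x)["shannon_entropy"] == pytest.approx(
        np.log(16.0), rel=1e-9)


def test_threshold_entropy_hand_count():
    out = entropy_features(np.array([0.1, 0.5, 0.9]), eps=0.4)
    assert out["threshold_entropy"] == 2.0


def test_wavelet_zero_signal_and_parseval(rng):
    zero = wavelet_features(np.zeros(1024))
    assert all(v == 0.0 for v in zero.values())
    x = rng.standard_normal(1100) * 30
    energies, approx = wavelet_energies(x, levels=8)
    total = energies.sum() + approx
    assert abs(total - np.sum(x**2)) / np.sum(x**2) < 1e-6


def test_wavelet_high_band_sinusoid_concentrates_in_d1():
    t = np.arange(1024) / 1000.0
    x = np.sin(2 * np.pi * 250.0 * t)
    energies, _ = wavelet_energies(x, levels=8)
    assert energies[0] / energies.sum() >= 0.8


def test_wavelet_infeasible_level_names_max():
    with pytest.raises(ValueError, match="max feasible level is 5"):
        wavelet_features(np.ones(100), levels=8)
    assert max_wavelet_level(1100) == 8


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_all_features_match_bruteforce_oracles(seed):
    """Normalized-trace features on 100 samples, wavelet/Hjorth on the
    raw-rate slice, each against an independently coded oracle."""
    r = np.random.default_rng(seed)
    x = r.standard_normal(100) * r.uniform(0.5, 40)
    td = time_domain_features(x)
    assert td["mad"] == pytest.approx(oracles.mad(list(x)), rel=1e-10)
    assert td["rms"] == pytest.approx(oracles.rms(list(x)), rel=1e-10)
    assert td["variance"] == pytest.approx(oracles.variance(list(x)), rel=1e-10)
    assert td["skewness"] == pytest.approx(oracles.skewness(list(x)), rel=1e-9)
    assert td["kurtosis"] == pytest.approx(oracles.kurtosis(list(x)), rel=1e-9)
    assert td["aac"] == pytest.approx(oracles.aac(list(x)), rel=1e-10)
    assert td["max"] == x.max() and td["min"] == x.min()
    assert td["mean"] == pytest.approx(np.mean(x), rel=1e-12)

    eps = 0.2 * float(np.std(x))
    ent = entropy_features(x)
    assert ent["shannon_entropy"] == pytest.approx(
        oracles.shannon_entropy(list(x)), rel=1e-10)
    assert ent["log_entropy"] == pytest.approx(
        oracles.log_entropy(list(x)), rel=1e-10)
    assert ent["threshold_entropy"] == oracles.threshold_entropy(list(x), eps)
    assert ent["sure_entropy"] == pytest.approx(
        oracles.sure_entropy(list(x), eps), rel=1e-10)
    assert ent["norm_entropy"] == pytest.approx(
        oracles.norm_entropy(list(x), 1.5), rel=1e-10)

    raw = r.standard_normal(1100) * 20
    act, mob, comp = hjorth(raw)
    oact, omob, ocomp = oracles.hjorth(list(raw))
    assert act == pytest.approx(oact, rel=1e-10)
    assert mob == pytest.approx(omob, rel=1e-10)
    assert comp == pytest.approx(ocomp, rel=1e-10)

    wf = wavelet_features(raw, levels=8)
    oe, _ = oracles.dwt_detail_energies(raw, 8)
    for i, e in enumerate(oe):
        assert wf[f"wavelet_energy_d{i + 1}"] == pytest.approx(e, rel=1e-10)
    sd = np.std(np.array(oe))
    assert wf["wavelet_energy_sd"] == pytest.approx(sd, rel=1e-10)


@settings(max_examples=15, deadline=None)
@given(st.integers(0, 2**31 - 1),
       st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
def test_scale_and_shift_equivariance(seed, a, c):
    r = np.random.default_rng(seed)
    x = r.standard_normal(400)
    base = time_domain_features(x)
    scaled = time_domain_features(a * x)
    assert scaled["rms"] == pytest.approx(a * base["rms"], rel=1e-9)
    assert scaled["mad"] == pytest.approx(a * base["mad"], rel=1e-9)
    assert scaled["variance"] == pytest.approx(a**2 * base["variance"],
                                               rel=1e-9)
    shifted = time_domain_features(x + c)
    assert shifted["variance"] == pytest.approx(base["variance"], rel=1e-6)
    assert shifted["mad"] == pytest.approx(base["mad"], rel=1e-6)

    _, mob0, comp0 = hjorth(x)
    _, mob1, comp1 = hjorth(a * x + c)
    assert mob1 == pytest.approx(mob0, rel=1e-7)
    assert comp1 == pytest.approx(comp0, rel=1e-7)

    e0, _ = wavelet_energies(x, levels=5)
    e1, _ = wavelet_energies(a * x, levels=5)
    sd_ratio = np.std(e1) / np.std(e0)
    assert sd_ratio == pytest.approx(a**2, rel=1e-7)


def _toy_cycle(rng, n_ch=3, fs=1000.0, dur=1.1):
    m = int(dur * fs)
    raw = rng.standard_normal((n_ch, m)) * 15
    pos = np.arange(100) * m / 100.0
    j = pos.astype(int)
    normalized = raw[:, j]
    return NormalizedCycle(raw=raw, normalized=normalized,
                           cycle_span=(0.0, dur), sampling_rate=fs,
                           channel_labels=["Cz", "C3", "C3x"][:n_ch],
                           subject=0, condition="NW", cycle_index=0)


def test_build_feature_vector_count_and_structure(rng):
    cyc = _toy_cycle(rng)
    vec = build_feature_vector(cyc)
    assert len(vec.values) == 3 * 29
    assert all(np.isfinite(v) for v in vec.values.values())
    assert f"Cz__mad" in vec.values


def test_identical_channels_get_identical_feature_blocks(rng):
    cyc = _toy_cycle(rng)
    cyc.raw[1] = cyc.raw[0]
    cyc.normalized[1] = cyc.normalized[0]
    vec = build_feature_vector(cyc)
    for feat in FEATURE_NAMES:
        assert vec.values[f"Cz__{feat}"] == vec.values[f"C3__{feat}"]


def test_channel_renaming_permutes_names_not_values(rng):
    cyc = _toy_cycle(rng)
    vec1 = build_feature_vector(cyc)
    cyc.channel_labels = ["A", "B", "C"]
    vec2 = build_feature_vector(cyc)
    for feat in FEATURE_NAMES:
        assert vec2.values[f"A__{feat}"] == vec1.values[f"Cz__{feat}"]


def test_extract_features_table_shape_and_vector_agreement(rng):
    cycles = [_toy_cycle(rng) for _ in range(4)]
    for i, c in enumerate(cycles):
        c.cycle_index = i
    table = extract_features(cycles)
    assert table.values.shape == (4, 3 * 29)
    vec = build_feature_vector(cycles[0])
    row = table.frame.iloc[0]
    for name, value in vec.values.items():
        assert row[name] == pytest.approx(value, rel=1e-12, abs=1e-12)


def test_nonfinite_cycle_rejected(rng):
    cyc = _toy_cycle(rng)
    cyc.normalized[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        build_feature_vector(cyc)
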