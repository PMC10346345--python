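"""Per-channel digital biomarkers computed on every gait cycle.

29 features per channel:

* 9 time-domain descriptors of the 0-100% normalized trace — mean absolute
  deviation (MAD), RMS, max, min, mean, population variance, skewness,
  kurtosis (standardized central moments, Gaussian kurtosis = 3) and
  average amplitude change (AAC);
* 6 Hjorth parameters — activity (variance), mobility (SD ratio of the
  first difference to the signal) and complexity (mobility ratio of the
  first difference to the signal), each on the alpha- (8-12 Hz) and
  beta- (12-30 Hz) band-filtered raw-rate cycle slice;
* 5 entropies of the normalized trace — Shannon (16-bin histogram,
  natural log), log-energy, threshold, SURE and norm entropy;
* 9 wavelet features of the raw-rate slice — Daubechies-2 detail-band
  energies d1..d8 and the standard deviation of those detail energies.

Feature vectors concatenate all channels in a stable
``<channel>__<feature>`` name order; 64 channels give 29 x 64 = 1856
features per cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal

from .io_formats import FeatureTable
from .segmentation import NormalizedCycle
from .synth import BANDS

__all__ = [
    "FeatureVector",
    "FeatureConfig",
    "FEATURE_NAMES",
    "time_domain_features",
    "hjorth",
    "entropy_features",
    "wavelet_features",
    "wavelet_energies",
    "max_wavelet_level",
    "build_feature_vector",
    "extract_features",
]

TIME_DOMAIN_NAMES = ("mad", "rms", "max", "min", "mean", "variance",
                     "skewness", "kurtosis", "aac")
HJORTH_NAMES = ("activity_alpha", "mobility_alpha", "complexity_alpha",
                "activity_beta", "mobility_beta", "complexity_beta")
ENTROPY_NAMES = ("shannon_entropy", "log_entropy", "threshold_entropy",
                 "sure_entropy", "norm_entropy")


def _wavelet_names(levels: int) -> tuple[str, ...]:
    return tuple(f"wavelet_energy_d{i}" for i in range(1, levels + 1)) + (
        "wavelet_energy_sd",)


FEATURE_NAMES = TIME_DOMAIN_NAMES + HJORTH_NAMES + ENTROPY_NAMES + _wavelet_names(8)


@dataclass
class FeatureConfig:
    """Tunable feature parameters."""

    wavelet: str = "db2"
    wavelet_levels: int = 8
    entropy_bins: int = 16
    entropy_eps_k: float = 0.2   # threshold/SURE epsilon = eps_k * SD(x)
    entropy_p: float = 1.5       # norm-entropy exponent
    alpha_band: tuple[float, float] = BANDS["alpha"]
    beta_band: tuple[float, float] = BANDS["beta"]

    @property
    def names(self) -> tuple[str, ...]:
        return (TIME_DOMAIN_NAMES + HJORTH_NAMES + ENTROPY_NAMES
                + _wavelet_names(self.wavelet_levels))


@dataclass
class FeatureVector:
    """Named per-cycle feature values, ``<channel>__<feature>`` keyed."""

    values: dict[str, float]
    subject: int | str | None = None
    condition: str | None = None
    cycle_index: int = 0


def _check_input(x: np.ndarray, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or len(x) < min_len:
        raise ValueError(f"need a 1-D signal of length >= {min_len}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    return x


def time_domain_features(x: np.ndarray) -> dict[str, float]:
    """MAD, RMS, max, min, mean, variance, skewness, kurtosis, AAC."""
    x = _check_input(x, 2)
    n = len(x)
    m = float(np.mean(x))
    dev = x - m
    m2 = float(np.mean(dev**2))
    if m2 > 0:
        skew = float(np.mean(dev**3) / m2**1.5)
        kurt = float(np.mean(dev**4) / m2**2)
    else:
        warnings.warn("zero-variance signal: skewness/kurtosis degenerate, "
                      "reported as 0", RuntimeWarning)
        skew = kurt = 0.0
    return {
        "mad": float(np.mean(np.abs(dev))),
        "rms": float(np.sqrt(np.mean(x**2))),
        "max": float(np.max(x)),
        "min": float(np.min(x)),
        "mean": m,
        "variance": m2,
        "skewness": skew,
        "kurtosis": kurt,
        "aac": float(np.sum(np.abs(np.diff(x))) / (n - 1)),
    }


def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility, complexity of a (band-filtered) signal.

    Derivatives are unscaled first differences (each order shortens the
    signal by one sample); variances use divisor n.
    """
    x = _check_input(x, 3)
    d1 = np.diff(x)
    d2 = np.diff(d1)
    v0, v1, v2 = (float(np.var(a)) for a in (x, d1, d2))
    if v0 == 0 or v1 == 0:
        warnings.warn("zero-variance signal: Hjorth mobility/complexity "
                      "degenerate, reported as 0", RuntimeWarning)
        return v0, 0.0, 0.0
    mobility = float(np.sqrt(v1 / v0))
    mobility_d = float(np.sqrt(v2 / v1))
    return v0, mobility, mobility_d / mobility


def entropy_features(x: np.ndarray, eps: float | None = None,
                     n_bins: int = 16, eps_k: float = 0.2,
                     p: float = 1.5) -> dict[str, float]:
    """Shannon (histogram), log-energy, threshold, SURE and norm entropy.

    Shannon entropy uses a ``n_bins``-bin histogram over [min, max] with
    natural log and 0*log0 := 0.  The wavelet-family entropies act on the
    raw samples: log-energy = sum log(x_i^2) (zero samples contribute 0),
    threshold = #{|x_i| > eps}, SURE = n - #{|x_i| <= eps} + sum
    min(x_i^2, eps^2), norm = sum |x_i|^p.  Default eps is
    ``eps_k * SD(x)``.
    """
    x = _check_input(x, 2)
    n = len(x)
    if eps is None:
        eps = eps_k * float(np.std(x))
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi > lo:
        counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
        probs = counts[counts > 0] / n
        shannon = float(-np.sum(probs * np.log(probs)))
    else:
        shannon = 0.0
    nonzero = x[x != 0.0]
    log_energy = float(np.sum(np.log(nonzero**2))) if len(nonzero) else 0.0
    n_small = int(np.sum(np.abs(x) <= eps))
    return {
        "shannon_entropy": shannon,
        "log_entropy": log_energy,
        "threshold_entropy": float(np.sum(np.abs(x) > eps)),
        "sure_entropy": float(n - n_small + np.sum(np.minimum(x**2, eps**2))),
        "norm_entropy": float(np.sum(np.abs(x) ** p)),
    }


def max_wavelet_level(n: int) -> int:
    """Deepest feasible Daubechies-2 decomposition for an n-sample signal."""
    if n < 4:
        return 0
    return int(np.floor(np.log2(n / 3.0)))


def wavelet_energies(x: np.ndarray, wavelet: str = "db2",
                     levels: int = 8) -> tuple[np.ndarray, float]:
    """Detail-band energies (d1..dL) and approximation energy.

    The signal is zero-padded to the next multiple of 2**levels and
    decomposed in periodization mode, which keeps the transform exactly
    orthogonal at every level; the energies therefore satisfy Parseval's
    identity: sum(detail energies) + approximation energy = sum(x^2).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    feasible = max_wavelet_level(n)
    if levels > feasible:
        raise ValueError(
            f"decomposition level {levels} infeasible for {n} samples; "
            f"max feasible level is {feasible}")
    block = 2 ** levels
    padded = -(-n // block) * block
    if padded != n:
        pad_width = [(0, 0)] * (x.ndim - 1) + [(0, padded - n)]
        x = np.pad(x, pad_width)
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=levels,
                          axis=-1)
    # coeffs = [aL, dL, ..., d1]; report in d1..dL order
    details = coeffs[:0:-1]
    energies = np.stack([np.sum(d**2, axis=-1) for d in details], axis=-1)
    approx = np.sum(coeffs[0] ** 2, axis=-1)
    return energies, approx


def wavelet_features(x_raw: np.ndarray, wavelet: str = "db2",
                     levels: int = 8) -> dict[str, float]:
    """Detail energies d1..dL plus their standard deviation (divisor L)."""
    x_raw = _check_input(x_raw, 4)
    energies, _ = wavelet_energies(x_raw, wavelet, levels)
    out = {f"wavelet_energy_d{i + 1}": float(e) for i, e in enumerate(energies)}
    out["wavelet_energy_sd"] = float(np.std(energies))
    return out


def _bandfilter(data: np.ndarray, band: tuple[float, float],
                fs: float) -> np.ndarray:
    sos = signal.butter(4, list(band), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def _channel_features(normalized: np.ndarray, raw: np.ndarray, fs: float,
                      cfg: FeatureConfig) -> np.ndarray:
    """All 29 features for every channel; vectorized over channels.

    ``normalized``: (channels, n) 0-100% traces; ``raw``: (channels, m)
    native-rate slices.  Returns (channels, 29).
    """
    if not (np.all(np.isfinite(normalized)) and np.all(np.isfinite(raw))):
        raise ValueError("cycle contains non-finite samples")
    n_ch, n = normalized.shape
    cols: list[np.ndarray] = []

    x = normalized
    m = x.mean(axis=1, keepdims=True)
    dev = x - m
    m2 = np.mean(dev**2, axis=1)
    degenerate = m2 == 0
    if np.any(degenerate):
        warnings.warn(f"{int(degenerate.sum())} zero-variance channel(s): "
                      "higher moments reported as 0", RuntimeWarning)
    safe_m2 = np.where(degenerate, 1.0, m2)
    cols += [
        np.mean(np.abs(dev), axis=1),                      # mad
        np.sqrt(np.mean(x**2, axis=1)),                    # rms
        x.max(axis=1), x.min(axis=1), m[:, 0], m2,         # max min mean var
        np.where(degenerate, 0.0, np.mean(dev**3, axis=1) / safe_m2**1.5),
        np.where(degenerate, 0.0, np.mean(dev**4, axis=1) / safe_m2**2),
        np.sum(np.abs(np.diff(x, axis=1)), axis=1) / (n - 1),  # aac
    ]

    for band in (cfg.alpha_band, cfg.beta_band):
        y = _bandfilter(raw, band, fs)
        d1 = np.diff(y, axis=1)
        d2 = np.diff(d1, axis=1)
        v0, v1, v2 = (np.var(a, axis=1) for a in (y, d1, d2))
        bad = (v0 == 0) | (v1 == 0)
        v0s, v1s = np.where(v0 == 0, 1.0, v0), np.where(v1 == 0, 1.0, v1)
        mob = np.sqrt(v1 / v0s)
        comp = np.sqrt(v2 / v1s) / np.where(mob == 0, 1.0, mob)
        cols += [v0, np.where(bad, 0.0, mob), np.where(bad, 0.0, comp)]

    # entropies on the normalized trace
    lo, hi = x.min(axis=1, keepdims=True), x.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    bin_idx = np.clip(((x - lo) / span * cfg.entropy_bins).astype(int),
                      0, cfg.entropy_bins - 1)
    counts = np.zeros((n_ch, cfg.entropy_bins))
    np.add.at(counts, (np.repeat(np.arange(n_ch), n), bin_idx.ravel()), 1.0)
    probs = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log(probs), 0.0)
    shannon = np.where((hi > lo)[:, 0], -plogp.sum(axis=1), 0.0)
    eps = cfg.entropy_eps_k * np.std(x, axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        logx2 = np.where(x != 0.0, np.log(np.where(x != 0.0, x**2, 1.0)), 0.0)
    small = np.abs(x) <= eps
    cols += [
        shannon,
        logx2.sum(axis=1),
        np.sum(~small, axis=1).astype(float),
        n - small.sum(axis=1) + np.sum(np.minimum(x**2, eps**2), axis=1),
        np.sum(np.abs(x) ** cfg.entropy_p, axis=1),
    ]

    energies, _ = wavelet_energies(raw, cfg.wavelet, cfg.wavelet_levels)
    cols += [energies[:, i] for i in range(cfg.wavelet_levels)]
    cols += [np.std(energies, axis=1)]

    return np.column_stack(cols)


def build_feature_vector(cycle: NormalizedCycle,
                         cfg: FeatureConfig | None = None) -> FeatureVector:
    """The full per-cycle feature vector, channels concatenated."""
    cfg = cfg or FeatureConfig()
    mat = _channel_features(cycle.normalized, cycle.raw, cycle.sampling_rate,
                            cfg)
    names = cfg.names
    values = {
        f"{ch}__{feat}": float(mat[i, j])
        for i, ch in enumerate(cycle.channel_labels)
        for j, feat in enumerate(names)
    }
    return FeatureVector(values=values, subject=cycle.subject,
                         condition=cycle.condition,
                         cycle_index=cycle.cycle_index)


def extract_features(cycles: list[NormalizedCycle],
                     cfg: FeatureConfig | None = None) -> FeatureTable:
    """Feature table over a list of cycles (one row per cycle)."""
    cfg = cfg or FeatureConfig()
    if not cycles:
        raise ValueError("no cycles to extract features from")
    labels = cycles[0].channel_labels
    names = cfg.names
    columns = [f"{ch}__{feat}" for ch in labels for feat in names]
    rows = np.empty((len(cycles), len(columns)))
    meta = {"subject": [], "condition": [], "cycle_index": []}
    for r, cyc in enumerate(cycles):
        if cyc.channel_labels != labels:
            raise ValueError("cycles have inconsistent channel labels")
        mat = _channel_features(cyc.normalized, cyc.raw, cyc.sampling_rate, cfg)
        rows[r] = mat.ravel()
        meta["subject"].append(cyc.subject)
        meta["condition"].append(cyc.condition)
        meta["cycle_index"].append(cyc.cycle_index)
    frame = pd.DataFrame(meta)
    frame = pd.concat([frame, pd.DataFrame(rows, columns=columns)], axis=1)
    return FeatureTable(frame)
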