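"""Synthetic treadmill-walking sessions: EEG + heel markers + GRF.

The generator emulates the statistical structure the downstream analysis
assumes: 64-channel EEG built from a 1/f background plus gait-phase-locked
band oscillations (posterior alpha, sensorimotor beta, frontal-midline
theta), heel-marker trajectories whose local minima fall exactly on the
ground-truth heel-strike times, double-peaked vertical GRF stance curves
rising sharply at each heel strike, and injectable blink / line-noise /
EMG artifacts with retained ground-truth time stamps.

Unstable conditions (Stroop dual task, medio-lateral perturbation) plant a
sensorimotor beta power reduction and a frontal-midline theta increase
relative to the stable conditions (normal walking, COM visual feedback),
which is the condition effect every later stage must recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .io_formats import (
    EEGRecording,
    MotionSeries,
    read_brainvision,
    read_timeseries_csv,
    ColumnSpec,
    write_brainvision,
    write_timeseries_tsv,
)

__all__ = [
    "CONDITIONS",
    "STABLE_CONDITIONS",
    "UNSTABLE_CONDITIONS",
    "CHANNEL_LABELS_64",
    "ArtifactSpec",
    "SessionConfig",
    "SyntheticSession",
    "channel_groups",
    "generate_session",
    "inject_artifacts",
    "save_session",
    "load_session",
]

CONDITIONS = ("NW", "STROOP", "COM", "MLP")
STABLE_CONDITIONS = frozenset({"NW", "COM"})
UNSTABLE_CONDITIONS = frozenset({"STROOP", "MLP"})

# Standard 64-electrode 10-20 montage (actiCAP-64 ordering).
CHANNEL_LABELS_64 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6", "FT9", "FT7", "FC3",
    "FC4", "FT8", "FT10", "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4",
    "TP8", "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
]

_POSTERIOR = {
    "O1", "Oz", "O2", "PO9", "PO10", "PO7", "PO3", "POz", "PO4", "PO8",
    "P7", "P3", "Pz", "P4", "P8", "P5", "P1", "P2", "P6",
}
_SENSORIMOTOR = {
    "C3", "Cz", "C4", "C5", "C1", "C2", "C6",
    "CP5", "CP1", "CP2", "CP6", "CP3", "CPz", "CP4",
}
_FRONTAL_MIDLINE = {"Fz", "F1", "F2", "FC1", "FC2"}
_FRONTAL_BLINK = {"Fp1": 1.0, "Fp2": 1.0, "AF7": 0.6, "AF3": 0.6, "AF4": 0.6,
                  "AF8": 0.6, "F7": 0.25, "F8": 0.25}
_TEMPORAL_LEFT = {"FT9": 0.4, "FT7": 0.8, "T7": 1.0, "TP7": 0.8, "TP9": 0.4}
_TEMPORAL_RIGHT = {"FT10": 0.4, "FT8": 0.8, "T8": 1.0, "TP8": 0.8, "TP10": 0.4}

BANDS = {"theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (12.0, 30.0)}


def channel_groups(labels: list[str]) -> dict[str, np.ndarray]:
    """Index arrays of the functional channel groups present in ``labels``."""
    def idx(names) -> np.ndarray:
        return np.array([i for i, l in enumerate(labels) if l in names], dtype=int)

    return {
        "posterior": idx(_POSTERIOR),
        "sensorimotor": idx(_SENSORIMOTOR),
        "frontal_midline": idx(_FRONTAL_MIDLINE),
        "frontal": idx(_FRONTAL_BLINK),
        "temporal_left": idx(_TEMPORAL_LEFT),
        "temporal_right": idx(_TEMPORAL_RIGHT),
    }


def _weight_vector(labels: list[str], weights: dict[str, float]) -> np.ndarray:
    return np.array([weights.get(l, 0.0) for l in labels])


def default_band_effects() -> dict[str, dict[str, float]]:
    """Per-condition multiplicative band-power factors.

    Unstable conditions reduce sensorimotor beta (x0.7) and raise
    frontal-midline theta (x1.3); stable conditions are the baseline.
    """
    effects = {}
    for cond in CONDITIONS:
        if cond in UNSTABLE_CONDITIONS:
            effects[cond] = {"alpha": 1.0, "beta": 0.7, "theta": 1.3}
        else:
            effects[cond] = {"alpha": 1.0, "beta": 1.0, "theta": 1.0}
    return effects


@dataclass
class ArtifactSpec:
    """Rates and amplitudes of the injectable artifacts (all off by default)."""

    blink_rate: float = 0.0          # blinks per second
    blink_amplitude: float = 150.0   # µV at the most frontal channels
    blink_duration: float = 0.3      # seconds
    line_amplitude: float = 0.0      # µV (zero-to-peak)
    line_freq: float = 60.0          # Hz
    emg_rate: float = 0.0            # bursts per second per side
    emg_amplitude: float = 30.0      # µV RMS at the dominant temporal channel

    def __post_init__(self) -> None:
        for name in ("blink_rate", "line_amplitude", "emg_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def any_active(self) -> bool:
        return self.blink_rate > 0 or self.line_amplitude > 0 or self.emg_rate > 0


@dataclass
class SessionConfig:
    """Study conditions for one synthetic walking cohort."""

    n_subjects: int = 13
    trial_duration: float = 300.0       # seconds
    sampling_rate_eeg: float = 1000.0   # Hz
    sampling_rate_mocap: float = 100.0  # Hz
    n_channels: int = 64
    stride_mean: float = 1.10           # seconds
    stride_cv_stable: float = 0.03
    stride_cv_unstable: float = 0.07
    band_effects: dict = field(default_factory=default_band_effects)
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    modulation_depth: float = 0.2       # gait-phase amplitude modulation
    background_rms: float = 10.0        # µV, 1/f background
    alpha_rms: float = 20.0             # µV, posterior channels
    beta_rms: float = 20.0              # µV, sensorimotor channels
    theta_rms: float = 15.0             # µV, frontal-midline channels
    heel_noise_mm: float = 0.3
    grf_noise_n: float = 2.0
    body_weight_n: float = 700.0
    stance_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trial_duration", "sampling_rate_eeg", "sampling_rate_mocap",
                     "stride_mean", "body_weight_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_channels < 1 or self.n_channels > 64:
            raise ValueError("n_channels must be in 1..64")
        for cond, bands in self.band_effects.items():
            for band, factor in bands.items():
                if factor <= 0:
                    raise ValueError(f"band factor {cond}/{band} must be positive")

    @property
    def channel_labels(self) -> list[str]:
        return CHANNEL_LABELS_64[: self.n_channels]

    def stride_cv(self, condition: str) -> float:
        return (self.stride_cv_unstable if condition in UNSTABLE_CONDITIONS
                else self.stride_cv_stable)


@dataclass
class SyntheticSession:
    """One trial: EEG plus kinematics with ground-truth heel-strike times."""

    eeg: EEGRecording
    heel_z_left: MotionSeries
    heel_z_right: MotionSeries
    grf_left: MotionSeries
    grf_right: MotionSeries
    true_events: dict[str, np.ndarray]  # side -> heel-strike times (s)
    condition: str
    subject_id: int

    def __post_init__(self) -> None:
        for side, times in self.true_events.items():
            times = np.asarray(times, dtype=float)
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"true_events[{side}] must be strictly increasing")
            self.true_events[side] = times


def _event_times(rng: np.random.Generator, config: SessionConfig,
                 condition: str) -> tuple[np.ndarray, np.ndarray]:
    """Right and left heel-strike times with the condition's stride variability."""
    mean, cv = config.stride_mean, config.stride_cv(condition)
    # Leave headroom at both ends so every heel-strike minimum is interior.
    t_stop = config.trial_duration - 1.5 * mean
    times = [rng.uniform(0.6, 0.6 + mean)]
    while times[-1] < t_stop:
        gap = rng.normal(mean, cv * mean)
        gap = float(np.clip(gap, 0.5 * mean, 1.5 * mean))
        times.append(times[-1] + gap)
    right = np.array(times[:-1]) if times[-1] >= t_stop else np.array(times)
    # Left strikes near mid-interval of the right strides.
    gaps = np.diff(right)
    left = right[:-1] + gaps * (0.5 + rng.normal(0.0, 0.01, size=len(gaps)))
    return right, np.sort(left)


def _phase(t: np.ndarray, events: np.ndarray, stride_mean: float) -> np.ndarray:
    """Continuous gait phase: integer values exactly at the event times."""
    ext = np.concatenate((
        [events[0] - stride_mean], events, [events[-1] + stride_mean]))
    return np.interp(t, ext, np.arange(len(ext), dtype=float))


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int],
                fs: float) -> np.ndarray:
    """1/f-power background (spectral slope -1), unit RMS per channel."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], 0.5))
    shaped = np.fft.irfft(spec * scale, n=n, axis=1)
    rms = np.sqrt(np.mean(shaped**2, axis=1, keepdims=True))
    return shaped / rms


def _band_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Band-limited Gaussian oscillation, unit RMS per channel."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / rms


_BAND_GROUP = {"alpha": "posterior", "beta": "sensorimotor",
               "theta": "frontal_midline"}
_BAND_RMS_FIELD = {"alpha": "alpha_rms", "beta": "beta_rms", "theta": "theta_rms"}


def generate_session(config: SessionConfig, condition: str,
                     subject_id: int) -> SyntheticSession:
    """Generate one synthetic walking trial for ``subject_id``/``condition``."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(
        [config.seed, int(subject_id), CONDITIONS.index(condition)])

    fs, fsm = config.sampling_rate_eeg, config.sampling_rate_mocap
    n = int(round(config.trial_duration * fs))
    t = np.arange(n) / fs
    labels = config.channel_labels
    groups = channel_groups(labels)

    right, left = _event_times(rng, config, condition)
    phase_r = _phase(t, right, config.stride_mean)

    # --- EEG: 1/f background + phase-modulated band oscillations -----------
    data = config.background_rms * _pink_noise(rng, (len(labels), n), fs)
    modulation = 1.0 + config.modulation_depth * np.sin(2 * np.pi * phase_r)
    effects = config.band_effects[condition]
    for band, group in _BAND_GROUP.items():
        idx = groups[group]
        if len(idx) == 0:
            continue
        target_rms = getattr(config, _BAND_RMS_FIELD[band])
        amp = target_rms * np.sqrt(effects.get(band, 1.0))
        osc = amp * _band_noise(rng, (len(idx), n), fs, BANDS[band])
        data[idx] += osc * modulation[None, :]

    eeg = EEGRecording(data, fs, labels, metadata={
        "condition": condition, "subject_id": int(subject_id)})

    if config.artifact_spec.any_active:
        artifact_seed = int(rng.integers(0, 2**31 - 1))
        eeg = inject_artifacts(eeg, config.artifact_spec, artifact_seed)

    # --- Kinematics ---------------------------------------------------------
    n_m = int(round(config.trial_duration * fsm))
    t_m = np.arange(n_m) / fsm
    heel, grf = {}, {}
    for side, events in (("right", right), ("left", left)):
        ph = np.mod(_phase(t_m, events, config.stride_mean), 1.0)
        # smooth swing arc plus a sharp, time-symmetric dip at heel strike
        # (the heel decelerates abruptly at contact)
        height = 12.0 + 18.0 * 0.5 * (1.0 - np.cos(2 * np.pi * ph))
        for ev in events:
            height -= 6.0 * np.exp(-0.5 * ((t_m - ev) / 0.02) ** 2)
        height = height + config.heel_noise_mm * rng.standard_normal(n_m)
        heel[side] = MotionSeries(t_m, height, side=side, kind="marker")

        s = ph / config.stance_fraction
        stance = s < 1.0
        shape = 0.75 * np.sin(np.pi * s) + 0.25 * np.sin(3 * np.pi * s)
        shape[~stance] = 0.0
        grid = np.linspace(0, 1, 2001)
        peak = np.max(0.75 * np.sin(np.pi * grid) + 0.25 * np.sin(3 * np.pi * grid))
        force = 1.1 * config.body_weight_n * shape / peak
        force += config.grf_noise_n * rng.standard_normal(n_m)
        force[~stance & (force < 0)] = 0.0
        np.clip(force, 0.0, None, out=force)
        grf[side] = MotionSeries(t_m, force, side=side, kind="force")

    return SyntheticSession(
        eeg=eeg,
        heel_z_left=heel["left"], heel_z_right=heel["right"],
        grf_left=grf["left"], grf_right=grf["right"],
        true_events={"right": right, "left": left},
        condition=condition, subject_id=int(subject_id),
    )


def inject_artifacts(eeg: EEGRecording, spec: ArtifactSpec,
                     seed: int) -> EEGRecording:
    """Add blink, line-noise and EMG artifacts; the input is not modified.

    Ground-truth artifact time stamps are recorded under
    ``metadata["artifacts"]`` of the returned recording.
    """
    rng = np.random.default_rng(seed)
    out = eeg.copy()
    if not spec.any_active:
        return out
    fs, n = eeg.sampling_rate, eeg.n_samples
    t = np.arange(n) / fs
    duration = n / fs
    stamps: dict = {}

    if spec.blink_rate > 0:
        weights = _weight_vector(out.channel_labels, _FRONTAL_BLINK)
        n_blinks = rng.poisson(spec.blink_rate * duration)
        times = np.sort(rng.uniform(0.2, duration - 0.5, size=n_blinks))
        width = int(round(spec.blink_duration * fs))
        bump = np.sin(np.pi * np.arange(width) / width) ** 2
        course = np.zeros(n)
        for bt in times:
            i0 = int(round(bt * fs))
            seg = min(width, n - i0)
            course[i0:i0 + seg] += bump[:seg]
        out.data += spec.blink_amplitude * weights[:, None] * course[None, :]
        stamps["blink_times"] = [float(x) for x in times]
        stamps["blink_duration"] = spec.blink_duration

    if spec.line_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        line = spec.line_amplitude * np.sin(2 * np.pi * spec.line_freq * t + phase)
        out.data += line[None, :]
        stamps["line"] = {"freq": spec.line_freq, "amplitude": spec.line_amplitude}

    if spec.emg_rate > 0:
        sos = signal.butter(4, 30.0, btype="highpass", fs=fs, output="sos")
        windows: dict[str, list] = {"left": [], "right": []}
        for side, wmap in (("left", _TEMPORAL_LEFT), ("right", _TEMPORAL_RIGHT)):
            weights = _weight_vector(out.channel_labels, wmap)
            if not np.any(weights):
                continue
            n_bursts = rng.poisson(spec.emg_rate * duration)
            for _ in range(n_bursts):
                dur = rng.uniform(0.2, 0.5)
                t0 = rng.uniform(0.0, max(duration - dur, 0.0))
                i0, i1 = int(t0 * fs), int((t0 + dur) * fs)
                carrier = signal.sosfiltfilt(sos, rng.standard_normal(i1 - i0))
                carrier /= max(np.sqrt(np.mean(carrier**2)), 1e-12)
                taper = np.sin(np.pi * np.arange(i1 - i0) / (i1 - i0)) ** 2
                out.data[:, i0:i1] += (spec.emg_amplitude
                                       * weights[:, None] * (carrier * taper)[None, :])
                windows[side].append([t0, t0 + dur])
        stamps["emg_windows"] = windows

    out.metadata["artifacts"] = stamps
    return out


# ---------------------------------------------------------------------------
# Fixture plumbing
# ---------------------------------------------------------------------------


def save_session(session: SyntheticSession, outdir: str | Path,
                 basename: str | None = None) -> Path:
    """Write a session as BrainVision + TSVs + ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = basename or f"sub{session.subject_id:02d}_{session.condition}"
    write_brainvision(session.eeg, outdir / base)
    for name, series in (
        ("heel_left", session.heel_z_left), ("heel_right", session.heel_z_right),
        ("grf_left", session.grf_left), ("grf_right", session.grf_right),
    ):
        write_timeseries_tsv(series, outdir / f"{base}_{name}.tsv")
    sidecar = {
        "condition": session.condition,
        "subject_id": session.subject_id,
        "true_events": {s: list(map(float, v))
                        for s, v in session.true_events.items()},
        "artifacts": session.eeg.metadata.get("artifacts", {}),
    }
    (outdir / f"{base}_truth.json").write_text(json.dumps(sidecar, indent=1))
    return outdir / base


def load_session(outdir: str | Path, basename: str) -> SyntheticSession:
    outdir = Path(outdir)
    sidecar = json.loads((outdir / f"{basename}_truth.json").read_text())
    eeg = read_brainvision(outdir / f"{basename}.vhdr")
    eeg.metadata.update({"condition": sidecar["condition"],
                         "subject_id": sidecar["subject_id"],
                         "artifacts": sidecar.get("artifacts", {})})

    def ts(name: str, side: str, kind: str) -> MotionSeries:
        return read_timeseries_csv(
            outdir / f"{basename}_{name}.tsv",
            ColumnSpec(side=side, kind=kind, delimiter="\t"),
        )

    return SyntheticSession(
        eeg=eeg,
        heel_z_left=ts("heel_left", "left", "marker"),
        heel_z_right=ts("heel_right", "right", "marker"),
        grf_left=ts("grf_left", "left", "force"),
        grf_right=ts("grf_right", "right", "force"),
        true_events={s: np.asarray(v)
                     for s, v in sidecar["true_events"].items()},
        condition=sidecar["condition"],
        subject_id=sidecar["subject_id"],
    )
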