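"""End-to-end pipeline: simulate -> preprocess -> segment -> features ->
select -> evaluate, driven by a single validated JSON config.

Every stage logs its parameters and counts (cycles kept/discarded,
components removed, features selected) so a run can be audited, and the
whole run is reproducible from config + seed alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import models as _models
from .evaluation import LABELINGS, crossvalidate, make_labels
from .features import FeatureConfig, extract_features
from .io_formats import write_feature_table
from .preprocess import (bandpass_bandstop, decompose_ica, remove_artifacts,
                         score_components)
from .segmentation import (cycles_to_tensor, detect_events_grf,
                           detect_events_marker, reconcile_events,
                           segment_and_normalize)
from .selection import select_features
from .synth import (CONDITIONS, ArtifactSpec, SessionConfig, generate_session)

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

log = logging.getLogger(__name__)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Section):
    enabled: bool = True
    n_subjects: int = 4
    trial_duration: float = 120.0
    sampling_rate_eeg: float = 1000.0
    sampling_rate_mocap: float = 100.0
    n_channels: int = 64
    stride_mean: float = 1.10
    stride_cv_stable: float = 0.03
    stride_cv_unstable: float = 0.07
    conditions: list[str] = Field(default_factory=lambda: list(CONDITIONS))
    blink_rate: float = 0.0
    line_amplitude: float = 0.0
    emg_rate: float = 0.0


class PreprocessSection(_Section):
    hp: float = 1.0
    lp: float = 70.0
    stop: tuple[float, float] = (55.0, 65.0)
    ica: bool = False
    ica_threshold: float = 0.90


class SegmentSection(_Section):
    side: str = "right"
    n: int = 100
    grf_threshold: float = 20.0
    reconcile_tol: float = 0.05


class FeatureSection(_Section):
    wavelet_levels: int = 8
    entropy_eps_k: float = 0.2
    entropy_p: float = 1.5


class SelectionSection(_Section):
    k: int = 40
    corr_threshold: float = 0.8
    per_fold: bool = False


class ModelsSection(_Section):
    kinds: list[str] = Field(default_factory=lambda: ["random_forest",
                                                      "chrononet"])
    epochs: int = 20
    batch_size: int = 64
    lr: float = 2e-3
    patience: int = 20


class EvaluationSection(_Section):
    k: int = 5
    labelings: list[str] = Field(default_factory=lambda: list(LABELINGS))
    group_by_subject: bool = False


class PipelineConfig(_Section):
    """Validated nested configuration; unknown keys are rejected."""

    seed: int = 0
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    segment: SegmentSection = Field(default_factory=SegmentSection)
    features: FeatureSection = Field(default_factory=FeatureSection)
    selection: SelectionSection = Field(default_factory=SelectionSection)
    models: ModelsSection = Field(default_factory=ModelsSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1))


def demo_config() -> PipelineConfig:
    """A small end-to-end demonstration configuration (~2 subjects, 60 s)."""
    cfg = PipelineConfig(seed=7)
    cfg.simulate.n_subjects = 2
    cfg.simulate.trial_duration = 60.0
    cfg.simulate.n_channels = 32
    cfg.simulate.blink_rate = 0.15
    cfg.simulate.emg_rate = 0.05
    cfg.preprocess.ica = True
    cfg.models.kinds = ["random_forest", "chrononet"]
    cfg.models.epochs = 18
    return cfg


def _session_config(cfg: PipelineConfig) -> SessionConfig:
    sim = cfg.simulate
    return SessionConfig(
        n_subjects=sim.n_subjects,
        trial_duration=sim.trial_duration,
        sampling_rate_eeg=sim.sampling_rate_eeg,
        sampling_rate_mocap=sim.sampling_rate_mocap,
        n_channels=sim.n_channels,
        stride_mean=sim.stride_mean,
        stride_cv_stable=sim.stride_cv_stable,
        stride_cv_unstable=sim.stride_cv_unstable,
        artifact_spec=ArtifactSpec(blink_rate=sim.blink_rate,
                                   line_amplitude=sim.line_amplitude,
                                   emg_rate=sim.emg_rate),
        seed=cfg.seed,
    )


def collect_cycles(cfg: PipelineConfig):
    """Simulate + preprocess + segment; returns the retained cycles."""
    scfg = _session_config(cfg)
    all_cycles = []
    counts = {"discarded_cycles": 0, "removed_components": 0}
    for subject in range(cfg.simulate.n_subjects):
        for condition in cfg.simulate.conditions:
            session = generate_session(scfg, condition, subject)
            rec = bandpass_bandstop(session.eeg, cfg.preprocess.hp,
                                    cfg.preprocess.lp, cfg.preprocess.stop)
            if cfg.preprocess.ica:
                decomp = decompose_ica(rec, seed=cfg.seed)
                decomp = score_components(decomp, rec)
                rec = remove_artifacts(decomp, cfg.preprocess.ica_threshold)
                counts["removed_components"] += len(
                    rec.metadata.get("removed_components", []))
                rec.metadata.update({"condition": condition,
                                     "subject_id": subject})
            heel = (session.heel_z_right if cfg.segment.side == "right"
                    else session.heel_z_left)
            grf = (session.grf_right if cfg.segment.side == "right"
                   else session.grf_left)
            marker = detect_events_marker(heel)
            force = detect_events_grf(grf, cfg.segment.grf_threshold)
            events = reconcile_events(marker, force, cfg.segment.reconcile_tol)
            cycles = segment_and_normalize(rec, events, n=cfg.segment.n,
                                           subject=subject,
                                           condition=condition)
            counts["discarded_cycles"] += max(len(events) - 1 - len(cycles), 0)
            all_cycles.extend(cycles)
            log.info("subject %d %s: %d events, %d cycles",
                     subject, condition, len(events), len(cycles))
    log.info("pipeline counts: %s", counts)
    return all_cycles, counts


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; writes reports + intermediates to out_dir.

    Returns ``{labeling: {model_kind: EvaluationReport}}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        cycles, counts = collect_cycles(cfg)
        if not cycles:
            raise RuntimeError("no gait cycles retained")
        fcfg = FeatureConfig(wavelet_levels=cfg.features.wavelet_levels,
                             entropy_eps_k=cfg.features.entropy_eps_k,
                             entropy_p=cfg.features.entropy_p)
        table = extract_features(cycles, fcfg)
        write_feature_table(table, out_dir / "features.tsv")
        tensor = cycles_to_tensor(cycles)
        conditions = table.conditions
        subjects = table.subjects.astype(int)
    except Exception as err:  # pragma: no cover - stage attribution
        raise RuntimeError(f"pipeline stage failed before evaluation: {err}"
                           ) from err

    reports: dict[str, dict] = {}
    for labeling in cfg.evaluation.labelings:
        mask, labels = make_labels(conditions, labeling)
        if not mask.any():
            continue
        X = table.values[mask]
        tens = tensor[mask]
        groups = subjects[mask] if cfg.evaluation.group_by_subject else None

        sel = None
        if not cfg.selection.per_fold:
            from .io_formats import FeatureTable
            sub = FeatureTable(table.frame.loc[mask].reset_index(drop=True))
            sel = select_features(sub, labels, k=cfg.selection.k,
                                  corr_threshold=cfg.selection.corr_threshold)
            cols = [table.feature_names.index(f) for f in sel.selected]
            Xsel = X[:, cols]
            log.info("%s: selected %d features", labeling, len(cols))
            (out_dir / f"selection_{labeling}.json").write_text(json.dumps(
                {"selected": sel.selected,
                 "scores": {n: round(s, 6) for n, s in sel.ranked[:50]}},
                indent=1, sort_keys=True))
        reports[labeling] = {}
        for kind in cfg.models.kinds:
            hp: dict = {}
            if kind in _models.DEEP_KINDS:
                hp = {"epochs": cfg.models.epochs,
                      "batch_size": cfg.models.batch_size,
                      "lr": cfg.models.lr, "patience": cfg.models.patience}
            spec = _models.ModelSpec(
                kind=kind, hyperparameters=hp, seed=cfg.seed,
                n_classes=min(max(len(np.unique(labels)), 2), 4))
            if kind in _models.DEEP_KINDS:
                rep = crossvalidate(tens, labels, spec, k=cfg.evaluation.k,
                                    seed=cfg.seed, groups=groups,
                                    labeling=labeling)
            elif cfg.selection.per_fold:
                rep = crossvalidate(
                    X, labels, spec, k=cfg.evaluation.k, seed=cfg.seed,
                    groups=groups, feature_names=table.feature_names,
                    per_fold_selection={"k": cfg.selection.k,
                                        "corr_threshold":
                                            cfg.selection.corr_threshold},
                    labeling=labeling)
            else:
                rep = crossvalidate(Xsel, labels, spec, k=cfg.evaluation.k,
                                    seed=cfg.seed, groups=groups,
                                    labeling=labeling)
            reports[labeling][kind] = rep
            log.info("%s / %s: accuracy %.3f", labeling, kind,
                     rep.metrics["accuracy"])
        (out_dir / f"report_{labeling}.json").write_text(json.dumps(
            {kind: rep.to_dict() for kind, rep in reports[labeling].items()},
            sort_keys=True, indent=1))
    (out_dir / "config.json").write_text(cfg.model_dump_json(indent=1))
    return reports
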