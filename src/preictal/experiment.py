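"""End-to-end synthetic benchmark: generate a cohort, train per subject,
evaluate held-out sessions.

The default conditions are a desk-scale cohort: 5 subjects with 2 seizure
sessions each, 22-minute sessions with onset at minute 20 (satisfying the
onset >= 20 min eligibility rule; the 2 minutes after onset carry the ictal
and postictal intervals), a 10-minute preictal state, and a matching
10-minute labeling horizon. For every subject the first session trains the
CSP filter and the classifier; the remaining sessions are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import pipeline as pl
from . import spatial as spatial_mod
from .features import window_signal
from .io import Recording, StateAnnotation
from .synth import SynthConfig, generate_cohort


def scaled_synth_config(seed: int = 0) -> SynthConfig:
    """Session conditions for the desk-scale benchmark."""
    return SynthConfig(
        session_minutes=22.0,
        onset_minute=20.0,
        preictal_minutes=10.0,
        seed=seed,
    )


def scaled_pipeline_config(seed: int = 0) -> pl.PipelineConfig:
    """Analysis settings for the desk-scale benchmark (horizon matches the
    generator's 10-minute preictal state)."""
    return pl.PipelineConfig(preictal_horizon_min=10.0, seed=seed)


def extract_class_segments(
    recording: Recording,
    annotation: StateAnnotation,
    config: pl.PipelineConfig,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """1-second multichannel segments for CSP fitting: (preictal, interictal)."""
    fs = int(round(recording.fs))
    n_windows = recording.n_times // fs
    dummy = window_signal(np.zeros(n_windows * fs), fs)  # index/time grid only
    labeled = pl.label_windows(
        dummy, annotation, config.preictal_horizon_min, config.guard_band_min
    )
    pre, inter = [], []
    for win, lab in labeled:
        seg = recording.samples[:, win.index * fs : (win.index + 1) * fs]
        (pre if lab == pl.PREICTAL else inter).append(seg)
    return pre, inter


def train_subject_model(
    train_sessions: list[tuple[Recording, StateAnnotation]],
    config: pl.PipelineConfig,
) -> pl.TrainedModel:
    """Fit the per-subject CSP filter and classifier from training sessions."""
    csp_filter = None
    if config.spatial_method == "csp":
        pre, inter = [], []
        for rec, ann in train_sessions:
            p, i = extract_class_segments(rec, ann, config)
            pre.extend(p)
            inter.extend(i)
        csp_filter = spatial_mod.fit_csp(pre, inter)

    labeled_windows: list[pl.LabeledWindow] = []
    for rec, ann in train_sessions:
        denoised = pl.preprocess_session(rec, config, csp_filter)
        windows = window_signal(denoised, rec.fs)
        labeled = pl.label_windows(
            windows, ann, config.preictal_horizon_min, config.guard_band_min
        )
        labeled_windows.extend(
            pl.attach_features(labeled, rec.subject_id, rec.session_id)
        )
    return pl.train_model(
        labeled_windows, kind=config.classifier, seed=config.seed,
        csp_filter=csp_filter,
    )


@dataclass
class ExperimentResult:
    report: pl.EvalReport
    models: dict[str, pl.TrainedModel]
    n_sessions: int


def run_synthetic_experiment(
    seed: int = 0,
    n_subjects: int = 5,
    sessions_per_subject: int = 2,
    synth_config: SynthConfig | None = None,
    pipeline_config: pl.PipelineConfig | None = None,
) -> ExperimentResult:
    """Generate, train and evaluate the full cohort; deterministic under seed."""
    synth_config = synth_config or scaled_synth_config(seed)
    config = pipeline_config or scaled_pipeline_config(seed)
    config = replace(config, seed=seed)
    sessions = generate_cohort(
        n_subjects, synth_config, seed=seed,
        sessions_per_subject=sessions_per_subject,
    )
    by_subject: dict[str, list[tuple[Recording, StateAnnotation]]] = {}
    for rec, ann in sessions:
        by_subject.setdefault(rec.subject_id, []).append((rec, ann))

    models: dict[str, pl.TrainedModel] = {}
    test_sessions: list[tuple[Recording, StateAnnotation]] = []
    for subject, subj_sessions in by_subject.items():
        models[subject] = train_subject_model(subj_sessions[:1], config)
        test_sessions.extend(subj_sessions[1:])

    report = pl.evaluate_cohort(models, test_sessions, config)
    return ExperimentResult(report=report, models=models, n_sessions=len(sessions))
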