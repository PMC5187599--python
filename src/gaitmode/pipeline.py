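"""End-to-end orchestration: train a recognizer on one trial, classify
others, and reproduce the study layout (per-subject training, per-mode
success rates, transition delays)."""

from __future__ import annotations

import numpy as np

from . import evaluation
from .ann import TrainConfig, TrainingSet, build_input_matrix, train
from .decision import DecisionModel, classify_stream, fit_decision_model
from .model_io import TrainedRecognizer
from .signal_processing import ZuptConfig, process_stream, tune_eps_g
from .simulate import ScenarioConfig, TrialTruth, generate_study
from .streams import SensorStream

__all__ = ["train_recognizer", "classify_trial", "run_study"]


def train_recognizer(
    stream: SensorStream,
    labels: np.ndarray,
    stance_windows: list[tuple[int, int]] | None = None,
    train_cfg: TrainConfig | None = None,
    zupt_cfg: ZuptConfig | None = None,
    epsilon: float = 0.02,
    lam12: float = 1.0,
    lam21: float = 0.5,
) -> tuple[TrainedRecognizer, dict]:
    """Full training pass on one labeled trial.

    Tunes the zero-velocity threshold on the training trial (against the
    given stance windows, or FSR-derived both-on intervals when absent),
    derives velocity and pitch, fits the network and then the decision
    layer.  Returns the bundled recognizer and the training record.
    """
    zupt_cfg = zupt_cfg or ZuptConfig()
    if stance_windows is None:
        from .signal_processing import _runs
        stance_windows = _runs(stream.fsr_heel & stream.fsr_toe)
    # re-tune eps_g on this trial's vertical acceleration
    if stream.accel_z_world is not None:
        a_z = stream.accel_z_world
    else:
        from .signal_processing import rotate_to_world
        a_z = rotate_to_world(stream.quat, stream.accel_body)[:, 2]
    eps_g, clean = tune_eps_g(a_z, stance_windows, zupt_cfg)
    zupt_cfg = ZuptConfig(eps_g=eps_g, g=zupt_cfg.g, min_dwell=zupt_cfg.min_dwell,
                          drift_mode=zupt_cfg.drift_mode)
    signals = process_stream(stream, zupt_cfg)

    from .decision import coding_matrix
    X = build_input_matrix(signals.v_z, signals.theta)
    T = coding_matrix(np.asarray(labels, dtype=int))
    model, record = train(TrainingSet(X=X, T=T), train_cfg or TrainConfig())
    decision = fit_decision_model(model, signals, labels, fs=stream.fs,
                                  epsilon=epsilon, lam12=lam12, lam21=lam21)
    record["eps_g"] = eps_g
    record["eps_g_clean"] = clean
    rec = TrainedRecognizer(network=model, decision=decision, zupt=zupt_cfg,
                            fs=stream.fs)
    return rec, record


def classify_trial(
    rec: TrainedRecognizer,
    stream: SensorStream,
    truth: TrialTruth | None = None,
) -> tuple[np.ndarray, list[evaluation.Step]]:
    """Classify one trial and segment it into annotated steps.

    Returns per-sample mode labels and the step table; with ground truth
    supplied, each step also carries its true mode.
    """
    signals = process_stream(stream, rec.zupt)
    pred = classify_stream(rec.network, rec.decision, signals, stream.fs)
    steps = evaluation.segment_steps(stream.fsr_heel, stream.fsr_toe)
    true_labels = truth.mode if truth is not None else None
    evaluation.annotate_steps(steps, pred, true_labels)
    return pred, steps


def _train_pooled(trials, subjects, base_train: TrainConfig):
    """One recognizer trained on the pooled training trials of all subjects."""
    from .ann import predict_stream
    from .decision import (coding_matrix, filter_stream, fit_class_gaussians,
                           solve_threshold)

    per_subj = []
    for subject in subjects:
        stream, truth, _ = trials[(subject, 1)]
        from .signal_processing import rotate_to_world
        a_z = (stream.accel_z_world if stream.accel_z_world is not None
               else rotate_to_world(stream.quat, stream.accel_body)[:, 2])
        eps_g, _ = tune_eps_g(a_z, truth.stance_windows)
        zcfg = ZuptConfig(eps_g=eps_g)
        signals = process_stream(stream, zcfg)
        per_subj.append((signals, truth, stream.fs, zcfg))

    X = np.vstack([build_input_matrix(s.v_z, s.theta) for s, _, _, _ in per_subj])
    T = np.vstack([coding_matrix(t.mode) for _, t, _, _ in per_subj])
    model, record = train(TrainingSet(X=X, T=T), base_train)

    y_bar = np.vstack([filter_stream(predict_stream(model, s), 0.02, fs)
                       for s, _, fs, _ in per_subj])
    targets = np.vstack([coding_matrix(t.mode) for _, t, _, _ in per_subj])
    stats = np.empty((3, 4))
    thresholds = np.empty(3)
    for el in range(3):
        mu1, s1, mu2, s2 = fit_class_gaussians(y_bar[:, el], targets[:, el] == 1.0)
        stats[el] = (mu1, s1, mu2, s2)
        thresholds[el], _ = solve_threshold(mu1, s1, mu2, s2)
    decision = DecisionModel(class_stats=stats, thresholds=thresholds)
    rec = TrainedRecognizer(network=model, decision=decision,
                            zupt=per_subj[0][3], fs=per_subj[0][2])
    return rec, record


def run_study(
    cfg: ScenarioConfig,
    train_cfg: TrainConfig | None = None,
    pool_subjects: bool = False,
) -> dict:
    """Reproduce the study design for one scenario.

    Generates ``n_subjects`` × ``n_trials`` trials, trains one recognizer
    per subject on trial 1 (or one pooled recognizer when
    ``pool_subjects``), classifies the remaining trials, and aggregates
    per-mode success rates and the mean transition-detection delay.
    """
    trials = generate_study(cfg)
    base_train = train_cfg or TrainConfig()

    recognizers: dict[int, TrainedRecognizer] = {}
    records: dict[int, dict] = {}
    per_trial_steps: dict[tuple, list] = {}

    subjects = sorted({s for s, _ in trials})
    if pool_subjects:
        rec, record = _train_pooled(trials, subjects, base_train)
        recognizers = {s: rec for s in subjects}
        records = {"pooled": record}
    else:
        for subject in subjects:
            stream, truth, _ = trials[(subject, 1)]
            sub_cfg = TrainConfig(**{**base_train.__dict__,
                                     "seed": base_train.seed + subject})
            rec, record = train_recognizer(stream, truth.mode,
                                           truth.stance_windows, sub_cfg)
            recognizers[subject] = rec
            records[subject] = record

    for (subject, trial), (stream, truth, is_train) in trials.items():
        if is_train:
            continue
        _, steps = classify_trial(recognizers[subject], stream, truth)
        per_trial_steps[(subject, trial)] = steps

    report = evaluation.evaluate_trials(per_trial_steps)
    report["scenario"] = cfg.scenario
    report["seed"] = cfg.seed
    report["training_records"] = records
    report["per_trial_steps"] = per_trial_steps
    return report
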