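"""Per-step evaluation: gait-cycle segmentation and the two study metrics.

A gait cycle runs between consecutive heel strikes of the same limb and is
normalized to 0–100 %GC; swing starts at toe-off.  Heel strikes are
debounced OFF→ON transitions of the heel FSR; toe-off is the last ON→OFF
transition of the toe FSR before the next heel strike.

Metrics:

* success rate = 100 × (#steps whose predicted mode equals the true mode)
  / (#steps); a step predicted Undetermined counts as incorrect.
* detection delay = 100 × (detect_sample − swing_start) / cycle length,
  in percent gait cycle, evaluated on transition steps (steps whose true
  mode differs from the previous step's).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision import ModeLabel

__all__ = [
    "Step",
    "TooFewStepsError",
    "segment_steps",
    "step_mode",
    "success_rate",
    "detection_delay",
    "annotate_steps",
    "evaluate_trials",
]

DEBOUNCE_SAMPLES = 10


class TooFewStepsError(ValueError):
    """Fewer than two heel strikes: no complete gait cycle exists."""


@dataclass
class Step:
    """One gait cycle: heel strike → next heel strike of the same limb."""

    heel_strike: int
    swing_start: int          # toe-off sample
    next_heel_strike: int
    true_mode: int = int(ModeLabel.Undetermined)
    pred_mode: int = int(ModeLabel.Undetermined)
    detect_sample: int | None = None
    delay_pct_gc: float | None = None

    def __post_init__(self) -> None:
        if not self.heel_strike < self.swing_start < self.next_heel_strike:
            raise ValueError("requires heel_strike < swing_start < next_heel_strike")


def _debounced_edges(series: np.ndarray, rising: bool, window: int) -> np.ndarray:
    """Edge indices where the new state persists for >= window samples
    (or to the end of the stream)."""
    s = np.asarray(series, dtype=bool).astype(int)
    d = np.diff(s)
    raw = np.flatnonzero(d == (1 if rising else -1)) + 1
    state = bool(rising)
    keep = []
    for i in raw:
        seg = s[i:i + window].astype(bool)
        if np.all(seg == state):
            keep.append(i)
    return np.array(keep, dtype=int)


def segment_steps(fsr_heel: np.ndarray, fsr_toe: np.ndarray,
                  debounce: int = DEBOUNCE_SAMPLES) -> list[Step]:
    """Segment gait cycles from the two foot-switch channels.

    Raises :class:`TooFewStepsError` with fewer than two debounced heel
    strikes.  Cycles without a toe-off strictly inside are dropped.
    """
    heel = np.asarray(fsr_heel, dtype=bool)
    toe = np.asarray(fsr_toe, dtype=bool)
    if heel.size != toe.size:
        raise ValueError("FSR series must share length")
    hs = _debounced_edges(heel, rising=True, window=debounce)
    if hs.size < 2:
        raise TooFewStepsError(f"found {hs.size} heel strike(s); need at least 2")
    toe_off = _debounced_edges(toe, rising=False, window=debounce)

    steps = []
    for a, b in zip(hs[:-1], hs[1:]):
        inside = toe_off[(toe_off > a) & (toe_off < b)]
        if inside.size == 0:
            continue
        steps.append(Step(heel_strike=int(a), swing_start=int(inside[-1]),
                          next_heel_strike=int(b)))
    return steps


def step_mode(pred: np.ndarray, step: Step) -> tuple[int, int | None]:
    """Assign one predicted mode to a step and locate the detection sample.

    The window is [swing_start, next_heel_strike).  The step's mode is the
    label of the longest run of non-Undetermined samples in the window
    (ties broken toward the later run).  The detection sample is the first
    window sample from which the prediction equals that mode and never
    switches to a *different determined* label before the window ends.
    An all-Undetermined window yields (Undetermined, None).
    """
    pred = np.asarray(pred, dtype=int)
    window = pred[step.swing_start:step.next_heel_strike]
    und = int(ModeLabel.Undetermined)
    determined = window != und
    if not np.any(determined):
        return und, None

    # longest run of identical determined labels; ties -> later run
    best_label, best_len, best_start = und, 0, -1
    i = 0
    n = window.size
    while i < n:
        if window[i] == und:
            i += 1
            continue
        j = i
        while j < n and window[j] == window[i]:
            j += 1
        if j - i >= best_len:
            best_label, best_len, best_start = int(window[i]), j - i, i
        i = j

    other = determined & (window != best_label)
    last_other = np.flatnonzero(other)
    start = int(last_other[-1]) + 1 if last_other.size else 0
    candidates = np.flatnonzero(window[start:] == best_label)
    if candidates.size == 0:
        return best_label, None
    return best_label, step.swing_start + start + int(candidates[0])


def success_rate(steps: list[Step], mode_filter: int | None = None) -> float:
    """Percent of steps whose predicted mode equals the true mode.

    ``mode_filter`` restricts to steps with that true mode.  Undetermined
    predictions count as incorrect.  Raises on an empty selection.
    """
    sel = [s for s in steps if mode_filter is None or s.true_mode == mode_filter]
    if not sel:
        raise ValueError("no steps match the selection; success rate undefined")
    correct = sum(1 for s in sel if s.pred_mode == s.true_mode)
    return 100.0 * correct / len(sel)


def detection_delay(step: Step) -> float | None:
    """Detection latency after swing start, in percent of the gait cycle."""
    if step.detect_sample is None:
        return None
    cycle = step.next_heel_strike - step.heel_strike
    return 100.0 * (step.detect_sample - step.swing_start) / cycle


def annotate_steps(steps: list[Step], pred: np.ndarray,
                   true_labels: np.ndarray | None = None) -> list[Step]:
    """Fill pred_mode / detect_sample / delay (and true mode) for each step.

    The true mode of a step, when per-sample truth is given, is the
    majority truth label over the same swing→next-heel-strike window used
    for prediction.
    """
    true_labels = None if true_labels is None else np.asarray(true_labels, dtype=int)
    for s in steps:
        s.pred_mode, s.detect_sample = step_mode(pred, s)
        s.delay_pct_gc = detection_delay(s)
        if true_labels is not None:
            window = true_labels[s.swing_start:s.next_heel_strike]
            s.true_mode = int(np.bincount(window, minlength=4).argmax())
    return steps


def transition_steps(steps: list[Step]) -> list[Step]:
    """Steps whose true mode differs from the previous step's true mode."""
    return [b for a, b in zip(steps[:-1], steps[1:]) if b.true_mode != a.true_mode]


def steps_to_frame(steps: list[Step]) -> pd.DataFrame:
    """Tabulate a step list (modes by name) for reports."""
    return pd.DataFrame([{
        "heel_strike": s.heel_strike,
        "swing_start": s.swing_start,
        "next_heel_strike": s.next_heel_strike,
        "true_mode": ModeLabel(s.true_mode).name,
        "pred_mode": ModeLabel(s.pred_mode).name,
        "detect_sample": s.detect_sample,
        "delay_pct_gc": s.delay_pct_gc,
    } for s in steps])


def evaluate_trials(per_trial_steps: dict[tuple, list[Step]]) -> dict:
    """Aggregate per-mode success rates and mean transition delay.

    ``per_trial_steps`` maps (subject, trial) → annotated step list.
    Returns a report with a per-subject × per-mode success table (plus an
    Overall row pooling subjects) and the mean detection delay over
    transition steps.
    """
    if not per_trial_steps:
        raise ValueError("no trials to evaluate")
    mode_names = [ModeLabel.Level, ModeLabel.Ascent, ModeLabel.Descent]
    by_subject: dict = {}
    for (subject, _trial), steps in per_trial_steps.items():
        by_subject.setdefault(subject, []).extend(steps)

    rows = []
    for subject in sorted(by_subject):
        row = {"subject": subject}
        for m in mode_names:
            sel = [s for s in by_subject[subject] if s.true_mode == int(m)]
            row[m.name.lower()] = success_rate(sel) if sel else float("nan")
        rows.append(row)
    pooled = [s for steps in by_subject.values() for s in steps]
    overall = {"subject": "Overall"}
    for m in mode_names:
        sel = [s for s in pooled if s.true_mode == int(m)]
        overall[m.name.lower()] = success_rate(sel) if sel else float("nan")
    rows.append(overall)

    # transitions are defined within a trial; delays are taken over the
    # transition steps whose new mode was actually detected
    delays = [s.delay_pct_gc for steps in per_trial_steps.values()
              for s in transition_steps(steps)
              if s.delay_pct_gc is not None and s.pred_mode == s.true_mode]
    return {
        "success_table": pd.DataFrame(rows).set_index("subject"),
        "overall": {m.name.lower(): overall[m.name.lower()] for m in mode_names},
        "mean_transition_delay_pct_gc": float(np.mean(delays)) if delays else None,
        "n_transition_steps": len(delays),
        "n_steps": len(pooled),
    }
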