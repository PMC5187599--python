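"""Train a recognizer on one trial and score it on a held-out trial.

Reproduces the per-subject workflow: the first trial trains the network
(Levenberg–Marquardt with Bayesian regularization) and the decision layer
(output filter + minimum-risk thresholds); a later trial of the same
subject is classified step by step.
"""

from gaitmode import (ModeLabel, ScenarioConfig, TrainConfig, classify_trial,
                      generate_trial, success_rate, train_recognizer)
from gaitmode.evaluation import transition_steps

cfg = ScenarioConfig(scenario="stairs", seed=42)
train_stream, train_truth = generate_trial(cfg, subject_id=1, trial_id=1)

rec, record = train_recognizer(train_stream, train_truth.mode,
                               train_truth.stance_windows,
                               TrainConfig(seed=1))
print(f"trained in {record['epochs']} epochs (stop: {record['stop']}); "
      f"eps_g = {record['eps_g']:.3f} m/s^2")
print("risk thresholds per output element:",
      [round(float(t), 3) for t in rec.decision.thresholds])

test_stream, test_truth = generate_trial(cfg, subject_id=1, trial_id=2)
_, steps = classify_trial(rec, test_stream, test_truth)

print(f"\nheld-out trial: {len(steps)} steps, "
      f"success rate {success_rate(steps):.1f}%")
for mode in (ModeLabel.Level, ModeLabel.Ascent, ModeLabel.Descent):
    sel = [s for s in steps if s.true_mode == int(mode)]
    if sel:
        print(f"  {mode.name:<8} {success_rate(sel):6.1f}%  ({len(sel)} steps)")

print("\ntransition steps (new mode detected after swing start):")
for s in transition_steps(steps):
    print(f"  -> {ModeLabel(s.true_mode).name:<8} detected at "
          f"{s.delay_pct_gc:4.1f}% of the gait cycle after toe-off")
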