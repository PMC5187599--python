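"""JSON (de)serialization of a trained recognizer.

One version-tagged document bundles the network weights, the input
standardization constants, the decision layer (filter constant, class
Gaussians, loss and thresholds) and the zero-velocity-update settings, so
a model trained on one trial can be applied to another unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .ann import NetworkModel
from .decision import DecisionModel
from .signal_processing import ZuptConfig

__all__ = ["TrainedRecognizer", "save_model", "load_model"]

FORMAT_VERSION = 1


@dataclass
class TrainedRecognizer:
    """Everything needed to classify a new trial."""

    network: NetworkModel
    decision: DecisionModel
    zupt: ZuptConfig
    fs: float = 200.0
    meta: dict | None = None


def save_model(recognizer: TrainedRecognizer, path) -> None:
    net, dec, z = recognizer.network, recognizer.decision, recognizer.zupt
    doc = {
        "format_version": FORMAT_VERSION,
        "fs": recognizer.fs,
        "network": {
            "w_h": net.w_h.tolist(), "b_h": net.b_h.tolist(),
            "w_o": net.w_o.tolist(), "b_o": net.b_o.tolist(),
            "input_mean": net.input_mean.tolist(),
            "input_scale": net.input_scale.tolist(),
            "alpha": net.alpha, "beta": net.beta,
            "n_delays": net.n_delays, "n_hidden": net.n_hidden, "n_out": net.n_out,
        },
        "decision": {
            "epsilon": dec.epsilon, "lam12": dec.lam12, "lam21": dec.lam21,
            "class_stats": dec.class_stats.tolist(),
            "thresholds": dec.thresholds.tolist(),
            "use_naive_half_cut": dec.use_naive_half_cut,
        },
        "zupt": {"eps_g": z.eps_g, "g": z.g, "min_dwell": z.min_dwell,
                 "drift_mode": z.drift_mode},
        "meta": recognizer.meta or {},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> TrainedRecognizer:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')!r}")
    net = NetworkModel(**doc["network"])
    dec = DecisionModel(**doc["decision"])
    zupt = ZuptConfig(**doc["zupt"])
    return TrainedRecognizer(network=net, decision=dec, zupt=zupt,
                             fs=doc["fs"], meta=doc.get("meta") or {})
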