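"""From raw network outputs to gait-mode decisions.

The three-element network output is smoothed by a first-order low-pass
filter ``eps * dy̅/dt + y̅ = y`` (time constant 0.02 s by default),
binarized element-wise against minimum-Bayes-risk thresholds, and mapped
to a mode through the three-element coding.

For each output element two classes are assumed Gaussian: class 1 ("the
element should be 0") and class 2 ("should be 1").  With loss matrix
``L = [[0, lam12], [lam21, 0]]`` the optimal threshold ``z_o`` solves

    lam12 * p(z | w1) = lam21 * p(z | w2).

The default loss ``L = [[0, 1.0], [0.5, 0]]`` makes a false positive
(declaring an element active when it should be 0) twice as costly as a
false negative, shifting every threshold conservatively toward class 2.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.stats import norm

from .ann import NetworkModel, predict_stream
from .streams import ProcessedSignals

__all__ = [
    "ModeLabel",
    "DecisionModel",
    "InvalidTrainingDataError",
    "filter_stream",
    "fit_class_gaussians",
    "solve_threshold",
    "binarize",
    "map_mode",
    "classify_stream",
    "fit_decision_model",
]

SIGMA_FLOOR = 1e-3


class InvalidTrainingDataError(ValueError):
    """Training data does not cover both classes / all modes."""


class ModeLabel(enum.IntEnum):
    """Gait mode with its three-element target coding."""

    Ascent = 0
    Level = 1
    Descent = 2
    Undetermined = 3

    @property
    def coding(self) -> tuple[int, int, int]:
        return _CODINGS[self]


_CODINGS = {
    ModeLabel.Ascent: (1, 0, 0),
    ModeLabel.Level: (0, 1, 0),
    ModeLabel.Descent: (0, 0, 1),
    ModeLabel.Undetermined: (0, 0, 0),
}
_FROM_CODING = {v: k for k, v in _CODINGS.items()}


def coding_matrix(labels: np.ndarray) -> np.ndarray:
    """(N, 3) target matrix for an integer array of :class:`ModeLabel`."""
    table = np.array([_CODINGS[ModeLabel(i)] for i in range(4)], dtype=float)
    return table[np.asarray(labels, dtype=int)]


@dataclass
class DecisionModel:
    """Filter constant, per-element class Gaussians and risk thresholds."""

    epsilon: float = 0.02                    # filter time constant, s
    lam12: float = 1.0                       # cost of calling class 1 "1"
    lam21: float = 0.5                       # cost of calling class 2 "0"
    class_stats: np.ndarray = field(         # (3, 4): mu1, sigma1, mu2, sigma2
        default_factory=lambda: np.tile([0.0, 1.0, 1.0, 1.0], (3, 1)))
    thresholds: np.ndarray = field(default_factory=lambda: np.full(3, 0.5))
    use_naive_half_cut: bool = False         # plain 0.5 cut, for comparison

    def __post_init__(self) -> None:
        self.class_stats = np.asarray(self.class_stats, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if not (self.lam12 > 0 and self.lam21 > 0):
            raise ValueError("off-diagonal losses must be positive")
        if not np.all(np.isfinite(self.thresholds)):
            raise ValueError("thresholds must be finite")


def filter_stream(y: np.ndarray, epsilon: float, fs: float) -> np.ndarray:
    """First-order low-pass filter, exact exponential-hold discretization.

    ``y̅[k] = y̅[k-1] + (1 - e^(-1/(fs*eps))) (y[k] - y̅[k-1])`` with
    ``y̅[0] = y[0]``; applied per element of an (N, d) array.
    """
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    a = 1.0 - np.exp(-1.0 / (fs * epsilon))
    # out[k] = (1-a) out[k-1] + a y[k], seeded so that out[0] = y[0]
    zi = (1.0 - a) * y[0][None, :]
    out, _ = lfilter([a], [1.0, a - 1.0], y, axis=0, zi=zi)
    return out


def fit_class_gaussians(values: np.ndarray, is_class2: np.ndarray) -> tuple[float, float, float, float]:
    """Sample (mu1, sigma1, mu2, sigma2) for one output element.

    ``is_class2`` marks samples whose target value for this element is 1.
    Standard deviations are floored at 1e-3 so that (near-)noise-free
    training data cannot produce degenerate densities.
    """
    values = np.asarray(values, dtype=float)
    is_class2 = np.asarray(is_class2, dtype=bool)
    if values.size != is_class2.size:
        raise ValueError("values and labels must share length")
    z1, z2 = values[~is_class2], values[is_class2]
    if z1.size == 0 or z2.size == 0:
        raise InvalidTrainingDataError("both classes must be present for each element")
    mu1, mu2 = float(np.mean(z1)), float(np.mean(z2))
    s1 = max(float(np.std(z1, ddof=1)) if z1.size > 1 else 0.0, SIGMA_FLOOR)
    s2 = max(float(np.std(z2, ddof=1)) if z2.size > 1 else 0.0, SIGMA_FLOOR)
    return mu1, s1, mu2, s2


def solve_threshold(mu1: float, sigma1: float, mu2: float, sigma2: float,
                    lam12: float = 1.0, lam21: float = 0.5) -> tuple[float, bool]:
    """Minimum-risk threshold between two Gaussian classes.

    Solves ``lam12 N(z; mu1, sigma1) = lam21 N(z; mu2, sigma2)`` for z.
    Equal sigmas give the closed form
    ``z = (mu1+mu2)/2 + sigma^2 ln(lam12/lam21) / (mu2-mu1)``; otherwise
    the equality is a quadratic in z whose two roots are the stationary
    points of the expected risk — the root at which the risk is lower is
    taken, preferring roots inside ``(mu1 - sigma1, mu2 + sigma2)``.  If
    no real root exists the midpoint is returned with the warning flag set.

    Requires ``mu1 < mu2`` (class 1 has the lower mean).
    Returns ``(z_o, clean)``.
    """
    if not mu1 < mu2:
        raise ValueError("requires mu1 < mu2")
    if sigma1 < SIGMA_FLOOR or sigma2 < SIGMA_FLOOR:
        raise ValueError("sigmas must be >= the floor 1e-3")
    mid = 0.5 * (mu1 + mu2)
    if np.isclose(sigma1, sigma2):
        s2 = sigma1 * sigma2
        return mid + s2 * np.log(lam12 / lam21) / (mu2 - mu1), True
    # log of the density equality: a z^2 + b z + c = 0
    a = 0.5 / sigma2**2 - 0.5 / sigma1**2
    b = mu1 / sigma1**2 - mu2 / sigma2**2
    c = (0.5 * mu2**2 / sigma2**2 - 0.5 * mu1**2 / sigma1**2
         + np.log((lam12 * sigma2) / (lam21 * sigma1)))
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return mid, False
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots > mu1 - sigma1) & (roots < mu2 + sigma2)]
    candidates = inside if inside.size else roots
    # both roots are stationary points of the expected risk
    # R(z) = lam12 P(Z1 > z) + lam21 P(Z2 < z); keep the minimum
    risk = (lam12 * norm.sf(candidates, mu1, sigma1)
            + lam21 * norm.cdf(candidates, mu2, sigma2))
    return float(candidates[np.argmin(risk)]), True


def binarize(y_bar: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Element-wise 0/1 against the thresholds; ties map to 1."""
    return (np.asarray(y_bar, dtype=float) >= np.asarray(thresholds, dtype=float)).astype(int)


def map_mode(y_hat: np.ndarray) -> ModeLabel:
    """Binary 3-vector → mode; codings outside the four defined ones
    (e.g. two elements high) are Undetermined."""
    return _FROM_CODING.get(tuple(int(v) for v in np.asarray(y_hat).ravel()),
                            ModeLabel.Undetermined)


def map_mode_stream(y_hat: np.ndarray) -> np.ndarray:
    """Vectorized :func:`map_mode` over an (N, 3) binary array."""
    y_hat = np.asarray(y_hat, dtype=int)
    out = np.full(y_hat.shape[0], int(ModeLabel.Undetermined), dtype=int)
    for mode, code in _CODINGS.items():
        out[np.all(y_hat == np.array(code), axis=1)] = int(mode)
    return out


def classify_stream(model: NetworkModel, decision: DecisionModel,
                    signals: ProcessedSignals, fs: float | None = None) -> np.ndarray:
    """Per-sample mode labels: predict → filter → binarize → map, causal."""
    fs = fs or signals.fs
    y = predict_stream(model, signals)
    y_bar = filter_stream(y, decision.epsilon, fs)
    thr = np.full(3, 0.5) if decision.use_naive_half_cut else decision.thresholds
    return map_mode_stream(binarize(y_bar, thr))


def fit_decision_model(model: NetworkModel, signals: ProcessedSignals,
                       labels: np.ndarray, fs: float | None = None,
                       epsilon: float = 0.02,
                       lam12: float = 1.0, lam21: float = 0.5) -> DecisionModel:
    """Fit per-element Gaussians and risk thresholds on training data.

    ``labels`` are per-sample true modes.  For each output element,
    class 2 collects the samples whose target coding has a 1 in that
    element; class 1 the rest.  All three modes must appear.
    """
    fs = fs or signals.fs
    labels = np.asarray(labels, dtype=int)
    present = set(labels.tolist())
    needed = {int(ModeLabel.Ascent), int(ModeLabel.Level), int(ModeLabel.Descent)}
    if not needed <= present:
        missing = [ModeLabel(m).name for m in sorted(needed - present)]
        raise InvalidTrainingDataError(f"training data lacks mode(s): {missing}")

    y_bar = filter_stream(predict_stream(model, signals), epsilon, fs)
    targets = coding_matrix(labels)
    stats = np.empty((3, 4))
    thresholds = np.empty(3)
    for el in range(3):
        mu1, s1, mu2, s2 = fit_class_gaussians(y_bar[:, el], targets[:, el] == 1.0)
        stats[el] = (mu1, s1, mu2, s2)
        thresholds[el], _ = solve_threshold(mu1, s1, mu2, s2, lam12, lam21)
    return DecisionModel(epsilon=epsilon, lam12=lam12, lam21=lam21,
                         class_stats=stats, thresholds=thresholds)
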