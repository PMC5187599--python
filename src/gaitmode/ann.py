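"""Feed-forward network for gait-mode recognition.

Architecture: a 12-element input vector (vertical foot velocity and foot
pitch, each with six tapped delays of consecutive samples), one hidden
layer of 10 log-sigmoid neurons, and a linear output layer of 3 neurons
whose targets follow the three-element mode coding

    Ascent  -> (1, 0, 0)
    Level   -> (0, 1, 0)
    Descent -> (0, 0, 1)
    Undetermined -> (0, 0, 0)

Training minimizes the regularized cost

    E = alpha * sum ||t_i - y_i||^2  +  beta * E_w,

where ``E_w`` is the sum of squares of all weights and biases, by the
Levenberg–Marquardt algorithm with Bayesian re-estimation of
``(alpha, beta)`` under the evidence framework.  Note the convention:
``alpha`` multiplies the error term and ``beta`` the weight penalty, so
the effective number of parameters is ``gamma = k - 2*beta*tr(H^-1)`` and
the updates are ``beta = gamma / (2 E_w)``,
``alpha = (N - gamma) / (2 E_D)`` with ``N`` the residual count.

Inputs are z-scored with training-set statistics (velocity in m/s and
pitch in degrees differ by orders of magnitude); the constants are stored
in the model so inference matches training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .streams import ProcessedSignals

__all__ = [
    "NetworkModel",
    "TrainingSet",
    "TrainConfig",
    "TrainingFailureError",
    "logsig",
    "build_input_vector",
    "build_input_matrix",
    "forward",
    "cost",
    "train",
    "predict_stream",
]

N_DELAYS = 6
N_HIDDEN = 10
N_OUT = 3
N_IN = 2 * N_DELAYS


class TrainingFailureError(RuntimeError):
    """Levenberg–Marquardt could not make progress (singular damped Hessian)."""


@dataclass
class NetworkModel:
    """Weights, biases, input standardization and cost parameters."""

    w_h: np.ndarray                 # (10, 12)
    b_h: np.ndarray                 # (10,)
    w_o: np.ndarray                 # (3, 10)
    b_o: np.ndarray                 # (3,)
    input_mean: np.ndarray          # (12,)
    input_scale: np.ndarray         # (12,)
    alpha: float = 1.0
    beta: float = 0.005
    n_delays: int = N_DELAYS
    n_hidden: int = N_HIDDEN
    n_out: int = N_OUT

    def __post_init__(self) -> None:
        for name in ("w_h", "b_h", "w_o", "b_o", "input_mean", "input_scale"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n_in = 2 * self.n_delays
        if self.w_h.shape != (self.n_hidden, n_in) or self.b_h.shape != (self.n_hidden,):
            raise ValueError("hidden-layer dimensions inconsistent")
        if self.w_o.shape != (self.n_out, self.n_hidden) or self.b_o.shape != (self.n_out,):
            raise ValueError("output-layer dimensions inconsistent")
        if self.input_mean.shape != (n_in,) or self.input_scale.shape != (n_in,):
            raise ValueError("standardization constants must have length 2*n_delays")
        if np.any(self.input_scale <= 0):
            raise ValueError("input_scale must be positive elementwise")
        arrays = (self.w_h, self.b_h, self.w_o, self.b_o, self.input_mean, self.input_scale)
        if not all(np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("model contains non-finite entries")

    @property
    def n_params(self) -> int:
        return self.w_h.size + self.b_h.size + self.w_o.size + self.b_o.size

    def pack(self) -> np.ndarray:
        return np.concatenate([self.w_h.ravel(), self.b_h, self.w_o.ravel(), self.b_o])

    def unpack(self, theta: np.ndarray) -> None:
        h, n_in, o = self.n_hidden, 2 * self.n_delays, self.n_out
        i = 0
        self.w_h = theta[i:i + h * n_in].reshape(h, n_in); i += h * n_in
        self.b_h = theta[i:i + h].copy(); i += h
        self.w_o = theta[i:i + o * h].reshape(o, h); i += o * h
        self.b_o = theta[i:i + o].copy()


@dataclass
class TrainingSet:
    """Raw (unstandardized) tapped-delay inputs and mode-coded targets."""

    X: np.ndarray    # (N, 12)
    T: np.ndarray    # (N, 3), rows in {(1,0,0),(0,1,0),(0,0,1),(0,0,0)}

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.T = np.atleast_2d(np.asarray(self.T, dtype=float))
        if self.X.shape[0] != self.T.shape[0]:
            raise ValueError("X and T must have the same number of rows")
        valid = {(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0), (0.0, 0.0, 0.0)}
        if not set(map(tuple, self.T)) <= valid:
            raise ValueError("targets must use the three-element mode coding")


@dataclass
class TrainConfig:
    """Levenberg–Marquardt hyperparameters (all positive)."""

    max_epochs: int = 300
    mu_init: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    tol_grad: float = 1e-7
    tol_cost: float = 1e-9
    seed: int = 0
    reestimate_every: int = 1
    alpha_init: float = 1.0
    beta_init: float = 0.005

    def __post_init__(self) -> None:
        pos = (self.max_epochs, self.mu_init, self.mu_inc, self.mu_dec, self.mu_max,
               self.tol_grad, self.tol_cost, self.reestimate_every,
               self.alpha_init, self.beta_init)
        if not all(v > 0 for v in pos):
            raise ValueError("all TrainConfig fields must be positive")


def logsig(n):
    """Log-sigmoid 1 / (1 + e^-n), numerically stable over the float range."""
    n = np.asarray(n, dtype=float)
    out = np.empty_like(n)
    pos = n >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-n[pos]))
    en = np.exp(n[~pos])
    out[~pos] = en / (1.0 + en)
    return out if out.ndim else float(out)


def _windows(series: np.ndarray, n_delays: int) -> np.ndarray:
    """Causal sliding windows (newest last), front-padded with the first sample."""
    s = np.asarray(series, dtype=float)
    padded = np.concatenate([np.full(n_delays - 1, s[0]), s])
    idx = np.arange(n_delays)[None, :] + np.arange(s.size)[:, None]
    return padded[idx]


def build_input_vector(
    v_window: np.ndarray, theta_window: np.ndarray, model: NetworkModel
) -> tuple[np.ndarray, bool]:
    """Assemble and standardize one tapped-delay input vector.

    Both windows hold the ``n_delays`` most recent samples, newest last.
    Short windows (at stream start) are front-padded by repeating the
    earliest sample; the returned flag marks that case.
    """
    v = np.asarray(v_window, dtype=float)
    th = np.asarray(theta_window, dtype=float)
    if v.size == 0 or th.size == 0:
        raise ValueError("windows must be nonempty")
    padded = v.size < model.n_delays or th.size < model.n_delays
    if v.size < model.n_delays:
        v = np.concatenate([np.full(model.n_delays - v.size, v[0]), v])
    if th.size < model.n_delays:
        th = np.concatenate([np.full(model.n_delays - th.size, th[0]), th])
    if v.size != model.n_delays or th.size != model.n_delays:
        raise ValueError("windows longer than n_delays")
    x = np.concatenate([v, th])
    return (x - model.input_mean) / model.input_scale, padded


def build_input_matrix(v_z: np.ndarray, theta: np.ndarray, n_delays: int = N_DELAYS) -> np.ndarray:
    """Raw tapped-delay matrix (N, 2*n_delays) for a whole stream, causal."""
    if len(v_z) != len(theta):
        raise ValueError("v_z and theta must share length")
    return np.hstack([_windows(v_z, n_delays), _windows(theta, n_delays)])


def _hidden(model: NetworkModel, X: np.ndarray) -> np.ndarray:
    return logsig(X @ model.w_h.T + model.b_h)


def forward(model: NetworkModel, x: np.ndarray) -> np.ndarray:
    """Network output for one standardized input vector (or a batch).

    Hidden layer ``a_h = logsig(w_h x + b_h)``, linear output
    ``y = w_o a_h + b_o`` — unbounded reals.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != 2 * model.n_delays:
        raise ValueError(f"input must have {2 * model.n_delays} elements")
    Y = _hidden(model, X) @ model.w_o.T + model.b_o
    return Y[0] if single else Y


def cost(model: NetworkModel, data: TrainingSet) -> tuple[float, float, float]:
    """Regularized cost ``(E, E_D, E_w)`` with E = alpha*E_D + beta*E_w.

    ``data.X`` is standardized with the model's constants before evaluation.
    """
    if data.X.shape[0] == 0:
        raise ValueError("training set is empty")
    Xs = (data.X - model.input_mean) / model.input_scale
    R = data.T - forward(model, Xs)
    E_D = float(np.sum(R * R))
    E_w = float(sum(np.sum(a * a) for a in (model.w_h, model.b_h, model.w_o, model.b_o)))
    return model.alpha * E_D + model.beta * E_w, E_D, E_w


def _nguyen_widrow_init(rng: np.random.Generator, n_in: int, n_hidden: int, n_out: int):
    """Seeded small-uniform initialization with Nguyen–Widrow hidden scaling."""
    w_h = rng.uniform(-0.5, 0.5, size=(n_hidden, n_in))
    norm = 0.7 * n_hidden ** (1.0 / n_in)
    w_h *= norm / np.linalg.norm(w_h, axis=1, keepdims=True)
    b_h = norm * np.linspace(-1.0, 1.0, n_hidden) * np.sign(w_h[:, 0])
    w_o = rng.uniform(-0.5, 0.5, size=(n_out, n_hidden))
    b_o = rng.uniform(-0.5, 0.5, size=n_out)
    return w_h, b_h, w_o, b_o


def _residuals(model: NetworkModel, Xs: np.ndarray, T: np.ndarray):
    """Residuals r = t - y (flattened) and the hidden activations."""
    A = _hidden(model, Xs)
    Y = A @ model.w_o.T + model.b_o
    return (T - Y).reshape(-1), A


def _jacobian(model: NetworkModel, Xs: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Jacobian J = dy/dtheta, shape (3N, k), from cached activations."""
    N = Xs.shape[0]
    h, o, n_in = model.n_hidden, model.n_out, 2 * model.n_delays
    S = A * (1.0 - A)                           # logsig derivative
    # dy_m/dw_h[j,i] = w_o[m,j] * s_j * x_i
    WS = model.w_o[None, :, :] * S[:, None, :]              # (N, o, h)
    Jwh = (WS[:, :, :, None] * Xs[:, None, None, :]).reshape(N, o, h * n_in)
    Jbh = WS                                                # (N, o, h)
    Jwo = np.zeros((N, o, o, h))
    for m in range(o):
        Jwo[:, m, m, :] = A
    Jwo = Jwo.reshape(N, o, o * h)
    Jbo = np.broadcast_to(np.eye(o), (N, o, o))
    return np.concatenate([Jwh, Jbh, Jwo, Jbo], axis=2).reshape(N * o, -1)


def train(data: TrainingSet, cfg: TrainConfig | None = None) -> tuple[NetworkModel, dict]:
    """Fit the network by Levenberg–Marquardt with Bayesian regularization.

    Returns ``(model, record)`` where ``record`` holds the per-epoch trace
    (cost at the governing ``alpha, beta`` before and after each accepted
    step, the damping, and the evidence quantities) for diagnostics.

    Raises ``ValueError`` on degenerate data (fewer than 10 samples or a
    single target class) and :class:`TrainingFailureError` if the damped
    Hessian stays singular up to the damping ceiling.
    """
    cfg = cfg or TrainConfig()
    X, T = data.X, data.T
    N = X.shape[0]
    if N < 10:
        raise ValueError("need at least 10 training samples")
    if len(set(map(tuple, T))) < 2:
        raise ValueError("degenerate training data: only one target class present")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    Xs = (X - mean) / scale

    rng = np.random.default_rng(cfg.seed)
    w_h, b_h, w_o, b_o = _nguyen_widrow_init(rng, X.shape[1], N_HIDDEN, N_OUT)
    model = NetworkModel(w_h=w_h, b_h=b_h, w_o=w_o, b_o=b_o,
                         input_mean=mean, input_scale=scale,
                         alpha=cfg.alpha_init, beta=cfg.beta_init)

    theta = model.pack()
    k = theta.size
    n_resid = N * N_OUT
    alpha, beta = cfg.alpha_init, cfg.beta_init
    mu = cfg.mu_init
    eye = np.eye(k)
    trace: list[dict] = []
    stop = "max_epochs"

    R, A = _residuals(model, Xs, T)
    J = _jacobian(model, Xs, A)
    E_D = float(R @ R)
    E_w = float(theta @ theta)

    for epoch in range(cfg.max_epochs):
        E = alpha * E_D + beta * E_w
        grad = -2.0 * alpha * (J.T @ R) + 2.0 * beta * theta
        if np.max(np.abs(grad)) < cfg.tol_grad:
            stop = "gradient"
            break
        JtJ = J.T @ J

        accepted = False
        while mu <= cfg.mu_max:
            H = 2.0 * alpha * JtJ + 2.0 * beta * eye
            try:
                step = np.linalg.solve(H + mu * eye, -grad)
            except np.linalg.LinAlgError:
                mu *= cfg.mu_inc
                continue
            if not np.all(np.isfinite(step)):
                mu *= cfg.mu_inc
                continue
            theta_new = theta + step
            model.unpack(theta_new)
            R_new, A_new = _residuals(model, Xs, T)
            E_D_new = float(R_new @ R_new)
            E_w_new = float(theta_new @ theta_new)
            E_new = alpha * E_D_new + beta * E_w_new
            if E_new < E:
                accepted = True
                theta, R = theta_new, R_new
                J = _jacobian(model, Xs, A_new)
                E_D, E_w = E_D_new, E_w_new
                mu = max(mu * cfg.mu_dec, 1e-20)
                break
            mu *= cfg.mu_inc
        if not accepted:
            model.unpack(theta)
            if mu > cfg.mu_max and np.max(np.abs(grad)) > 1e3 * cfg.tol_grad:
                raise TrainingFailureError(
                    "damped Hessian singular or no descent up to damping ceiling"
                )
            stop = "no_improving_step"
            break

        entry = {"epoch": epoch, "alpha": alpha, "beta": beta, "mu": mu,
                 "E_before": E, "E_after": E_new, "E_D": E_D, "E_w": E_w}

        if (epoch + 1) % cfg.reestimate_every == 0:
            H = 2.0 * alpha * (J.T @ J) + 2.0 * beta * eye
            tr_Hinv = float(np.trace(np.linalg.inv(H)))
            gamma = np.clip(k - 2.0 * beta * tr_Hinv, 1e-3, k)
            beta = float(gamma / max(2.0 * E_w, 1e-12))
            alpha = float(max(n_resid - gamma, 1e-3) / max(2.0 * E_D, 1e-12))
            entry["gamma"] = float(gamma)
        trace.append(entry)

        if abs(E - E_new) < cfg.tol_cost:
            stop = "cost_change"
            break

    model.unpack(theta)
    model.alpha, model.beta = alpha, beta
    record = {"trace": trace, "stop": stop, "epochs": len(trace)}
    return model, record


def predict_stream(model: NetworkModel, signals: ProcessedSignals) -> np.ndarray:
    """Raw network outputs for every sample of a processed stream.

    Causal tapped-delay windows; the first ``n_delays - 1`` samples use the
    front-padding rule.  Returns an (N, 3) array.
    """
    if len(signals) == 0:
        raise ValueError("empty signal stream")
    X = build_input_matrix(signals.v_z, signals.theta, model.n_delays)
    Xs = (X - model.input_mean) / model.input_scale
    return forward(model, Xs)
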