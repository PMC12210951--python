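"""Feed-forward surrogate with Bayesian-regularized Levenberg-Marquardt training.

The surrogate maps three medium-component concentrations (glucose, peptone,
sweet corn juice) to the viable count of the culture.  It is a small
fully-connected network — 3 inputs, one hidden layer of tanh units
(3 by default), one linear output — trained by minimizing the regularized
objective

    F(w) = beta * SSE + alpha * SSW,

where SSE is the sum of squared prediction errors, SSW the sum of squared
weights, and the hyperparameters are re-estimated during training by the
MacKay evidence approximation: after each accepted Levenberg-Marquardt
step,

    gamma = k - 2 alpha * tr(H^-1)       (effective number of parameters)
    alpha = gamma / (2 SSW)
    beta  = (n - gamma) / (2 SSE)

with H = 2 beta J'J + 2 alpha I the Gauss-Newton Hessian of F and k the
total weight count.  Inputs and target are min-max scaled to [-1, 1]
before training, which keeps the tanh units in range and makes the weight
prior meaningful.

Everything here is deterministic given the seed: weight initialization and
cross-validation fold shuffling are the only stochastic elements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Scaler",
    "MLP",
    "TrainConfig",
    "TrainState",
    "CVReport",
    "Committee",
    "fit_scaler",
    "mlp_forward",
    "train_bayesian_lm",
    "train_committee",
    "kfold_cv",
    "regression_metrics",
]


@dataclass(frozen=True)
class Scaler:
    """Per-feature affine map onto [lo, hi] (default [-1, 1])."""

    data_min: np.ndarray
    data_max: np.ndarray
    lo: float = -1.0
    hi: float = 1.0

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        frac = (X - self.data_min) / (self.data_max - self.data_min)
        out = self.lo + frac * (self.hi - self.lo)
        if np.any(out < self.lo - 1e-12) or np.any(out > self.hi + 1e-12):
            logger.warning("scaler applied outside its fitted range (extrapolating)")
        return out

    def unapply(self, Xs: np.ndarray) -> np.ndarray:
        Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
        frac = (Xs - self.lo) / (self.hi - self.lo)
        return self.data_min + frac * (self.data_max - self.data_min)


def fit_scaler(X: np.ndarray, lo: float = -1.0, hi: float = 1.0) -> Scaler:
    """Fit a min-max scaler so each feature spans exactly [lo, hi]."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    dmin, dmax = X.min(axis=0), X.max(axis=0)
    const = np.flatnonzero(dmax == dmin)
    if const.size:
        raise ValueError(f"feature {int(const[0])} is constant; cannot min-max scale")
    return Scaler(data_min=dmin, data_max=dmax, lo=lo, hi=hi)


@dataclass
class MLP:
    """One-hidden-layer tanh network with a linear output unit.

    ``hidden_w`` is (n_hidden, n_in); ``out_w`` is (n_hidden,).  With more
    than one hidden layer, ``extra_w``/``extra_b`` chain additional square
    tanh layers between the first hidden layer and the output.
    """

    hidden_w: np.ndarray
    hidden_b: np.ndarray
    out_w: np.ndarray
    out_b: float
    extra_w: tuple[np.ndarray, ...] = ()
    extra_b: tuple[np.ndarray, ...] = ()

    def __post_init__(self) -> None:
        h, n_in = self.hidden_w.shape
        if self.hidden_b.shape != (h,):
            raise ValueError("hidden bias shape mismatch")
        for W, b in zip(self.extra_w, self.extra_b):
            if W.shape != (h, h) or b.shape != (h,):
                raise ValueError("extra layer shape mismatch")
        if self.out_w.shape != (h,):
            raise ValueError("output weight shape mismatch")

    @property
    def n_in(self) -> int:
        return self.hidden_w.shape[1]

    @property
    def n_weights(self) -> int:
        k = self.hidden_w.size + self.hidden_b.size + self.out_w.size + 1
        for W, b in zip(self.extra_w, self.extra_b):
            k += W.size + b.size
        return k

    def get_weights(self) -> np.ndarray:
        parts = [self.hidden_w.ravel(), self.hidden_b]
        for W, b in zip(self.extra_w, self.extra_b):
            parts.extend([W.ravel(), b])
        parts.extend([self.out_w, [self.out_b]])
        return np.concatenate(parts)

    def set_weights(self, w: np.ndarray) -> None:
        w = np.asarray(w, dtype=float)
        if w.size != self.n_weights:
            raise ValueError("weight vector length mismatch")
        i = 0

        def take(shape):
            nonlocal i
            size = int(np.prod(shape))
            out = w[i:i + size].reshape(shape)
            i += size
            return out

        self.hidden_w = take(self.hidden_w.shape)
        self.hidden_b = take(self.hidden_b.shape)
        self.extra_w = tuple(take(W.shape) for W in self.extra_w)
        self.extra_b = tuple(take(b.shape) for b in self.extra_b)
        self.out_w = take(self.out_w.shape)
        self.out_b = float(w[i])

    def to_dict(self) -> dict:
        return {
            "hidden_w": self.hidden_w.tolist(),
            "hidden_b": self.hidden_b.tolist(),
            "extra_w": [W.tolist() for W in self.extra_w],
            "extra_b": [b.tolist() for b in self.extra_b],
            "out_w": self.out_w.tolist(),
            "out_b": self.out_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        return cls(
            hidden_w=np.asarray(d["hidden_w"], dtype=float),
            hidden_b=np.asarray(d["hidden_b"], dtype=float),
            out_w=np.asarray(d["out_w"], dtype=float),
            out_b=float(d["out_b"]),
            extra_w=tuple(np.asarray(W, dtype=float) for W in d.get("extra_w", [])),
            extra_b=tuple(np.asarray(b, dtype=float) for b in d.get("extra_b", [])),
        )


def mlp_forward(net: MLP, X: np.ndarray) -> np.ndarray:
    """Network output for scaled inputs X (n, n_in) -> (n,)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.n_in:
        raise ValueError(f"expected {net.n_in} input features, got {X.shape[1]}")
    h = np.tanh(X @ net.hidden_w.T + net.hidden_b)
    for W, b in zip(net.extra_w, net.extra_b):
        h = np.tanh(h @ W.T + b)
    return h @ net.out_w + net.out_b


def _forward_with_jacobian(net: MLP, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Output and Jacobian d yhat / d w, columns ordered as get_weights()."""
    n = X.shape[0]
    acts = [X]
    h = np.tanh(X @ net.hidden_w.T + net.hidden_b)
    acts.append(h)
    for W, b in zip(net.extra_w, net.extra_b):
        h = np.tanh(h @ W.T + b)
        acts.append(h)
    y = h @ net.out_w + net.out_b

    # backprop a unit output sensitivity through the tanh stack
    cols = []
    # delta at the top hidden layer
    delta = net.out_w * (1.0 - acts[-1] ** 2)  # (n, h)
    deltas = [delta]
    for li in range(len(net.extra_w) - 1, -1, -1):
        delta = (deltas[0] @ net.extra_w[li]) * (1.0 - acts[li + 1] ** 2)
        deltas.insert(0, delta)
    # first hidden layer weights/biases
    d0 = deltas[0]
    cols.append((d0[:, :, None] * acts[0][:, None, :]).reshape(n, -1))
    cols.append(d0)
    for li, W in enumerate(net.extra_w):
        dl = deltas[li + 1]
        cols.append((dl[:, :, None] * acts[li + 1][:, None, :]).reshape(n, -1))
        cols.append(dl)
    cols.append(acts[-1])           # d y / d out_w
    cols.append(np.ones((n, 1)))    # d y / d out_b
    return y, np.concatenate(cols, axis=1)


@dataclass
class TrainConfig:
    """Settings for Bayesian-regularized Levenberg-Marquardt training.

    The run starts in a warmup phase with negligible weight decay
    (``alpha0``); evidence re-estimation of alpha and beta begins only once
    that pure least-squares phase has converged (gradient below
    ``warmup_grad_tol``) or ``warmup_max_epochs`` have elapsed — starting
    the updates from an unconverged small-weight state routinely locks the
    fixed-point iteration into an over-regularized equilibrium.
    ``n_restarts`` seeded restarts are run and the one with the lowest
    final data SSE kept; the whole procedure is deterministic per seed.
    """

    n_hidden: int = 3
    n_hidden_layers: int = 1
    max_epochs: int = 300
    mu0: float = 0.005
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    grad_tol: float = 1e-7
    warmup_grad_tol: float = 1e-6
    warmup_max_epochs: int = 150
    alpha0: float = 1e-7
    beta0: float = 1.0
    alpha_max: float = 1e6
    beta_max: float = 1e12
    init_scale: float = 0.5
    n_restarts: int = 3


@dataclass
class TrainState:
    """Hyperparameter and convergence trace of one training run."""

    alpha: float
    beta: float
    gamma: float
    mu: float
    epochs: int
    objective_history: list[float] = field(default_factory=list)
    sse: float = math.nan
    ssw: float = math.nan
    stop_reason: str = ""


def train_bayesian_lm(X: np.ndarray, y: np.ndarray,
                      config: Optional[TrainConfig] = None,
                      seed: int = 0) -> tuple[MLP, TrainState]:
    """Train the surrogate on *scaled* data by Bayesian-regularized LM.

    X is (n, n_in) and y (n,) — both already scaled to [-1, 1].  Runs
    ``config.n_restarts`` seeded weight initializations and returns the
    network with the lowest final data SSE together with its hyperparameter
    trace.  Deterministic for a fixed seed.
    """
    config = config or TrainConfig()
    best: Optional[tuple[MLP, TrainState]] = None
    for r in range(max(config.n_restarts, 1)):
        net, state = _train_single(X, y, config, seed + 7919 * r)
        if best is None or state.sse < best[1].sse:
            best = (net, state)
    return best


def _train_single(X: np.ndarray, y: np.ndarray, config: TrainConfig,
                  seed: int) -> tuple[MLP, TrainState]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, n_in = X.shape
    if len(y) != n:
        raise ValueError("X and y lengths differ")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("training data must be finite")
    rng = np.random.default_rng(seed)
    h = config.n_hidden
    extra = config.n_hidden_layers - 1
    net = MLP(
        hidden_w=rng.uniform(-config.init_scale, config.init_scale, (h, n_in)),
        hidden_b=rng.uniform(-config.init_scale, config.init_scale, h),
        out_w=rng.uniform(-config.init_scale, config.init_scale, h),
        out_b=float(rng.uniform(-config.init_scale, config.init_scale)),
        extra_w=tuple(rng.uniform(-config.init_scale, config.init_scale, (h, h))
                      for _ in range(extra)),
        extra_b=tuple(rng.uniform(-config.init_scale, config.init_scale, h)
                      for _ in range(extra)),
    )
    k = net.n_weights
    if n < k / 3:
        logger.warning("only %d samples for %d weights; fit may be underdetermined", n, k)

    alpha, beta, mu = config.alpha0, config.beta0, config.mu0
    w = net.get_weights()
    yhat, J = _forward_with_jacobian(net, X)
    e = yhat - y
    sse, ssw = float(e @ e), float(w @ w)
    obj = beta * sse + alpha * ssw
    state = TrainState(alpha=alpha, beta=beta, gamma=float(k), mu=mu,
                       epochs=0, objective_history=[obj], sse=sse, ssw=ssw)

    warmup = True
    for epoch in range(config.max_epochs):
        grad = 2.0 * beta * (J.T @ e) + 2.0 * alpha * w
        gnorm = np.linalg.norm(grad, ord=np.inf)
        if warmup and (gnorm < config.warmup_grad_tol
                       or epoch >= config.warmup_max_epochs):
            warmup = False
        if not warmup and gnorm < config.grad_tol:
            state.stop_reason = "gradient tolerance"
            break
        H = 2.0 * beta * (J.T @ J) + 2.0 * alpha * np.eye(k)
        accepted = False
        while mu <= config.mu_max:
            try:
                step = np.linalg.solve(H + mu * np.eye(k), -grad)
            except np.linalg.LinAlgError:
                mu *= config.mu_inc
                continue
            w_new = w + step
            net.set_weights(w_new)
            yhat_new, J_new = _forward_with_jacobian(net, X)
            e_new = yhat_new - y
            sse_new = float(e_new @ e_new)
            ssw_new = float(w_new @ w_new)
            obj_new = beta * sse_new + alpha * ssw_new
            if not math.isfinite(obj_new):
                raise FloatingPointError(
                    f"non-finite training objective at epoch {epoch}")
            if obj_new < obj:
                accepted = True
                w, e, J = w_new, e_new, J_new
                sse, ssw = sse_new, ssw_new
                mu = max(mu * config.mu_dec, 1e-20)
                break
            mu *= config.mu_inc
        if not accepted:
            net.set_weights(w)
            state.stop_reason = "mu overflow"
            break
        if not warmup:
            # MacKay evidence update on the new point
            H = 2.0 * beta * (J.T @ J) + 2.0 * alpha * np.eye(k)
            try:
                tr_hinv = float(np.trace(np.linalg.inv(H)))
            except np.linalg.LinAlgError:
                tr_hinv = float(np.trace(np.linalg.pinv(H)))
            gamma = k - 2.0 * alpha * tr_hinv
            gamma = min(max(gamma, 0.0), float(k))
            if ssw > 0:
                alpha = min(max(gamma / (2.0 * ssw), 1e-12), config.alpha_max)
            if sse > 0 and n > gamma:
                beta = min(max((n - gamma) / (2.0 * sse), 1e-12), config.beta_max)
            state.alpha, state.beta, state.gamma = alpha, beta, gamma
        obj = beta * sse + alpha * ssw
        state.mu = mu
        state.objective_history.append(obj)
        state.epochs = epoch + 1
    else:
        state.stop_reason = "max epochs"
    if not state.stop_reason:
        state.stop_reason = state.stop_reason or "converged"
    net.set_weights(w)
    state.sse, state.ssw = sse, ssw
    return net, state


@dataclass(frozen=True)
class Committee:
    """A committee of independently trained networks; predictions are the
    member mean.  Averaging over restarts damps the idiosyncratic
    between-point wiggle of any single near-interpolating member, which
    matters when the surrogate is optimized rather than merely evaluated
    at the design points."""

    members: tuple[MLP, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.mean([mlp_forward(m, X) for m in self.members], axis=0)


def train_committee(X: np.ndarray, y: np.ndarray,
                    config: Optional[TrainConfig] = None,
                    seed: int = 0, n_members: int = 12,
                    keep_factor: float = 2.0) -> tuple[Committee, list[TrainState]]:
    """Train ``n_members`` independently initialized networks and keep the
    ones whose final data SSE is within ``keep_factor`` of the best.

    Returns the committee of kept members and the full list of training
    states (kept or not).  Deterministic per seed.
    """
    config = config or TrainConfig()
    runs = [_train_single(X, y, config, seed + 7919 * r) for r in range(n_members)]
    best_sse = min(st.sse for _, st in runs)
    cut = max(keep_factor * best_sse, best_sse + 1e-6)
    members = tuple(net for net, st in runs if st.sse <= cut)
    return Committee(members=members), [st for _, st in runs]


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float]:
    """Return (RMSE, R^2, MAE)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    err = yhat - y
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined: target values are constant")
    r2 = 1.0 - float(np.sum(err ** 2)) / sst
    return rmse, r2, mae


@dataclass(frozen=True)
class CVReport:
    """Per-fold and mean regression metrics from k-fold cross-validation.

    ``folds`` maps partition name ('train', 'validation', 'test') to a list
    of per-fold (RMSE, R^2, MAE) tuples; ``means`` to their arithmetic
    means.  The held-out fold serves as the test partition; a slice of the
    training portion is set aside as a validation partition for reporting.
    """

    k: int
    folds: dict[str, list[tuple[float, float, float]]]
    means: dict[str, tuple[float, float, float]]
    #: metrics over the *concatenated* partition predictions; for 'test'
    #: this is the usual cross-validated Q2-style summary, far more stable
    #: than fold-wise R2 when folds are tiny
    pooled: dict[str, tuple[float, float, float]]


def kfold_cv(X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0,
             config: Optional[TrainConfig] = None,
             val_fraction: float = 0.15,
             n_committee: int = 0) -> CVReport:
    """k-fold cross-validation of the surrogate with a seeded shuffle.

    Inputs are in physical units; scaling is re-fitted inside every fold on
    its training portion only.  Metrics are reported in the original target
    units.  With ``n_committee`` > 0 each fold trains a committee of that
    many members instead of a single network.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available samples")
    if k < 2:
        raise ValueError("need k >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.array_split(order, k)
    folds: dict[str, list[tuple[float, float, float]]] = {
        "train": [], "validation": [], "test": []}
    collected: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
        "train": [], "validation": [], "test": []}
    for fi, test_idx in enumerate(fold_ids):
        rest = np.concatenate([f for j, f in enumerate(fold_ids) if j != fi])
        n_val = max(1, int(round(val_fraction * len(rest)))) if val_fraction > 0 else 0
        val_idx, train_idx = rest[:n_val], rest[n_val:]
        xs = fit_scaler(X[train_idx])
        ys = fit_scaler(y[train_idx].reshape(-1, 1))
        Xtr = xs.apply(X[train_idx])
        ytr = ys.apply(y[train_idx].reshape(-1, 1)).ravel()
        if n_committee > 0:
            model, _ = train_committee(Xtr, ytr, config=config, seed=seed + fi,
                                       n_members=n_committee)
            raw_predict = model.predict
        else:
            net, _ = train_bayesian_lm(Xtr, ytr, config=config, seed=seed + fi)
            raw_predict = lambda Xq: mlp_forward(net, Xq)  # noqa: E731

        def predict(idx):
            return ys.unapply(
                raw_predict(xs.apply(X[idx])).reshape(-1, 1)).ravel()

        def metrics(idx):
            # R^2 is undefined on singleton or constant partitions
            yv, pv = y[idx], predict(idx)
            if len(idx) < 2 or np.ptp(yv) == 0:
                err = np.abs(pv - yv)
                return (float(np.sqrt(np.mean(err ** 2))), math.nan,
                        float(np.mean(err)))
            return regression_metrics(yv, pv)

        folds["train"].append(metrics(train_idx))
        collected["train"].append((y[train_idx], predict(train_idx)))
        folds["test"].append(metrics(test_idx))
        collected["test"].append((y[test_idx], predict(test_idx)))
        if n_val:
            folds["validation"].append(metrics(val_idx))
            collected["validation"].append((y[val_idx], predict(val_idx)))
    means = {part: tuple(float(np.mean([m[i] for m in ms])) for i in range(3))
             for part, ms in folds.items() if ms}
    pooled = {}
    for part, pairs in collected.items():
        if pairs:
            yy = np.concatenate([p[0] for p in pairs])
            pp = np.concatenate([p[1] for p in pairs])
            pooled[part] = regression_metrics(yy, pp)
    return CVReport(k=k, folds=folds, means=means, pooled=pooled)
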