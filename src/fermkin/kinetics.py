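"""Coupled logistic / Luedeking-Piret fermentation kinetics.

Growth of the culture is described by a logistic law on the *increment* of
the log-scale viable count above its initial load,

    dX~/dt = c * X~ * (1 - X~/b),        X~(0) = a,

whose integral, shifted by the baseline load ``d``, gives the closed form

    X(t) = a e^{ct} / D(t) + d,          D(t) = 1 - (a/b)(1 - e^{ct}).

Product formation follows the Luedeking-Piret partition into a
growth-associated term ``m`` and a non-growth-associated term ``n``
applied to the same logistic increment,

    P(t) = P0 + m g(t) + (n b / c) ln D(t),     g(t) = a e^{ct} / D(t),

and substrate consumption mirrors it with coefficients ``M``, ``N`` and a
flipped sign,

    S(t) = S0 - M g(t) - (N b / c) ln D(t).

All three closed forms are fitted to time series by bound-constrained
trust-region nonlinear least squares, with some coefficients optionally
held fixed (the product and substrate fits inherit ``a`` and ``c`` from the
growth fit).  Goodness of fit follows the convention RMSE = sqrt(SSE / (n -
p)) with p counting only the *free* coefficients, and 95% confidence
intervals come from the linearized-Jacobian covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .datasets import FermentationSeries

__all__ = [
    "GrowthParams",
    "ProductParams",
    "SubstrateParams",
    "Constraint",
    "KineticFit",
    "GROWTH_CONSTRAINTS",
    "PRODUCT_CONSTRAINTS",
    "SUBSTRATE_CONSTRAINTS",
    "logistic_denominator",
    "logistic_increment",
    "eval_growth",
    "eval_product",
    "eval_substrate",
    "ode_rhs",
    "fit_growth",
    "fit_product",
    "fit_substrate",
    "gof_metrics",
    "confidence_intervals",
    "DEFAULT_INITIAL_GLUCOSE",
]

#: Residual-glucose offset used to reconstruct S(t) from cumulative
#: consumption when the caller does not supply one (matches the fitted
#: initial substrate level of the study culture, g/L).
DEFAULT_INITIAL_GLUCOSE = 30.44


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth coefficients on the lg-count increment.

    a: initial increment (lg CFU/mL); b: carrying-capacity increment
    (lg CFU/mL); c: maximum specific growth rate (1/h); d: baseline
    initial load (lg CFU/mL).
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError("a, b and c must be positive")
        if self.d < 0:
            raise ValueError("d must be non-negative")
        if self.a > self.b:
            raise ValueError("initial increment a cannot exceed capacity b")


@dataclass(frozen=True)
class ProductParams:
    """Luedeking-Piret product coefficients plus the shared growth shape."""

    p0: float
    m: float
    n: float
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.p0 < 0:
            raise ValueError("p0 must be non-negative")
        if not (self.b > self.a > 0 and self.c > 0):
            raise ValueError("need b > a > 0 and c > 0")


@dataclass(frozen=True)
class SubstrateParams:
    """Modified Luedeking-Piret substrate coefficients plus growth shape."""

    s0: float
    M: float
    N: float
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.b > self.a > 0 and self.c > 0):
            raise ValueError("need b > a > 0 and c > 0")


@dataclass(frozen=True)
class Constraint:
    """Start value and box bounds for one coefficient; lower == upper fixes it."""

    start: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if not (self.lower <= self.start <= self.upper):
            raise ValueError(
                f"start {self.start} outside bounds [{self.lower}, {self.upper}]")

    @property
    def fixed(self) -> bool:
        return self.lower == self.upper


#: Default fitting constraints (start / lower / upper) for each model.
GROWTH_CONSTRAINTS: dict[str, Constraint] = {
    "a": Constraint(0.05, 0.0, np.inf),
    "b": Constraint(2.0, 0.0, np.inf),
    "c": Constraint(0.5, 0.0, np.inf),
    "d": Constraint(7.6, 0.0, np.inf),
}

PRODUCT_CONSTRAINTS: dict[str, Constraint] = {
    "p0": Constraint(0.0, 0.0, np.inf),
    "a": Constraint(0.0477, 0.0477, 0.0477),
    "b": Constraint(2.0, 2.0, 10.0),
    "c": Constraint(0.6830, 0.6830, 0.6830),
    "m": Constraint(0.9),
    "n": Constraint(0.02),
}

SUBSTRATE_CONSTRAINTS: dict[str, Constraint] = {
    "s0": Constraint(0.0),
    "a": Constraint(0.0477, 0.0477, 0.0477),
    "b": Constraint(2.0, 2.0, np.inf),
    "c": Constraint(0.6830, 0.6830, 0.6830),
    "M": Constraint(0.9),
    "N": Constraint(0.02),
}


@dataclass(frozen=True)
class KineticFit:
    """Result of a constrained nonlinear least-squares kinetic fit."""

    model: str
    params: dict[str, float]
    free_names: tuple[str, ...]
    ci: dict[str, tuple[float, float]]
    cov: Optional[np.ndarray]
    r_squared: float
    rmse: float
    sse: float
    residuals: np.ndarray
    dfe: int
    converged: bool
    n_iter: int

    def __getitem__(self, name: str) -> float:
        return self.params[name]


# --- closed-form model evaluation ------------------------------------------


def logistic_denominator(t, a: float, b: float, c: float):
    """D(t) = 1 - (a/b)(1 - e^{ct}); must stay positive for a valid state."""
    t = np.asarray(t, dtype=float)
    return 1.0 - (a / b) * (1.0 - np.exp(c * t))


def logistic_increment(t, a: float, b: float, c: float):
    """g(t) = a e^{ct} / D(t), the logistic solution with g(0) = a."""
    t = np.asarray(t, dtype=float)
    den = logistic_denominator(t, a, b, c)
    if np.any(den <= 0):
        raise ValueError("logistic denominator is non-positive for these parameters")
    return a * np.exp(c * t) / den


def eval_growth(t, p: GrowthParams):
    """Viable count X(t) = g(t) + d in lg CFU/mL."""
    return logistic_increment(t, p.a, p.b, p.c) + p.d


def eval_product(t, p: ProductParams):
    """Lactic acid P(t) = P0 + m g(t) + (n b / c) ln D(t) in g/L."""
    den = logistic_denominator(t, p.a, p.b, p.c)
    if np.any(np.asarray(den) <= 0):
        raise ValueError("logistic denominator is non-positive for these parameters")
    g = p.a * np.exp(p.c * np.asarray(t, dtype=float)) / den
    return p.p0 + p.m * g + (p.n * p.b / p.c) * np.log(den)


def eval_substrate(t, p: SubstrateParams):
    """Residual glucose S(t) = S0 - M g(t) - (N b / c) ln D(t) in g/L."""
    den = logistic_denominator(t, p.a, p.b, p.c)
    if np.any(np.asarray(den) <= 0):
        raise ValueError("logistic denominator is non-positive for these parameters")
    g = p.a * np.exp(p.c * np.asarray(t, dtype=float)) / den
    return p.s0 - p.M * g - (p.N * p.b / p.c) * np.log(den)


def ode_rhs(kind: str, state: float, t: float, params) -> float:
    """Right-hand side of the differential form of each model.

    kind='growth': dX~/dt = c X~ (1 - X~/b) with state = X~ (the increment);
    kind='product': dP/dt = m dX~/dt + n X~ evaluated along the logistic
    trajectory at time t; kind='substrate': the sign-flipped analogue.
    For 'product'/'substrate' the state argument is ignored (the biomass
    trajectory is the closed-form logistic increment at time t).
    """
    if kind == "growth":
        x = state
        return params.c * x * (1.0 - x / params.b)
    g = float(logistic_increment(t, params.a, params.b, params.c))
    dg = params.c * g * (1.0 - g / params.b)
    if kind == "product":
        return params.m * dg + params.n * g
    if kind == "substrate":
        return -params.M * dg - params.N * g
    raise ValueError(f"unknown model kind {kind!r}")


# --- goodness of fit --------------------------------------------------------


def gof_metrics(observed, predicted, n_free_params: int) -> tuple[float, float, float]:
    """Return (R^2, RMSE, SSE) with RMSE = sqrt(SSE / (n - n_free_params)).

    R^2 is 1 - SSE/SST with SST about the observed mean.  The degrees of
    freedom count only free coefficients, so fixed ones do not shrink the
    denominator.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    n = len(observed)
    dfe = n - n_free_params
    if dfe < 1:
        raise ValueError(f"need more observations than free parameters (n={n}, p={n_free_params})")
    sse = float(np.sum((observed - predicted) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined: observed values are constant (SST = 0)")
    return 1.0 - sse / sst, math.sqrt(sse / dfe), sse


# --- fitting ----------------------------------------------------------------


def _fit(model: str, names: Sequence[str],
         predict: Callable[[Mapping[str, float], np.ndarray], np.ndarray],
         t: np.ndarray, y: np.ndarray,
         constraints: Mapping[str, Constraint]) -> KineticFit:
    missing = [k for k in names if k not in constraints]
    if missing:
        raise ValueError(f"{model} fit needs constraints for {missing}")
    fixed = {k: constraints[k].start for k in names if constraints[k].fixed}
    free = [k for k in names if not constraints[k].fixed]
    n = len(t)
    if n < len(free) + 1:
        raise ValueError(
            f"{model} fit needs at least {len(free) + 1} points for {len(free)} "
            f"free coefficients, got {n}")

    def unpack(theta: np.ndarray) -> dict[str, float]:
        p = dict(fixed)
        p.update(zip(free, theta))
        return p

    def resid(theta: np.ndarray) -> np.ndarray:
        return predict(unpack(theta), t) - y

    x0 = np.array([constraints[k].start for k in free])
    lb = np.array([constraints[k].lower for k in free])
    ub = np.array([constraints[k].upper for k in free])
    # nudge starts off active bounds so the trust-region solver can move
    span = np.where(np.isfinite(ub - lb), ub - lb, 1.0)
    x0 = np.clip(x0, lb + 1e-12 * span, ub - 1e-12 * span)
    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-10, max_nfev=1000)
    params = unpack(sol.x)
    r = sol.fun
    dfe = n - len(free)
    r2, rmse, sse = gof_metrics(y, predict(params, t), len(free))
    cov = None
    if dfe >= 1:
        J = sol.jac
        JtJ = J.T @ J
        try:
            cov = np.linalg.inv(JtJ) * (sse / dfe)
        except np.linalg.LinAlgError:
            cov = None
    fit = KineticFit(
        model=model, params=params, free_names=tuple(free), ci={}, cov=cov,
        r_squared=r2, rmse=rmse, sse=sse, residuals=r, dfe=dfe,
        converged=bool(sol.status > 0), n_iter=int(sol.nfev),
    )
    object.__setattr__(fit, "ci", confidence_intervals(fit))
    return fit


def confidence_intervals(fit: KineticFit, level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Wald intervals estimate +/- t(level, dfe) * SE per free coefficient.

    Fixed coefficients get degenerate intervals.  If the linearized normal
    matrix was singular, intervals for free coefficients are (-inf, inf).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    tcrit = stats.t.ppf(0.5 + level / 2, fit.dfe)
    ci: dict[str, tuple[float, float]] = {}
    for name, value in fit.params.items():
        if name not in fit.free_names:
            ci[name] = (value, value)
            continue
        if fit.cov is None:
            ci[name] = (-np.inf, np.inf)
            continue
        i = fit.free_names.index(name)
        se = math.sqrt(max(fit.cov[i, i], 0.0))
        ci[name] = (value - tcrit * se, value + tcrit * se)
    return ci


def fit_growth(series: FermentationSeries,
               constraints: Optional[Mapping[str, Constraint]] = None) -> KineticFit:
    """Fit the shifted logistic model to the viable-count column.

    Uses the default start values and box bounds (all four coefficients
    free, non-negative) unless ``constraints`` overrides them.
    """
    if len(series) < 5:
        raise ValueError("growth fit needs at least 5 time points")
    cons = dict(GROWTH_CONSTRAINTS)
    if constraints:
        cons.update(constraints)

    def predict(p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
        return logistic_increment(t, p["a"], p["b"], p["c"]) + p["d"]

    return _fit("growth", ("a", "b", "c", "d"), predict,
                series.time, series.viable_lg, cons)


def fit_product(series: FermentationSeries,
                constraints: Optional[Mapping[str, Constraint]] = None,
                growth_fit: Optional[KineticFit] = None) -> KineticFit:
    """Fit the Luedeking-Piret product model to the lactate column.

    The growth shape coefficients a and c are held fixed — taken from
    ``growth_fit`` when given, otherwise from the default constraint table —
    and are excluded from the error degrees of freedom.
    """
    cons = dict(PRODUCT_CONSTRAINTS)
    if constraints:
        cons.update(constraints)
    if growth_fit is not None:
        for k in ("a", "c"):
            v = growth_fit.params[k]
            cons[k] = Constraint(v, v, v)

    def predict(p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
        den = logistic_denominator(t, p["a"], p["b"], p["c"])
        g = p["a"] * np.exp(p["c"] * t) / den
        return p["p0"] + p["m"] * g + (p["n"] * p["b"] / p["c"]) * np.log(den)

    return _fit("product", ("p0", "a", "b", "c", "m", "n"), predict,
                series.time, series.lactate, cons)


def fit_substrate(series: FermentationSeries,
                  constraints: Optional[Mapping[str, Constraint]] = None,
                  growth_fit: Optional[KineticFit] = None,
                  initial_glucose: float = DEFAULT_INITIAL_GLUCOSE) -> KineticFit:
    """Fit the substrate model to residual glucose ``initial_glucose - consumed``.

    The series records cumulative glucose *consumed*; the model describes
    residual glucose, so the column is reconstructed with a caller-chosen
    offset.  Every output except the fitted s0 is invariant to that offset:
    changing it by delta shifts s0 by exactly delta and nothing else.
    """
    cons = dict(SUBSTRATE_CONSTRAINTS)
    if constraints:
        cons.update(constraints)
    if growth_fit is not None:
        for k in ("a", "c"):
            v = growth_fit.params[k]
            cons[k] = Constraint(v, v, v)
    # fit on the offset-centred scale (y - K, s0 - K) so every output except
    # the reported s0 is exactly invariant to the chosen offset
    K = float(initial_glucose)
    y = -series.glucose_consumed
    s0 = cons["s0"]
    cons["s0"] = Constraint(s0.start - K if s0.start != 0.0 or s0.fixed else 0.0,
                            s0.lower - K if np.isfinite(s0.lower) else s0.lower,
                            s0.upper - K if np.isfinite(s0.upper) else s0.upper)

    def predict(p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
        den = logistic_denominator(t, p["a"], p["b"], p["c"])
        g = p["a"] * np.exp(p["c"] * t) / den
        return p["s0"] - p["M"] * g - (p["N"] * p["b"] / p["c"]) * np.log(den)

    fit = _fit("substrate", ("s0", "a", "b", "c", "M", "N"), predict,
               series.time, y, cons)
    params = dict(fit.params)
    params["s0"] += K
    ci = dict(fit.ci)
    ci["s0"] = (ci["s0"][0] + K, ci["s0"][1] + K)
    object.__setattr__(fit, "params", params)
    object.__setattr__(fit, "ci", ci)
    return fit
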