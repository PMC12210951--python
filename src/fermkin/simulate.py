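"""Synthetic-data generation for every stage of the analysis.

Two generators cover the two kinds of raw data the pipeline consumes:

* :func:`simulate_fermentation` draws batch-culture time series from the
  closed-form logistic / Luedeking-Piret curves with additive homoscedastic
  Gaussian noise per channel — the structure of a real sampled batch run
  (means of triplicate plate counts and titrations at two-hour intervals).
* :func:`simulate_bbd` evaluates a known concave quadratic response surface
  on a Box-Behnken design and adds noise — the structure of a three-factor
  medium-optimization experiment whose interior optimum is known exactly,
  so surrogate training and GA search can be scored against ground truth.

Default parameter values are the fitted coefficients of the study culture
(growth a=0.04773, b=2.106, c=0.683, d=7.582; product m=1.559, n=0.07135,
b=4.821; substrate M=1.858, N=0.09254, b=3.917, s0=30.44) on the 0-14 h
two-hour grid, with noise standard deviations 0.02 lg for counts and
0.15 g/L for the chemistry channels, matching the order of the reported
replicate scatter.  All randomness flows from explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import kinetics
from .ann import TrainConfig, fit_scaler, train_committee
from .datasets import FermentationSeries
from .doe import BBDesign, box_behnken
from .ga import GAConfig, ga_minimize, negate_objective
from .kinetics import GrowthParams, ProductParams, SubstrateParams

__all__ = [
    "SimConfig",
    "SurfaceConfig",
    "DEFAULT_GROWTH",
    "DEFAULT_PRODUCT",
    "DEFAULT_SUBSTRATE",
    "simulate_fermentation",
    "simulate_bbd",
    "recovery_experiment",
]

DEFAULT_GROWTH = GrowthParams(a=0.04773, b=2.106, c=0.683, d=7.582)
DEFAULT_PRODUCT = ProductParams(p0=0.0, m=1.559, n=0.07135, a=0.04772, b=4.821, c=0.683)
DEFAULT_SUBSTRATE = SubstrateParams(s0=30.44, M=1.858, N=0.09254, a=0.0477, b=3.917, c=0.683)


@dataclass(frozen=True)
class SimConfig:
    """Ground truth and noise for a synthetic batch-fermentation series."""

    growth: GrowthParams = DEFAULT_GROWTH
    product: ProductParams = DEFAULT_PRODUCT
    substrate: SubstrateParams = DEFAULT_SUBSTRATE
    time: np.ndarray = field(default_factory=lambda: np.arange(0.0, 16.0, 2.0))
    noise_viable: float = 0.02
    noise_lactate: float = 0.15
    noise_glucose: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        if min(self.noise_viable, self.noise_lactate, self.noise_glucose) < 0:
            raise ValueError("noise standard deviations must be non-negative")


def simulate_fermentation(cfg: SimConfig) -> FermentationSeries:
    """Draw one noisy batch-culture series from the closed-form kinetics.

    The glucose channel is returned as cumulative consumption
    (s0 - S(t)), mirroring how the analysis tabulates it.
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.time
    viable = kinetics.eval_growth(t, cfg.growth)
    lactate = kinetics.eval_product(t, cfg.product)
    consumed = cfg.substrate.s0 - kinetics.eval_substrate(t, cfg.substrate)
    viable = viable + rng.normal(0.0, cfg.noise_viable, t.shape) if cfg.noise_viable else viable
    lactate = lactate + rng.normal(0.0, cfg.noise_lactate, t.shape) if cfg.noise_lactate else lactate
    consumed = consumed + rng.normal(0.0, cfg.noise_glucose, t.shape) if cfg.noise_glucose else consumed
    return FermentationSeries(
        time=t,
        viable_lg=np.maximum(viable, 1e-9),
        lactate=np.maximum(lactate, 0.0),
        glucose_consumed=np.maximum(consumed, 0.0),
    )


@dataclass(frozen=True)
class SurfaceConfig:
    """A concave quadratic response surface over three coded factors.

    The response at coded point x is ``peak + (x - optimum)' Q (x - optimum)``
    with Q negative definite, so ``optimum`` is the unique interior argmax
    and ``peak`` the value there.  Defaults place the optimum strictly
    inside the coded [-1, 1]^3 box with a peak of 9.6 lg CFU/mL and
    curvature strong enough that the edge runs span ~1 lg unit.
    """

    optimum: np.ndarray = field(default_factory=lambda: np.array([0.3, -0.2, 0.4]))
    peak: float = 9.6
    quad: np.ndarray = field(default_factory=lambda: np.array(
        [[-0.50, 0.05, 0.02],
         [0.05, -0.35, 0.03],
         [0.02, 0.03, -0.40]]))
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "optimum", np.asarray(self.optimum, dtype=float))
        object.__setattr__(self, "quad", np.asarray(self.quad, dtype=float))
        if self.quad.shape != (3, 3) or not np.allclose(self.quad, self.quad.T):
            raise ValueError("quadratic part must be a symmetric 3x3 matrix")
        if np.any(np.linalg.eigvalsh(self.quad) >= 0):
            raise ValueError("quadratic part must be negative definite "
                             "(the surface needs an interior maximum)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    def value(self, coded: np.ndarray) -> np.ndarray:
        """Noise-free surface value at coded points (n, 3) or (3,)."""
        x = np.atleast_2d(np.asarray(coded, dtype=float)) - self.optimum
        return self.peak + np.einsum("ni,ij,nj->n", x, self.quad, x)

    def argmax(self) -> np.ndarray:
        """Closed-form maximizer (solves the zero-gradient linear system)."""
        # gradient 2 Q (x - x*) = 0  =>  x = x*
        g0 = -2.0 * self.quad @ self.optimum  # gradient at the origin
        return np.linalg.solve(2.0 * self.quad, -g0)


def simulate_bbd(design: BBDesign, cfg: SurfaceConfig) -> np.ndarray:
    """Responses of the quadratic surface on a Box-Behnken design, with noise."""
    rng = np.random.default_rng(cfg.seed)
    y = cfg.value(design.coded)
    if cfg.noise_sd:
        y = y + rng.normal(0.0, cfg.noise_sd, len(y))
    return y


_DEFAULT_BBD_FACTORS = {
    "glucose": (10.0, 20.0, 30.0),
    "peptone": (20.0, 40.0, 60.0),
    "corn_juice": (4.0, 8.0, 12.0),
}


def recovery_experiment(stage: str, n_reps: int = 100, seed: int = 0,
                        noise_viable: float = 0.02,
                        noise_surface: float = 0.01) -> pd.DataFrame:
    """Ground-truth recovery study for one pipeline stage.

    ``stage='kinetics'``: simulate noisy growth series and refit; one row
    per replicate with the relative error of each recovered coefficient.
    ``stage='ann_ga'``: simulate a noisy Box-Behnken response surface,
    train the surrogate, run the GA on its negation, and record the
    per-variable distance of the found optimum from the true one as a
    fraction of each variable's coded range.
    """
    rows = []
    if stage == "kinetics":
        truth = DEFAULT_GROWTH
        for rep in range(n_reps):
            cfg = SimConfig(noise_viable=noise_viable, noise_lactate=0.15,
                            noise_glucose=0.15, seed=seed + rep)
            series = simulate_fermentation(cfg)
            fit = kinetics.fit_growth(series)
            rows.append({
                "replicate": rep, "seed": cfg.seed,
                "rel_err_a": abs(fit["a"] - truth.a) / truth.a,
                "rel_err_b": abs(fit["b"] - truth.b) / truth.b,
                "rel_err_c": abs(fit["c"] - truth.c) / truth.c,
                "rel_err_d": abs(fit["d"] - truth.d) / truth.d,
                "r_squared": fit.r_squared,
            })
        return pd.DataFrame(rows)
    if stage == "ann_ga":
        design = box_behnken(_DEFAULT_BBD_FACTORS, center_runs=3)
        # a committee of 6-unit members localizes the interior optimum far
        # better than any single near-interpolating network
        cfg = TrainConfig(n_hidden=6)
        for rep in range(n_reps):
            scfg = SurfaceConfig(noise_sd=noise_surface, seed=seed + rep)
            y = simulate_bbd(design, scfg)
            xs = fit_scaler(design.coded)
            ys = fit_scaler(y.reshape(-1, 1))
            committee, _ = train_committee(xs.apply(design.coded),
                                           ys.apply(y.reshape(-1, 1)).ravel(),
                                           config=cfg, seed=seed + rep)

            def surrogate(x):
                return float(committee.predict(xs.apply(x.reshape(1, -1)))[0])

            ga_cfg = GAConfig(bounds=((-1.0, 1.0),) * 3, seed=seed + rep)
            res = ga_minimize(negate_objective(surrogate), ga_cfg)
            err = np.abs(res.best_point - scfg.optimum) / 2.0  # range is 2 coded units
            rows.append({
                "replicate": rep, "seed": seed + rep,
                "err_frac_x1": err[0], "err_frac_x2": err[1], "err_frac_x3": err[2],
                "max_err_frac": float(err.max()),
                "ga_best": -res.best_fitness,
            })
        return pd.DataFrame(rows)
    raise ValueError(f"unknown stage {stage!r}; expected 'kinetics' or 'ann_ga'")
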