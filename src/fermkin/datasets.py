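"""Built-in study tables and tabular I/O.

The quantitative inputs of the analysis are small printed tables: an L9
orthogonal design of buffer-salt combinations with viable-count responses,
a batch-fermentation time series (viable count, lactic acid, glucose), a
resin-dose adsorption series and an hourly viable-count series for three
resin addition rates.  They are shipped here as versioned in-memory
fixtures, validated on construction, alongside CSV read/write helpers for
user-supplied series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FermentationSeries",
    "OrthogonalTable",
    "AdsorptionTable",
    "RateCountTable",
    "load_builtin",
    "read_series_csv",
    "write_series_csv",
]


@dataclass(frozen=True)
class FermentationSeries:
    """Timed observations from a batch culture.

    Attributes
    ----------
    time : array of sampling times, hours, strictly increasing.
    viable_lg : viable count, lg CFU/mL (base-10 log of CFU/mL).
    lactate : lactic acid concentration, g/L.
    glucose_consumed : cumulative glucose consumed, g/L.
    *_sd : optional per-observation standard deviations (reported but not
        used as fitting weights).
    """

    time: np.ndarray
    viable_lg: np.ndarray
    lactate: np.ndarray
    glucose_consumed: np.ndarray
    viable_lg_sd: Optional[np.ndarray] = None
    lactate_sd: Optional[np.ndarray] = None
    glucose_consumed_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("time", "viable_lg", "lactate", "glucose_consumed"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("viable_lg_sd", "lactate_sd", "glucose_consumed_sd"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))
        n = len(self.time)
        for name in ("viable_lg", "lactate", "glucose_consumed"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has length "
                                 f"{len(getattr(self, name))}, expected {n}")
        if n and self.time[0] < 0:
            raise ValueError("time values must be non-negative")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValueError(
                f"time must be strictly increasing; violation at row {i + 1} "
                f"(t={self.time[i]} followed by t={self.time[i + 1]})")
        if np.any(self.viable_lg <= 0):
            raise ValueError("viable_lg must be positive")
        if np.any(self.lactate < 0) or np.any(self.glucose_consumed < 0):
            raise ValueError("lactate and glucose_consumed must be non-negative")

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time": self.time,
            "viable_lg": self.viable_lg,
            "lactate": self.lactate,
            "glucose_consumed": self.glucose_consumed,
        }
        for name in ("viable_lg_sd", "lactate_sd", "glucose_consumed_sd"):
            v = getattr(self, name)
            if v is not None:
                data[name] = v
        return pd.DataFrame(data)


@dataclass(frozen=True)
class OrthogonalTable:
    """An L9(3^3) orthogonal design with one response column.

    ``levels`` is a 9 x 3 integer array with entries in {1, 2, 3};
    ``response`` holds the viable count (lg CFU/mL) per run and may be
    absent for a design skeleton.
    """

    factors: tuple[str, str, str]
    levels: np.ndarray
    response: Optional[np.ndarray] = None
    response_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", np.asarray(self.levels, dtype=int))
        if self.levels.shape != (9, 3):
            raise ValueError(f"an L9 design needs a 9x3 level array, got {self.levels.shape}")
        if not np.isin(self.levels, (1, 2, 3)).all():
            raise ValueError("levels must be coded 1, 2 or 3")
        for j, name in enumerate(self.factors):
            counts = np.bincount(self.levels[:, j], minlength=4)[1:]
            if not (counts == 3).all():
                raise ValueError(f"factor {name!r} is unbalanced: level counts {counts.tolist()}")
        for i in range(3):
            for j in range(i + 1, 3):
                pairs = {tuple(row) for row in self.levels[:, (i, j)]}
                if len(pairs) != 9:
                    raise ValueError(
                        f"factors {self.factors[i]!r} and {self.factors[j]!r} are not "
                        "orthogonal: some level pair repeats")
        if self.response is not None:
            object.__setattr__(self, "response", np.asarray(self.response, dtype=float))
            if self.response.shape != (9,):
                raise ValueError("response must have one value per run")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.levels, columns=list(self.factors))
        df.insert(0, "run", np.arange(1, 10))
        if self.response is not None:
            df["response"] = self.response
        return df


@dataclass(frozen=True)
class AdsorptionTable:
    """Lactic acid adsorbed (C0 - C, g/L) versus resin dose (g/L)."""

    dose: np.ndarray
    delta_c: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose", np.asarray(self.dose, dtype=float))
        object.__setattr__(self, "delta_c", np.asarray(self.delta_c, dtype=float))
        if len(self.dose) != len(self.delta_c):
            raise ValueError("dose and delta_c must have equal length")
        if np.any(self.dose < 0):
            raise ValueError("doses must be non-negative")
        if np.any(np.diff(self.dose) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(np.diff(self.delta_c) < 0):
            raise ValueError("adsorbed amount must be non-decreasing in dose")


@dataclass(frozen=True)
class RateCountTable:
    """Hourly viable counts (lg CFU/mL, 8-16 h) for resin addition rates in BV/h."""

    rates: tuple[str, ...]
    time: np.ndarray
    counts: np.ndarray  # one row per rate
    counts_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if self.counts.shape != (len(self.rates), len(self.time)):
            raise ValueError("counts must be (n_rates, n_times)")
        if self.counts.shape != (3, 9):
            raise ValueError("expected 3 rate rows x 9 hourly time points")
        if np.any(self.counts <= 0):
            raise ValueError("counts must be positive")


# --- printed study tables ---------------------------------------------------

_TABLE1 = OrthogonalTable(
    factors=("sodium_acetate", "ammonium_citrate", "dipotassium_phosphate"),
    levels=[[1, 1, 1], [1, 2, 2], [1, 3, 3],
            [2, 1, 2], [2, 2, 3], [2, 3, 1],
            [3, 1, 3], [3, 2, 1], [3, 3, 2]],
    response=[9.32, 9.43, 9.39, 9.38, 9.49, 9.30, 9.49, 9.46, 9.35],
    response_sd=np.array([0.04, 0.02, 0.02, 0.02, 0.05, 0.07, 0.07, 0.03, 0.01]),
)

_TABLE3 = FermentationSeries(
    time=[0, 2, 4, 6, 8, 10, 12, 14],
    viable_lg=[7.63, 7.75, 8.15, 8.79, 9.38, 9.59, 9.66, 9.68],
    lactate=[0.00, 0.36, 1.08, 2.88, 6.12, 7.83, 9.09, 9.99],
    glucose_consumed=[0.00, 0.40, 1.20, 3.20, 6.30, 7.90, 9.00, 10.10],
    viable_lg_sd=[0.00, 0.01, 0.02, 0.01, 0.03, 0.02, 0.02, 0.04],
    lactate_sd=[0.00, 0.02, 0.03, 0.04, 0.07, 0.08, 0.14, 0.07],
    glucose_consumed_sd=[0.00, 0.01, 0.02, 0.01, 0.03, 0.02, 0.05, 0.04],
)

_TABLE7 = AdsorptionTable(
    dose=[0, 5, 10, 20, 40, 50, 60, 80],
    delta_c=[0, 0.95, 1.55, 3.05, 5.8, 6.9, 8, 9],
)

_TABLE9 = RateCountTable(
    rates=("0.5", "1.0", "1.5"),
    time=[8, 9, 10, 11, 12, 13, 14, 15, 16],
    counts=[[9.38, 9.55, 9.62, 9.67, 9.74, 9.71, 9.65, 9.62, 9.60],
            [9.38, 9.63, 9.76, 9.79, 9.85, 9.76, 9.73, 9.72, 9.70],
            [9.38, 9.70, 9.79, 9.79, 9.78, 9.75, 9.71, 9.57, 9.53]],
    counts_sd=np.array([[0.03, 0.04, 0.01, 0.03, 0.00, 0.00, 0.04, 0.00, 0.01],
                        [0.03, 0.00, 0.00, 0.01, 0.03, 0.03, 0.04, 0.04, 0.03],
                        [0.03, 0.00, 0.01, 0.01, 0.01, 0.04, 0.03, 0.08, 0.03]]),
)

_BUILTINS = {
    "table1": _TABLE1,
    "table3": _TABLE3,
    "table7": _TABLE7,
    "table9": _TABLE9,
}


def load_builtin(name: str):
    """Return a built-in study table by fixture name.

    ``table1``: the L9 buffer-salt design with viable-count responses;
    ``table3``: the batch-fermentation time series; ``table7``: adsorbed
    lactic acid versus resin dose; ``table9``: hourly viable counts for
    three resin addition rates.
    """
    try:
        return _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"unknown builtin fixture {name!r}; available: {sorted(_BUILTINS)}"
        ) from None


_REQUIRED_COLS = ("time", "viable_lg", "lactate", "glucose_consumed")
_OPTIONAL_COLS = ("viable_lg_sd", "lactate_sd", "glucose_consumed_sd")


def read_series_csv(path) -> FermentationSeries:
    """Read a fermentation time series from a headed CSV file.

    Required columns: time, viable_lg, lactate, glucose_consumed.  Optional
    ``*_sd`` columns are picked up; any other columns are ignored with a
    logged warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extras = [c for c in df.columns if c not in _REQUIRED_COLS + _OPTIONAL_COLS]
    if extras:
        logger.warning("%s: ignoring extra column(s) %s", path, extras)
    for col in _REQUIRED_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, row {row + 1}")
    t = df["time"].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"{path}: time column must be strictly increasing; row {i + 2} "
            f"has t={t[i + 1]} after t={t[i]}")
    kwargs = {c: df[c].to_numpy(float) for c in _REQUIRED_COLS}
    for c in _OPTIONAL_COLS:
        if c in df.columns:
            kwargs[c] = df[c].to_numpy(float)
    return FermentationSeries(**kwargs)


def write_series_csv(series: FermentationSeries, path) -> None:
    """Write a series to CSV using shortest round-trippable decimal text."""
    df = series.to_frame()
    # repr of a float is the shortest decimal string that reads back exactly
    df.to_csv(path, index=False, float_format=None)
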