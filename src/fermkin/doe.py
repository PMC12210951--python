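"""Design-of-experiments helpers: L9 orthogonal array, main-effects ANOVA
with classical eta-squared, Tukey HSD on level means, and the three-factor
Box-Behnken design used to plan the surrogate's training data.

The L9(3^3) analysis treats each of the three factors as a categorical
main effect with 2 df, leaving 2 residual df.  Factor sums of squares use
the balanced-design shortcut SS = sum(level_sum^2 / 3) - grand^2 / 9, which
equals the usual between-level deviation sum.  Effect size is classical
eta-squared SS_factor / SS_total, so the three values add up to the model
R^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import OrthogonalTable

__all__ = [
    "AnovaRow",
    "AnovaTable",
    "BBDesign",
    "TukeyComparison",
    "l9_design",
    "main_effects_anova",
    "best_levels",
    "tukey_hsd",
    "box_behnken",
]

# Standard L9(3^3) level pattern (columns: factor A, B, C).
_L9 = np.array([
    [1, 1, 1], [1, 2, 2], [1, 3, 3],
    [2, 1, 2], [2, 2, 3], [2, 3, 1],
    [3, 1, 3], [3, 2, 1], [3, 3, 2],
])


@dataclass(frozen=True)
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float
    f: Optional[float]
    p: Optional[float]
    eta_squared: Optional[float]


@dataclass(frozen=True)
class AnovaTable:
    rows: tuple[AnovaRow, ...]
    r_squared: float
    grand_mean: float

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"source": r.source, "SS": r.ss, "df": r.df, "MS": r.ms,
              "F": r.f, "p": r.p, "eta_squared": r.eta_squared}
             for r in self.rows])


def l9_design(factors: Sequence[str] = ("A", "B", "C")) -> OrthogonalTable:
    """The 9-run, 3-factor, 3-level orthogonal array (no responses)."""
    if len(factors) != 3:
        raise ValueError("the L9(3^3) array takes exactly 3 factors")
    return OrthogonalTable(factors=tuple(factors), levels=_L9.copy())


def main_effects_anova(table: OrthogonalTable) -> AnovaTable:
    """Three-factor main-effects ANOVA of an L9 table.

    Each factor is tested against the 2-df residual with an F(2, 2)
    reference distribution; eta-squared is SS_factor / SS_total.  An
    intercept row (SS = 9 * grand_mean^2) is included for completeness but
    its F-test is against the residual too.
    """
    if table.response is None:
        raise ValueError("orthogonal table has no response column")
    y = table.response
    grand = float(y.sum())
    n = 9
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_factor: dict[str, float] = {}
    for j, name in enumerate(table.factors):
        lv = table.levels[:, j]
        ss_factor[name] = float(
            sum(y[lv == k].sum() ** 2 / 3.0 for k in (1, 2, 3)) - grand ** 2 / n)
    ss_res = ss_total - sum(ss_factor.values())
    df_res = n - 1 - 6
    ms_res = ss_res / df_res
    ss_intercept = grand ** 2 / n

    def f_and_p(ms: float, df_num: int) -> tuple[Optional[float], Optional[float]]:
        if ms_res == 0.0:
            warnings.warn("zero residual mean square; F is infinite", stacklevel=3)
            return math.inf, 0.0
        f = ms / ms_res
        return f, float(stats.f.sf(f, df_num, df_res))

    rows = [AnovaRow("intercept", ss_intercept, 1, ss_intercept,
                     *f_and_p(ss_intercept, 1), None)]
    for name in table.factors:
        ss = ss_factor[name]
        f, p = f_and_p(ss / 2.0, 2)
        eta = ss / ss_total if ss_total > 0 else None
        rows.append(AnovaRow(name, ss, 2, ss / 2.0, f, p, eta))
    rows.append(AnovaRow("residual", ss_res, df_res, ms_res, None, None, None))
    r2 = sum(ss_factor.values()) / ss_total if ss_total > 0 else float("nan")
    return AnovaTable(rows=tuple(rows), r_squared=r2, grand_mean=grand / n)


def best_levels(table: OrthogonalTable) -> dict[str, int]:
    """Per-factor level (1-3) with the highest mean response.

    Ties resolve to the lowest level index.
    """
    if table.response is None:
        raise ValueError("orthogonal table has no response column")
    out: dict[str, int] = {}
    for j, name in enumerate(table.factors):
        lv = table.levels[:, j]
        means = np.array([table.response[lv == k].mean() for k in (1, 2, 3)])
        out[name] = int(np.argmax(means)) + 1  # argmax takes the first max
    return out


@dataclass(frozen=True)
class TukeyComparison:
    level_a: int
    level_b: int
    diff: float
    q: float
    p: float
    significant: bool


def tukey_hsd(table: OrthogonalTable, factor: str,
              alpha: float = 0.05) -> list[TukeyComparison]:
    """Tukey HSD comparisons of the three level means of one factor.

    Uses the studentized range with the ANOVA residual mean square (df 2)
    as the error term; each level mean averages 3 runs.
    """
    anova = main_effects_anova(table)
    ms_res = anova["residual"].ms
    df_res = anova["residual"].df
    if ms_res == 0.0:
        warnings.warn("zero residual mean square; Tukey comparisons degenerate",
                      stacklevel=2)
    j = list(table.factors).index(factor)
    lv = table.levels[:, j]
    means = {k: float(table.response[lv == k].mean()) for k in (1, 2, 3)}
    se = math.sqrt(ms_res / 3.0)
    out = []
    for ka in (1, 2, 3):
        for kb in (1, 2, 3):
            if ka >= kb:
                continue
            diff = means[ka] - means[kb]
            if se == 0.0:
                q = math.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, 3, df_res))
            out.append(TukeyComparison(ka, kb, diff, q, p, p < alpha))
    return out


@dataclass(frozen=True)
class BBDesign:
    """Three-factor Box-Behnken design in coded and physical units."""

    factors: tuple[str, str, str]
    coded: np.ndarray     # (n_runs, 3) in {-1, 0, +1}
    decoded: np.ndarray   # (n_runs, 3) physical units
    n_center: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.decoded, columns=list(self.factors))
        for j, name in enumerate(self.factors):
            df[f"{name}_coded"] = self.coded[:, j].astype(int)
        return df


def box_behnken(factor_specs: dict[str, Sequence[float]],
                center_runs: int = 3) -> BBDesign:
    """Build the 12-edge-run + center-replicate Box-Behnken design.

    ``factor_specs`` maps each of exactly three factor names to its (low,
    mid, high) physical levels; coded -1/0/+1 map onto those.  Edge runs
    pair the +/-1 combinations of two factors while the third sits at its
    midpoint.
    """
    if len(factor_specs) != 3:
        raise ValueError("a three-factor Box-Behnken design needs exactly 3 factors")
    for name, levels in factor_specs.items():
        if len(levels) != 3:
            raise ValueError(f"factor {name!r} needs exactly 3 levels, got {len(levels)}")
        lo, mid, hi = levels
        if not lo < mid < hi:
            raise ValueError(f"factor {name!r} levels must be strictly increasing")
    if center_runs < 1:
        raise ValueError("need at least one center run")
    names = tuple(factor_specs)
    coded_rows = []
    for i in range(3):
        for j in range(i + 1, 3):
            for si in (-1, 1):
                for sj in (-1, 1):
                    row = [0, 0, 0]
                    row[i], row[j] = si, sj
                    coded_rows.append(row)
    coded_rows.extend([[0, 0, 0]] * center_runs)
    coded = np.array(coded_rows, dtype=float)
    levels = np.array([factor_specs[n] for n in names], dtype=float)  # (3 factors, 3 levels)
    # coded -1/0/+1 index the stated low/mid/high levels directly
    idx = (coded + 1).astype(int)
    decoded = levels[np.arange(3)[np.newaxis, :], idx]
    return BBDesign(factors=names, coded=coded, decoded=decoded, n_center=center_runs)
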