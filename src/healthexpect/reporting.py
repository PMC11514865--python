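"""Derived comparison statistics, descriptive tables and figures.

The derived statistics operate on HLE/LE schedules (in percent):

* ``hle_le_ratio`` — 100·HLE/LE, rounded half away from zero to 1 decimal;
* ``gender_difference`` (GD) — men minus women per age within a group;
* ``age_decrement`` (AD) — the ratio at the starting age minus the ratio at
  the closing age (negative when the ratio rises with age).

Rounding to one decimal, half away from zero, is applied only at this
reporting layer; model internals stay unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.weightstats import DescrStatsW, CompareMeans

__all__ = [
    "HleLeSeries",
    "round1",
    "hle_le_ratio",
    "gender_difference",
    "age_decrement",
    "descriptives_table",
    "plot_series",
]


def round1(x: float) -> float:
    """Round to 1 decimal, ties away from zero (reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def hle_le_ratio(hle: float, le: float) -> float:
    """Share of remaining life expected healthy, 100·HLE/LE, in percent (1 dp)."""
    if le <= 0:
        raise ValueError("life expectancy must be positive")
    if not 0 <= hle <= le:
        raise ValueError(f"HLE must lie in [0, LE]; got HLE={hle}, LE={le}")
    return round1(100.0 * hle / le)


@dataclass
class HleLeSeries:
    """An HLE/LE (%) schedule over ages for one group."""

    ages: np.ndarray
    values: np.ndarray
    labels: dict[str, str] = field(default_factory=dict)  # e.g. gender, loneliness, indicator

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.shape != self.values.shape:
            raise ValueError("ages and values must have matching shapes")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any((self.values < 0) | (self.values > 100)):
            raise ValueError("HLE/LE values must lie in [0, 100]")

    def at(self, age: float) -> float:
        idx = np.flatnonzero(np.isclose(self.ages, age))
        if idx.size == 0:
            raise ValueError(f"age {age} not present in series")
        return float(self.values[idx[0]])


def gender_difference(men: HleLeSeries, women: HleLeSeries) -> pd.DataFrame:
    """Per-age gender difference in HLE/LE, men minus women (1 dp).

    The sign convention is men − women, matching the published positive
    values for groups where men's ratio exceeds women's.
    """
    if men.ages.shape != women.ages.shape or not np.allclose(men.ages, women.ages):
        raise ValueError("age grids differ between the two series")
    for key in set(men.labels) & set(women.labels) - {"gender"}:
        if men.labels[key] != women.labels[key]:
            raise ValueError(f"series differ in grouping label {key!r}")
    gd = [round1(m - w) for m, w in zip(men.values, women.values)]
    return pd.DataFrame({"age": men.ages, "men": men.values, "women": women.values, "gd": gd})


def age_decrement(series: HleLeSeries, from_age: float = 65, to_age: float = 99) -> float:
    """HLE/LE at ``from_age`` minus at ``to_age`` (1 dp; negative if rising)."""
    return round1(series.at(from_age) - series.at(to_age))


# ---------------------------------------------------------------------------
# descriptives


def descriptives_table(
    cohort: pd.DataFrame,
    continuous: Sequence[str] = ("interview_age",),
    categorical: Sequence[str] = (),
    group: str = "female",
    weight: str = "weight",
) -> pd.DataFrame:
    """Weighted baseline descriptives with gender-comparison tests.

    Continuous variables get weighted mean (SD) per group and a two-sample
    t test on the weighted statistics; 0/1 categoricals get weighted
    percentages and a chi-square test on the weighted 2x2 counts.
    """
    w = cohort[weight].to_numpy(dtype=float)
    g = cohort[group].to_numpy()
    masks = {"overall": np.ones(len(cohort), bool), "men": g == 0, "women": g == 1}
    for name in ("men", "women"):
        if w[masks[name]].sum() <= 0:
            raise ValueError(f"zero total weight in the {name} stratum")

    rows = []
    for var in continuous:
        x = cohort[var].to_numpy(dtype=float)
        summ = {}
        for name, m in masks.items():
            d = DescrStatsW(x[m], weights=w[m])
            summ[name] = f"{d.mean:.2f} ({d.std:.2f})"
        cm = CompareMeans(
            DescrStatsW(x[masks["men"]], weights=w[masks["men"]]),
            DescrStatsW(x[masks["women"]], weights=w[masks["women"]]),
        )
        tstat, pval, _ = cm.ttest_ind(usevar="unequal")
        rows.append(
            dict(variable=var, overall=summ["overall"], men=summ["men"],
                 women=summ["women"], statistic=float(tstat), p_value=float(pval))
        )
    for var in categorical:
        x = cohort[var].to_numpy(dtype=float)
        summ = {
            name: f"{100 * np.average(x[m], weights=w[m]):.1f}%" for name, m in masks.items()
        }
        table = np.array(
            [
                [w[masks[n] & (x == 1)].sum(), w[masks[n] & (x == 0)].sum()]
                for n in ("men", "women")
            ]
        )
        if np.allclose(table[0] / table[0].sum(), table[1] / table[1].sum()):
            chi2, pval = 0.0, 1.0
        else:
            chi2, pval, _, _ = stats.chi2_contingency(table)
        rows.append(
            dict(variable=var, overall=summ["overall"], men=summ["men"],
                 women=summ["women"], statistic=float(chi2), p_value=float(pval))
        )
    return pd.DataFrame(rows)


def plot_series(
    series_list: Sequence[HleLeSeries],
    path: str,
    ylabel: str = "HLE/LE (%)",
    title: str | None = None,
) -> None:
    """Line chart of one or more HLE/LE (or LE/HLE) schedules vs age."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for s in series_list:
        label = ", ".join(f"{v}" for v in s.labels.values()) or None
        ax.plot(s.ages, s.values, marker="o", ms=3, label=label)
    ax.set_xlabel("age")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    if any(s.labels for s in series_list):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
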