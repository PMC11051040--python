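"""Bland–Altman agreement between the continuous equations and table lookup.

The classical table-based workflow converts the formation ratio to an age by
looking it up in a growth table printed at whole-year (or half-year) steps,
so every estimate is rounded to the grid.  The equation-based method reads
the same curve continuously.  This module emulates the table workflow by
discretising a fitted curve at a fixed age step, and quantifies the
agreement between the two readings with Bland–Altman statistics: the
discrepancy between the methods is, by construction, the rounding error the
tables impose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .growth_models import GrowthCurve, age_at_ratio, invert_raw, ratio_at_age

__all__ = [
    "LookupTable",
    "AgreementStats",
    "build_lookup",
    "table_age",
    "bland_altman",
    "equation_vs_lookup",
]

#: limits of agreement use the conventional normal-quantile multiplier
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class LookupTable:
    """Growth table emulation: (age, ratio-percent) rows at a fixed age step,
    strictly increasing in both columns."""

    entries: tuple[tuple[float, float], ...]  # (age years, x percent)
    age_step: float
    source_label: str = ""

    def __post_init__(self) -> None:
        ages = [e[0] for e in self.entries]
        xs = [e[1] for e in self.entries]
        if any(b <= a for a, b in zip(ages, ages[1:])) or any(
            b <= a for a, b in zip(xs, xs[1:])
        ):
            raise ValueError("lookup table must be strictly increasing")


def build_lookup(curve: GrowthCurve, age_step: float = 1.0) -> LookupTable:
    """Tabulate a growth curve at whole- or half-year ages.

    Rows run from the last grid age covering the curve's minimum age to the
    last grid age at/below its adult age.  Like the printed growth tables
    being emulated, the first row may sit just below the curve's validated
    domain; it is obtained by inverting the raw formula so that low ratios
    are not all attracted to an artificially late first row.
    """
    if age_step not in (0.5, 1.0):
        raise ValueError("age_step must be 0.5 or 1.0 years")
    start = math.floor(curve.min_age / age_step + 1e-9) * age_step
    stop = math.floor(curve.adult_age / age_step + 1e-9) * age_step
    entries = []
    for a in np.arange(start, stop + age_step / 2, age_step):
        a = float(a)
        if a >= curve.min_age:
            entries.append((a, ratio_at_age(curve, a).x))
        else:
            x = invert_raw(curve, a)
            if x is not None:
                entries.append((a, x))
    return LookupTable(entries=tuple(entries), age_step=age_step,
                       source_label=curve.label)


def table_age(table: LookupTable, x: float) -> float:
    """Table reading: the age of the row whose ratio is nearest the query.

    Ties between two equidistant rows break toward the younger age.
    """
    if not table.entries:
        raise ValueError("empty lookup table")
    xs = np.array([e[1] for e in table.entries])
    dist = np.abs(xs - x)
    # argmin returns the first (lowest-age) index on exact ties
    return table.entries[int(np.argmin(dist))][0]


@dataclass(frozen=True)
class AgreementStats:
    """Bland–Altman summary of paired estimates (method A minus method B)."""

    n_pairs: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    max_abs_diff: float
    pairs: tuple[tuple[float, float], ...]  # (mean of the pair, difference)


def bland_altman(pairs: Sequence[tuple[float, float]]) -> AgreementStats:
    """Bland–Altman statistics for paired (estimate_A, estimate_B) values.

    Differences are A - B; the spread uses the sample (n-1) standard
    deviation; limits of agreement are mean +/- 1.96 SD.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    diff = a - b
    mean_diff = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))
    return AgreementStats(
        n_pairs=len(pairs),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - LOA_MULTIPLIER * sd_diff,
        loa_high=mean_diff + LOA_MULTIPLIER * sd_diff,
        max_abs_diff=float(np.max(np.abs(diff))),
        pairs=tuple(
            (float(m), float(d)) for m, d in zip((a + b) / 2.0, diff)
        ),
    )


def equation_vs_lookup(
    curves: Sequence[GrowthCurve],
    n_per_curve: int = 200,
    age_step: float = 1.0,
    seed: int = 0,
) -> AgreementStats:
    """Agreement between continuous and table readings of the same curves.

    Draws ``n_per_curve`` formation ratios uniformly over each curve's
    validated domain, ages them with the equation and with a table built at
    ``age_step``, and summarises the paired differences.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[float, float]] = []
    for curve in curves:
        lo, hi = curve.x_domain
        table = build_lookup(curve, age_step)
        for x in rng.uniform(lo, hi, size=n_per_curve):
            eq_age = age_at_ratio(curve, float(x)).age
            tab_age = table_age(table, float(x))
            pairs.append((eq_age, tab_age))
    return bland_altman(pairs)


def plot_bland_altman(stats: AgreementStats, ax=None):
    """Render the agreement as the conventional mean-vs-difference scatter.

    Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    means = [p[0] for p in stats.pairs]
    diffs = [p[1] for p in stats.pairs]
    ax.scatter(means, diffs, s=12, alpha=0.6)
    for y, style in ((stats.mean_diff, "-"), (stats.loa_low, "--"),
                     (stats.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of paired estimates (years)")
    ax.set_ylabel("difference between methods (years)")
    return ax
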