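"""Bone growth curves for age-at-Harris-Line estimation.

A Harris Line (HL) is laid down at the growth plate when longitudinal bone
growth is transiently arrested, and it persists in the adult bone.  If we know
the fraction *x* of adult bone length that the bone had reached when a given
HL formed, a growth curve ``age = y(x)`` dates the arrest event.

This module provides the curve representation (evaluation and inversion) and
the published curve sets for the human tibia and femur, fitted to the
mid-20th-century North American growth reference data compiled by Byers.
Three model families are supported:

* linear        ``y = a*x + b``
* quadratic     ``y = a*x**2 + b*x + c``
* exponential   ``y = a*exp(b*x) + c``

Throughout the package *x* is a percentage in ``(0, 100]`` ("bone length at
HL formation / adult bone length"); *y* is age in years.  Plugging fractional
ratios (0-1) into the published coefficients gives nonsense, so every API
takes percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModelFamily",
    "Bone",
    "SexGroup",
    "GrowthCurve",
    "AgeResult",
    "RatioResult",
    "AgeBelowDomainError",
    "age_at_ratio",
    "ratio_at_age",
    "make_curve",
    "published_curves",
    "published_statistics",
    "export_published_curves",
    "invert_raw",
    "MIN_RATIO_FLOOR",
]

# The source growth tables cover childhood onward; below ~30 % of adult
# length the fitted curves are unvalidated extrapolation.
MIN_RATIO_FLOOR = 30.0

#: x tolerance of the numerical curve inversion (percent).
INVERSION_XTOL = 1e-9


class Bone(str, Enum):
    TIBIA = "tibia"
    FEMUR = "femur"


class SexGroup(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNISEX = "unisex"


class ModelFamily(str, Enum):
    """Curve family; the member value doubles as its CSV/CLI token."""

    LINEAR = "linear"
    QUADRATIC = "quadratic"
    EXPONENTIAL = "exponential"

    @property
    def n_coeffs(self) -> int:
        return {"linear": 2, "quadratic": 3, "exponential": 3}[self.value]


def _evaluate(family: ModelFamily, coeffs: Sequence[float], x):
    """Raw evaluation of the family formula at ratio-percent ``x``."""
    x = np.asarray(x, dtype=float)
    if family is ModelFamily.LINEAR:
        a, b = coeffs
        out = a * x + b
    elif family is ModelFamily.QUADRATIC:
        a, b, c = coeffs
        out = a * x**2 + b * x + c
    elif family is ModelFamily.EXPONENTIAL:
        a, b, c = coeffs
        out = a * np.exp(b * x) + c
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown family {family!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GrowthCurve:
    """One fitted growth equation ``age = y(ratio_percent)``.

    ``x_domain`` is the closed ratio interval on which the curve is
    considered validated; its upper bound is always 100 (the adult bone).
    Monotonicity of age in ratio is verified numerically at construction.
    """

    family: ModelFamily
    coeffs: tuple[float, ...]
    bone: Bone
    group: SexGroup
    x_domain: tuple[float, float] = (MIN_RATIO_FLOOR, 100.0)
    n_source: int = 0
    is_selected_best: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", ModelFamily(self.family))
        object.__setattr__(self, "bone", Bone(self.bone))
        object.__setattr__(self, "group", SexGroup(self.group))
        object.__setattr__(self, "coeffs", tuple(float(c) for c in self.coeffs))
        if len(self.coeffs) != self.family.n_coeffs:
            raise ValueError(
                f"{self.family.value} family takes {self.family.n_coeffs} "
                f"coefficients, got {len(self.coeffs)}"
            )
        lo, hi = self.x_domain
        if not (0.0 < lo < hi):
            raise ValueError(f"invalid x_domain {self.x_domain}")
        if hi != 100.0:
            raise ValueError("x_domain upper bound must be 100 (adult bone)")
        grid = np.linspace(lo, hi, 1000)
        ages = _evaluate(self.family, self.coeffs, grid)
        if not np.all(np.diff(ages) > 0):
            raise ValueError(
                "age is not strictly increasing in ratio over the x_domain"
            )

    # -- convenience ------------------------------------------------------

    @property
    def label(self) -> str:
        return f"{self.bone.value}/{self.group.value}/{self.family.value}"

    def age_at(self, x):
        """Raw formula value at ratio-percent ``x`` (no clamping, no flags)."""
        return _evaluate(self.family, self.coeffs, x)

    @property
    def adult_age(self) -> float:
        """Age (years) at which the bone reaches adult length (x = 100)."""
        return float(self.age_at(100.0))

    @property
    def min_age(self) -> float:
        """Age (years) at the lower edge of the validated ratio domain."""
        return float(self.age_at(self.x_domain[0]))


@dataclass(frozen=True)
class AgeResult:
    """Age estimate with quality flags ('extrapolated', 'clamped')."""

    age: float
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class RatioResult:
    """Ratio-percent estimate with quality flags ('adult')."""

    x: float
    flags: frozenset[str] = frozenset()


class AgeBelowDomainError(ValueError):
    """Requested age predates the curve's validated domain."""


def age_at_ratio(curve: GrowthCurve, x: float) -> AgeResult:
    """Age (years) at which a bone measured ``x`` percent of adult length.

    Ratios outside ``curve.x_domain`` still yield an estimate but are flagged
    ``extrapolated``; a negative formula value is clamped to 0 and flagged
    ``clamped``.  Callers should report ages to 0.01-year precision.
    """
    flags = set()
    lo, hi = curve.x_domain
    if not (lo <= x <= hi):
        flags.add("extrapolated")
    age = float(curve.age_at(float(x)))
    if age < 0.0:
        age = 0.0
        flags.add("clamped")
    return AgeResult(age=age, flags=frozenset(flags))


def _invert_closed_form(curve: GrowthCurve, age: float) -> float | None:
    """Closed-form inverse of the family formula; None if inapplicable."""
    if curve.family is ModelFamily.LINEAR:
        a, b = curve.coeffs
        return (age - b) / a
    if curve.family is ModelFamily.QUADRATIC:
        a, b, c = curve.coeffs
        disc = b * b - 4.0 * a * (c - age)
        if disc < 0.0:
            return None
        lo, hi = curve.x_domain
        roots = [(-b + math.sqrt(disc)) / (2.0 * a), (-b - math.sqrt(disc)) / (2.0 * a)]
        inside = [r for r in roots if lo - 1e-6 <= r <= hi + 1e-6]
        return inside[0] if inside else None
    a, b, c = curve.coeffs
    arg = (age - c) / a
    if arg <= 0.0:
        return None
    return math.log(arg) / b


def ratio_at_age(curve: GrowthCurve, age: float) -> RatioResult:
    """Inverse prediction: the ratio-percent at which the curve gives ``age``.

    Uses the closed-form inverse per family (quadratic root selection inside
    the domain, logarithmic form for the exponential) with a bisection
    fallback; tolerance 1e-9 on x.  Ages at or above the curve's adult age
    return 100 flagged ``adult``; ages below the domain raise
    :class:`AgeBelowDomainError`.
    """
    lo, hi = curve.x_domain
    min_age, adult = curve.min_age, curve.adult_age
    if age >= adult:
        flags = frozenset() if abs(age - adult) <= 1e-12 else frozenset({"adult"})
        return RatioResult(x=100.0, flags=flags)
    if age < min_age - 1e-9:
        raise AgeBelowDomainError(
            f"age {age:.3f} y is below the model domain of {curve.label} "
            f"(minimum {min_age:.3f} y at x = {lo:.1f} %)"
        )
    x = _invert_closed_form(curve, age)
    if x is None or not (lo - 1e-6 <= x <= hi + 1e-6):
        x = brentq(lambda t: float(curve.age_at(t)) - age, lo, hi, xtol=INVERSION_XTOL)
    return RatioResult(x=float(min(max(x, lo), hi)))


def invert_raw(curve: GrowthCurve, age: float) -> float | None:
    """Invert the raw formula over (0, 100] without the domain floor.

    Unlike :func:`ratio_at_age` this reaches below the validated domain
    (used when emulating printed growth tables, which cover early
    childhood).  Returns None when no ratio in (0, 100] gives ``age``.
    """
    if age > curve.adult_age:
        return None
    x = _invert_closed_form(curve, age)
    if x is not None and 0.0 < x <= 100.0:
        return float(x)
    f = lambda t: float(curve.age_at(t)) - age
    if f(1e-9) >= 0.0:
        return None
    return float(brentq(f, 1e-9, 100.0, xtol=INVERSION_XTOL))


def _zero_crossing(family: ModelFamily, coeffs: Sequence[float]) -> float | None:
    """Ratio-percent at which the raw formula crosses age 0, if in (0, 100)."""
    f = lambda t: float(_evaluate(family, coeffs, t))
    if f(1e-6) >= 0.0 or f(100.0) <= 0.0:
        return None
    return brentq(f, 1e-6, 100.0, xtol=1e-9)


def make_curve(
    family: ModelFamily,
    coeffs: Sequence[float],
    bone: Bone,
    group: SexGroup,
    n_source: int = 0,
    is_selected_best: bool = False,
) -> GrowthCurve:
    """Build a curve, deriving the validated domain's lower bound.

    The lower bound is the ratio at which the formula gives age 0, floored at
    ``MIN_RATIO_FLOOR`` percent: below the source tables' coverage the curve
    is extrapolation, whatever the formula says.
    """
    x0 = _zero_crossing(ModelFamily(family), coeffs)
    x_min = MIN_RATIO_FLOOR if x0 is None else max(MIN_RATIO_FLOOR, x0)
    return GrowthCurve(
        family=family,
        coeffs=tuple(coeffs),
        bone=bone,
        group=group,
        x_domain=(x_min, 100.0),
        n_source=n_source,
        is_selected_best=is_selected_best,
    )


# ---------------------------------------------------------------------------
# Published curve sets
# ---------------------------------------------------------------------------
# 18 fitted equations: 6 strata (tibia/femur x male/female/unisex minus the
# femur/tibia split, i.e. femur m/f/unisex + tibia m/f/unisex) x 3 families.
# AIC/AICc/RSS are the published fit statistics; exactly one family per
# stratum (lowest AICc) is marked selected.  The source-table sizes
# (16 points for male and unisex strata, 14 for female) are not published
# directly; they are recovered from the AICc - AIC gaps, see
# ``model_fitting.infer_n_from_aicc_gap``.
#
# The tibia/female exponential AIC is stored as -6.38: the published table
# prints "6.38", which is inconsistent with its own AICc of -1.94 (AICc is
# AIC plus a positive small-sample correction) and with recomputation from
# the published residual sum of squares; the minus sign was evidently
# dropped in print.  No other value is altered.

_ROWS: list[dict] = [
    # bone, group, family, coeffs, aic, aicc, rss, selected
    dict(bone="femur", group="male", family="linear",
         coeffs=(0.217859, -6.43422), aic=25.82, aicc=27.82, rss=3.234),
    dict(bone="femur", group="male", family="quadratic",
         coeffs=(0.00106893, 0.077086, -2.28129), aic=-18.35, aicc=-14.71,
         rss=0.1804, selected=True),
    dict(bone="femur", group="male", family="exponential",
         coeffs=(11.5213, 0.00979342, -14.5196), aic=-15.94, aicc=-12.30,
         rss=0.2098),
    dict(bone="femur", group="female", family="linear",
         coeffs=(0.191588, -5.93988), aic=24.19, aicc=26.59, rss=3.007),
    dict(bone="femur", group="female", family="quadratic",
         coeffs=(0.00114036, 0.0387797, -1.33028), aic=-12.01, aicc=-7.56,
         rss=0.1963),
    dict(bone="femur", group="female", family="exponential",
         coeffs=(6.84604, 0.0121551, -9.07047), aic=-14.22, aicc=-9.77,
         rss=0.1676, selected=True),
    dict(bone="tibia", group="male", family="linear",
         coeffs=(0.216145, -6.14786), aic=20.56, aicc=22.56, rss=2.328),
    dict(bone="tibia", group="male", family="quadratic",
         coeffs=(0.000860092, 0.103426, -2.84765), aic=-13.35, aicc=-9.71,
         rss=0.2467, selected=True),
    dict(bone="tibia", group="male", family="exponential",
         coeffs=(16.227, 0.00787971, -19.5643), aic=-11.19, aicc=-7.55,
         rss=0.2823),
    dict(bone="tibia", group="female", family="linear",
         coeffs=(0.19219, -5.90254), aic=22.61, aicc=25.01, rss=2.685),
    dict(bone="tibia", group="female", family="quadratic",
         coeffs=(0.00105703, 0.0508895, -1.64875), aic=-4.59, aicc=-0.15,
         rss=0.3333),
    dict(bone="tibia", group="female", family="exponential",
         coeffs=(7.78153, 0.011363, -10.1631), aic=-6.38, aicc=-1.94,
         rss=0.2933, selected=True, aic_note="sign corrected from printed 6.38"),
    dict(bone="tibia", group="unisex", family="linear",
         coeffs=(0.211442, -6.50326), aic=33.78, aicc=35.78, rss=5.318),
    dict(bone="tibia", group="unisex", family="quadratic",
         coeffs=(0.00128889, 0.0374516, -1.24991), aic=4.29, aicc=7.93,
         rss=0.7431),
    dict(bone="tibia", group="unisex", family="exponential",
         coeffs=(6.79694, 0.0128072, -9.00042), aic=1.11, aicc=4.75,
         rss=0.6093, selected=True),
    dict(bone="femur", group="unisex", family="linear",
         coeffs=(0.211759, -6.65994), aic=36.57, aicc=38.57, rss=6.331),
    dict(bone="femur", group="unisex", family="quadratic",
         coeffs=(0.00142038, 0.0191624, -0.812149), aic=6.1, aicc=9.74,
         rss=0.8323),
    dict(bone="femur", group="unisex", family="exponential",
         coeffs=(5.61797, 0.0140969, -7.60929), aic=2.58, aicc=6.21,
         rss=0.6677, selected=True),
]

_N_SOURCE = {"male": 16, "female": 14, "unisex": 16}


def published_curves() -> list[GrowthCurve]:
    """All 18 published growth curves; the lowest-AICc curve of each of the
    six (bone, sex-group) strata carries ``is_selected_best``.

    The validated ratio domain is set per stratum from the *selected* curve
    (its age-zero crossing, floored at ``MIN_RATIO_FLOOR``) and shared by
    all three family fits of that stratum, so readings from alternative
    families are flagged consistently.
    """
    x_min: dict[tuple[str, str], float] = {}
    for r in _ROWS:
        if r.get("selected"):
            x0 = _zero_crossing(ModelFamily(r["family"]), r["coeffs"])
            x_min[(r["bone"], r["group"])] = (
                MIN_RATIO_FLOOR if x0 is None else max(MIN_RATIO_FLOOR, x0)
            )
    return [
        GrowthCurve(
            family=ModelFamily(r["family"]),
            coeffs=tuple(r["coeffs"]),
            bone=Bone(r["bone"]),
            group=SexGroup(r["group"]),
            x_domain=(x_min[(r["bone"], r["group"])], 100.0),
            n_source=_N_SOURCE[r["group"]],
            is_selected_best=bool(r.get("selected", False)),
        )
        for r in _ROWS
    ]


def selected_curves() -> list[GrowthCurve]:
    """The six per-stratum best (lowest AICc) published curves."""
    return [c for c in published_curves() if c.is_selected_best]


def published_statistics():
    """Published per-curve fit statistics as a :class:`pandas.DataFrame`.

    Columns: bone, group, family, a, b, c, aic, aicc, rss, selected,
    n_source, note.  AIC/AICc/RSS are the published values (the one known
    sign typo corrected, see the module comment), not recomputations.
    """
    import pandas as pd

    recs = []
    for r in _ROWS:
        co = list(r["coeffs"]) + [math.nan] * (3 - len(r["coeffs"]))
        recs.append(
            dict(
                bone=r["bone"], group=r["group"], family=r["family"],
                a=co[0], b=co[1], c=co[2],
                aic=r["aic"], aicc=r["aicc"], rss=r["rss"],
                selected=bool(r.get("selected", False)),
                n_source=_N_SOURCE[r["group"]],
                note=r.get("aic_note", ""),
            )
        )
    return pd.DataFrame.from_records(recs)


def export_published_curves(path) -> None:
    """Write the published constants to a plain CSV file so that other tools
    can consume the curves without this library."""
    df = published_statistics()
    df.to_csv(path, index=False)


def find_curve(
    curves: Iterable[GrowthCurve],
    bone: Bone | str,
    group: SexGroup | str,
    best_only: bool = True,
) -> GrowthCurve:
    """Pick the curve for a (bone, sex-group) stratum from a curve set."""
    bone, group = Bone(bone), SexGroup(group)
    matches = [c for c in curves if c.bone == bone and c.group == group]
    if best_only:
        best = [c for c in matches if c.is_selected_best]
        matches = best or matches
    if not matches:
        raise LookupError(f"no curve for {bone.value}/{group.value}")
    return matches[0]
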