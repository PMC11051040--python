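"""From bone measurements to the HL formation ratio and age.

Two measurements date a Harris Line: the total bone length *L* and the
distance *d* from the line to the nearest bone end.  Longitudinal growth is
apportioned between the two ends in fixed, bone-specific proportions, so the
growth deposited at one end after the line formed (*d*) implies the total
growth at both ends (*d / f*, with *f* the end's apportionment fraction),
hence the bone length when the line formed, hence the ratio

    x = 100 * (L - d/f) / L          (percent of adult length)

For an immature bone the adult length is not observable; it is projected
from the individual's estimated age at death via the growth curve
("would-be-adult" length), and the formation ratio is taken against that
projection.  The selected growth curve then converts the ratio to an age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .growth_models import (
    Bone,
    GrowthCurve,
    SexGroup,
    age_at_ratio,
    find_curve,
    ratio_at_age,
)

__all__ = [
    "Maturity",
    "End",
    "BoneMeasurement",
    "HLObservation",
    "GrowthApportionment",
    "HLAgeEstimate",
    "DEFAULT_APPORTIONMENTS",
    "ratio_adult",
    "projected_adult_length",
    "estimate_hl_age",
]

Maturity = str  # "adult" | "nonadult"
End = str       # "proximal" | "distal"

_MATURITIES = frozenset({"adult", "nonadult"})
_ENDS = frozenset({"proximal", "distal"})


@dataclass(frozen=True)
class BoneMeasurement:
    """One measured bone (tibia or femur), measured to the nearest 0.1 cm."""

    bone: Bone
    group: SexGroup
    maturity: Maturity
    total_length: float  # cm
    estimated_age: float | None = None  # years; required for non-adults
    specimen_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bone", Bone(self.bone))
        object.__setattr__(self, "group", SexGroup(self.group))
        if self.maturity not in _MATURITIES:
            raise ValueError(f"maturity must be adult|nonadult, got {self.maturity!r}")
        if self.total_length <= 0:
            raise ValueError("total_length must be positive")
        if self.maturity == "nonadult":
            if self.estimated_age is None or self.estimated_age <= 0:
                raise ValueError("non-adult bones require estimated_age > 0")


@dataclass(frozen=True)
class HLObservation:
    """One Harris Line: distance (cm) to the nearest bone end.

    The ``end`` field is mandatory and never inferred from d < L/2 — lines
    near mid-shaft are ambiguous, so the observer's call is authoritative.
    """

    distance: float  # cm
    end: End
    hl_id: str = ""

    def __post_init__(self) -> None:
        if self.end not in _ENDS:
            raise ValueError(f"end must be proximal|distal, got {self.end!r}")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


@dataclass(frozen=True)
class GrowthApportionment:
    """Fraction of total longitudinal growth contributed by each bone end."""

    bone: Bone
    fraction_proximal: float
    fraction_distal: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "bone", Bone(self.bone))
        for f in (self.fraction_proximal, self.fraction_distal):
            if not 0.0 < f < 1.0:
                raise ValueError("growth fractions must be in (0, 1)")
        if abs(self.fraction_proximal + self.fraction_distal - 1.0) > 1e-9:
            raise ValueError("growth fractions must sum to 1")

    def fraction(self, end: End) -> float:
        if end not in _ENDS:
            raise ValueError(f"end must be proximal|distal, got {end!r}")
        return self.fraction_proximal if end == "proximal" else self.fraction_distal


# Conventional end-growth apportionment of the two bones: the tibia grows
# predominantly proximally (~57 %), the femur predominantly distally (~71 %).
# Configurable because they are reference constants, not measurements.
DEFAULT_APPORTIONMENTS: Mapping[Bone, GrowthApportionment] = {
    Bone.TIBIA: GrowthApportionment(Bone.TIBIA, fraction_proximal=0.57,
                                    fraction_distal=0.43),
    Bone.FEMUR: GrowthApportionment(Bone.FEMUR, fraction_proximal=0.29,
                                    fraction_distal=0.71),
}


@dataclass(frozen=True)
class HLAgeEstimate:
    """Result for one Harris Line.

    ``flags`` may contain: ``extrapolated`` (ratio outside the curve's
    validated domain), ``clamped`` (negative formula age clamped to 0),
    ``adult`` (non-adult projection hit the curve's adult age),
    ``inconsistent_chronology`` (estimated formation age exceeds the
    individual's estimated age), ``unisex_curve`` (unisex curve applied to a
    sexed adult context).
    """

    specimen_id: str
    hl_id: str
    ratio_percent: float
    age_years: float
    curve_label: str
    fraction_used: float
    flags: frozenset[str] = frozenset()


def ratio_adult(L: float, d: float, f: float) -> float:
    """Formation ratio (percent of adult length) for an adult bone.

    ``d`` cm of post-formation growth at the line's end implies ``d / f`` cm
    of total post-formation growth, so the bone measured ``L - d/f`` cm when
    the line formed.
    """
    if L <= 0:
        raise ValueError("bone length must be positive")
    if not 0.0 < f < 1.0:
        raise ValueError("growth fraction must be in (0, 1)")
    if d < 0:
        raise ValueError("HL distance must be non-negative")
    if d >= f * L:
        raise ValueError(
            "HL distance exceeds growth attributable to this end - "
            "check end assignment or apportionment constants"
        )
    return 100.0 * (L - d / f) / L


def projected_adult_length(
    L_current: float, estimated_age: float, curve: GrowthCurve
) -> tuple[float, frozenset[str]]:
    """'Would-be-adult' length of an immature bone.

    Divides the current length by the expected percent-of-adult-length at the
    individual's estimated age.  Returns the projection and any inversion
    flags (``adult`` when the estimated age is at/above the curve's adult
    age, in which case the bone is treated as fully grown).
    """
    res = ratio_at_age(curve, estimated_age)
    return 100.0 * L_current / res.x, res.flags


def estimate_hl_age(
    measurement: BoneMeasurement,
    hl: HLObservation,
    curves: Iterable[GrowthCurve],
    apportionment: GrowthApportionment | None = None,
) -> HLAgeEstimate:
    """Estimate the age at which one Harris Line formed.

    The curve is chosen from ``curves`` by (bone, sex group); for non-adult
    bones the unisex stratum is forced, since the sex of immature skeletons
    cannot be reliably determined.  Adult bones use the measured length as
    the adult length; non-adult bones first project the would-be-adult
    length from the individual's estimated age.
    """
    curves = list(curves)
    if apportionment is None:
        apportionment = DEFAULT_APPORTIONMENTS[measurement.bone]
    if apportionment.bone != measurement.bone:
        raise ValueError("apportionment constants are for a different bone")
    f = apportionment.fraction(hl.end)

    flags: set[str] = set()
    group = measurement.group
    if measurement.maturity == "nonadult":
        group = SexGroup.UNISEX
    elif group == SexGroup.UNISEX:
        flags.add("unisex_curve")
    curve = find_curve(curves, measurement.bone, group)

    L = measurement.total_length
    if measurement.maturity == "adult":
        x = ratio_adult(L, hl.distance, f)
    else:
        L_adult, proj_flags = projected_adult_length(
            L, measurement.estimated_age, curve
        )
        flags |= proj_flags
        formation_length = L - hl.distance / f
        if formation_length <= 0:
            raise ValueError(
                "HL distance exceeds growth attributable to this end - "
                "check end assignment or apportionment constants"
            )
        x = 100.0 * formation_length / L_adult

    age_res = age_at_ratio(curve, x)
    flags |= age_res.flags
    if (
        measurement.maturity == "nonadult"
        and age_res.age > measurement.estimated_age + 1e-9
    ):
        flags.add("inconsistent_chronology")

    return HLAgeEstimate(
        specimen_id=measurement.specimen_id,
        hl_id=hl.hl_id,
        ratio_percent=x,
        age_years=age_res.age,
        curve_label=curve.label,
        fraction_used=f,
        flags=frozenset(flags),
    )
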