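"""Demand side: insurance-group classification and preventive-care need.

Children are grouped by family income as a percentage of the federal
poverty level (FPL).  At or below 247% FPL a child is eligible for public
insurance (Medicaid/CHIP); above 400% FPL the family is assumed to hold
private dental insurance or to afford care out of pocket.  Children in the
247-400% band are excluded from the analysis: they are assumed to have
neither public eligibility nor reliable means to pay, and they enter no
assignment.

Need is denominated in annual provider-hours.  A :class:`NeedModel` maps
the population mix over age bands and caries-risk classes to expected
provider-hours per child per year; a tract's need is its child count times
that expectation.  Each tract-group's children are further split into
with-vehicle and without-vehicle sub-demands by the tract's vehicle
ownership fraction, because travel standards differ by mobility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Tract",
    "NeedBand",
    "NeedModel",
    "TractDemand",
    "classify_income",
    "tract_need",
    "build_demands",
    "GROUPS",
    "VEHICLE_CLASSES",
]

GROUPS = ("public", "private")
VEHICLE_CLASSES = ("vehicle", "no_vehicle")

#: county population below which every tract in the county is rural
RURAL_COUNTY_POP = 35_000

#: income cut points, percent of the federal poverty level
PUBLIC_FPL_MAX = 247.0
PRIVATE_FPL_MIN = 400.0


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0) or not math.isfinite(value):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class Tract:
    """A census tract: the demand node of the model.

    Parameters
    ----------
    tract_id, county_id
        Unique tract identifier and the identifier of the containing county.
    lon, lat
        WGS84 centroid coordinates in decimal degrees.
    rural
        True iff the containing county has population below 35,000.
    children_public, children_private, children_excluded
        Child counts by insurance group (<=247% FPL, >400% FPL, and the
        excluded 247-400% band respectively).
    vehicle_fraction
        Fraction of households with a personal vehicle; splits each group's
        children into mobility sub-demands.
    high_risk_fraction
        Tract-level share of children at elevated caries risk. The pipeline
        uses a statewide scalar sampled per microsimulation replicate; this
        field records the generator's nominal value.
    """

    tract_id: str
    county_id: str
    lon: float
    lat: float
    rural: bool
    children_public: float
    children_private: float
    children_excluded: float
    vehicle_fraction: float
    high_risk_fraction: float = 0.3

    def __post_init__(self) -> None:
        for name in ("children_public", "children_private", "children_excluded"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        _check_prob(self.vehicle_fraction, "vehicle_fraction")
        _check_prob(self.high_risk_fraction, "high_risk_fraction")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat!r} outside [-90, 90]")

    @property
    def children_total(self) -> float:
        return self.children_public + self.children_private + self.children_excluded

    def children_in(self, group: str) -> float:
        if group == "public":
            return self.children_public
        if group == "private":
            return self.children_private
        raise KeyError(group)


def classify_income(income_pct_fpl: float) -> str:
    """Classify a family income (% FPL) into an insurance group.

    ``<= 247`` -> ``"public"`` (Medicaid/CHIP-eligible), ``> 400`` ->
    ``"private"``, the band in between -> ``"excluded"``.
    """
    if not isinstance(income_pct_fpl, (int, float)) or isinstance(income_pct_fpl, bool):
        raise TypeError("income_pct_fpl must be a real number")
    if not math.isfinite(income_pct_fpl) or income_pct_fpl < 0:
        raise ValueError(
            f"income_pct_fpl must be finite and >= 0, got {income_pct_fpl!r}"
        )
    if income_pct_fpl <= PUBLIC_FPL_MAX:
        return "public"
    if income_pct_fpl > PRIVATE_FPL_MIN:
        return "private"
    return "excluded"


@dataclass(frozen=True)
class NeedBand:
    """One (age band, risk class) cell with its annual hours per child."""

    age_band: str
    risk_class: str  # "low" | "high"
    hours_per_child_year: float

    def __post_init__(self) -> None:
        if self.risk_class not in ("low", "high"):
            raise ValueError(f"risk_class must be 'low' or 'high', got {self.risk_class!r}")
        if not math.isfinite(self.hours_per_child_year) or self.hours_per_child_year <= 0:
            raise ValueError("hours_per_child_year must be positive and finite")


@dataclass(frozen=True)
class NeedModel:
    """Expected annual preventive provider-hours per child.

    The population is a product mix over age bands (fixed weights) and risk
    classes (weight of the high-risk class supplied at evaluation time as
    the statewide high-risk fraction). Defaults carry two age bands and two
    risk classes with placeholder hours in the range of periodicity-schedule
    estimates; the values are configuration, not constants.
    """

    bands: tuple[NeedBand, ...] = (
        NeedBand("0-5", "low", 0.9),
        NeedBand("0-5", "high", 1.8),
        NeedBand("6-18", "low", 0.7),
        NeedBand("6-18", "high", 1.5),
    )
    age_weights: dict[str, float] = field(
        default_factory=lambda: {"0-5": 0.32, "6-18": 0.68}
    )

    def __post_init__(self) -> None:
        ages = {b.age_band for b in self.bands}
        if ages != set(self.age_weights):
            raise ValueError("age_weights keys must match the band age bands")
        total = sum(self.age_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"age_weights must sum to 1 (got {total})")
        for a in ages:
            if not ({b.risk_class for b in self.bands if b.age_band == a} == {"low", "high"}):
                raise ValueError(f"age band {a!r} must have both risk classes")

    def band_weights(self, high_risk_fraction: float) -> dict[NeedBand, float]:
        """Joint band probabilities at a given statewide high-risk fraction."""
        _check_prob(high_risk_fraction, "high_risk_fraction")
        out: dict[NeedBand, float] = {}
        for b in self.bands:
            risk_w = high_risk_fraction if b.risk_class == "high" else 1.0 - high_risk_fraction
            out[b] = self.age_weights[b.age_band] * risk_w
        return out

    def hours_per_child(self, high_risk_fraction: float) -> float:
        """Expected provider-hours per child per year at the given risk mix."""
        w = self.band_weights(high_risk_fraction)
        return sum(wi * b.hours_per_child_year for b, wi in w.items())


@dataclass(frozen=True)
class TractDemand:
    """One demand record: a (tract, insurance group, vehicle class) cell."""

    tract_id: str
    group: str
    vehicle_class: str
    children: float
    need_hours: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.vehicle_class not in VEHICLE_CLASSES:
            raise ValueError(
                f"vehicle_class must be one of {VEHICLE_CLASSES}, got {self.vehicle_class!r}"
            )
        if self.children < 0 or self.need_hours < 0:
            raise ValueError("children and need_hours must be >= 0")

    @property
    def hours_per_child(self) -> float:
        """Hours a single child of this record consumes (0 if no children)."""
        return self.need_hours / self.children if self.children > 0 else 0.0


def tract_need(
    tract: Tract, model: NeedModel, high_risk_fraction: float
) -> list[TractDemand]:
    """Convert one tract's child counts into four demand records.

    Emits (public, private) x (vehicle, no_vehicle); children are split by
    the tract's vehicle fraction and hours per child come from the need
    model at the supplied statewide high-risk fraction. Excluded children
    (247-400% FPL, uninsured) generate no demand.
    """
    h = model.hours_per_child(high_risk_fraction)
    records = []
    for group in GROUPS:
        n = tract.children_in(group)
        for vc, frac in (
            ("vehicle", tract.vehicle_fraction),
            ("no_vehicle", 1.0 - tract.vehicle_fraction),
        ):
            kids = n * frac
            records.append(
                TractDemand(
                    tract_id=tract.tract_id,
                    group=group,
                    vehicle_class=vc,
                    children=kids,
                    need_hours=kids * h,
                )
            )
    return records


def build_demands(
    tracts: Iterable[Tract], model: NeedModel, high_risk_fraction: float
) -> list[TractDemand]:
    """Demand records for every tract, in tract order."""
    out: list[TractDemand] = []
    for t in tracts:
        out.extend(tract_need(t, model, high_risk_fraction))
    return out
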