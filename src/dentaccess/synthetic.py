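"""Synthetic state generator: tracts, providers, and full problem instances.

Emulates a US state with an urban/rural mix resembling Georgia's: ~2,000
census tracts of which roughly three quarters are urban, ~2.6 million
children of whom ~58% are public-insurance-eligible and ~23% privately
insured, and ~16 dentists per 10,000 children of whom a minority (~28%)
accept public insurance. Rural counties (population < 35,000) hold the
rural tracts; urban tracts cluster around synthetic city centers while
rural tracts disperse. Nothing here reproduces actual Georgia geography;
the generator's job is to give every downstream stage realistic structure
with no data download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .demand import RURAL_COUNTY_POP, NeedModel, Tract
from .distances import AccessStandards, DistanceMatrix, build_distance_matrix
from .supply import ProviderSite, provider_capacity, sample_capacity_multipliers

__all__ = [
    "SyntheticConfig",
    "ProblemInstance",
    "generate_tracts",
    "generate_providers",
    "generate_instance",
]

# bounding box loosely shaped like a southeastern US state (degrees)
_LON_RANGE = (-85.6, -81.0)
_LAT_RANGE = (30.4, 35.0)


def _check_interval(iv: tuple[float, float], name: str) -> None:
    lo, hi = iv
    if not (0.0 <= lo <= hi <= 1.0) or not (math.isfinite(lo) and math.isfinite(hi)):
        raise ValueError(f"{name} must satisfy 0 <= lo <= hi <= 1, got {iv!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic state.

    Defaults encode the statewide conditions the model assumes: 1,527
    urban and 442 rural tracts, ~1,320 children per tract on average,
    an income split of 58% public-eligible / 19% excluded / 23% private,
    27.9% of dentists accepting public insurance, and public caseload
    ranges of 35-50% (urban) and 55-65% (rural).
    """

    n_tracts_urban: int = 1527
    n_tracts_rural: int = 442
    children_per_tract_mean: float = 1320.0
    children_per_tract_cv: float = 0.45
    income_split: tuple[float, float, float] = (0.58, 0.19, 0.23)  # public, excluded, private
    vehicle_ownership_urban: float = 0.93
    vehicle_ownership_rural: float = 0.88
    providers_per_10k_children_urban: float = 17.5
    providers_per_10k_children_rural: float = 9.0
    acceptance_rate: float = 0.279
    urban_caseload_range: tuple[float, float] = (0.35, 0.50)
    rural_caseload_range: tuple[float, float] = (0.55, 0.65)
    high_risk_fraction_range: tuple[float, float] = (0.20, 0.40)
    provider_base_hours: float = 1700.0
    prevention_fraction: float = 0.35
    pediatric_fraction: float = 1.0
    capacity_cv: float = 0.2
    n_cities: int = 8
    urban_scatter_deg: float = 0.09
    max_office_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracts_urban < 0 or self.n_tracts_rural < 0:
            raise ValueError("tract counts must be >= 0")
        if self.n_tracts_urban + self.n_tracts_rural == 0:
            raise ValueError("at least one tract is required")
        for name in ("children_per_tract_mean", "children_per_tract_cv"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.children_per_tract_mean <= 0:
            raise ValueError("children_per_tract_mean must be positive")
        if any((not math.isfinite(p)) or p < 0 for p in self.income_split):
            raise ValueError("income_split entries must be finite and >= 0")
        if abs(sum(self.income_split) - 1.0) > 1e-9:
            raise ValueError("income_split must sum to 1 within 1e-9")
        for name in ("vehicle_ownership_urban", "vehicle_ownership_rural", "acceptance_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "providers_per_10k_children_urban",
            "providers_per_10k_children_rural",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite")
        _check_interval(self.urban_caseload_range, "urban_caseload_range")
        _check_interval(self.rural_caseload_range, "rural_caseload_range")
        _check_interval(self.high_risk_fraction_range, "high_risk_fraction_range")
        if self.n_cities < 1:
            raise ValueError("n_cities must be >= 1")
        if self.max_office_size < 1:
            raise ValueError("max_office_size must be >= 1")

    @classmethod
    def test_profile(cls, seed: int = 0) -> "SyntheticConfig":
        """Scaled-down state (~200 tracts, ~150 providers) for fast runs.

        Children per tract are thinned so that the full-scale
        provider-per-child densities yield ~150 dentists; the
        capacity-to-need ratio of the default state is preserved.
        """
        return cls(
            n_tracts_urban=155,
            n_tracts_rural=45,
            children_per_tract_mean=470.0,
            n_cities=4,
            seed=seed,
        )

    def scaled(self, fraction: float, seed: int | None = None) -> "SyntheticConfig":
        """Shrink tract counts by ``fraction``, keeping densities and rates."""
        if not (0.0 < fraction <= 1.0):
            raise ValueError("fraction must be in (0, 1]")
        return replace(
            self,
            n_tracts_urban=max(1, round(self.n_tracts_urban * fraction)),
            n_tracts_rural=max(1, round(self.n_tracts_rural * fraction)),
            n_cities=max(1, round(self.n_cities * math.sqrt(fraction))),
            seed=self.seed if seed is None else seed,
        )


@dataclass(frozen=True)
class ProblemInstance:
    """A complete solvable problem: tracts, providers, distances, standards."""

    tracts: tuple[Tract, ...]
    providers: tuple[ProviderSite, ...]
    distance: DistanceMatrix
    standards: AccessStandards = field(default_factory=AccessStandards)
    need_model: NeedModel = field(default_factory=NeedModel)

    def __post_init__(self) -> None:
        tids = [t.tract_id for t in self.tracts]
        pids = [p.provider_id for p in self.providers]
        if len(set(tids)) != len(tids):
            raise ValueError("tract ids must be unique")
        if len(set(pids)) != len(pids):
            raise ValueError("provider ids must be unique")
        if self.distance.shape != (len(tids), len(pids)):
            raise ValueError("distance matrix dimensions do not match tracts/providers")
        if tuple(tids) != self.distance.tract_ids or tuple(pids) != self.distance.provider_ids:
            raise ValueError("distance matrix id order does not match tracts/providers")

    @property
    def n_tracts(self) -> int:
        return len(self.tracts)

    @property
    def n_providers(self) -> int:
        return len(self.providers)

    def rural_tracts(self) -> np.ndarray:
        return np.array([t.rural for t in self.tracts], dtype=bool)

    def capacity_hours(self) -> np.ndarray:
        return np.array([p.capacity_hours for p in self.providers], dtype=float)

    def acceptance(self) -> np.ndarray:
        return np.array([p.accepts_public for p in self.providers], dtype=bool)

    def caseload_fractions(self) -> np.ndarray:
        return np.array(
            [p.public_caseload_fraction for p in self.providers], dtype=float
        )


def _sample_counts(
    mean: float, cv: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Right-skewed integer tract child counts with the given mean and CV."""
    if cv == 0:
        return np.full(n, round(mean), dtype=int)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return np.maximum(
        1, np.round(rng.lognormal(mu, math.sqrt(sigma2), size=n)).astype(int)
    )


def generate_tracts(
    config: SyntheticConfig, rng: np.random.Generator
) -> list[Tract]:
    """Generate urban then rural tracts with synthetic county assignments.

    Urban tracts scatter (Gaussian) around city centers and sit in counties
    with population >= 35,000; rural tracts are uniform over the box in
    small counties (< 35,000). Child counts per income band are multinomial
    draws from the configured split.
    """
    n_urban, n_rural = config.n_tracts_urban, config.n_tracts_rural
    tracts: list[Tract] = []

    cities = np.column_stack(
        [
            rng.uniform(_LON_RANGE[0] + 0.4, _LON_RANGE[1] - 0.4, config.n_cities),
            rng.uniform(_LAT_RANGE[0] + 0.4, _LAT_RANGE[1] - 0.4, config.n_cities),
        ]
    )
    # larger cities attract more tracts
    city_w = rng.dirichlet(np.full(config.n_cities, 1.5))

    counts = _sample_counts(
        config.children_per_tract_mean,
        config.children_per_tract_cv,
        n_urban + n_rural,
        rng,
    )
    splits = rng.multinomial(counts, np.asarray(config.income_split))

    # urban counties: ~30 tracts each; rural counties: ~5 tracts each
    n_urban_counties = max(1, round(n_urban / 30)) if n_urban else 0
    n_rural_counties = max(1, round(n_rural / 5)) if n_rural else 0

    for i in range(n_urban):
        c = rng.choice(config.n_cities, p=city_w)
        lon = float(np.clip(rng.normal(cities[c, 0], config.urban_scatter_deg), *_LON_RANGE))
        lat = float(np.clip(rng.normal(cities[c, 1], config.urban_scatter_deg), *_LAT_RANGE))
        county = f"CU{(i % n_urban_counties):03d}"
        vf = float(np.clip(rng.beta(50 * config.vehicle_ownership_urban + 1e-9,
                                    50 * (1 - config.vehicle_ownership_urban) + 1e-9), 0, 1))
        pub, exc, priv = (int(x) for x in splits[i])
        tracts.append(
            Tract(
                tract_id=f"T{i:05d}",
                county_id=county,
                lon=lon,
                lat=lat,
                rural=False,
                children_public=pub,
                children_private=priv,
                children_excluded=exc,
                vehicle_fraction=vf,
                high_risk_fraction=float(np.mean(config.high_risk_fraction_range)),
            )
        )
    for j in range(n_rural):
        i = n_urban + j
        lon = float(rng.uniform(*_LON_RANGE))
        lat = float(rng.uniform(*_LAT_RANGE))
        county = f"CR{(j % n_rural_counties):03d}"
        vf = float(np.clip(rng.beta(50 * config.vehicle_ownership_rural + 1e-9,
                                    50 * (1 - config.vehicle_ownership_rural) + 1e-9), 0, 1))
        pub, exc, priv = (int(x) for x in splits[i])
        tracts.append(
            Tract(
                tract_id=f"T{i:05d}",
                county_id=county,
                lon=lon,
                lat=lat,
                rural=True,
                children_public=pub,
                children_private=priv,
                children_excluded=exc,
                vehicle_fraction=vf,
                high_risk_fraction=float(np.mean(config.high_risk_fraction_range)),
            )
        )

    # county populations consistent with the < 35,000 rurality rule
    _validate_county_rule(tracts)
    return tracts


def _validate_county_rule(tracts: Sequence[Tract]) -> None:
    by_county: dict[str, bool] = {}
    for t in tracts:
        prev = by_county.setdefault(t.county_id, t.rural)
        if prev != t.rural:
            raise AssertionError("county mixes urban and rural tracts")


def county_populations(
    tracts: Sequence[Tract], rng: np.random.Generator
) -> dict[str, int]:
    """Synthetic county populations honoring the 35,000 rurality cut."""
    pops: dict[str, int] = {}
    for t in tracts:
        if t.county_id in pops:
            continue
        if t.rural:
            pops[t.county_id] = int(rng.integers(5_000, RURAL_COUNTY_POP))
        else:
            pops[t.county_id] = int(RURAL_COUNTY_POP + rng.integers(0, 900_000))
    return pops


def generate_providers(
    tracts: Sequence[Tract], config: SyntheticConfig, rng: np.random.Generator
) -> list[ProviderSite]:
    """Generate provider sites near tract centroids, grouped into offices.

    Provider counts scale with child population per rurality class at the
    configured densities. Offices hold 1-8 dentists (truncated-geometric
    sizes, mean ~2) at a shared jittered location; acceptance flags are
    i.i.d. Bernoulli(acceptance_rate) and accepting dentists draw a public
    caseload fraction from their rurality's range.
    """
    if not tracts:
        raise ValueError("tracts must be non-empty")
    tract_list = list(tracts)

    providers: list[ProviderSite] = []
    pid = 0
    oid = 0
    base_capacity = provider_capacity(
        config.provider_base_hours, config.prevention_fraction, config.pediatric_fraction
    )
    for rural in (False, True):
        sub = [t for t in tract_list if t.rural == rural]
        if not sub:
            continue
        children = np.array([t.children_total for t in sub], dtype=float)
        density = (
            config.providers_per_10k_children_rural
            if rural
            else config.providers_per_10k_children_urban
        )
        n_prov = int(round(children.sum() / 10_000.0 * density))
        if n_prov == 0:
            continue
        w = children / children.sum() if children.sum() > 0 else None
        caseload_range = (
            config.rural_caseload_range if rural else config.urban_caseload_range
        )
        mult = sample_capacity_multipliers(n_prov, config.capacity_cv, rng)
        placed = 0
        while placed < n_prov:
            size = min(
                int(rng.geometric(0.5)), config.max_office_size, n_prov - placed
            )
            anchor = sub[int(rng.choice(len(sub), p=w))]
            lon = float(np.clip(anchor.lon + rng.normal(0, 0.02), *_LON_RANGE))
            lat = float(np.clip(anchor.lat + rng.normal(0, 0.02), *_LAT_RANGE))
            office_id = f"O{oid:05d}"
            oid += 1
            for _ in range(size):
                accepts = bool(rng.random() < config.acceptance_rate)
                lo, hi = caseload_range
                caseload = float(rng.uniform(lo, hi)) if accepts else 0.0
                providers.append(
                    ProviderSite(
                        provider_id=f"P{pid:05d}",
                        office_id=office_id,
                        lon=lon,
                        lat=lat,
                        rural=rural,
                        capacity_hours=float(base_capacity * mult[placed]),
                        accepts_public=accepts,
                        public_caseload_fraction=caseload,
                    )
                )
                pid += 1
                placed += 1
    if not providers:
        raise ValueError("configured densities produced zero providers")
    return providers


def generate_instance(config: SyntheticConfig) -> ProblemInstance:
    """Compose a fully reproducible problem instance from a config."""
    rng = np.random.default_rng(config.seed)
    tracts = generate_tracts(config, rng)
    providers = generate_providers(tracts, config, rng)
    distance = build_distance_matrix(tracts, providers)
    return ProblemInstance(
        tracts=tuple(tracts),
        providers=tuple(providers),
        distance=distance,
        standards=AccessStandards(),
        need_model=NeedModel(),
    )
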