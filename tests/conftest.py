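import math

import numpy as np
import pytest
from hypothesis import settings

from dentaccess import (
    AccessStandards,
    NeedBand,
    NeedModel,
    ProblemInstance,
    ProviderSite,
    SyntheticConfig,
    Tract,
    TractDemand,
    build_distance_matrix,
    generate_instance,
)
from dentaccess.distances import EARTH_RADIUS_MI

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

#: miles per degree of latitude on the great-circle metric; a pure
#: latitude offset of d/MI_PER_DEG_LAT degrees is exactly d miles
MI_PER_DEG_LAT = math.pi * EARTH_RADIUS_MI / 180.0

BASE_LON, BASE_LAT = -83.0, 33.0


def flat_need_model(hours: float = 1.0) -> NeedModel:
    """Need model where every child needs exactly ``hours`` per year."""
    return NeedModel(
        bands=(
            NeedBand("0-5", "low", hours),
            NeedBand("0-5", "high", hours),
            NeedBand("6-18", "low", hours),
            NeedBand("6-18", "high", hours),
        ),
        age_weights={"0-5": 0.5, "6-18": 0.5},
    )


def make_tract(
    tract_id: str,
    miles_north: float = 0.0,
    *,
    rural: bool = False,
    public: float = 0.0,
    private: float = 0.0,
    excluded: float = 0.0,
    vehicle_fraction: float = 1.0,
) -> Tract:
    return Tract(
        tract_id=tract_id,
        county_id=("CR0" if rural else "CU0"),
        lon=BASE_LON,
        lat=BASE_LAT + miles_north / MI_PER_DEG_LAT,
        rural=rural,
        children_public=public,
        children_private=private,
        children_excluded=excluded,
        vehicle_fraction=vehicle_fraction,
    )


def make_provider(
    provider_id: str,
    miles_north: float = 0.0,
    *,
    rural: bool = False,
    capacity: float = 1e6,
    accepts: bool = True,
    caseload: float = 1.0,
    office_id: str = "OFF0",
) -> ProviderSite:
    return ProviderSite(
        provider_id=provider_id,
        office_id=office_id,
        lon=BASE_LON,
        lat=BASE_LAT + miles_north / MI_PER_DEG_LAT,
        rural=rural,
        capacity_hours=capacity,
        accepts_public=accepts,
        public_caseload_fraction=caseload if accepts else 0.0,
    )


def make_instance(tracts, providers, standards=None, need_model=None) -> ProblemInstance:
    return ProblemInstance(
        tracts=tuple(tracts),
        providers=tuple(providers),
        distance=build_distance_matrix(list(tracts), list(providers)),
        standards=standards or AccessStandards(),
        need_model=need_model or flat_need_model(),
    )


def demand(tract_id, group, children, *, vehicle_class="vehicle", hours_per_child=1.0):
    return TractDemand(
        tract_id=tract_id,
        group=group,
        vehicle_class=vehicle_class,
        children=children,
        need_hours=children * hours_per_child,
    )


@pytest.fixture(scope="session")
def test_instance():
    """The scaled-down default synthetic state (~200 tracts, ~150 providers)."""
    return generate_instance(SyntheticConfig.test_profile(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
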