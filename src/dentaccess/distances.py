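"""Tract-provider distances and the travel-standard feasibility mask.

State access standards cap how far a child may travel to a provider for
that provider to count as accessible: 30 miles urban / 45 miles rural for
families with a vehicle, 8 miles urban / 15 miles rural without one.
Thresholds attach to the tract of residence, and the boundary is
inclusive ("does not exceed").

Distances default to great-circle (haversine) miles between tract
centroids and provider addresses. This understates road miles; an
external distance table (e.g. street-network distances) can be supplied
instead and is passed through untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .demand import Tract, TractDemand
    from .supply import ProviderSite

__all__ = [
    "EARTH_RADIUS_MI",
    "AccessStandards",
    "DistanceMatrix",
    "haversine_miles",
    "build_distance_matrix",
    "distance_matrix_from_table",
    "feasible",
    "feasibility_mask",
]

#: mean Earth radius in statute miles
EARTH_RADIUS_MI = 3958.8


@dataclass(frozen=True)
class AccessStandards:
    """Maximum 1-way travel miles by rurality and vehicle ownership."""

    vehicle_urban_mi: float = 30.0
    vehicle_rural_mi: float = 45.0
    no_vehicle_urban_mi: float = 8.0
    no_vehicle_rural_mi: float = 15.0

    def __post_init__(self) -> None:
        for name in (
            "vehicle_urban_mi",
            "vehicle_rural_mi",
            "no_vehicle_urban_mi",
            "no_vehicle_rural_mi",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.no_vehicle_urban_mi > self.vehicle_urban_mi:
            raise ValueError("no-vehicle urban threshold exceeds vehicle urban threshold")
        if self.no_vehicle_rural_mi > self.vehicle_rural_mi:
            raise ValueError("no-vehicle rural threshold exceeds vehicle rural threshold")

    def threshold(self, rural: bool, vehicle_class: str) -> float:
        """Threshold in miles for a tract's rurality and a mobility class."""
        if vehicle_class == "vehicle":
            return self.vehicle_rural_mi if rural else self.vehicle_urban_mi
        if vehicle_class == "no_vehicle":
            return self.no_vehicle_rural_mi if rural else self.no_vehicle_urban_mi
        raise KeyError(vehicle_class)

    def with_vehicle_threshold(self, miles: float) -> "AccessStandards":
        """Copy with both vehicle thresholds replaced (policy sweep).

        No-vehicle thresholds are untouched but clipped to the new vehicle
        threshold so the standards invariant still holds.
        """
        return AccessStandards(
            vehicle_urban_mi=miles,
            vehicle_rural_mi=miles,
            no_vehicle_urban_mi=min(self.no_vehicle_urban_mi, miles),
            no_vehicle_rural_mi=min(self.no_vehicle_rural_mi, miles),
        )


def haversine_miles(
    lon1: np.ndarray | float,
    lat1: np.ndarray | float,
    lon2: np.ndarray | float,
    lat2: np.ndarray | float,
) -> np.ndarray | float:
    """Great-circle distance in statute miles (Earth radius 3958.8 mi)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_MI * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class DistanceMatrix:
    """Dense tract x provider distance matrix in statute miles."""

    miles: np.ndarray
    tract_ids: tuple[str, ...]
    provider_ids: tuple[str, ...]
    metric: str = "haversine"  # "haversine" | "euclidean" | "external-table"

    def __post_init__(self) -> None:
        m = np.asarray(self.miles, dtype=float)
        if m.shape != (len(self.tract_ids), len(self.provider_ids)):
            raise ValueError(
                f"distance matrix shape {m.shape} does not match "
                f"{len(self.tract_ids)} tracts x {len(self.provider_ids)} providers"
            )
        if not np.all(np.isfinite(m)) or (m < 0).any():
            raise ValueError("distances must be finite and >= 0")
        object.__setattr__(self, "miles", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.miles.shape

    def tract_index(self, tract_id: str) -> int:
        return self.tract_ids.index(tract_id)

    def provider_index(self, provider_id: str) -> int:
        return self.provider_ids.index(provider_id)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (tract_id, provider_id, miles)."""
        ti, pi = np.meshgrid(
            np.arange(len(self.tract_ids)), np.arange(len(self.provider_ids)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "tract_id": np.asarray(self.tract_ids)[ti.ravel()],
                "provider_id": np.asarray(self.provider_ids)[pi.ravel()],
                "miles": self.miles.ravel(),
            }
        )


def build_distance_matrix(
    tracts: Sequence["Tract"], providers: Sequence["ProviderSite"]
) -> DistanceMatrix:
    """Haversine distances between every tract centroid and provider."""
    tlon = np.array([t.lon for t in tracts])
    tlat = np.array([t.lat for t in tracts])
    plon = np.array([p.lon for p in providers])
    plat = np.array([p.lat for p in providers])
    if np.any(np.abs(tlat) > 90) or np.any(np.abs(plat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    miles = haversine_miles(
        tlon[:, None], tlat[:, None], plon[None, :], plat[None, :]
    )
    return DistanceMatrix(
        miles=np.asarray(miles, dtype=float),
        tract_ids=tuple(t.tract_id for t in tracts),
        provider_ids=tuple(p.provider_id for p in providers),
        metric="haversine",
    )


def distance_matrix_from_table(
    table: pd.DataFrame,
    tracts: Sequence["Tract"],
    providers: Sequence["ProviderSite"],
) -> DistanceMatrix:
    """Build a matrix from a long (tract_id, provider_id, miles) table.

    Every tract-provider pair must be present; a missing pair raises with
    the offending ids named.
    """
    required = {"tract_id", "provider_id", "miles"}
    if not required.issubset(table.columns):
        raise ValueError(f"distance table must have columns {sorted(required)}")
    tids = [t.tract_id for t in tracts]
    pids = [p.provider_id for p in providers]
    wide = table.pivot_table(
        index="tract_id", columns="provider_id", values="miles", aggfunc="first"
    )
    try:
        wide = wide.loc[tids, pids]
    except KeyError as e:
        raise ValueError(f"distance table missing ids: {e}") from None
    if wide.isna().any().any():
        ti, pi = np.argwhere(wide.isna().to_numpy())[0]
        raise ValueError(
            f"distance table missing pair (tract {tids[ti]!r}, provider {pids[pi]!r})"
        )
    return DistanceMatrix(
        miles=wide.to_numpy(dtype=float),
        tract_ids=tuple(tids),
        provider_ids=tuple(pids),
        metric="external-table",
    )


def feasible(
    demand: "TractDemand",
    tract: "Tract",
    provider: "ProviderSite",
    D: DistanceMatrix,
    S: AccessStandards,
) -> bool:
    """True iff the provider is within the demand's travel standard."""
    miles = D.miles[D.tract_index(tract.tract_id), D.provider_index(provider.provider_id)]
    return bool(miles <= S.threshold(tract.rural, demand.vehicle_class))


def feasibility_mask(
    D: DistanceMatrix, rural: np.ndarray, standards: AccessStandards
) -> dict[str, np.ndarray]:
    """Boolean tract x provider mask per vehicle class.

    ``rural`` is the per-tract rurality vector aligned with the matrix rows.
    Raising any threshold can only grow the mask.
    """
    rural = np.asarray(rural, dtype=bool)
    if rural.shape[0] != D.shape[0]:
        raise ValueError("rural vector length does not match distance matrix rows")
    out: dict[str, np.ndarray] = {}
    for vc in ("vehicle", "no_vehicle"):
        thr = np.where(
            rural,
            standards.threshold(True, vc),
            standards.threshold(False, vc),
        )
        out[vc] = D.miles <= thr[:, None]
    return out
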