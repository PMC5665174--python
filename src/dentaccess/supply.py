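"""Supply side: provider capacity, roster linkage, and public caseload.

A provider site is a dentist practising at a geocoded office address with
an annual pediatric-preventive capacity in provider-hours. Whether a
dentist accepts public insurance is determined by linking the state
licensure roster against a public-insurance provider directory with
approximate string matching; because directories list offices, acceptance
propagates to every dentist sharing a matched office. Accepting dentists
devote only a fraction of capacity to publicly insured children (the public
caseload fraction), sampled uniformly from rurality-specific ranges:
35-50% urban, 55-65% rural.
"""

from __future__ import annotations

import math
import re
import string
from dataclasses import dataclass
from difflib import SequenceMatcher
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ProviderSite",
    "RosterRecord",
    "provider_capacity",
    "normalize_record_text",
    "token_set_similarity",
    "link_rosters",
    "sample_caseload",
    "sample_capacity_multipliers",
]


@dataclass(frozen=True)
class ProviderSite:
    """One dentist at one office: the supply node of the model."""

    provider_id: str
    office_id: str
    lon: float
    lat: float
    rural: bool
    capacity_hours: float
    accepts_public: bool
    public_caseload_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.capacity_hours) or self.capacity_hours < 0:
            raise ValueError("capacity_hours must be finite and >= 0")
        if not (0.0 <= self.public_caseload_fraction <= 1.0):
            raise ValueError("public_caseload_fraction must be in [0, 1]")
        if not self.accepts_public and self.public_caseload_fraction != 0.0:
            raise ValueError(
                "public_caseload_fraction must be 0 for a provider that does "
                "not accept public insurance"
            )
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat!r} outside [-90, 90]")

    @property
    def public_capacity_hours(self) -> float:
        """Hours nominally reserved for publicly insured children."""
        return self.capacity_hours * self.public_caseload_fraction


@dataclass(frozen=True)
class RosterRecord:
    """A raw roster entry from either the licensure list or the directory.

    Licensure records carry the provider and office identifiers used to
    propagate a match; directory records need only the text fields.
    """

    name: str
    address: str
    office_name: str = ""
    source: str = "licensure"  # "licensure" | "public-insurance-directory"
    provider_id: str | None = None
    office_id: str | None = None

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError("roster record name must be non-empty")


def provider_capacity(
    total_hours: float, prevention_fraction: float, pediatric_fraction: float
) -> float:
    """Annual pediatric-preventive capacity in provider-hours.

    ``total_hours`` is the dentist's annual chair time; the two fractions
    carve out the share of services that are preventive and the share of
    the patient mix that is pediatric.
    """
    if not math.isfinite(total_hours) or total_hours <= 0:
        raise ValueError("total_hours must be positive and finite")
    for name, v in (
        ("prevention_fraction", prevention_fraction),
        ("pediatric_fraction", pediatric_fraction),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v!r}")
    return total_hours * prevention_fraction * pediatric_fraction


# -- record linkage ----------------------------------------------------------

_SUFFIXES = re.compile(r"\b(dds|dmd|pc|llc|inc|dr|jr|sr|ii|iii)\b")
_PUNCT = str.maketrans({c: " " for c in string.punctuation})


def normalize_record_text(record: RosterRecord) -> str:
    """Canonical comparison string: lowercased name+address, punctuation
    stripped, professional/corporate suffixes (DDS, DMD, PC, ...) removed.

    Periods are deleted (not blanked) first so dotted credentials like
    "D.D.S." collapse to a removable token."""
    text = f"{record.name} {record.address}".lower().replace(".", "")
    text = text.translate(_PUNCT)
    text = _SUFFIXES.sub(" ", text)
    return " ".join(text.split())


def token_set_similarity(a: str, b: str) -> float:
    """Normalized token-set ratio in [0, 1].

    Tokens common to both strings anchor the comparison so word order and
    one-sided extras (middle initials, suite numbers) are forgiven; the
    residual difference is scored with difflib's ratio.
    """
    ta, tb = set(a.split()), set(b.split())
    if not ta and not tb:
        return 1.0
    inter = " ".join(sorted(ta & tb))
    sa = (inter + " " + " ".join(sorted(ta - tb))).strip()
    sb = (inter + " " + " ".join(sorted(tb - ta))).strip()
    pairs = [(inter, sa), (inter, sb), (sa, sb)]
    # difflib's ratio is order-sensitive; score both orders for symmetry
    return max(
        max(SequenceMatcher(None, x, y).ratio(), SequenceMatcher(None, y, x).ratio())
        for x, y in pairs
    )


def link_rosters(
    licensure: Sequence[RosterRecord],
    directory: Sequence[RosterRecord],
    similarity_threshold: float = 0.90,
) -> dict[str, bool]:
    """Flag licensure providers that accept public insurance.

    The directory is deduplicated on exact normalized text; each remaining
    directory record is matched to at most one licensure record with
    token-set similarity at or above the threshold (greedy, descending
    similarity; ties broken lexicographically so record order is
    irrelevant). A match flags the licensure provider and, through its
    office id, every colleague at the same office.

    Returns a mapping ``provider_id -> accepts_public`` covering every
    licensure record with a provider id.
    """
    if not (0.0 <= similarity_threshold <= 1.0):
        raise ValueError("similarity_threshold must be in [0, 1]")
    if not licensure or not directory:
        raise ValueError("both rosters must be non-empty")

    lic = sorted(
        (r for r in licensure if r.provider_id is not None),
        key=lambda r: r.provider_id,
    )
    if not lic:
        raise ValueError("licensure roster carries no provider ids")
    lic_text = [normalize_record_text(r) for r in lic]

    seen: set[str] = set()
    dir_dedup: list[tuple[str, RosterRecord]] = []
    for r in directory:
        key = normalize_record_text(r)
        if key not in seen:
            seen.add(key)
            dir_dedup.append((key, r))
    dir_dedup.sort(key=lambda kr: kr[0])

    # all candidate pairs at/above threshold, best first, deterministic ties
    candidates: list[tuple[float, str, int, int]] = []
    for j, (dtext, _) in enumerate(dir_dedup):
        for i, ltext in enumerate(lic_text):
            s = token_set_similarity(dtext, ltext)
            if s >= similarity_threshold:
                candidates.append((s, lic[i].provider_id, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1], dir_dedup[c[3]][0]))

    matched_lic: set[int] = set()
    matched_dir: set[int] = set()
    for s, _, i, j in candidates:
        if i in matched_lic or j in matched_dir:
            continue
        matched_lic.add(i)
        matched_dir.add(j)

    accepting_offices = {
        lic[i].office_id for i in matched_lic if lic[i].office_id is not None
    }
    flags: dict[str, bool] = {}
    for i, r in enumerate(lic):
        by_office = r.office_id is not None and r.office_id in accepting_offices
        flags[r.provider_id] = (i in matched_lic) or by_office
    return flags


# -- caseload and capacity heterogeneity ------------------------------------


def sample_caseload(
    provider: ProviderSite,
    urban_range: tuple[float, float],
    rural_range: tuple[float, float],
    rng: np.random.Generator,
) -> float:
    """Draw the provider's public caseload fraction.

    Uniform over the rurality-appropriate interval; only meaningful for an
    accepting provider.
    """
    if not provider.accepts_public:
        raise ValueError(
            f"provider {provider.provider_id} does not accept public insurance"
        )
    lo, hi = rural_range if provider.rural else urban_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("caseload range must satisfy 0 <= lo <= hi <= 1")
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def sample_capacity_multipliers(
    n: int, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Mean-1 lognormal multipliers giving providers heterogeneous capacity.

    ``cv`` is the coefficient of variation (default pipeline value 0.2);
    cv=0 returns ones.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
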