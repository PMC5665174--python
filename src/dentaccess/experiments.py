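"""Microsimulation ensemble and policy sweeps.

Provider public-insurance caseload fractions and the statewide share of
high-caries-risk children are uncertain; the pipeline propagates that
uncertainty by re-drawing both, rebuilding demand, and re-solving the
assignment across replicates (65 by default). Three policy levers are
swept the same way:

acceptance rate
    the share of dentists accepting public insurance (20-80% around the
    observed minority rate of ~28%); accepting sets are nested across
    rates so curves are monotone and comparable,
caseload level
    the public caseload fraction of currently accepting dentists held
    constant at each level (20-75%),
maximum travel distance
    the with-vehicle standard for both rurality classes (30-60 miles).

Replicate random streams are derived from the master seed and the
replicate index only, so draws are coupled across sweep levels: moving a
lever, not re-rolling luck, is what changes the curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .demand import build_demands
from .distances import AccessStandards
from .measures import compute_access_report
from .optimizer import AssignmentSolution, solve_assignment
from .synthetic import ProblemInstance

__all__ = [
    "Ensemble",
    "PolicyGrid",
    "run_microsim",
    "sweep_acceptance",
    "sweep_caseload",
    "sweep_max_distance",
    "plot_policy_curves",
]

DEFAULT_N_REPLICATES = 65


@dataclass
class Ensemble:
    """Access reports across microsimulation replicates of one instance."""

    reports: pd.DataFrame  # long: replicate + compute_access_report columns
    params: pd.DataFrame  # per replicate: high_risk_fraction, mean caseload
    n: int
    failed: tuple[int, ...] = ()
    instance: ProblemInstance | None = field(default=None, repr=False)

    @property
    def completeness(self) -> float:
        return 1.0 - len(self.failed) / self.n if self.n else 0.0

    @property
    def n_ok(self) -> int:
        return self.n - len(self.failed)


@dataclass
class PolicyGrid:
    """Median access measures along one policy lever.

    ``medians`` is tidy: level, region, group, measure, median — medians
    pooled over tracts and replicates, matching how sweep curves are
    reported. ``reports`` keeps the full per-tract distributions.
    """

    param: str
    levels: tuple[float, ...]
    medians: pd.DataFrame
    reports: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def curve(self, measure: str, region: str = "all", group: str = "public") -> pd.Series:
        sub = self.medians[
            (self.medians["measure"] == measure)
            & (self.medians["region"] == region)
            & (self.medians["group"] == group)
        ]
        return sub.set_index("level")["median"].sort_index()


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    # stream depends on (seed, replicate) only -> coupled across sweep levels
    return np.random.default_rng(np.random.SeedSequence((seed, replicate)))


def _draw_caseloads(
    instance: ProblemInstance,
    rng: np.random.Generator,
    urban_range: tuple[float, float],
    rural_range: tuple[float, float],
) -> np.ndarray:
    """Uniform caseload draw for every provider from its rurality range.

    Drawn for all providers (not just accepting ones) so the same draws
    apply under any acceptance mask a sweep may impose.
    """
    rural = np.array([p.rural for p in instance.providers])
    u = rng.uniform(size=instance.n_providers)
    lo = np.where(rural, rural_range[0], urban_range[0])
    hi = np.where(rural, rural_range[1], urban_range[1])
    return lo + u * (hi - lo)


def run_microsim(
    instance: ProblemInstance,
    n: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    *,
    acceptance: np.ndarray | None = None,
    caseload_level: float | None = None,
    standards: AccessStandards | None = None,
    high_risk_range: tuple[float, float] = (0.20, 0.40),
    urban_caseload_range: tuple[float, float] = (0.35, 0.50),
    rural_caseload_range: tuple[float, float] = (0.55, 0.65),
) -> Ensemble:
    """Run ``n`` replicates: re-draw parameters, rebuild demand, re-solve.

    Each replicate draws every provider's public caseload fraction from
    its rurality range (unless ``caseload_level`` pins it) and a statewide
    high-risk fraction from ``high_risk_range``, then solves the full
    two-group assignment and computes an access report. A replicate whose
    solver fails is recorded in ``failed``; the ensemble reports
    completeness rather than silently dropping it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    report_frames = []
    params = []
    failed = []
    for r in range(n):
        rng = _replicate_rng(seed, r)
        caseloads = _draw_caseloads(
            instance, rng, urban_caseload_range, rural_caseload_range
        )
        hrf = float(rng.uniform(*high_risk_range))
        if caseload_level is not None:
            caseloads = np.full(instance.n_providers, float(caseload_level))
        demands = build_demands(instance.tracts, instance.need_model, hrf)
        sol = solve_assignment(
            instance,
            demands,
            standards=standards,
            acceptance=acceptance,
            caseload=caseloads,
        )
        params.append(
            {
                "replicate": r,
                "high_risk_fraction": hrf,
                "mean_caseload": float(np.mean(caseloads)),
                "status": sol.status,
            }
        )
        if sol.status != "optimal":
            failed.append(r)
            continue
        rep = compute_access_report(sol)
        rep.insert(0, "replicate", r)
        report_frames.append(rep)
    reports = (
        pd.concat(report_frames, ignore_index=True) if report_frames else pd.DataFrame()
    )
    return Ensemble(
        reports=reports,
        params=pd.DataFrame(params),
        n=n,
        failed=tuple(failed),
        instance=instance,
    )


_MEASURE_COLS = {
    "met_need": "met_need",
    "travel_mi": "mean_travel_mi",
    "scarcity": "scarcity",
}


def _grid_medians(reports: pd.DataFrame, level: float) -> list[dict]:
    rows = []
    for region in ("all", "urban", "rural"):
        if region == "all":
            sub = reports
        elif region == "rural":
            sub = reports[reports["rural"]]
        else:
            sub = reports[~reports["rural"]]
        for group in ("public", "private", "all"):
            g = sub[sub["group"] == group]
            if g.empty:
                continue
            for mname, col in _MEASURE_COLS.items():
                rows.append(
                    {
                        "level": level,
                        "region": region,
                        "group": group,
                        "measure": mname,
                        "median": float(g[col].median()),
                    }
                )
    return rows


def _nested_acceptance_masks(
    instance: ProblemInstance, rates: Sequence[float], seed: int
) -> dict[float, np.ndarray]:
    """Nested accepting sets per rate, stratified by provider rurality.

    Providers are put in a seeded random order within each rurality class;
    rate r accepts the first ceil(r * n_class) of each class, so the
    accepting set at a higher rate contains every lower-rate set.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2**20)))
    rural = np.array([p.rural for p in instance.providers])
    order = {}
    for flag in (False, True):
        idx = np.nonzero(rural == flag)[0]
        order[flag] = rng.permutation(idx)
    masks = {}
    for rate in rates:
        m = np.zeros(instance.n_providers, dtype=bool)
        for flag in (False, True):
            k = math.ceil(rate * len(order[flag]))
            m[order[flag][:k]] = True
        masks[rate] = m
    return masks


def sweep_acceptance(
    instance: ProblemInstance,
    rates: Sequence[float],
    n_per_rate: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
) -> PolicyGrid:
    """Vary the share of dentists accepting public insurance."""
    if not rates:
        raise ValueError("rates must be non-empty")
    if any(not (0.0 <= r <= 1.0) for r in rates):
        raise ValueError("acceptance rates must be in [0, 1]")
    masks = _nested_acceptance_masks(instance, rates, seed)
    med_rows: list[dict] = []
    rep_frames = []
    for rate in rates:
        ens = run_microsim(instance, n=n_per_rate, seed=seed, acceptance=masks[rate])
        med_rows.extend(_grid_medians(ens.reports, rate))
        rep = ens.reports.copy()
        rep.insert(0, "level", rate)
        rep_frames.append(rep)
    return PolicyGrid(
        param="acceptance_rate",
        levels=tuple(rates),
        medians=pd.DataFrame(med_rows),
        reports=pd.concat(rep_frames, ignore_index=True),
    )


def sweep_caseload(
    instance: ProblemInstance,
    levels: Sequence[float],
    n_per_level: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
) -> PolicyGrid:
    """Vary the public caseload fraction of the current accepting set."""
    if not levels:
        raise ValueError("levels must be non-empty")
    if any(not (0.0 <= v <= 1.0) for v in levels):
        raise ValueError("caseload levels must be in [0, 1]")
    med_rows: list[dict] = []
    rep_frames = []
    for level in levels:
        ens = run_microsim(
            instance, n=n_per_level, seed=seed, caseload_level=float(level)
        )
        med_rows.extend(_grid_medians(ens.reports, level))
        rep = ens.reports.copy()
        rep.insert(0, "level", level)
        rep_frames.append(rep)
    return PolicyGrid(
        param="caseload_level",
        levels=tuple(levels),
        medians=pd.DataFrame(med_rows),
        reports=pd.concat(rep_frames, ignore_index=True),
    )


def sweep_max_distance(
    instance: ProblemInstance,
    miles_list: Sequence[float],
    n_per_level: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
) -> PolicyGrid:
    """Vary the with-vehicle travel standard for both rurality classes.

    No-vehicle thresholds are left at their defaults (clipped if the
    vehicle standard drops below them).
    """
    if not miles_list:
        raise ValueError("miles_list must be non-empty")
    if any((not math.isfinite(m)) or m < 0 for m in miles_list):
        raise ValueError("distance levels must be finite and >= 0")
    med_rows: list[dict] = []
    rep_frames = []
    for miles in miles_list:
        std = instance.standards.with_vehicle_threshold(float(miles))
        ens = run_microsim(instance, n=n_per_level, seed=seed, standards=std)
        med_rows.extend(_grid_medians(ens.reports, miles))
        rep = ens.reports.copy()
        rep.insert(0, "level", miles)
        rep_frames.append(rep)
    return PolicyGrid(
        param="max_distance_mi",
        levels=tuple(miles_list),
        medians=pd.DataFrame(med_rows),
        reports=pd.concat(rep_frames, ignore_index=True),
    )


def plot_policy_curves(grid: PolicyGrid, axes=None, reference_level: float | None = None):
    """Three-panel median curves (met need, travel, scarcity) by region x group.

    ``reference_level`` draws a vertical dashed line (e.g. the observed
    28% acceptance rate).
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(13, 4))
    titles = {
        "met_need": "Median met need",
        "travel_mi": "Median travel distance (mi)",
        "scarcity": "Median provider scarcity",
    }
    for ax, measure in zip(axes, titles):
        for region in ("urban", "rural"):
            for group in ("public", "private"):
                c = grid.curve(measure, region=region, group=group)
                ax.plot(c.index, c.values, marker="o", label=f"{region}-{group}")
        if reference_level is not None:
            ax.axvline(reference_level, ls="--", color="gray", lw=1)
        ax.set_title(titles[measure])
        ax.set_xlabel(grid.param)
    axes[0].legend(fontsize=8)
    return axes
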