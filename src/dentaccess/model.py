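"""Model/Results front end tying the pipeline stages together.

:class:`PreventiveDentalAccessModel` wraps a problem instance (tracts,
providers, distances, standards, need model). ``fit()`` solves the
capacitated two-stage assignment at nominal parameters and returns an
:class:`AccessResults` carrying the solution, the per-tract access
report, and a summary table. ``simulate()`` runs the microsimulation
ensemble and returns :class:`MicrosimResults`, from which disparity
flags and the summary tables are computed; the three policy sweeps hang
off the model as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import experiments, measures
from .demand import NeedModel, build_demands
from .distances import AccessStandards
from .experiments import Ensemble, PolicyGrid
from .optimizer import AssignmentSolution, solve_assignment
from .synthetic import ProblemInstance, SyntheticConfig, generate_instance

__all__ = ["PreventiveDentalAccessModel", "AccessResults", "MicrosimResults"]


class PreventiveDentalAccessModel:
    """Capacitated assignment model of children's access to preventive care.

    Parameters
    ----------
    instance
        The problem instance: tracts, provider sites, distance matrix,
        access standards and need model.
    high_risk_fraction
        Statewide share of high-caries-risk children used for the nominal
        ``fit()``; defaults to 0.30 (the midpoint of the microsimulation
        sampling range).

    Examples
    --------
    >>> model = PreventiveDentalAccessModel.from_synthetic(
    ...     SyntheticConfig.test_profile(seed=1))
    >>> res = model.fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self, instance: ProblemInstance, high_risk_fraction: float = 0.30
    ) -> None:
        if not (0.0 <= high_risk_fraction <= 1.0):
            raise ValueError("high_risk_fraction must be in [0, 1]")
        self.instance = instance
        self.high_risk_fraction = high_risk_fraction

    @classmethod
    def from_synthetic(
        cls,
        config: SyntheticConfig | None = None,
        *,
        seed: int | None = None,
        high_risk_fraction: float = 0.30,
    ) -> "PreventiveDentalAccessModel":
        """Build the model on a generated synthetic state."""
        if config is None:
            config = SyntheticConfig() if seed is None else SyntheticConfig(seed=seed)
        elif seed is not None:
            from dataclasses import replace

            config = replace(config, seed=seed)
        model = cls(generate_instance(config), high_risk_fraction=high_risk_fraction)
        model.config = config
        return model

    @classmethod
    def from_tables(
        cls,
        tracts: pd.DataFrame,
        providers: pd.DataFrame,
        distances: pd.DataFrame | None = None,
        *,
        standards: AccessStandards | None = None,
        need_model: NeedModel | None = None,
        high_risk_fraction: float = 0.30,
    ) -> "PreventiveDentalAccessModel":
        """Build the model from tract/provider tables (see :mod:`dentaccess.io`)."""
        from .io import instance_from_frames

        inst = instance_from_frames(
            tracts, providers, distances, standards=standards, need_model=need_model
        )
        return cls(inst, high_risk_fraction=high_risk_fraction)

    # -- fitting and simulation ---------------------------------------------

    def build_demands(self, high_risk_fraction: float | None = None):
        hrf = self.high_risk_fraction if high_risk_fraction is None else high_risk_fraction
        return build_demands(self.instance.tracts, self.instance.need_model, hrf)

    def fit(self, **overrides) -> "AccessResults":
        """Solve the assignment at nominal parameters.

        ``overrides`` are forwarded to the solver (``standards``,
        ``acceptance``, ``caseload``, ``capacity`` arrays).
        """
        demands = self.build_demands()
        sol = solve_assignment(self.instance, demands, **overrides)
        if sol.status != "optimal":
            from .optimizer import SolverError

            raise SolverError(f"assignment solve ended with status {sol.status!r}")
        report = measures.compute_access_report(sol)
        return AccessResults(model=self, solution=sol, report=report)

    def simulate(
        self, n_replicates: int = experiments.DEFAULT_N_REPLICATES, seed: int = 0, **kw
    ) -> "MicrosimResults":
        """Run the microsimulation ensemble (65 replicates by default)."""
        ens = experiments.run_microsim(self.instance, n=n_replicates, seed=seed, **kw)
        return MicrosimResults(model=self, ensemble=ens)

    def sweep_acceptance(
        self, rates: Sequence[float], n_per_rate: int = 8, seed: int = 0
    ) -> PolicyGrid:
        return experiments.sweep_acceptance(self.instance, rates, n_per_rate, seed)

    def sweep_caseload(
        self, levels: Sequence[float], n_per_level: int = 8, seed: int = 0
    ) -> PolicyGrid:
        return experiments.sweep_caseload(self.instance, levels, n_per_level, seed)

    def sweep_max_distance(
        self, miles_list: Sequence[float], n_per_level: int = 8, seed: int = 0
    ) -> PolicyGrid:
        return experiments.sweep_max_distance(self.instance, miles_list, n_per_level, seed)


def _fmt_pct(x: float) -> str:
    return f"{100 * x:5.1f}%"


@dataclass
class AccessResults:
    """Results of a single nominal solve."""

    model: PreventiveDentalAccessModel = field(repr=False)
    solution: AssignmentSolution = field(repr=False)
    report: pd.DataFrame

    def met_need(self, tract_id: str, group: str) -> float:
        return measures.met_need(self.solution, tract_id, group)

    def measures_by_region(self) -> pd.DataFrame:
        rep = self.report.copy()
        rep["replicate"] = 0
        return measures.table1_summary(rep)

    def service_level_shares(self, group: str = "all") -> pd.DataFrame:
        rep = self.report.copy()
        rep["replicate"] = 0
        return measures.table2_summary(rep, group=group)

    def summary(self) -> str:
        """Human-readable overview of the solved state."""
        inst = self.model.instance
        rural = inst.rural_tracts()
        lines = [
            "Preventive Dental Care Access — assignment results",
            "=" * 58,
            f"Tracts: {inst.n_tracts} ({int((~rural).sum())} urban, "
            f"{int(rural.sum())} rural)   Providers: {inst.n_providers} "
            f"({int(inst.acceptance().sum())} accepting public insurance)",
            f"Solver status: {self.solution.status}   "
            f"total child-miles: {self.solution.objective_distance:,.0f}",
            "",
            f"{'group':<9}{'children':>12}{'served':>12}{'met need':>10}"
            f"{'mean travel':>13}{'scarcity':>10}",
        ]
        for group in ("public", "private"):
            sub = self.report[self.report["group"] == group]
            kids = sub["children"].sum()
            served = sub["served"].sum()
            met = served / kids if kids else 1.0
            w = sub["served"].to_numpy()
            trav = (
                float(np.average(sub["mean_travel_mi"], weights=w)) if w.sum() else 0.0
            )
            lines.append(
                f"{group:<9}{kids:>12,.0f}{served:>12,.0f}{_fmt_pct(met):>10}"
                f"{trav:>11.1f}mi{sub['scarcity'].mean():>10.2f}"
            )
        lines += [
            "",
            "Tract service levels (combined population):",
        ]
        shares = self.service_level_shares()
        for _, row in shares[shares["region"] == "all"].iterrows():
            lines.append(
                f"  {row['service_level']:<12}{_fmt_pct(row['mean_share'])}"
            )
        return "\n".join(lines)


@dataclass
class MicrosimResults:
    """Results of a microsimulation ensemble."""

    model: PreventiveDentalAccessModel = field(repr=False)
    ensemble: Ensemble

    @property
    def reports(self) -> pd.DataFrame:
        return self.ensemble.reports

    def access_summary(self) -> pd.DataFrame:
        """Mean and 10th/90th percentile of each measure by region x group."""
        return measures.table1_summary(self.ensemble.reports)

    def service_level_shares(self, group: str = "all") -> pd.DataFrame:
        """Mean (min-max) share of tracts per service level by region."""
        return measures.table2_summary(self.ensemble.reports, group=group)

    def flag_disparities(
        self,
        measure: str,
        thresholds: Sequence[float] | None = None,
        alpha: float = 0.05,
    ) -> pd.DataFrame:
        """Holm-corrected disparity flags at the given thresholds.

        Defaults: 2/6/8/10 miles for travel, 0/0.1/0.2/0.3 for scarcity.
        """
        if thresholds is None:
            thresholds = {"travel": (2, 6, 8, 10), "scarcity": (0.0, 0.1, 0.2, 0.3)}[
                measure
            ]
        return measures.flag_disparity_tracts(
            self.ensemble.reports, measure, thresholds, alpha
        )

    def summary(self) -> str:
        ens = self.ensemble
        lines = [
            "Preventive Dental Care Access — microsimulation ensemble",
            "=" * 58,
            f"Replicates: {ens.n} (completed {ens.n_ok}, "
            f"completeness {_fmt_pct(ens.completeness)})",
            "",
            f"{'measure':<10}{'region':<8}{'public':>18}{'private':>18}",
        ]
        t1 = self.access_summary()
        for measure in ("met_need", "travel_mi", "scarcity"):
            for region in ("all", "rural", "urban"):
                cells = {}
                for group in ("public", "private"):
                    row = t1[
                        (t1["measure"] == measure)
                        & (t1["region"] == region)
                        & (t1["group"] == group)
                    ]
                    if row.empty:
                        cells[group] = "-"
                    else:
                        r = row.iloc[0]
                        cells[group] = f"{r['mean']:.2f} ({r['p10']:.2f}-{r['p90']:.2f})"
                lines.append(
                    f"{measure:<10}{region:<8}{cells['public']:>18}{cells['private']:>18}"
                )
        return "\n".join(lines)
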