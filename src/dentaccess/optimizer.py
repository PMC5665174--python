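"""Capacitated assignment of preventive-care need to providers.

The model assigns children from (tract, insurance group, vehicle class)
demand cells to provider sites so that

* no child travels beyond the state access standard for their tract and
  mobility class (feasibility mask),
* no provider's assigned hours exceed capacity, and publicly insured
  assignments respect the provider's public caseload pool,
* as much need as possible is served, and among maximal-service
  assignments total child-miles are minimal (lexicographic two-stage LP).

A pure distance minimizer would trivially serve nobody; the two-stage
reading — maximize served children, then pin that total and minimize
total distance — is what makes "minimize travel" coexist with reported
unmet need.

The two insurance groups are assigned separately, drawing on disjoint
capacity pools defined by the public caseload split: publicly insured
children use capacity x caseload at accepting providers, privately
insured children use the complementary capacity x (1 - caseload). The
private pool depends on the caseload fraction but never on the
acceptance flag, so flipping which providers accept public insurance
(the central policy lever) leaves the private solution exactly
unchanged, while the disjoint split guarantees total assigned hours
never exceed capacity and public hours never exceed capacity x
caseload. Because each group's pools are fixed inputs to its own
program, widening any travel standard or raising any caseload or
acceptance rate can only grow that group's served total.

Flows are continuous (fractional children): populations are large and the
LP relaxation of this transportation structure is integral whenever
demands and capacities are integral. The enumeration oracle uses integer
flows only to bound its search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .demand import GROUPS, TractDemand
from .distances import AccessStandards, feasibility_mask
from .synthetic import ProblemInstance

__all__ = [
    "AssignmentSolution",
    "SolverError",
    "OracleSizeError",
    "solve_assignment",
    "brute_force_oracle",
]

#: relative tolerance on the stage-2 served-total pin
_PIN_RTOL = 1e-7
#: flows below this many children are treated as numerical zeros
_FLOW_EPS = 1e-9


class SolverError(RuntimeError):
    """The LP backend failed to converge; never reported as silent zeros."""


class OracleSizeError(ValueError):
    """Instance exceeds the enumeration oracle's size bounds."""


@dataclass
class AssignmentSolution:
    """Flows of children to providers plus per-provider utilization."""

    demands: tuple[TractDemand, ...]
    served: np.ndarray  # children served, per demand
    unmet: np.ndarray  # children unserved, per demand
    flows: pd.DataFrame  # demand_index, tract_id, group, vehicle_class, provider_id, children, miles
    objective_distance: float  # total child-miles, both groups
    distance_by_group: dict[str, float]
    served_by_group: dict[str, float]
    provider_assigned_hours: dict[str, np.ndarray]  # per group, aligned with providers
    provider_pool_hours: dict[str, np.ndarray]  # capacity pool each group drew on
    status: str  # "optimal" | "infeasible-input" | "failed"
    standards: AccessStandards
    instance: ProblemInstance = field(repr=False)

    def validate(self, rtol: float = 1e-6) -> None:
        """Raise if conservation, capacity, or feasibility invariants fail.

        Pools are the ones this solution was solved against (overrides
        included): the public pool is capacity x caseload at accepting
        providers and the private pool the complementary capacity x
        (1 - caseload), so respecting both pools implies total assigned
        hours <= capacity.
        """
        n = np.array([d.children for d in self.demands])
        resid = np.abs(self.served + self.unmet - n)
        scale = np.maximum(n, 1.0)
        if np.any(resid > rtol * scale):
            raise AssertionError("flow + unmet != demand children")
        for g in GROUPS:
            assigned = self.provider_assigned_hours[g]
            pool = self.provider_pool_hours[g]
            if np.any(assigned > pool * (1 + rtol) + 1e-9):
                raise AssertionError(f"{g} assigned hours exceed the {g} pool")
        if len(self.flows):
            tract_pos = {t.tract_id: i for i, t in enumerate(self.instance.tracts)}
            rural = self.instance.rural_tracts()
            thr = np.array(
                [
                    self.standards.threshold(
                        rural[tract_pos[t]], vc
                    )
                    for t, vc in zip(self.flows["tract_id"], self.flows["vehicle_class"])
                ]
            )
            if np.any(self.flows["miles"].to_numpy() > thr + 1e-9):
                raise AssertionError("flow on an infeasible (beyond-standard) pair")


def _solve_stage(c, A_ub, b_ub, A_eq=None, b_eq=None):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs"
    )
    return res


def _solve_group_lp(
    n_children: np.ndarray,
    hours_per_child: np.ndarray,
    pair_demand: np.ndarray,
    pair_provider: np.ndarray,
    pair_miles: np.ndarray,
    pools: np.ndarray,
):
    """Two-stage lexicographic LP for one insurance group.

    Returns (flows per pair, served total, total child-miles, status).
    """
    n_dem = len(n_children)
    n_pairs = len(pair_demand)
    if n_pairs == 0:
        return np.zeros(0), 0.0, 0.0, "optimal"

    used_providers, pair_pcol = np.unique(pair_provider, return_inverse=True)
    n_prov = len(used_providers)
    k = np.arange(n_pairs)
    h_pairs = hours_per_child[pair_demand]
    A_ub = sp.coo_matrix(
        (
            np.concatenate([np.ones(n_pairs), h_pairs]),
            (
                np.concatenate([pair_demand, n_dem + pair_pcol]),
                np.concatenate([k, k]),
            ),
        ),
        shape=(n_dem + n_prov, n_pairs),
    ).tocsr()
    b_ub = np.concatenate([n_children, pools[used_providers]])

    res1 = _solve_stage(-np.ones(n_pairs), A_ub, b_ub)
    if res1.status != 0:
        return np.zeros(n_pairs), 0.0, 0.0, "failed"
    served_total = float(np.sum(res1.x))
    if served_total <= _FLOW_EPS:
        return np.zeros(n_pairs), 0.0, 0.0, "optimal"

    A_eq = sp.csr_matrix(np.ones((1, n_pairs)))
    res2 = _solve_stage(pair_miles, A_ub, b_ub, A_eq=A_eq, b_eq=[served_total])
    if res2.status != 0:
        # relax the pin to an inequality at the stated relative tolerance
        A_ub2 = sp.vstack([A_ub, -A_eq]).tocsr()
        b_ub2 = np.concatenate([b_ub, [-served_total * (1 - _PIN_RTOL)]])
        res2 = _solve_stage(pair_miles, A_ub2, b_ub2)
        if res2.status != 0:
            return np.zeros(n_pairs), 0.0, 0.0, "failed"
    x = np.asarray(res2.x, dtype=float)
    x[x < _FLOW_EPS] = 0.0
    return x, float(np.sum(x)), float(np.dot(x, pair_miles)), "optimal"


def solve_assignment(
    instance: ProblemInstance,
    demands: Sequence[TractDemand],
    *,
    standards: AccessStandards | None = None,
    acceptance: np.ndarray | None = None,
    caseload: np.ndarray | None = None,
    capacity: np.ndarray | None = None,
) -> AssignmentSolution:
    """Solve the two-group capacitated assignment.

    ``acceptance``, ``caseload`` and ``capacity`` override the instance's
    provider attributes (per-provider arrays); ``standards`` overrides the
    travel standards. Used by the microsimulation and policy sweeps.
    """
    if not demands:
        raise ValueError("at least one demand is required")
    standards = standards if standards is not None else instance.standards
    caps = (
        np.asarray(capacity, dtype=float)
        if capacity is not None
        else instance.capacity_hours()
    )
    accept = (
        np.asarray(acceptance, dtype=bool)
        if acceptance is not None
        else instance.acceptance()
    )
    f = (
        np.asarray(caseload, dtype=float)
        if caseload is not None
        else instance.caseload_fractions()
    )
    P = instance.n_providers
    for name, arr in (("capacity", caps), ("acceptance", accept), ("caseload", f)):
        if arr.shape != (P,):
            raise ValueError(f"{name} override must have one entry per provider")
    if np.any(caps < 0) or not np.all(np.isfinite(caps)):
        raise ValueError("capacity must be finite and >= 0")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("caseload fractions must be in [0, 1]")
    if any(d.children < 0 or d.need_hours < 0 for d in demands):
        raise ValueError("demands must be nonnegative")
    f_eff = np.where(accept, f, 0.0)

    tract_pos = {t.tract_id: i for i, t in enumerate(instance.tracts)}
    masks = feasibility_mask(instance.distance, instance.rural_tracts(), standards)

    n_all = np.array([d.children for d in demands], dtype=float)
    served_all = np.zeros(len(demands))
    flow_frames: list[pd.DataFrame] = []
    dist_by_group: dict[str, float] = {}
    served_by_group: dict[str, float] = {}
    assigned_hours = {g: np.zeros(P) for g in GROUPS}
    pools_by_group: dict[str, np.ndarray] = {}
    status = "optimal"
    provider_ids = np.array([p.provider_id for p in instance.providers])

    # disjoint pools: the caseload split partitions each provider's hours
    for group in ("private", "public"):
        pools = caps * f_eff if group == "public" else caps * (1.0 - f)
        pools_by_group[group] = pools

        idx = [i for i, d in enumerate(demands) if d.group == group and d.children > 0]
        nc = n_all[np.array(idx, dtype=int)] if idx else np.zeros(0)
        h = np.array([demands[i].hours_per_child for i in idx])
        pair_d_list, pair_p_list = [], []
        pool_pos = pools > 0
        for j, i in enumerate(idx):
            d = demands[i]
            row = masks[d.vehicle_class][tract_pos[d.tract_id]] & pool_pos
            cols = np.nonzero(row)[0]
            pair_d_list.append(np.full(len(cols), j, dtype=np.int64))
            pair_p_list.append(cols.astype(np.int64))
        pair_d = np.concatenate(pair_d_list) if pair_d_list else np.zeros(0, dtype=np.int64)
        pair_p = np.concatenate(pair_p_list) if pair_p_list else np.zeros(0, dtype=np.int64)
        trow = np.array([tract_pos[demands[i].tract_id] for i in idx], dtype=np.int64)
        pair_miles = (
            instance.distance.miles[trow[pair_d], pair_p] if len(pair_d) else np.zeros(0)
        )

        x, served_total, dist, gstatus = _solve_group_lp(
            nc, h, pair_d, pair_p, pair_miles, pools
        )
        if gstatus != "optimal":
            status = "failed"
        served_by_group[group] = served_total
        dist_by_group[group] = dist
        if len(pair_d):
            served_all[np.array(idx, dtype=int)] += np.bincount(
                pair_d, weights=x, minlength=len(idx)
            )
            assigned_hours[group] = np.bincount(
                pair_p, weights=x * h[pair_d], minlength=P
            )
            nz = x > 0
            if nz.any():
                gi = np.array(idx, dtype=int)[pair_d[nz]]
                flow_frames.append(
                    pd.DataFrame(
                        {
                            "demand_index": gi,
                            "tract_id": [demands[i].tract_id for i in gi],
                            "group": group,
                            "vehicle_class": [demands[i].vehicle_class for i in gi],
                            "provider_id": provider_ids[pair_p[nz]],
                            "children": x[nz],
                            "miles": pair_miles[nz],
                        }
                    )
                )

    flows = (
        pd.concat(flow_frames, ignore_index=True)
        if flow_frames
        else pd.DataFrame(
            columns=[
                "demand_index",
                "tract_id",
                "group",
                "vehicle_class",
                "provider_id",
                "children",
                "miles",
            ]
        )
    )
    # guard against solver round-off pushing served past the demand
    served_all = np.minimum(served_all, n_all)
    sol = AssignmentSolution(
        demands=tuple(demands),
        served=served_all,
        unmet=n_all - served_all,
        flows=flows,
        objective_distance=sum(dist_by_group.values()),
        distance_by_group=dist_by_group,
        served_by_group=served_by_group,
        provider_assigned_hours=assigned_hours,
        provider_pool_hours=pools_by_group,
        status=status,
        standards=standards,
        instance=instance,
    )
    return sol


# -- enumeration oracle ------------------------------------------------------

_MAX_ORACLE_DEMANDS = 6
_MAX_ORACLE_PROVIDERS = 4
_MAX_ORACLE_CHILDREN = 12


def _enumerate_group(
    children: list[int],
    caps_children: list[float],
    feas: list[list[int]],
    miles: np.ndarray,
) -> tuple[float, float, list[dict[int, int]]]:
    """Exhaustive lexicographic optimum over integer flows for one group.

    Returns (served, total child-miles, per-demand allocation dicts).
    Depth-first over per-demand allocations with memoization on the used
    integer capacity vector.
    """
    n_dem = len(children)
    n_prov = len(caps_children)
    memo: dict[tuple, tuple[float, float, tuple]] = {}

    def allocations(d: int, used: tuple[int, ...]):
        provs = feas[d]
        total = children[d]
        out: list[tuple[dict[int, int], int, float]] = []

        def rec(i: int, remaining: int, alloc: dict[int, int]):
            if i == len(provs):
                served = total - remaining
                dist = sum(a * miles[d, p] for p, a in alloc.items())
                out.append((dict(alloc), served, dist))
                return
            p = provs[i]
            cap_left = int(math.floor(caps_children[p] - used[p] + 1e-9))
            for a in range(0, min(remaining, max(cap_left, 0)) + 1):
                if a:
                    alloc[p] = a
                rec(i + 1, remaining - a, alloc)
                alloc.pop(p, None)

        rec(0, total, {})
        return out

    def best(d: int, used: tuple[int, ...]) -> tuple[float, float, tuple]:
        if d == n_dem:
            return 0.0, 0.0, ()
        key = (d, used)
        if key in memo:
            return memo[key]
        best_val: tuple[float, float, tuple] | None = None
        for alloc, served, dist in allocations(d, used):
            nxt = list(used)
            for p, a in alloc.items():
                nxt[p] += a
            s_rest, c_rest, tail = best(d + 1, tuple(nxt))
            cand = (served + s_rest, dist + c_rest, (alloc,) + tail)
            if (
                best_val is None
                or cand[0] > best_val[0] + 1e-12
                or (abs(cand[0] - best_val[0]) <= 1e-12 and cand[1] < best_val[1] - 1e-12)
            ):
                best_val = cand
        memo[key] = best_val
        return best_val

    served, dist, allocs = best(0, tuple([0] * n_prov))
    return served, dist, list(allocs)


def brute_force_oracle(
    instance: ProblemInstance, demands: Sequence[TractDemand]
) -> AssignmentSolution:
    """Exhaustive reference solver for tiny instances.

    Mirrors :func:`solve_assignment` (disjoint caseload-split pools per
    group) but enumerates integer flow vectors. Refuses instances
    beyond 6 nonzero demands, 4 providers, or 12 children per demand, and
    requires integer child counts and a uniform hours-per-child within
    each group so capacities convert exactly to children units.
    """
    active = [d for d in demands if d.children > 0]
    if len(active) > _MAX_ORACLE_DEMANDS:
        raise OracleSizeError(f"too many demands for the oracle ({len(active)} > 6)")
    if instance.n_providers > _MAX_ORACLE_PROVIDERS:
        raise OracleSizeError("too many providers for the oracle (> 4)")
    for d in active:
        if abs(d.children - round(d.children)) > 1e-9:
            raise OracleSizeError("oracle requires integer child counts")
        if d.children > _MAX_ORACLE_CHILDREN:
            raise OracleSizeError("oracle requires <= 12 children per demand")

    caps = instance.capacity_hours()
    accept = instance.acceptance()
    f_eff = np.where(accept, instance.caseload_fractions(), 0.0)
    tract_pos = {t.tract_id: i for i, t in enumerate(instance.tracts)}
    masks = feasibility_mask(
        instance.distance, instance.rural_tracts(), instance.standards
    )

    P = instance.n_providers
    n_all = np.array([d.children for d in demands], dtype=float)
    served_all = np.zeros(len(demands))
    assigned_hours = {g: np.zeros(P) for g in GROUPS}
    pools_by_group: dict[str, np.ndarray] = {}
    dist_by_group: dict[str, float] = {}
    served_by_group: dict[str, float] = {}
    flow_rows = []
    provider_ids = [p.provider_id for p in instance.providers]

    f = instance.caseload_fractions()
    for group in ("private", "public"):
        pools = caps * f_eff if group == "public" else caps * (1.0 - f)
        pools_by_group[group] = pools
        idx = [i for i, d in enumerate(demands) if d.group == group and d.children > 0]
        hs = {demands[i].hours_per_child for i in idx}
        if idx:
            h_vals = sorted(hs)
            if h_vals[-1] - h_vals[0] > 1e-9 or h_vals[0] <= 0:
                raise OracleSizeError(
                    "oracle requires a uniform positive hours-per-child within a group"
                )
            h = h_vals[0]
        else:
            h = 1.0
        children = [int(round(demands[i].children)) for i in idx]
        caps_children = [pools[p] / h for p in range(P)]
        feas = []
        dmiles = np.zeros((len(idx), P))
        for j, i in enumerate(idx):
            d = demands[i]
            row = masks[d.vehicle_class][tract_pos[d.tract_id]]
            feas.append([p for p in range(P) if row[p] and caps_children[p] > 0])
            dmiles[j] = instance.distance.miles[tract_pos[d.tract_id]]
        served, dist, allocs = _enumerate_group(children, caps_children, feas, dmiles)
        served_by_group[group] = served
        dist_by_group[group] = dist
        for j, alloc in enumerate(allocs):
            i = idx[j]
            for p, a in alloc.items():
                served_all[i] += a
                assigned_hours[group][p] += a * h
                flow_rows.append(
                    {
                        "demand_index": i,
                        "tract_id": demands[i].tract_id,
                        "group": group,
                        "vehicle_class": demands[i].vehicle_class,
                        "provider_id": provider_ids[p],
                        "children": float(a),
                        "miles": dmiles[j, p],
                    }
                )

    flows = pd.DataFrame(
        flow_rows,
        columns=[
            "demand_index",
            "tract_id",
            "group",
            "vehicle_class",
            "provider_id",
            "children",
            "miles",
        ],
    )
    return AssignmentSolution(
        demands=tuple(demands),
        served=served_all,
        unmet=n_all - served_all,
        flows=flows,
        objective_distance=sum(dist_by_group.values()),
        distance_by_group=dist_by_group,
        served_by_group=served_by_group,
        provider_assigned_hours=assigned_hours,
        provider_pool_hours=pools_by_group,
        status="optimal",
        standards=instance.standards,
        instance=instance,
    )
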