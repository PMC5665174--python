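"""Access measures, service-level classes, and disparity inference.

Three measures are computed per census tract and insurance group from a
solved assignment:

met need
    children served within the access standards divided by children
    needing care; 1.0 for a group with no children (no unmet need can
    exist).
travel distance
    flow-weighted mean 1-way miles over served children; when nobody in
    the cell is served the value is censored at the tract's with-vehicle
    standard (30 mi urban / 45 mi rural) and flagged, so ensemble means
    stay finite.
provider scarcity
    assigned hours divided by pool hours, aggregated capacity-weighted
    over the providers reachable from the tract (with-vehicle standard);
    1 means saturated supply, and an empty or zero-hour feasible pool
    counts as fully scarce.

Tracts are classed served (met need >= 90%), underserved (50-90%), or
unserved (< 50%).

Disparity flagging tests, per tract, whether the mean absolute
public-private gap across microsimulation replicates exceeds a threshold
tau, with one-sided one-sample t statistics and Holm correction across
tracts to control the familywise error at alpha = 0.05.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .optimizer import AssignmentSolution

__all__ = [
    "compute_access_report",
    "met_need",
    "mean_travel",
    "scarcity",
    "classify_service_level",
    "holm_reject",
    "exceedance_flags",
    "flag_disparity_tracts",
    "table1_summary",
    "table2_summary",
]

_REPORT_GROUPS = ("public", "private", "all")
_CLIP = 1e-9


def classify_service_level(met: float) -> str:
    """Service-level class of a met-need fraction.

    >= 0.90 -> served; [0.50, 0.90) -> underserved; < 0.50 -> unserved.
    """
    if not (0.0 <= met <= 1.0) or not math.isfinite(met):
        raise ValueError(f"met_need must be in [0, 1], got {met!r}")
    if met >= 0.90:
        return "served"
    if met >= 0.50:
        return "underserved"
    return "unserved"


def _classify_vec(met: np.ndarray) -> np.ndarray:
    out = np.where(met >= 0.90, "served", np.where(met >= 0.50, "underserved", "unserved"))
    return out


def compute_access_report(solution: AssignmentSolution) -> pd.DataFrame:
    """Per-(tract, group) access measures for a solved assignment.

    Rows cover groups ``public``, ``private`` and the children-weighted
    combination ``all``. Columns: tract_id, rural, group, children,
    served, met_need, mean_travel_mi, travel_censored, scarcity,
    service_level.
    """
    if solution.status != "optimal":
        raise ValueError(f"cannot compute measures from a {solution.status!r} solution")
    inst = solution.instance
    n_t = inst.n_tracts
    tract_pos = {t.tract_id: i for i, t in enumerate(inst.tracts)}
    rural = inst.rural_tracts()

    # children and served per tract x group
    children = {g: np.zeros(n_t) for g in _REPORT_GROUPS}
    served = {g: np.zeros(n_t) for g in _REPORT_GROUPS}
    for i, d in enumerate(solution.demands):
        ti = tract_pos[d.tract_id]
        children[d.group][ti] += d.children
        served[d.group][ti] += solution.served[i]
    children["all"] = children["public"] + children["private"]
    served["all"] = served["public"] + served["private"]

    # flow-weighted miles per tract x group
    miles_num = {g: np.zeros(n_t) for g in _REPORT_GROUPS}
    if len(solution.flows):
        fl = solution.flows
        ti = fl["tract_id"].map(tract_pos).to_numpy()
        wmiles = (fl["children"] * fl["miles"]).to_numpy()
        for g in ("public", "private"):
            sel = (fl["group"] == g).to_numpy()
            miles_num[g] = np.bincount(ti[sel], weights=wmiles[sel], minlength=n_t)
    miles_num["all"] = miles_num["public"] + miles_num["private"]

    # provider utilization aggregated over each tract's reachable set
    vehicle_mask = inst.distance.miles <= np.where(
        rural,
        solution.standards.vehicle_rural_mi,
        solution.standards.vehicle_urban_mi,
    )[:, None]
    assigned = dict(solution.provider_assigned_hours)
    pools = dict(solution.provider_pool_hours)
    assigned["all"] = assigned["public"] + assigned["private"]
    pools["all"] = pools["public"] + pools["private"]  # total usable hours
    scarcity_by_group: dict[str, np.ndarray] = {}
    for g in _REPORT_GROUPS:
        num = vehicle_mask @ assigned[g]
        den = vehicle_mask @ pools[g]
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(den > 0, num / den, 1.0)
        scarcity_by_group[g] = np.clip(s, 0.0, 1.0)

    censor_mi = np.where(
        rural, solution.standards.vehicle_rural_mi, solution.standards.vehicle_urban_mi
    )
    frames = []
    for g in _REPORT_GROUPS:
        with np.errstate(invalid="ignore", divide="ignore"):
            met = np.where(children[g] > 0, served[g] / np.maximum(children[g], _CLIP), 1.0)
        met = np.clip(met, 0.0, 1.0)
        has_flow = served[g] > _CLIP
        travel = np.where(has_flow, miles_num[g] / np.maximum(served[g], _CLIP), censor_mi)
        frames.append(
            pd.DataFrame(
                {
                    "tract_id": [t.tract_id for t in inst.tracts],
                    "rural": rural,
                    "group": g,
                    "children": children[g],
                    "served": served[g],
                    "met_need": met,
                    "mean_travel_mi": travel,
                    "travel_censored": ~has_flow,
                    "scarcity": scarcity_by_group[g],
                    "service_level": _classify_vec(met),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _report_value(solution: AssignmentSolution, tract_id: str, group: str, col: str):
    rep = compute_access_report(solution)
    row = rep[(rep["tract_id"] == tract_id) & (rep["group"] == group)]
    if row.empty:
        raise KeyError(f"no report row for tract {tract_id!r}, group {group!r}")
    return row.iloc[0][col]


def met_need(solution: AssignmentSolution, tract_id: str, group: str) -> float:
    """Fraction of the tract-group's children served within standards."""
    return float(_report_value(solution, tract_id, group, "met_need"))


def mean_travel(solution: AssignmentSolution, tract_id: str, group: str) -> float:
    """Flow-weighted mean 1-way miles (censored at the vehicle standard)."""
    return float(_report_value(solution, tract_id, group, "mean_travel_mi"))


def scarcity(solution: AssignmentSolution, tract_id: str, group: str) -> float:
    """Capacity-weighted utilization of the tract's reachable providers."""
    return float(_report_value(solution, tract_id, group, "scarcity"))


# -- simultaneous disparity inference ---------------------------------------


def holm_reject(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down rejections controlling familywise error at alpha."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, i in enumerate(order):
        if p[i] <= alpha / (m - rank):
            reject[i] = True
        else:
            break
    return reject


_MEASURE_COLS = {"travel": "mean_travel_mi", "scarcity": "scarcity"}


def exceedance_flags(
    dmat: np.ndarray, tau: float, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided exceedance test per row of a tract x replicate gap matrix.

    Tests H0: mean gap <= tau with the one-sample t statistic across
    replicates (a zero-variance row is strict exceedance), then applies
    Holm across rows. Returns (p-values, flagged).
    """
    vals = np.asarray(dmat, dtype=float)
    n = vals.shape[1]
    if n < 2:
        raise ValueError("exceedance test needs >= 2 replicates")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean - tau) / (sd / math.sqrt(n))
    p = np.where(
        sd > 0,
        stats.t.sf(np.where(sd > 0, t, 0.0), df=n - 1),
        np.where(mean > tau, 0.0, 1.0),
    )
    return p, holm_reject(p, alpha)


def disparity_matrix(reports: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Tract x replicate matrix of |public - private| for one measure.

    ``reports`` is a long ensemble table with a ``replicate`` column.
    """
    reports = getattr(reports, "reports", reports)  # accept an Ensemble
    col = _MEASURE_COLS[measure]
    wide = reports[reports["group"].isin(["public", "private"])].pivot_table(
        index=["tract_id", "replicate"], columns="group", values=col
    )
    d = (wide["public"] - wide["private"]).abs().rename("diff").reset_index()
    return d.pivot(index="tract_id", columns="replicate", values="diff")


def flag_disparity_tracts(
    reports: pd.DataFrame,
    measure: str,
    thresholds: Sequence[float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag tracts whose public-private access gap exceeds each threshold.

    Per tract and threshold tau, tests H0: mean |gap| <= tau against the
    one-sided alternative with the across-replicate t statistic; a
    zero-variance gap is handled as strict exceedance. P-values are Holm-
    corrected across tracts separately for each (measure, tau) family.
    Default thresholds in the pipeline are 2/6/8/10 miles for travel and
    0/0.1/0.2/0.3 for scarcity.

    Returns a tidy frame: tract_id, measure, threshold, mean_abs_diff,
    p_value, flagged.
    """
    if measure not in _MEASURE_COLS:
        raise ValueError(f"measure must be one of {sorted(_MEASURE_COLS)}")
    reports = getattr(reports, "reports", reports)  # accept an Ensemble
    dmat = disparity_matrix(reports, measure)
    n = dmat.shape[1]
    if n < 2:
        raise ValueError("disparity inference needs >= 2 replicates")
    vals = dmat.to_numpy(dtype=float)
    out = []
    for tau in thresholds:
        p, flagged = exceedance_flags(vals, tau, alpha)
        mean = vals.mean(axis=1)
        out.append(
            pd.DataFrame(
                {
                    "tract_id": dmat.index,
                    "measure": measure,
                    "threshold": tau,
                    "mean_abs_diff": mean,
                    "p_value": p,
                    "flagged": flagged,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


# -- ensemble summary tables -------------------------------------------------

_MEASURES = {
    "met_need": "met_need",
    "travel_mi": "mean_travel_mi",
    "scarcity": "scarcity",
}
_REGIONS = ("all", "urban", "rural")


def _region_mask(df: pd.DataFrame, region: str) -> pd.Series:
    if region == "all":
        return pd.Series(True, index=df.index)
    return df["rural"] if region == "rural" else ~df["rural"]


def table1_summary(reports: pd.DataFrame) -> pd.DataFrame:
    """Mean and 10th/90th percentile of each measure by region and group.

    Values pool tract-level measures across replicates; percentiles use
    linear interpolation.
    """
    reports = getattr(reports, "reports", reports)
    rows = []
    for mname, col in _MEASURES.items():
        for region in _REGIONS:
            sub = reports[_region_mask(reports, region)]
            for group in ("all", "public", "private"):
                v = sub.loc[sub["group"] == group, col].to_numpy(dtype=float)
                if len(v) == 0:
                    continue
                rows.append(
                    {
                        "measure": mname,
                        "region": region,
                        "group": group,
                        "mean": float(v.mean()),
                        "p10": float(np.percentile(v, 10)),
                        "p90": float(np.percentile(v, 90)),
                    }
                )
    return pd.DataFrame(rows)


def table2_summary(reports: pd.DataFrame, group: str = "all") -> pd.DataFrame:
    """Share of tracts in each service level, by region, across replicates.

    Reports the across-replicate mean share and its (min, max) range for
    the chosen group (default the combined child population).
    """
    reports = getattr(reports, "reports", reports)
    sub = reports[reports["group"] == group]
    rows = []
    for region in _REGIONS:
        r = sub[_region_mask(sub, region)]
        if r.empty:
            continue
        shares = (
            r.groupby("replicate")["service_level"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
        for level in ("served", "underserved", "unserved"):
            col = shares[level] if level in shares else pd.Series(0.0, index=shares.index)
            rows.append(
                {
                    "region": region,
                    "service_level": level,
                    "mean_share": float(col.mean()),
                    "min_share": float(col.min()),
                    "max_share": float(col.max()),
                }
            )
    return pd.DataFrame(rows)
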