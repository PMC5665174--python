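import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dentaccess import (
    classify_service_level,
    compute_access_report,
    flag_disparity_tracts,
    solve_assignment,
    table1_summary,
    table2_summary,
)
from dentaccess.measures import holm_reject, mean_travel, met_need, scarcity

from .conftest import demand, make_instance, make_provider, make_tract


def solved_toy(public=10, cap=4.0, miles=(2.0, 5.0), caseload=1.0):
    t = make_tract("T1", public=public, vehicle_fraction=1.0)
    provs = [
        make_provider("P1", miles[0], capacity=cap, accepts=True, caseload=caseload),
        make_provider("P2", miles[1], capacity=1e6, accepts=True, caseload=caseload),
    ]
    inst = make_instance([t], provs)
    return solve_assignment(inst, [demand("T1", "public", public)])


class TestMetNeed:
    def test_all_served(self):
        sol = solved_toy(cap=1e6)
        assert met_need(sol, "T1", "public") == pytest.approx(1.0)

    def test_zero_feasible_capacity(self):
        t = make_tract("T1", public=10, vehicle_fraction=1.0)
        p = make_provider("P1", 2.0, capacity=10.0, accepts=False)
        inst = make_instance([t], [p])
        sol = solve_assignment(inst, [demand("T1", "public", 10)])
        assert met_need(sol, "T1", "public") == 0.0

    def test_partial_capacity(self):
        """10 children, single feasible provider holding 4: met need 0.4
        (the enumeration oracle gives the same optimum on this instance)."""
        from dentaccess import brute_force_oracle

        t = make_tract("T1", public=10, vehicle_fraction=1.0)
        p = make_provider("P1", 3.0, capacity=4.0, accepts=True, caseload=1.0)
        inst = make_instance([t], [p])
        dems = [demand("T1", "public", 10)]
        sol = solve_assignment(inst, dems)
        assert met_need(sol, "T1", "public") == pytest.approx(0.4)
        oracle = brute_force_oracle(inst, dems)
        assert oracle.served.sum() / 10 == pytest.approx(0.4)

    def test_zero_children_group_is_fully_met(self):
        sol = solved_toy()
        assert met_need(sol, "T1", "private") == 1.0


class TestMeanTravel:
    def test_single_provider(self):
        t = make_tract("T1", public=10, vehicle_fraction=1.0)
        p = make_provider("P1", 7.0, capacity=1e6, accepts=True, caseload=1.0)
        inst = make_instance([t], [p])
        sol = solve_assignment(inst, [demand("T1", "public", 10)])
        assert mean_travel(sol, "T1", "public") == pytest.approx(7.0, rel=1e-9)

    def test_flow_weighted_split(self):
        """4 children at 2 mi and 6 at 5 mi average to 3.8 miles."""
        sol = solved_toy(cap=4.0)
        assert mean_travel(sol, "T1", "public") == pytest.approx(3.8, rel=1e-9)

    def test_censored_when_unserved(self):
        t = make_tract("T1", public=10, vehicle_fraction=1.0)
        p = make_provider("P1", 2.0, capacity=10.0, accepts=False)
        inst = make_instance([t], [p])
        sol = solve_assignment(inst, [demand("T1", "public", 10)])
        rep = compute_access_report(sol)
        row = rep[(rep.tract_id == "T1") & (rep.group == "public")].iloc[0]
        assert row["mean_travel_mi"] == 30.0  # urban vehicle standard
        assert bool(row["travel_censored"])

    def test_rural_censoring_value(self):
        t = make_tract("T1", rural=True, public=5, vehicle_fraction=1.0)
        p = make_provider("P1", 50.0, capacity=10.0, accepts=True, caseload=1.0)
        inst = make_instance([t], [p])
        sol = solve_assignment(inst, [demand("T1", "public", 5)])
        assert mean_travel(sol, "T1", "public") == 45.0

    def test_served_distance_within_standard(self, test_instance):
        """Standards cap every served child's distance, so uncensored
        tract means never exceed the vehicle threshold."""
        from dentaccess import build_demands

        dems = build_demands(test_instance.tracts, test_instance.need_model, 0.3)
        sol = solve_assignment(test_instance, dems)
        rep = compute_access_report(sol)
        thr = np.where(rep["rural"], 45.0, 30.0)
        assert (rep["mean_travel_mi"] <= thr + 1e-9).all()
        assert ((rep["met_need"] >= 0) & (rep["met_need"] <= 1)).all()
        assert ((rep["scarcity"] >= 0) & (rep["scarcity"] <= 1)).all()


class TestScarcity:
    def test_fully_booked(self):
        t = make_tract("T1", public=100, vehicle_fraction=1.0)
        p = make_provider("P1", 3.0, capacity=50.0, accepts=True, caseload=1.0)
        inst = make_instance([t], [p])
        sol = solve_assignment(inst, [demand("T1", "public", 100)])
        assert scarcity(sol, "T1", "public") == pytest.approx(1.0)

    def test_no_assignments(self):
        t = make_tract("T1", public=0, private=0, vehicle_fraction=1.0)
        p = make_provider("P1", 3.0, capacity=50.0, accepts=True, caseload=1.0)
        inst = make_instance([t], [p])
        sol = solve_assignment(inst, [demand("T1", "public", 0), demand("T1", "private", 0)])
        assert scarcity(sol, "T1", "public") == 0.0

    def test_half_pool_assigned(self):
        t = make_tract("T1", public=5, vehicle_fraction=1.0)
        p = make_provider("P1", 3.0, capacity=10.0, accepts=True, caseload=1.0)
        inst = make_instance([t], [p])
        sol = solve_assignment(inst, [demand("T1", "public", 5)])
        assert scarcity(sol, "T1", "public") == pytest.approx(0.5)

    def test_empty_feasible_set_is_fully_scarce(self):
        t = make_tract("T1", public=5, vehicle_fraction=1.0)
        p = make_provider("P1", 40.0, capacity=10.0, accepts=True, caseload=1.0)
        inst = make_instance([t], [p])  # beyond the 30-mile urban standard
        sol = solve_assignment(inst, [demand("T1", "public", 5)])
        assert scarcity(sol, "T1", "public") == 1.0


class TestServiceLevels:
    @pytest.mark.parametrize(
        "met,level",
        [
            (0.95, "served"),
            (0.90, "served"),
            (0.899, "underserved"),
            (0.50, "underserved"),
            (0.499, "unserved"),
            (0.49, "unserved"),
            (0.0, "unserved"),
            (1.0, "served"),
        ],
    )
    def test_cutpoints(self, met, level):
        assert classify_service_level(met) == level

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_service_level(1.5)
        with pytest.raises(ValueError):
            classify_service_level(-0.1)

    @given(st.floats(0.0, 1.0))
    def test_partition(self, met):
        """Every met-need value gets exactly one level; no gaps, no overlap."""
        assert classify_service_level(met) in {"served", "underserved", "unserved"}


def _ensemble_frame(dmat: np.ndarray, measure_col: str = "mean_travel_mi"):
    """Long report frame realizing a given tract x replicate disparity
    matrix with private access pinned at zero."""
    n_tracts, n_reps = dmat.shape
    rows = []
    for r in range(n_reps):
        for t in range(n_tracts):
            for group, val in (("public", dmat[t, r]), ("private", 0.0)):
                rows.append(
                    {
                        "replicate": r,
                        "tract_id": f"T{t:03d}",
                        "rural": False,
                        "group": group,
                        measure_col: val,
                        "met_need": 1.0,
                        "scarcity": 0.0,
                        "mean_travel_mi": val if measure_col == "mean_travel_mi" else 0.0,
                    }
                )
    return pd.DataFrame(rows)


class TestDisparityInference:
    def test_identical_access_never_flagged(self):
        reports = _ensemble_frame(np.zeros((10, 8)))
        for tau in (0.1, 2.0, 10.0):
            res = flag_disparity_tracts(reports, "travel", [tau])
            assert not res["flagged"].any()

    def test_constant_exceedance_flagged(self):
        """A constant 12-mile gap has zero variance; strict exceedance of
        tau = 10 flags the tract."""
        reports = _ensemble_frame(np.full((5, 6), 12.0))
        res = flag_disparity_tracts(reports, "travel", [10.0])
        assert res["flagged"].all()
        res11 = flag_disparity_tracts(reports, "travel", [12.0])
        assert not res11["flagged"].any()  # not strictly above 12

    def test_noisy_known_disparity(self, rng):
        """Gap ~ N(6, 0.5) over 65 replicates: flagged at tau=2, not at
        tau=8 (t statistic (6-2)/(0.5/sqrt(65)) ~ 64 vs negative)."""
        dmat = rng.normal(6.0, 0.5, size=(12, 65))
        reports = _ensemble_frame(dmat)
        res = flag_disparity_tracts(reports, "travel", [2.0, 8.0])
        at2 = res[res["threshold"] == 2.0]
        at8 = res[res["threshold"] == 8.0]
        assert at2["flagged"].all()
        assert not at8["flagged"].any()

    def test_monotone_in_threshold(self, rng):
        """Tracts flagged at a larger threshold are flagged at smaller ones."""
        dmat = rng.normal(5.0, 2.0, size=(30, 16)) + rng.uniform(0, 6, size=(30, 1))
        reports = _ensemble_frame(np.abs(dmat))
        res = flag_disparity_tracts(reports, "travel", [2.0, 6.0, 8.0, 10.0])
        flagged = {
            tau: set(res[(res["threshold"] == tau) & res["flagged"]]["tract_id"])
            for tau in (2.0, 6.0, 8.0, 10.0)
        }
        assert flagged[10.0] <= flagged[8.0] <= flagged[6.0] <= flagged[2.0]

    def test_requires_two_replicates(self):
        reports = _ensemble_frame(np.zeros((4, 1)))
        with pytest.raises(ValueError):
            flag_disparity_tracts(reports, "travel", [2.0])

    def test_unknown_measure(self):
        reports = _ensemble_frame(np.zeros((4, 3)))
        with pytest.raises(ValueError):
            flag_disparity_tracts(reports, "met_need", [0.1])


class TestHolm:
    def test_all_null_controls_fwer_structure(self):
        p = np.array([0.8, 0.9, 0.2, 0.6])
        assert not holm_reject(p, 0.05).any()

    def test_stepdown(self):
        # m=4: thresholds 0.05/4, 0.05/3, 0.05/2, 0.05
        p = np.array([0.001, 0.012, 0.02, 0.9])
        rej = holm_reject(p, 0.05)
        assert rej.tolist() == [True, True, True, False]

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_monotone_in_pvalues(self, pvals):
        """Inflating every p-value can only shrink the rejection set."""
        p = np.array(pvals)
        inflated = np.minimum(1.0, p * 1.5 + 0.01)
        r0, r1 = holm_reject(p), holm_reject(inflated)
        assert not np.any(r1 & ~r0)


class TestSummaries:
    def test_table2_shares_sum_to_one(self):
        rng = np.random.default_rng(3)
        dmat = rng.uniform(0, 10, size=(20, 4))
        reports = _ensemble_frame(dmat)
        reports["met_need"] = rng.uniform(0, 1, size=len(reports))
        reports["service_level"] = [
            classify_service_level(m) for m in reports["met_need"]
        ]
        # add the combined group rows table2 defaults to
        allg = reports[reports["group"] == "public"].copy()
        allg["group"] = "all"
        t2 = table2_summary(pd.concat([reports, allg]), group="all")
        for region in t2["region"].unique():
            assert t2[t2.region == region]["mean_share"].sum() == pytest.approx(1.0)

    def test_table1_percentile_interpolation(self):
        vals = np.arange(11, dtype=float)  # 0..10
        reports = _ensemble_frame(vals.reshape(11, 1))
        reports["replicate"] = 0
        t1 = table1_summary(reports)
        row = t1[(t1.measure == "travel_mi") & (t1.region == "all") & (t1.group == "public")]
        assert row["p10"].iloc[0] == pytest.approx(1.0)  # linear interpolation
        assert row["p90"].iloc[0] == pytest.approx(9.0)
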