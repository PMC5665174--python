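import numpy as np
import pytest

from dentaccess import (
    OracleSizeError,
    brute_force_oracle,
    build_demands,
    solve_assignment,
)

from .conftest import demand, make_instance, make_provider, make_tract


def one_tract_two_providers(cap_near=1e6, cap_far=1e6):
    """Urban tract with 10 public children; providers 2 and 5 miles out."""
    t = make_tract("T1", public=10, vehicle_fraction=1.0)
    near = make_provider("P1", 2.0, capacity=cap_near, accepts=True, caseload=1.0)
    far = make_provider("P2", 5.0, capacity=cap_far, accepts=True, caseload=1.0)
    return make_instance([t], [near, far])


class TestSolveAssignment:
    def test_nearest_wins_with_ample_capacity(self):
        inst = one_tract_two_providers()
        sol = solve_assignment(inst, [demand("T1", "public", 10)])
        assert sol.status == "optimal"
        assert sol.served_by_group["public"] == pytest.approx(10.0, abs=1e-6)
        assert sol.objective_distance == pytest.approx(20.0, rel=1e-6)
        by_prov = sol.flows.groupby("provider_id")["children"].sum()
        assert by_prov.get("P1", 0.0) == pytest.approx(10.0, abs=1e-6)

    def test_capacity_forces_split(self):
        """Near provider holds 4 children-equivalents: flows (4, 6), total
        child-miles 4*2 + 6*5 = 38 (verified by enumerating all splits)."""
        inst = one_tract_two_providers(cap_near=4.0)
        sol = solve_assignment(inst, [demand("T1", "public", 10)])
        assert sol.served_by_group["public"] == pytest.approx(10.0, abs=1e-6)
        assert sol.objective_distance == pytest.approx(38.0, rel=1e-6)
        by_prov = sol.flows.groupby("provider_id")["children"].sum()
        assert by_prov["P1"] == pytest.approx(4.0, abs=1e-6)
        assert by_prov["P2"] == pytest.approx(6.0, abs=1e-6)

    def test_all_providers_beyond_threshold(self):
        t = make_tract("T1", public=7, vehicle_fraction=1.0)
        p = make_provider("P1", 31.0)  # beyond the 30-mile urban standard
        inst = make_instance([t], [p])
        sol = solve_assignment(inst, [demand("T1", "public", 7)])
        assert sol.unmet.sum() == pytest.approx(7.0)
        assert sol.objective_distance == 0.0

    def test_conservation_and_validate(self):
        inst = one_tract_two_providers(cap_near=3.0, cap_far=4.0)
        d = [demand("T1", "public", 10)]
        sol = solve_assignment(inst, d)
        sol.validate()
        assert sol.served.sum() + sol.unmet.sum() == pytest.approx(10.0, abs=1e-6)
        assert sol.served_by_group["public"] == pytest.approx(7.0, abs=1e-6)

    def test_negative_demand_rejected(self):
        inst = one_tract_two_providers()
        with pytest.raises(ValueError):
            demand("T1", "public", -5)
        with pytest.raises(ValueError):
            solve_assignment(inst, [])

    def test_override_shape_validation(self):
        inst = one_tract_two_providers()
        with pytest.raises(ValueError):
            solve_assignment(
                inst, [demand("T1", "public", 5)], capacity=np.array([1.0])
            )
        with pytest.raises(ValueError):
            solve_assignment(
                inst, [demand("T1", "public", 5)], caseload=np.array([2.0, 0.5])
            )

    def test_capacity_monotonicity(self):
        """Raising capacity, caseload, or the travel standard never
        decreases total served."""
        t = make_tract("T1", public=20, private=10, vehicle_fraction=0.5)
        provs = [
            make_provider("P1", 6.0, capacity=8.0, accepts=True, caseload=0.5),
            make_provider("P2", 25.0, capacity=10.0, accepts=False),
        ]
        inst = make_instance([t], provs)
        dems = [
            demand("T1", "public", 10),
            demand("T1", "public", 10, vehicle_class="no_vehicle"),
            demand("T1", "private", 5),
            demand("T1", "private", 5, vehicle_class="no_vehicle"),
        ]
        base = solve_assignment(inst, dems)
        more_cap = solve_assignment(inst, dems, capacity=np.array([16.0, 10.0]))
        more_case = solve_assignment(inst, dems, caseload=np.array([1.0, 0.0]))
        wider = solve_assignment(
            inst, dems, standards=inst.standards.with_vehicle_threshold(60.0)
        )
        # growing both pools or the feasible set grows total served;
        # raising a caseload grows the public pool, hence public served
        assert more_cap.served.sum() >= base.served.sum() - 1e-9
        assert wider.served.sum() >= base.served.sum() - 1e-9
        assert (
            more_case.served_by_group["public"]
            >= base.served_by_group["public"] - 1e-9
        )

    def test_group_separation(self):
        """Removing public-insurance acceptance everywhere drives public
        served to zero and leaves the private solution exactly untouched
        (the private pool depends on the caseload split, never on the
        acceptance flag)."""
        t = make_tract("T1", public=12, private=9, vehicle_fraction=1.0)
        provs = [
            make_provider("P1", 3.0, capacity=15.0, accepts=True, caseload=0.6),
            make_provider("P2", 7.0, capacity=10.0, accepts=True, caseload=0.4),
        ]
        inst = make_instance([t], provs)
        dems = [demand("T1", "public", 12), demand("T1", "private", 9)]
        base = solve_assignment(inst, dems)
        zeroed = solve_assignment(inst, dems, acceptance=np.zeros(2, dtype=bool))
        assert zeroed.served_by_group["public"] == 0.0
        assert zeroed.served_by_group["private"] == pytest.approx(
            base.served_by_group["private"], abs=1e-9
        )
        assert zeroed.distance_by_group["private"] == pytest.approx(
            base.distance_by_group["private"], abs=1e-9
        )

    def test_private_ignores_acceptance(self):
        """The private assignment is solved first against full capacity, so
        acceptance flips cannot move it."""
        t = make_tract("T1", public=5, private=8, vehicle_fraction=1.0)
        provs = [make_provider("P1", 4.0, capacity=6.0, accepts=True, caseload=0.5)]
        inst = make_instance([t], provs)
        dems = [demand("T1", "public", 5), demand("T1", "private", 8)]
        on = solve_assignment(inst, dems, acceptance=np.array([True]))
        off = solve_assignment(inst, dems, acceptance=np.array([False]))
        assert on.served_by_group["private"] == off.served_by_group["private"]
        assert on.distance_by_group["private"] == off.distance_by_group["private"]
        assert off.served_by_group["public"] == 0.0

    def test_disjoint_caseload_pools(self):
        """The caseload split partitions capacity: an 8-hour provider at
        caseload 0.5 serves at most 4 public and 4 private hours."""
        t = make_tract("T1", public=10, private=5, vehicle_fraction=1.0)
        provs = [make_provider("P1", 2.0, capacity=8.0, accepts=True, caseload=0.5)]
        inst = make_instance([t], provs)
        dems = [demand("T1", "public", 10), demand("T1", "private", 5)]
        sol = solve_assignment(inst, dems)
        sol.validate()
        assert sol.served_by_group["private"] == pytest.approx(4.0, abs=1e-6)
        assert sol.served_by_group["public"] == pytest.approx(4.0, abs=1e-6)
        total = sum(sol.provider_assigned_hours[g] for g in ("public", "private"))
        assert np.all(total <= inst.capacity_hours() + 1e-9)


class TestBruteForceOracle:
    def test_zero_demand(self):
        inst = one_tract_two_providers()
        sol = brute_force_oracle(inst, [demand("T1", "public", 0)])
        assert sol.served.sum() == 0.0
        assert sol.objective_distance == 0.0

    def test_matches_lp_on_capacity_split(self):
        inst = one_tract_two_providers(cap_near=4.0, cap_far=12.0)
        dems = [demand("T1", "public", 10)]
        lp = solve_assignment(inst, dems)
        oracle = brute_force_oracle(inst, dems)
        assert oracle.served.sum() == pytest.approx(lp.served.sum(), abs=1e-6)
        assert oracle.objective_distance == pytest.approx(
            lp.objective_distance, abs=1e-6
        )

    def test_refuses_oversized_instances(self):
        t = make_tract("T1", public=10)
        provs = [make_provider(f"P{i}", float(i)) for i in range(5)]
        inst = make_instance([t], provs)
        with pytest.raises(OracleSizeError):
            brute_force_oracle(inst, [demand("T1", "public", 10)])
        inst2 = one_tract_two_providers()
        with pytest.raises(OracleSizeError):
            brute_force_oracle(inst2, [demand("T1", "public", 13)])
        with pytest.raises(OracleSizeError):
            brute_force_oracle(inst2, [demand("T1", "public", 2.5)])

    def test_two_group_programs_match_lp(self):
        """Two-group toy with integral pools: the oracle's independent
        group programs match the LP group by group."""
        t = make_tract("T1", public=6, private=4, vehicle_fraction=1.0)
        provs = [
            make_provider("P1", 1.0, capacity=5.0, accepts=True, caseload=1.0),
            make_provider("P2", 6.0, capacity=8.0, accepts=True, caseload=0.5),
        ]
        inst = make_instance([t], provs)
        dems = [demand("T1", "public", 6), demand("T1", "private", 4)]
        lp = solve_assignment(inst, dems)
        oracle = brute_force_oracle(inst, dems)
        for g in ("public", "private"):
            assert oracle.served_by_group[g] == pytest.approx(
                lp.served_by_group[g], abs=1e-6
            )
            assert oracle.distance_by_group[g] == pytest.approx(
                lp.distance_by_group[g], abs=1e-6
            )


def test_conservation_on_generated_instances(test_instance):
    """Flow conservation and capacity invariants on the synthetic state."""
    dems = build_demands(
        test_instance.tracts, test_instance.need_model, 0.3
    )
    sol = solve_assignment(test_instance, dems)
    assert sol.status == "optimal"
    sol.validate()
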