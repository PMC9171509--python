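import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lungalloc.activity import ratio_profile
from lungalloc.errors import InfeasibleAssignmentError, ValidationError
from lungalloc.geography import TravelTimeMatrix, eligible_pool, synthetic_travel_matrix
from lungalloc.optimizer import (
    CandidateUnit,
    OptimizerConfig,
    enumerate_feasible_units,
    optimize,
    pruned_subset_iterator,
    search_space_size,
    solve_assignment,
    solve_independent,
)
from lungalloc.synthetic import ScenarioConfig, generate_scenario

from .conftest import EQUITY_CONFIG, make_activity, make_centres


# ---------------------------------------------------------------- oracles

def powerset_filter(pool, supplies, transplants, config, travel=None, locked=frozenset()):
    """Exhaustive reference: every subset checked against all constraints."""
    out = set()
    pool = sorted(pool)
    for r in range(len(pool) + 1):
        for sub in itertools.combinations(pool, r):
            if not locked <= set(sub):
                continue
            if not (config.size_min <= len(sub) <= config.size_max):
                continue
            if travel is not None and any(travel[o] > config.max_minutes for o in sub):
                continue
            ratio = sum(supplies[o] for o in sub) / transplants
            if not math.isinf(config.ratio_tolerance):
                if abs(ratio - config.target_ratio) > config.ratio_tolerance + 1e-9:
                    continue
            out.add(frozenset(sub))
    return out


def cartesian_optimum(candidates, n_total):
    """Reference objective: population sd over the full cartesian product."""
    active = [l for l in sorted(candidates) if candidates[l]]
    n_empty = n_total - len(active)
    best = None
    for combo in itertools.product(*(candidates[l] for l in active)):
        used = set()
        ok = True
        for unit in combo:
            if used & set(unit.opcs):
                ok = False
                break
            used |= set(unit.opcs)
        if not ok:
            continue
        ratios = [u.ratio for u in combo] + [0.0] * n_empty
        sd = float(np.std(ratios))  # population convention
        if best is None or sd < best:
            best = sd
    return best


def _toy_geometry(rng, n_opc, n_ltc, field=200.0):
    opcs = [(f"O{i:02d}", *rng.uniform(0, field, 2), "R") for i in range(n_opc)]
    ltcs = [(f"L{i}", *rng.uniform(0, field, 2), "R") for i in range(n_ltc)]
    centres = make_centres(opcs, ltcs)
    matrix = synthetic_travel_matrix(centres, speed_kmh=80, seed=int(rng.integers(1e6)))
    lungs = {o[0]: int(rng.integers(0, 6)) for o in opcs}
    transplants = {l[0]: int(rng.integers(4, 15)) for l in ltcs}
    return centres, matrix, make_activity(lungs, transplants)


# ------------------------------------------------------- search space size

class TestSearchSpaceSize:
    def test_national_scale(self):
        # 183 OPCs that each join one of 9 units or none
        assert search_space_size(183, 9) == 10**183

    def test_empty_product(self):
        assert search_space_size(0, 5) == 1

    def test_small_case_by_enumeration(self):
        # every function {OPC1..3} -> {L1, L2, none}
        explicit = len(list(itertools.product(["L1", "L2", None], repeat=3)))
        assert search_space_size(3, 2) == explicit == 27

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            search_space_size(-1, 2)


# -------------------------------------------------- pruned subset iterator

class TestPrunedSubsetIterator:
    def _run(self, supplies, transplants, config):
        pool = sorted(supplies, key=lambda o: (-supplies[o], o))
        return {frozenset(s) for s in pruned_subset_iterator(pool, supplies, transplants, config)}

    def test_infinite_tolerance_yields_all_size_feasible(self):
        supplies = {f"o{i}": i for i in range(6)}
        config = OptimizerConfig(size_min=2, size_max=4, ratio_tolerance=math.inf)
        got = self._run(supplies, 10, config)
        expected = powerset_filter(supplies, supplies, 10, config)
        assert got == expected
        assert len(got) == sum(math.comb(6, k) for k in (2, 3, 4))

    @pytest.mark.parametrize("seed", range(4))
    def test_fifteen_opc_pool_equals_powerset_oracle(self, seed):
        rng = np.random.default_rng(seed)
        supplies = {f"o{i:02d}": int(rng.integers(0, 7)) for i in range(15)}
        transplants = 20
        config = OptimizerConfig(size_min=2, size_max=8, ratio_tolerance=0.15)
        got = self._run(supplies, transplants, config)
        expected = powerset_filter(supplies, supplies, transplants, config)
        assert got == expected

    def test_root_pruning_when_band_unreachable(self):
        # total supply below the band floor: nothing can ever be yielded
        supplies = {f"o{i}": 1 for i in range(10)}
        config = OptimizerConfig(size_min=1, size_max=5, ratio_tolerance=0.1)
        assert self._run(supplies, 1000, config) == set()

    def test_unsorted_pool_rejected(self):
        supplies = {"a": 1, "b": 5}
        config = OptimizerConfig(size_min=1, size_max=2)
        with pytest.raises(ValidationError):
            list(pruned_subset_iterator(["a", "b"], supplies, 10, config))


# ------------------------------------------------ enumerate feasible units

class TestEnumerateFeasibleUnits:
    def _flat_matrix(self, opcs, ltc="L1", minutes=10.0):
        return TravelTimeMatrix(
            pd.DataFrame({ltc: [minutes] * len(opcs)}, index=list(opcs))
        )

    def test_all_nonempty_subsets(self):
        supplies = {f"o{i}": 1 for i in range(6)}
        activity = make_activity(supplies, {"L1": 10})
        config = OptimizerConfig(size_min=1, size_max=6, ratio_tolerance=math.inf,
                                 shortlist_k=10**6)
        units = enumerate_feasible_units("L1", supplies, activity, self._flat_matrix(supplies), config)
        assert len(units) == 2**6 - 1

    def test_zero_supply_pool_unreachable_band(self):
        supplies = {f"o{i}": 0 for i in range(6)}
        activity = make_activity(supplies, {"L1": 10})
        config = OptimizerConfig(size_min=1, size_max=6, ratio_tolerance=0.1)
        assert enumerate_feasible_units("L1", supplies, activity, self._flat_matrix(supplies), config) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_random_12_opc_pool_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        centres, matrix, activity = _toy_geometry(rng, 12, 1)
        config = OptimizerConfig(size_min=2, size_max=7, ratio_tolerance=0.2,
                                 max_minutes=120, shortlist_k=10**6)
        pool = eligible_pool("L0", matrix, config.max_minutes)
        units = enumerate_feasible_units("L0", pool, activity, matrix, config)
        supplies = {o: activity.lungs_recovered(o) for o in matrix.opcs}
        travel = {o: matrix.minutes(o, "L0") for o in matrix.opcs}
        expected = powerset_filter(matrix.opcs, supplies, activity.transplants("L0"),
                                   config, travel=travel)
        assert {frozenset(u.opcs) for u in units} == expected

    def test_constraints_hold_on_every_unit(self, small_scenario):
        sc = small_scenario
        config = EQUITY_CONFIG
        for ltc in sc.activity.ltcs:
            pool = eligible_pool(ltc, sc.matrix, config.max_minutes)
            for unit in enumerate_feasible_units(ltc, pool, sc.activity, sc.matrix, config)[:500]:
                # independent re-check of all four constraints
                assert config.size_min <= len(unit.opcs) <= config.size_max
                assert all(sc.matrix.minutes(o, ltc) <= config.max_minutes for o in unit.opcs)
                ratio = sum(sc.activity.lungs_recovered(o) for o in unit.opcs) / sc.activity.transplants(ltc)
                assert ratio == pytest.approx(unit.ratio)
                assert abs(ratio - config.target_ratio) <= config.ratio_tolerance + 1e-9

    def test_small_pool_returns_empty_with_warning(self, caplog):
        supplies = {"o1": 3}
        activity = make_activity(supplies, {"L1": 6})
        config = OptimizerConfig(size_min=5, size_max=15)
        with caplog.at_level("WARNING", logger="lungalloc.optimizer"):
            units = enumerate_feasible_units("L1", supplies, activity, self._flat_matrix(supplies), config)
        assert units == []
        assert any("size_min" in r.message for r in caplog.records)

    def test_ranking_order(self):
        supplies = {"a": 5, "b": 4, "c": 6, "d": 1}
        activity = make_activity(supplies, {"L1": 10})
        matrix = TravelTimeMatrix(
            pd.DataFrame({"L1": [10.0, 20.0, 30.0, 40.0]}, index=["a", "b", "c", "d"])
        )
        config = OptimizerConfig(size_min=1, size_max=2, ratio_tolerance=0.2, shortlist_k=100)
        units = enumerate_feasible_units("L1", supplies, activity, matrix, config)
        keys = [(abs(u.ratio - 0.5), u.total_travel_min, u.opcs) for u in units]
        assert keys == sorted(keys)

    def test_locked_opcs_forced_into_units(self):
        supplies = {"a": 3, "b": 2, "c": 2, "d": 1}
        activity = make_activity(supplies, {"L1": 10})
        matrix = self._flat_matrix(supplies)
        config = OptimizerConfig(size_min=2, size_max=3, ratio_tolerance=0.2,
                                 locked={"L1": frozenset({"a"})}, shortlist_k=10**6)
        units = enumerate_feasible_units("L1", supplies, activity, matrix, config)
        assert units and all("a" in u.opcs for u in units)
        supplies_d = {o: supplies[o] for o in supplies}
        expected = powerset_filter(supplies, supplies_d, 10, config, locked={"a"})
        assert {frozenset(u.opcs) for u in units} == expected

    def test_locked_must_be_travel_eligible(self):
        supplies = {"a": 3, "b": 2}
        activity = make_activity(supplies, {"L1": 10})
        matrix = TravelTimeMatrix(pd.DataFrame({"L1": [300.0, 10.0]}, index=["a", "b"]))
        config = OptimizerConfig(size_min=1, size_max=2, locked={"L1": frozenset({"a"})})
        with pytest.raises(ValidationError, match="travel-eligible"):
            enumerate_feasible_units("L1", supplies, activity, matrix, config)

    def test_locked_size_exemption_flag(self):
        supplies = {"a": 5, "b": 1, "c": 1}
        activity = make_activity(supplies, {"L1": 10})
        matrix = self._flat_matrix(supplies)
        strict = OptimizerConfig(size_min=3, size_max=3, ratio_tolerance=math.inf,
                                 locked={"L1": frozenset({"a"})}, shortlist_k=10**6)
        exempt = OptimizerConfig(size_min=3, size_max=3, ratio_tolerance=math.inf,
                                 locked={"L1": frozenset({"a"})}, shortlist_k=10**6,
                                 exempt_locked_from_size=True)
        strict_units = enumerate_feasible_units("L1", supplies, activity, matrix, strict)
        assert {u.opcs for u in strict_units} == {("a", "b", "c")}
        exempt_units = enumerate_feasible_units("L1", supplies, activity, matrix, exempt)
        # locked member no longer counts toward the size screen
        assert any(len(u.opcs) == 4 for u in exempt_units) is False  # only 3 OPCs exist
        assert all(len(u.opcs) >= 3 for u in strict_units)


# --------------------------------------------------------- solve assignment

def _unit(ltc, opcs, ratio, travel=0.0):
    return CandidateUnit(ltc=ltc, opcs=tuple(sorted(opcs)), ratio=ratio, total_travel_min=travel)


class TestSolveAssignment:
    def test_disjoint_candidates_take_rank_one(self):
        candidates = {
            "L1": [_unit("L1", ["a", "b"], 0.5, 10), _unit("L1", ["a", "c"], 0.45, 5)],
            "L2": [_unit("L2", ["d", "e"], 0.5, 20), _unit("L2", ["d", "f"], 0.4, 5)],
        }
        activity = make_activity({o: 1 for o in "abcdef"}, {"L1": 4, "L2": 4})
        result = solve_assignment(candidates, activity, OptimizerConfig(size_min=1, size_max=5))
        assert result.chosen_units["L1"].opcs == ("a", "b")
        assert result.chosen_units["L2"].opcs == ("d", "e")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_cartesian_product_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        centres, matrix, activity = _toy_geometry(rng, 10, 3, field=150.0)
        config = OptimizerConfig(size_min=1, size_max=4, ratio_tolerance=0.25,
                                 shortlist_k=20)
        candidates = {
            ltc: enumerate_feasible_units(
                ltc, eligible_pool(ltc, matrix, config.max_minutes), activity, matrix, config
            )
            for ltc in activity.ltcs
        }
        oracle = cartesian_optimum(candidates, n_total=len(activity.ltcs))
        if oracle is None:
            with pytest.raises(InfeasibleAssignmentError):
                solve_assignment(candidates, activity, config)
        else:
            result = solve_assignment(candidates, activity, config)
            assert result.profile.summary.sd == pytest.approx(oracle, abs=1e-9)

    def test_symmetric_instance_reaches_zero_sd(self):
        candidates = {
            l: [_unit(l, [f"{l}x"], 0.5, 1.0), _unit(l, [f"{l}y"], 0.6, 1.0)]
            for l in ("L1", "L2", "L3")
        }
        activity = make_activity(
            {f"{l}{s}": 1 for l in ("L1", "L2", "L3") for s in "xy"},
            {l: 2 for l in ("L1", "L2", "L3")},
        )
        result = solve_assignment(candidates, activity, OptimizerConfig(size_min=1, size_max=2))
        assert result.profile.summary.sd == 0.0

    def test_infeasible_names_smallest_conflicting_pair(self):
        shared = _unit("L1", ["x"], 0.5)
        candidates = {
            "L1": [shared],
            "L2": [_unit("L2", ["x"], 0.5)],
            "L3": [_unit("L3", ["z"], 0.5)],
        }
        activity = make_activity({"x": 1, "z": 1}, {"L1": 2, "L2": 2, "L3": 2})
        with pytest.raises(InfeasibleAssignmentError) as err:
            solve_assignment(candidates, activity, OptimizerConfig(size_min=1, size_max=2))
        assert err.value.conflict == ("L1", "L2")

    def test_empty_candidate_list_gets_empty_unit(self):
        candidates = {
            "L1": [_unit("L1", ["a"], 0.5)],
            "L2": [],
        }
        activity = make_activity({"a": 1}, {"L1": 2, "L2": 2})
        result = solve_assignment(candidates, activity, OptimizerConfig(size_min=1, size_max=2))
        assert result.empty_ltcs == ["L2"]
        assert result.profile.ratios["L2"] == 0.0
        assert result.alloc_map.unit("L2") == ()

    def test_deterministic_under_input_permutation(self, rng):
        centres, matrix, activity = _toy_geometry(rng, 12, 3, field=150.0)
        config = OptimizerConfig(size_min=1, size_max=4, ratio_tolerance=0.25, shortlist_k=50)
        candidates = {
            ltc: enumerate_feasible_units(
                ltc, eligible_pool(ltc, matrix, config.max_minutes), activity, matrix, config
            )
            for ltc in activity.ltcs
        }
        baseline = solve_assignment(candidates, activity, config)
        for seed in range(3):
            sh = np.random.default_rng(seed)
            permuted = {}
            for ltc in sh.permutation(sorted(candidates)):
                units = list(candidates[ltc])
                permuted[ltc] = units
            result = solve_assignment(permuted, activity, config)
            assert result.alloc_map == baseline.alloc_map

    def test_widening_tolerance_never_raises_sd(self, rng):
        centres, matrix, activity = _toy_geometry(rng, 12, 2, field=120.0)
        sds = []
        for tol in (0.1, 0.2, 0.35, 0.5):
            config = OptimizerConfig(size_min=1, size_max=5, ratio_tolerance=tol,
                                     shortlist_k=10**6)
            try:
                result = optimize(activity.ltcs, matrix, activity, config)
            except InfeasibleAssignmentError:
                sds.append(math.inf)
                continue
            if result.empty_ltcs:
                sds.append(None)  # incomparable: feasible-LTC set changed
                continue
            sds.append(result.profile.summary.sd)
        numeric = [s for s in sds if s is not None]
        assert all(b <= a + 1e-12 for a, b in zip(numeric, numeric[1:]))

    def test_no_ltcs_rejected(self):
        with pytest.raises(ValidationError):
            solve_assignment({}, make_activity({}, {"L1": 1}), OptimizerConfig())


class TestSolveIndependent:
    def test_reports_overlaps_unresolved(self):
        candidates = {
            "L1": [_unit("L1", ["x", "a"], 0.5)],
            "L2": [_unit("L2", ["x", "b"], 0.5)],
        }
        chosen, overlaps = solve_independent(candidates)
        assert chosen["L1"].opcs == ("a", "x")
        assert overlaps == {"x": ["L1", "L2"]}

    def test_no_overlap_no_report(self):
        candidates = {"L1": [_unit("L1", ["a"], 0.5)], "L2": []}
        chosen, overlaps = solve_independent(candidates)
        assert chosen["L2"] is None
        assert overlaps == {}


class TestOptimizeEndToEnd:
    def test_small_scenario_profile(self, small_scenario):
        sc = small_scenario
        result = optimize(sc.activity.ltcs, sc.matrix, sc.activity, EQUITY_CONFIG)
        profile = ratio_profile(result.alloc_map, sc.activity, sd_mode="population")
        # ratios recomputed from the map match the solver's report
        for ltc, ratio in result.profile.ratios.items():
            assert profile.ratios[ltc] == pytest.approx(ratio)
        hist = ratio_profile(sc.historical_map, sc.activity, sd_mode="population")
        assert result.profile.summary.sd < hist.summary.sd

    def test_units_are_disjoint(self, small_scenario):
        sc = small_scenario
        result = optimize(sc.activity.ltcs, sc.matrix, sc.activity, EQUITY_CONFIG)
        seen = set()
        for ltc in sc.activity.ltcs:
            unit = set(result.alloc_map.unit(ltc))
            assert not (seen & unit)
            seen |= unit
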