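"""Redistricting optimizer.

Two stages mirror the design method:

1. per-LTC enumeration of every feasible local allocation unit — a subset
   of the travel-time-eligible OPC pool, of bounded size, containing the
   centre's locked OPCs, whose supply/demand ratio lands in the target
   band — accelerated by branch-and-bound pruning on supply prefix
   bounds;
2. a global exact search selecting one unit per LTC with pairwise
   disjoint OPC sets, minimizing the population standard deviation of
   the ratios across the fixed set of LTCs.

Without constraints the assignment space is (n_ltcs + 1)^n_opcs — each
OPC joins one centre's unit or none — which is why the constrained
enumeration exists at all.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from lungalloc.activity import (
    ActivityTable,
    AllocationMap,
    RatioProfile,
    dispersion_summary,
)
from lungalloc.errors import InfeasibleAssignmentError, ValidationError
from lungalloc.geography import DEFAULT_MAX_MINUTES, TravelTimeMatrix, eligible_pool

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class OptimizerConfig:
    """Tunables of the unit search.

    ``target_ratio`` is the common supply/demand ratio every unit should
    deliver; ``ratio_tolerance`` is the half-width of the acceptance band
    around it.  ``size_min``/``size_max`` bound the number of OPCs per
    unit and ``max_minutes`` is the driving-time eligibility threshold.
    ``locked`` pins OPCs that must belong to a given centre's unit;
    ``shortlist_k`` caps the per-LTC candidate list kept for the global
    stage.
    """

    target_ratio: float = 0.5
    ratio_tolerance: float = 0.1
    size_min: int = 5
    size_max: int = 15
    max_minutes: float = DEFAULT_MAX_MINUTES
    locked: Mapping[str, frozenset[str]] = field(default_factory=dict)
    shortlist_k: int = 200
    exempt_locked_from_size: bool = False

    def __post_init__(self):
        if not (1 <= self.size_min <= self.size_max):
            raise ValidationError("need 1 <= size_min <= size_max")
        if self.target_ratio <= 0:
            raise ValidationError("target_ratio must be positive")
        if self.ratio_tolerance < 0:
            raise ValidationError("ratio_tolerance must be non-negative")
        if self.shortlist_k < 1:
            raise ValidationError("shortlist_k must be >= 1")
        object.__setattr__(
            self, "locked", {str(l): frozenset(map(str, v)) for l, v in dict(self.locked).items()}
        )


@dataclass(frozen=True)
class CandidateUnit:
    """One feasible local allocation unit for one LTC."""

    ltc: str
    opcs: tuple[str, ...]
    ratio: float
    total_travel_min: float

    @property
    def size(self) -> int:
        return len(self.opcs)


def search_space_size(n_opcs: int, n_ltcs: int) -> int:
    """Number of unconstrained assignments, exact integer arithmetic.

    Each OPC independently joins one of the ``n_ltcs`` units or stays
    unassigned, hence (n_ltcs + 1) ** n_opcs.
    """
    if n_opcs < 0 or n_ltcs < 0:
        raise ValidationError("centre counts must be non-negative")
    return (n_ltcs + 1) ** n_opcs


def pruned_subset_iterator(
    pool: Sequence[str],
    supplies: Mapping[str, int],
    transplants: int,
    config: OptimizerConfig,
):
    """Yield the subsets of ``pool`` whose size and total supply are feasible.

    ``pool`` must be sorted by supply descending (ties broken by id) —
    the prefix sums of that order give the largest possible completions,
    which drive the branch-and-bound pruning:

    * a branch whose running supply already exceeds
      (target + tolerance) * transplants cannot come back down
      (supplies are non-negative) and is cut;
    * a branch that cannot reach (target - tolerance) * transplants even
      by adding the largest remaining supplies up to ``size_max`` is cut.

    The yielded set of subsets is exactly what an unpruned powerset
    filter would keep.
    """
    order = [supplies[o] for o in pool]
    if any(order[i] < order[i + 1] for i in range(len(order) - 1)):
        raise ValidationError("pool must be sorted by supply descending")
    if math.isinf(config.ratio_tolerance):
        lo, hi = -math.inf, math.inf
    else:
        lo = (config.target_ratio - config.ratio_tolerance) * transplants
        hi = (config.target_ratio + config.ratio_tolerance) * transplants
    for subset, _supply, _travel in _band_subsets(
        list(pool), dict(supplies), lo, hi, config.size_min, config.size_max
    ):
        yield subset


def _sorted_pool(pool: Iterable[str], activity: ActivityTable) -> list[str]:
    return sorted(pool, key=lambda o: (-activity.lungs_recovered(o), o))


def _enumerate(
    ltc: str,
    pool: Iterable[str],
    activity: ActivityTable,
    matrix: TravelTimeMatrix,
    config: OptimizerConfig,
) -> tuple[list[CandidateUnit], bool]:
    """Enumerate and shortlist feasible units; returns (units, truncated)."""
    eligible = eligible_pool(ltc, matrix, config.max_minutes)
    pool = frozenset(pool) & eligible
    locked = config.locked.get(ltc, frozenset())
    if not locked <= eligible:
        raise ValidationError(
            f"locked OPCs {sorted(locked - eligible)} are not travel-eligible for LTC {ltc!r}"
        )
    locked_supply = sum(activity.lungs_recovered(o) for o in locked)
    free = _sorted_pool(pool - locked, activity)
    transplants = activity.transplants(ltc)

    if config.exempt_locked_from_size or not locked:
        size_min, size_max = config.size_min, config.size_max
    else:
        size_max = config.size_max - len(locked)
        size_min = max(config.size_min - len(locked), 0)
        if size_max < 0:
            logger.warning("LTC %s: locked set alone exceeds size_max; no feasible unit", ltc)
            return [], False
    if len(free) + len(locked) < config.size_min and not config.exempt_locked_from_size:
        logger.warning(
            "LTC %s: eligible pool (%d OPCs) smaller than size_min=%d; no feasible unit",
            ltc, len(free) + len(locked), config.size_min,
        )
        return [], False

    # shift the supply band by the locked supply and enumerate the free part
    lo = (config.target_ratio - config.ratio_tolerance) * transplants - locked_supply
    hi = (config.target_ratio + config.ratio_tolerance) * transplants - locked_supply

    units: list[CandidateUnit] = []
    supplies = {o: activity.lungs_recovered(o) for o in free}
    travels = {o: matrix.minutes(o, ltc) for o in free}
    locked_tuple = tuple(locked)
    locked_travel = sum(matrix.minutes(o, ltc) for o in locked)
    for subset, supply, travel in _band_subsets(
        free, supplies, lo, hi, max(size_min, 0), size_max, travels
    ):
        members = tuple(sorted(subset + locked_tuple))
        ratio = (supply + locked_supply) / transplants
        units.append(CandidateUnit(ltc=ltc, opcs=members, ratio=ratio,
                                   total_travel_min=travel + locked_travel))

    units.sort(key=lambda u: (abs(u.ratio - config.target_ratio), u.total_travel_min, u.opcs))
    truncated = len(units) > config.shortlist_k
    if truncated:
        logger.warning(
            "LTC %s: %d feasible units truncated to shortlist_k=%d; the global optimum "
            "is relative to the shortlists", ltc, len(units), config.shortlist_k,
        )
    return units[: config.shortlist_k], truncated


def _band_subsets(pool, supplies, lo, hi, size_min, size_max, travels=None):
    """Branch-and-bound subset stream over an explicit supply band.

    Yields (subset, total_supply, total_travel) with sums accumulated
    along the recursion; ``total_travel`` is 0.0 when ``travels`` is None.
    """
    if size_max < max(size_min, 0):
        return
    order = sorted(pool, key=lambda o: (-supplies[o], o))
    vals = [supplies[o] for o in order]
    trav = [travels[o] if travels else 0.0 for o in order]
    n = len(order)
    lo, hi = lo - _EPS, hi + _EPS
    prefix = [0.0] * (n + 1)
    for i, s in enumerate(vals):
        prefix[i + 1] = prefix[i] + s

    def rec(start: int, chosen: tuple[str, ...], total: float, travel: float):
        k = len(chosen)
        if size_min <= k <= size_max and lo <= total <= hi:
            yield chosen, total, travel
        if k == size_max:
            return
        for j in range(start, n):
            if (k + 1) + (n - j - 1) < size_min:
                break
            new_total = total + vals[j]
            take = min(size_max - k - 1, n - j - 1)
            if new_total + (prefix[j + 1 + take] - prefix[j + 1]) < lo:
                break
            if new_total > hi:
                continue
            yield from rec(j + 1, chosen + (order[j],), new_total, travel + trav[j])

    yield from rec(0, (), 0.0, 0.0)


def enumerate_feasible_units(
    ltc: str,
    pool: Iterable[str],
    activity: ActivityTable,
    matrix: TravelTimeMatrix,
    config: OptimizerConfig,
) -> list[CandidateUnit]:
    """All feasible units for ``ltc``, ranked and capped at ``shortlist_k``.

    Ranking: |ratio - target| ascending, ties by total travel time, then
    by the lexicographic OPC-id tuple.  A pool smaller than ``size_min``
    yields an empty list with a logged warning, not an error.
    """
    units, _ = _enumerate(ltc, pool, activity, matrix, config)
    return units


@dataclass
class AssignmentResult:
    """Output of the global stage."""

    alloc_map: AllocationMap
    profile: RatioProfile
    chosen_units: dict[str, CandidateUnit | None]
    total_travel_min: float
    empty_ltcs: list[str]
    nodes_explored: int = 0
    shortlist_truncated: list[str] = field(default_factory=list)


def _pvariance_key(ratios: Sequence[float]) -> float:
    n = len(ratios)
    s = sum(ratios)
    ss = sum(r * r for r in ratios)
    return max(ss - s * s / n, 0.0) / n


def solve_assignment(
    candidates: Mapping[str, Sequence[CandidateUnit]],
    activity: ActivityTable,
    config: OptimizerConfig,
) -> AssignmentResult:
    """Pick one unit per LTC, pairwise disjoint, minimizing the ratio sd.

    Exact depth-first branch-and-bound over the shortlists with conflict
    pruning.  Because supplies are integer counts over a fixed transplant
    denominator, many candidate units of one LTC share the exact same
    ratio; the search therefore branches first over *distinct ratio
    values* per LTC — which alone determine the variance objective — and
    only inside a complete ratio vector runs a min-travel disjoint
    selection among the tied units.  Both stages carry admissible lower
    bounds (on the achievable variance of any completion, and on total
    travel), so the result is exact for the full objective key
    (variance, total travel, assignment tuple).  The sd uses the
    population convention over the fixed set of LTCs.  LTCs with no
    candidate unit receive the empty unit (ratio 0) and are flagged
    rather than aborting the solve.
    """
    ltcs = sorted(candidates)
    empty_ltcs = [l for l in ltcs if not candidates[l]]
    active = sorted((l for l in ltcs if candidates[l]), key=lambda l: (len(candidates[l]), l))
    n = len(ltcs)
    if n == 0:
        raise ValidationError("no LTCs to assign")

    n_fixed = len(empty_ltcs)  # empty units contribute ratio 0

    # per-LTC ratio groups: ratio -> units (sorted by travel, then id tuple)
    groups: list[list[tuple[float, list[CandidateUnit]]]] = []
    for ltc in active:
        by_ratio: dict[float, list[CandidateUnit]] = {}
        for unit in candidates[ltc]:
            by_ratio.setdefault(unit.ratio, []).append(unit)
        layer = sorted(
            ((r, sorted(us, key=lambda u: (u.total_travel_min, u.opcs)))
             for r, us in by_ratio.items()),
            key=lambda item: item[0],
        )
        groups.append(layer)

    ratio_intervals = [(layer[0][0], layer[-1][0]) for layer in groups]
    min_group_travel = [
        min(us[0].total_travel_min for _, us in layer) for layer in groups
    ]
    suffix_travel = [0.0] * (len(active) + 1)
    for i in range(len(active) - 1, -1, -1):
        suffix_travel[i] = suffix_travel[i + 1] + min_group_travel[i]

    best: dict | None = None
    nodes = 0

    def variance_lower_bound(chosen: list[float], idx: int) -> float:
        """min over mu of sum (c-mu)^2 + sum dist(mu, remaining interval)^2, / n.

        The objective in mu is convex piecewise-quadratic; ternary search
        over the hull of chosen values and remaining intervals.
        """
        points = list(chosen) + [0.0] * n_fixed
        intervals = ratio_intervals[idx:]
        lo = min([*points, *(iv[0] for iv in intervals)])
        hi = max([*points, *(iv[1] for iv in intervals)])

        def f(mu: float) -> float:
            tot = sum((c - mu) ** 2 for c in points)
            for a, b in intervals:
                if mu < a:
                    tot += (a - mu) ** 2
                elif mu > b:
                    tot += (mu - b) ** 2
            return tot

        exact_chosen_only = 0.0
        if points:
            mean_c = sum(points) / len(points)
            exact_chosen_only = sum((c - mean_c) ** 2 for c in points) / n
        for _ in range(40):
            m1 = lo + (hi - lo) / 3
            m2 = hi - (hi - lo) / 3
            if f(m1) <= f(m2):
                hi = m2
            else:
                lo = m1
        # ternary gives an approximate minimizer; deflate slightly to stay
        # an admissible lower bound, floored by the exact chosen-only bound
        approx = f((lo + hi) / 2) / n
        return max(approx * (1.0 - 1e-9) - 1e-15, exact_chosen_only)

    def exact_variance(chosen: list[float]) -> float:
        vals = list(chosen) + [0.0] * n_fixed
        s = sum(vals)
        ss = sum(v * v for v in vals)
        return max(ss - s * s / n, 0.0) / n

    def _component_min_travel(
        seq: list[list[tuple[frozenset[str], CandidateUnit]]],
        budget: float | None,
    ) -> tuple[float, list[CandidateUnit]] | None:
        """Min-travel disjoint pick of one unit per level of one conflict
        component; ``budget`` prunes selections that cannot beat it."""
        nonlocal nodes
        n_levels = len(seq)
        found: dict | None = None

        def rec(idx: int, used: frozenset[str], chosen: list[CandidateUnit], travel: float):
            nonlocal nodes, found
            nodes += 1
            # conflict-aware bound: cheapest still-compatible unit per level
            lb_travel = travel
            for i in range(idx, n_levels):
                cheapest = None
                for members, u in seq[i]:
                    if not (used & members):
                        cheapest = u.total_travel_min
                        break  # units are travel-sorted within the group
                if cheapest is None:
                    return  # some level has no compatible unit left
                lb_travel += cheapest
            if found is not None and lb_travel >= found["travel"]:
                return
            if budget is not None and lb_travel > budget:
                return
            if idx == n_levels:
                found = {"travel": travel, "units": list(chosen)}
                return
            for members, unit in seq[idx]:
                if used & members:
                    continue
                rec(idx + 1, used | members, chosen + [unit],
                    travel + unit.total_travel_min)

        rec(0, frozenset(), [], 0.0)
        return (found["travel"], found["units"]) if found else None

    def inner_select(level_units: list[list[CandidateUnit]], var: float) -> None:
        """Min-travel disjoint pick of one unit per level, given ratios fixed."""
        nonlocal best, nodes
        # reduce each level to one (cheapest) unit per contested-OPC
        # footprint: OPCs not claimed by any other level can never
        # conflict, so units differing only there are interchangeable
        footprints = [frozenset(o for u in units for o in u.opcs) for units in level_units]
        m = len(level_units)
        reduced: list[list[tuple[frozenset[str], CandidateUnit]]] = []
        for i, units in enumerate(level_units):
            contested = frozenset().union(
                *(footprints[j] for j in range(m) if j != i)
            ) if m > 1 else frozenset()
            seen: dict[frozenset[str], CandidateUnit] = {}
            for u in units:  # already travel-sorted: first wins its class
                key = frozenset(u.opcs) & contested
                if key not in seen:
                    seen[key] = u
            level = [(k, u) for k, u in seen.items()]
            level.sort(key=lambda kv: (kv[1].total_travel_min, kv[1].opcs))
            reduced.append(level)

        # split levels into connected components of the footprint-overlap
        # graph; disjointness couples levels only within a component
        parent = list(range(m))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(m):
            for j in range(i + 1, m):
                if footprints[i] & footprints[j]:
                    parent[find(i)] = find(j)
        components: dict[int, list[int]] = {}
        for i in range(m):
            components.setdefault(find(i), []).append(i)

        # only a cheaper-travel completion can win at equal variance
        budget = best["key"][1] if (best is not None and best["key"][0] == var) else None

        total_travel = 0.0
        units_out: list[CandidateUnit] = []
        for levels in components.values():
            levels.sort(key=lambda i: len(reduced[i]))
            seq = [reduced[i] for i in levels]
            remaining_budget = None if budget is None else budget - total_travel
            got = _component_min_travel(seq, remaining_budget)
            if got is None:
                return  # no disjoint selection for this ratio vector
            total_travel += got[0]
            units_out.extend(got[1])

        assignment = tuple(sorted((u.ltc, u.opcs) for u in units_out))
        key = (var, total_travel, assignment)
        if best is None or key < best["key"]:
            best = {"key": key, "units": units_out}

    def outer(idx: int, chosen_ratios: list[float], chosen_units: list[list[CandidateUnit]]):
        nonlocal nodes
        nodes += 1
        if best is not None:
            lb_var = variance_lower_bound(chosen_ratios, idx)
            best_var = best["key"][0]
            if lb_var > best_var:
                return
            # at equal variance only a cheaper-travel completion can win
            lb_travel = sum(
                min(u.total_travel_min for u in us) for us in chosen_units
            ) + suffix_travel[idx]
            if lb_var == best_var and lb_travel > best["key"][1]:
                return
        if idx == len(active):
            var = exact_variance(chosen_ratios)
            if best is not None and var > best["key"][0]:
                return
            inner_select(chosen_units, var)
            return
        for ratio, units in groups[idx]:
            outer(idx + 1, chosen_ratios + [ratio], chosen_units + [units])

    outer(0, [], [])

    if best is None:
        conflict = _smallest_conflicting_pair(candidates, active)
        if conflict:
            raise InfeasibleAssignmentError(
                f"no disjoint combination of candidate units exists; smallest conflicting "
                f"LTC pair: {conflict[0]!r} and {conflict[1]!r}",
                conflict=conflict,
            )
        raise InfeasibleAssignmentError(
            "no disjoint combination of candidate units exists (higher-order conflict)"
        )

    chosen_units: dict[str, CandidateUnit | None] = {l: None for l in empty_ltcs}
    assignment: dict[str, str] = {}
    for unit in best["units"]:
        chosen_units[unit.ltc] = unit
        for opc in unit.opcs:
            assignment[opc] = unit.ltc
    alloc_map = AllocationMap(assignment)
    ratios = {l: (chosen_units[l].ratio if chosen_units[l] else 0.0) for l in ltcs}
    profile = RatioProfile(
        ratios=ratios, summary=dispersion_summary(ratios.values(), sd_mode="population")
    )
    total_travel = sum(u.total_travel_min for u in best["units"])
    if empty_ltcs:
        logger.warning("LTCs with no feasible unit assigned the empty unit: %s", empty_ltcs)
    return AssignmentResult(
        alloc_map=alloc_map,
        profile=profile,
        chosen_units=chosen_units,
        total_travel_min=total_travel,
        empty_ltcs=empty_ltcs,
        nodes_explored=nodes,
    )


def _smallest_conflicting_pair(candidates, active) -> tuple[str, str] | None:
    for a, b in itertools.combinations(sorted(active), 2):
        sets_a = [set(u.opcs) for u in candidates[a]]
        sets_b = [set(u.opcs) for u in candidates[b]]
        if not any(not (sa & sb) for sa in sets_a for sb in sets_b):
            return (a, b)
    return None


def solve_independent(
    candidates: Mapping[str, Sequence[CandidateUnit]],
) -> tuple[dict[str, CandidateUnit | None], dict[str, list[str]]]:
    """Per-LTC mode: each centre takes its rank-1 unit; overlaps are
    reported, not resolved.

    Returns (chosen units, overlap report mapping OPC -> LTCs claiming it,
    restricted to OPCs claimed more than once).
    """
    chosen = {l: (units[0] if units else None) for l, units in candidates.items()}
    claims: dict[str, list[str]] = {}
    for ltc, unit in sorted(chosen.items()):
        if unit is None:
            continue
        for opc in unit.opcs:
            claims.setdefault(opc, []).append(ltc)
    overlaps = {o: sorted(ls) for o, ls in claims.items() if len(ls) > 1}
    return chosen, overlaps


def optimize(
    centres_ltcs: Iterable[str],
    matrix: TravelTimeMatrix,
    activity: ActivityTable,
    config: OptimizerConfig,
) -> AssignmentResult:
    """End-to-end: eligibility pools -> per-LTC enumeration -> global solve."""
    truncated: list[str] = []
    candidates: dict[str, list[CandidateUnit]] = {}
    for ltc in sorted(centres_ltcs):
        pool = eligible_pool(ltc, matrix, config.max_minutes)
        units, was_truncated = _enumerate(ltc, pool, activity, matrix, config)
        candidates[ltc] = units
        if was_truncated:
            truncated.append(ltc)
    result = solve_assignment(candidates, activity, config)
    result.shortlist_truncated = truncated
    return result
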