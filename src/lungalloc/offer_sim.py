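"""Per-graft offer cascades under the previous and new allocation schemes.

Previous scheme: high-urgency national tier, then local (if the source
OPC belongs to a unit), then regional (other LTCs sharing the source
OPC's region), then national.  New scheme: high-urgency national, then
local, then directly national — the regional tier is removed, and OPCs
outside every unit offer straight at the national level.

Candidate-level selection inside an LTC is not modelled: acceptance is a
per-LTC Bernoulli draw.  Each LTC is offered a given graft at most once.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lungalloc.activity import ActivityTable, AllocationMap, dispersion_summary
from lungalloc.errors import ValidationError
from lungalloc.geography import TravelTimeMatrix, euclidean_km, great_circle_km, ltc_ids

TIER_HU = "HU-national"
TIER_LOCAL = "local"
TIER_REGIONAL = "regional"
TIER_NATIONAL = "national"

SCHEME_PREVIOUS = "previous"
SCHEME_NEW = "new"


@dataclass
class SchemeConfig:
    """Cascade parameters.

    ``acceptance_prob`` is either a single probability applied to every
    LTC or a per-LTC mapping.  ``national_order`` picks the national-tier
    queueing rule: ``rotation`` (round-robin over sorted LTC ids, state
    carried across grafts) or ``random``; neither claims fidelity to the
    real national rule, which is not public.  Cold ischemia time is a
    labelled proxy: an affine function of shipping time.
    """

    scheme: str = SCHEME_NEW
    hu_fraction: float = 0.15
    acceptance_prob: float | Mapping[str, float] = 0.5
    national_order: str = "rotation"
    cold_ischemia_intercept_min: float = 240.0
    cold_ischemia_slope: float = 1.0

    def __post_init__(self):
        if self.scheme not in {SCHEME_PREVIOUS, SCHEME_NEW}:
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        if not 0.0 <= self.hu_fraction <= 1.0:
            raise ValidationError("hu_fraction must be in [0, 1]")
        if self.national_order not in {"rotation", "random"}:
            raise ValidationError(f"unknown national_order {self.national_order!r}")
        probs = (
            self.acceptance_prob.values()
            if isinstance(self.acceptance_prob, Mapping)
            else [self.acceptance_prob]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("acceptance probabilities must be in [0, 1]")

    def p_accept(self, ltc: str) -> float:
        if isinstance(self.acceptance_prob, Mapping):
            return float(self.acceptance_prob[ltc])
        return float(self.acceptance_prob)


@dataclass(frozen=True)
class Offer:
    graft_id: int
    opc: str
    ltc: str
    tier: str
    accepted: bool


@dataclass
class GraftOutcome:
    graft_id: int
    opc: str
    offers: list[Offer]
    recipient: str | None  # None == discarded

    @property
    def tier_accepted(self) -> str | None:
        for o in self.offers:
            if o.accepted:
                return o.tier
        return None


@dataclass
class _Rotation:
    """Round-robin pointer over the sorted LTC list, shared across grafts."""

    ltcs: list[str]
    cursor: int = 0

    def order(self) -> list[str]:
        k = self.cursor % len(self.ltcs)
        self.cursor += 1
        return self.ltcs[k:] + self.ltcs[:k]


@dataclass
class SimulationResult:
    offers: pd.DataFrame
    grafts: pd.DataFrame
    metrics: dict = field(default_factory=dict)


def _national_sequence(config: SchemeConfig, all_ltcs: list[str], rotation: _Rotation,
                       rng: np.random.Generator) -> list[str]:
    if config.national_order == "random":
        return list(rng.permutation(all_ltcs))
    return rotation.order()


def cascade_one_graft(
    opc: str,
    alloc_map: AllocationMap,
    centres: pd.DataFrame,
    config: SchemeConfig,
    rng: np.random.Generator,
    rotation: _Rotation | None = None,
    graft_id: int = 0,
) -> GraftOutcome:
    """Run one graft through its offer cascade.

    The first acceptance terminates the cascade; a graft declined by
    every offered LTC is discarded.
    """
    region_of = dict(zip(centres["id"], centres["region"]))
    all_ltcs = ltc_ids(centres)
    return _cascade(opc, region_of, all_ltcs, alloc_map, config, rng,
                    rotation or _Rotation(all_ltcs), graft_id)


def _cascade(
    opc: str,
    region_of: Mapping[str, str],
    all_ltcs: list[str],
    alloc_map: AllocationMap,
    config: SchemeConfig,
    rng: np.random.Generator,
    rotation: _Rotation,
    graft_id: int,
) -> GraftOutcome:
    if opc not in region_of:
        raise KeyError(f"unknown OPC id {opc!r}")

    offers: list[Offer] = []
    offered: set[str] = set()

    def offer_to(ltc: str, tier: str) -> bool:
        accepted = bool(rng.random() < config.p_accept(ltc))
        offers.append(Offer(graft_id, opc, ltc, tier, accepted))
        offered.add(ltc)
        return accepted

    def run_tier(sequence: list[str], tier: str) -> str | None:
        for ltc in sequence:
            if ltc in offered:
                continue
            if offer_to(ltc, tier):
                return ltc
        return None

    # HU diversion bypasses geographic allocation entirely
    if rng.random() < config.hu_fraction:
        recipient = run_tier(_national_sequence(config, all_ltcs, rotation, rng), TIER_HU)
        return GraftOutcome(graft_id, opc, offers, recipient)

    local_ltc = alloc_map.ltc_for(opc)
    if local_ltc is not None:
        if offer_to(local_ltc, TIER_LOCAL):
            return GraftOutcome(graft_id, opc, offers, local_ltc)

    if config.scheme == SCHEME_PREVIOUS:
        opc_region = region_of[opc]
        regional = [l for l in all_ltcs if region_of[l] == opc_region]
        recipient = run_tier(regional, TIER_REGIONAL)
        if recipient is not None:
            return GraftOutcome(graft_id, opc, offers, recipient)

    recipient = run_tier(_national_sequence(config, all_ltcs, rotation, rng), TIER_NATIONAL)
    return GraftOutcome(graft_id, opc, offers, recipient)


def run_simulation(
    donor_stream: Mapping[str, int],
    alloc_map: AllocationMap,
    centres: pd.DataFrame,
    config: SchemeConfig,
    seed: int = 0,
    matrix: TravelTimeMatrix | None = None,
    activity: ActivityTable | None = None,
) -> SimulationResult:
    """Simulate every graft in ``donor_stream`` (per-OPC counts) and
    aggregate allocation metrics.

    Reproducible for a fixed seed.  With an ``activity`` table the
    per-LTC offers-per-candidate dispersion is added; with a travel
    ``matrix`` shipping times and the cold-ischemia proxy are added.
    """
    if any(v < 0 for v in donor_stream.values()):
        raise ValidationError("graft counts must be non-negative")
    rng = np.random.default_rng(seed)
    all_ltcs = ltc_ids(centres)
    rotation = _Rotation(all_ltcs)
    region_of = dict(zip(centres["id"], centres["region"]))

    outcomes: list[GraftOutcome] = []
    graft_id = 0
    for opc in sorted(donor_stream):
        for _ in range(int(donor_stream[opc])):
            outcomes.append(
                _cascade(opc, region_of, all_ltcs, alloc_map, config, rng, rotation, graft_id)
            )
            graft_id += 1

    offer_rows = [
        {"graft_id": o.graft_id, "opc_id": o.opc, "ltc_id": o.ltc, "order": i,
         "tier": o.tier, "accepted": o.accepted}
        for g in outcomes
        for i, o in enumerate(g.offers)
    ]
    offers_df = pd.DataFrame(
        offer_rows, columns=["graft_id", "opc_id", "ltc_id", "order", "tier", "accepted"]
    )

    coords = {r["id"]: (r["x"], r["y"]) for _, r in centres.iterrows()}
    degrees = centres.attrs.get("coordinate_system", "km") == "degrees"

    def distance(a: str, b: str) -> float:
        (x1, y1), (x2, y2) = coords[a], coords[b]
        if degrees:
            return great_circle_km(x1, y1, x2, y2)
        return euclidean_km(x1, y1, x2, y2)

    graft_rows = []
    for g in outcomes:
        row: dict = {
            "graft_id": g.graft_id,
            "opc_id": g.opc,
            "recipient": g.recipient,
            "tier": g.tier_accepted,
            "n_offers": len(g.offers),
        }
        if g.recipient is not None:
            row["distance_km"] = distance(g.opc, g.recipient)
            if matrix is not None:
                minutes = matrix.minutes(g.opc, g.recipient)
                row["shipping_min"] = minutes
                row["cold_ischemia_min"] = (
                    config.cold_ischemia_intercept_min + config.cold_ischemia_slope * minutes
                )
        graft_rows.append(row)
    grafts_df = pd.DataFrame(graft_rows)

    metrics = _metrics(outcomes, offers_df, grafts_df, all_ltcs, config, activity)
    return SimulationResult(offers=offers_df, grafts=grafts_df, metrics=metrics)


def _metrics(outcomes, offers_df, grafts_df, all_ltcs, config, activity) -> dict:
    n = len(outcomes)
    metrics: dict = {"scheme": config.scheme, "n_grafts": n}
    if n == 0:
        metrics["empty"] = True
        return metrics
    accepted = int(sum(g.recipient is not None for g in outcomes))
    metrics["accepted"] = accepted
    metrics["discarded"] = n - accepted

    tiers = [TIER_HU, TIER_LOCAL, TIER_REGIONAL, TIER_NATIONAL]
    tx = grafts_df[grafts_df["recipient"].notna()]
    metrics["transplants_by_tier"] = {t: int((tx["tier"] == t).sum()) for t in tiers}
    metrics["offers_by_tier"] = {t: int((offers_df["tier"] == t).sum()) for t in tiers}
    metrics["local_share_pct"] = (
        100.0 * metrics["transplants_by_tier"][TIER_LOCAL] / accepted if accepted else None
    )

    # per-LTC share of own transplants performed after local allocation
    local_shares = []
    for ltc in all_ltcs:
        own = tx[tx["recipient"] == ltc]
        if len(own):
            local_shares.append(100.0 * (own["tier"] == TIER_LOCAL).mean())
    if local_shares:
        summary = dispersion_summary(local_shares, sd_mode="population")
        metrics["local_share_by_ltc"] = {
            "mean": summary.mean, "sd": summary.sd, "min": summary.min, "max": summary.max,
        }

    if accepted and "distance_km" in tx.columns:
        dist = dispersion_summary(tx["distance_km"].tolist(), sd_mode="population")
        metrics["shipping_distance_km"] = {"mean": dist.mean, "sd": dist.sd}
    if accepted and "cold_ischemia_min" in tx.columns and tx["cold_ischemia_min"].notna().all():
        cit = dispersion_summary(tx["cold_ischemia_min"].tolist(), sd_mode="population")
        metrics["cold_ischemia_min"] = {"mean": cit.mean, "sd": cit.sd}

    offer_counts = {ltc: int((offers_df["ltc_id"] == ltc).sum()) for ltc in all_ltcs}
    metrics["offers_by_ltc"] = offer_counts
    if activity is not None:
        opc_vals = [offer_counts[l] / activity.candidates(l) for l in all_ltcs]
        summary = dispersion_summary(opc_vals, sd_mode="sample" if len(opc_vals) > 1 else "population")
        metrics["offers_per_candidate"] = {
            "by_ltc": dict(zip(all_ltcs, opc_vals)),
            "mean": summary.mean, "sd": summary.sd,
        }
    return metrics
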