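"""Synthetic geographies, activity tables and waitlist cohorts.

The generator reproduces the *structure* of the national setting the
method addresses — many procurement centres with heterogeneous recovery
intensity, few transplant centres with heterogeneous demand, and a
deliberately size-skewed "historical" unit map (unit sizes spanning
roughly 1 to 32) for before/after contrasts.  It makes no claim of
fitting the restricted registry data.

Printed per-centre columns from the published disparity and follow-up
tables are embedded as fixtures for summary-statistic checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lungalloc.activity import ActivityTable, AllocationMap
from lungalloc.errors import ValidationError
from lungalloc.geography import (
    ROLE_LTC,
    ROLE_OPC,
    TravelTimeMatrix,
    synthetic_travel_matrix,
    validate_centres,
)
from lungalloc.survival import (
    EVENT_CENSORED,
    EVENT_DEATH_OR_DELISTING,
    EVENT_TRANSPLANT,
)

#: 2018 national counts: newly registered candidates and transplants performed.
NATIONAL_2018 = {"new_candidates": 419, "transplants": 373}

#: Season-matched evaluation cohorts (pre: Sep 2018-Sep 2019, post: Sep 2020-Sep 2021).
EVALUATION_COHORTS = {
    "pre_candidates": 358,
    "post_candidates": 285,
    "pre_recipients": 257,
    "post_recipients": 197,
}

_TABLE1 = {
    "centre": [
        "Bordeaux", "Lyon", "Marseille", "Marie Lannelongue", "Nantes",
        "Foch", "Bichat", "Strasbourg", "Toulouse",
    ],
    "opc_count": [10, 23, 28, 1, 32, 1, 2, 26, 11],
    "lungs_recovered": [39, 17, 96, 6, 54, 21, 10, 72, 19],
    "candidates": [176, 207, 287, 301, 153, 400, 308, 296, 134],
    "offers_per_candidate": [3.5, 4.4, 2.9, 2.8, 5.2, 1.4, 1.9, 2.4, 3.0],
}

_TABLE3_OFFERS = {
    "centre": _TABLE1["centre"],
    "pre": [3.4, 3.7, 2.6, 2.3, 4.1, 1.2, 1.6, 2.2, 3.2],
    "post": [2.8, 1.9, 1.7, 2.3, 2.5, 1.7, 1.0, 2.2, 2.7],
}

#: Historical unit-size pattern used to skew the synthetic "before" map.
HISTORICAL_UNIT_SIZES = tuple(_TABLE1["opc_count"])


def table_fixtures() -> dict[str, pd.DataFrame]:
    """Embedded per-centre columns of the printed disparity (2013-2018)
    and pre/post offers-per-candidate tables, one row per centre."""
    return {
        "disparity_2013_2018": pd.DataFrame(_TABLE1),
        "offers_per_candidate_pre_post": pd.DataFrame(_TABLE3_OFFERS),
    }


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the scenario generator.

    ``procurement_dispersion`` is the gamma shape of the per-OPC recovery
    intensity: small values give strong spatial heterogeneity, the
    homogeneous (pure Poisson) limit is shape -> infinity.
    ``demand_supply_coupling`` in [0, 1] blends per-LTC transplant counts
    toward the supply available in the historical unit (0 = independent,
    the disparity the method corrects).
    """

    n_opc: int = 183
    n_ltc: int = 9
    field_km: float = 1000.0
    procurement_dispersion: float = 1.0
    mean_lungs_per_opc: float = 2.0
    demand_range: tuple[int, int] = (15, 60)
    candidate_inflation: tuple[float, float] = (1.0, 1.6)
    speed_kmh: float = 70.0
    travel_noise_sd_min: float = 0.0
    demand_supply_coupling: float = 0.0
    region_grid: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_ltc < 1 or self.n_opc < self.n_ltc:
            raise ValidationError("need n_opc >= n_ltc >= 1")
        if self.field_km <= 0 or self.procurement_dispersion <= 0 or self.mean_lungs_per_opc <= 0:
            raise ValidationError("field_km, procurement_dispersion, mean_lungs_per_opc must be positive")
        if not (1 <= self.demand_range[0] <= self.demand_range[1]):
            raise ValidationError("demand_range must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.demand_supply_coupling <= 1.0:
            raise ValidationError("demand_supply_coupling must be in [0, 1]")


@dataclass
class Scenario:
    centres: pd.DataFrame
    matrix: TravelTimeMatrix
    activity: ActivityTable
    historical_map: AllocationMap
    config: ScenarioConfig = field(repr=False, default=None)


def _historical_sizes(n_opc: int, n_ltc: int) -> list[int]:
    sizes = [HISTORICAL_UNIT_SIZES[i % len(HISTORICAL_UNIT_SIZES)] for i in range(n_ltc)]
    total = sum(sizes)
    if total > n_opc:
        scale = n_opc / total
        sizes = [max(1, math.floor(s * scale)) for s in sizes]
        while sum(sizes) > n_opc:  # trim the largest units first
            sizes[sizes.index(max(sizes))] -= 1
    return sizes


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Draw a full reproducible scenario: centres, travel matrix, activity
    counts and a size-skewed historical allocation map."""
    rng = np.random.default_rng(config.seed)
    n_region = max(config.region_grid, 1)
    cell = config.field_km / n_region

    def region_label(x: float, y: float) -> str:
        i = min(int(x // cell), n_region - 1)
        j = min(int(y // cell), n_region - 1)
        return f"R{i}{j}"

    rows = []
    for k in range(config.n_opc):
        x, y = rng.uniform(0, config.field_km, size=2)
        rows.append({"id": f"OPC{k:03d}", "name": f"Procurement {k}", "role": ROLE_OPC,
                     "x": x, "y": y, "region": region_label(x, y)})
    for k in range(config.n_ltc):
        x, y = rng.uniform(0, config.field_km, size=2)
        rows.append({"id": f"LTC{k}", "name": f"Transplant {k}", "role": ROLE_LTC,
                     "x": x, "y": y, "region": region_label(x, y)})
    centres = pd.DataFrame(rows)
    centres.attrs["coordinate_system"] = "km"
    validate_centres(centres)

    matrix = synthetic_travel_matrix(
        centres,
        speed_kmh=config.speed_kmh,
        noise_sd_min=config.travel_noise_sd_min,
        seed=config.seed + 1,
    )

    opcs = [r["id"] for r in rows if r["role"] == ROLE_OPC]
    ltcs = [r["id"] for r in rows if r["role"] == ROLE_LTC]

    shape = config.procurement_dispersion
    intensity = rng.gamma(shape, config.mean_lungs_per_opc / shape, size=len(opcs))
    lungs = {o: int(c) for o, c in zip(opcs, rng.poisson(intensity))}

    # size-skewed historical map: each LTC (largest unit first) grabs its
    # nearest still-unassigned OPCs
    sizes = _historical_sizes(config.n_opc, config.n_ltc)
    order = sorted(range(len(ltcs)), key=lambda i: (-sizes[i], ltcs[i]))
    unassigned = set(opcs)
    assignment: dict[str, str] = {}
    for i in order:
        ltc = ltcs[i]
        nearest = sorted(unassigned, key=lambda o: (matrix.minutes(o, ltc), o))[: sizes[i]]
        for o in nearest:
            assignment[o] = ltc
            unassigned.discard(o)
    historical = AllocationMap(assignment)

    lo, hi = config.demand_range
    base_draw = rng.integers(lo, hi + 1, size=len(ltcs))
    c = config.demand_supply_coupling
    transplants = {}
    for ltc, draw in zip(ltcs, base_draw):
        hist_supply = sum(lungs[o] for o in historical.unit(ltc))
        transplants[ltc] = max(1, round((1 - c) * draw + c * max(hist_supply, 1)))
    infl = rng.uniform(*config.candidate_inflation, size=len(ltcs))
    candidates = {l: max(1, round(transplants[l] * f)) for l, f in zip(ltcs, infl)}

    activity = ActivityTable(lungs_recovered=lungs, transplants=transplants,
                             candidates=candidates)
    return Scenario(centres=centres, matrix=matrix, activity=activity,
                    historical_map=historical, config=config)


def write_scenario(scenario: Scenario, out_dir: str | Path,
                   header_comment: str | None = None) -> dict[str, Path]:
    """Write centres.csv, travel.csv, activity.csv, historical_map.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "centres": out_dir / "centres.csv",
        "travel": out_dir / "travel.csv",
        "activity": out_dir / "activity.csv",
        "historical_map": out_dir / "historical_map.csv",
    }
    with paths["centres"].open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        scenario.centres.to_csv(fh, index=False)
    scenario.matrix.to_csv(paths["travel"], header_comment=header_comment)
    scenario.activity.to_csv(paths["activity"], header_comment=header_comment)
    scenario.historical_map.to_csv(paths["historical_map"], header_comment=header_comment)
    return paths


def generate_waitlist(
    n: int,
    cif_transplant_3m: float,
    cif_death_3m: float,
    seed: int = 0,
    horizon_days: float = 90.0,
    censor_max_days: float = 365.0,
) -> pd.DataFrame:
    """Waitlist cohort with latent exponential cause-specific hazards.

    The two hazards are calibrated so the cumulative incidences at
    ``horizon_days`` match the targets in expectation:
    with p = p_tx + p_death, Lambda = -log(1 - p) / horizon and
    lambda_k = (p_k / p) * Lambda, since
    CIF_k(t) = (lambda_k / Lambda) * (1 - exp(-Lambda * t)).
    Censoring is uniform on [0, censor_max_days], independent of the
    event process.
    """
    if n < 0:
        raise ValidationError("n must be non-negative")
    if cif_transplant_3m < 0 or cif_death_3m < 0:
        raise ValidationError("target probabilities must be non-negative")
    p = cif_transplant_3m + cif_death_3m
    if p >= 1:
        raise ValidationError("target probabilities must sum to less than 1")
    rng = np.random.default_rng(seed)
    if n == 0:
        return pd.DataFrame(columns=["time", "event"])
    censor = rng.uniform(0.0, censor_max_days, size=n)
    if p == 0:
        return pd.DataFrame({"time": censor, "event": [EVENT_CENSORED] * n})
    lam_total = -math.log1p(-p) / horizon_days
    event_time = rng.exponential(1.0 / lam_total, size=n)
    is_tx = rng.random(n) < cif_transplant_3m / p
    observed = np.minimum(event_time, censor)
    events = np.where(
        censor < event_time,
        EVENT_CENSORED,
        np.where(is_tx, EVENT_TRANSPLANT, EVENT_DEATH_OR_DELISTING),
    )
    return pd.DataFrame({"time": observed, "event": events})


def generate_posttx(
    n: int,
    survival_3m: float,
    seed: int = 0,
    horizon_days: float = 90.0,
    censor_max_days: float = 365.0,
) -> pd.DataFrame:
    """Post-transplant cohort with exponential mortality calibrated so
    S(horizon) = ``survival_3m`` in expectation."""
    if not 0.0 < survival_3m <= 1.0:
        raise ValidationError("survival_3m must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if n == 0:
        return pd.DataFrame(columns=["time", "event"])
    censor = rng.uniform(0.0, censor_max_days, size=n)
    if survival_3m == 1.0:
        return pd.DataFrame({"time": censor, "event": [EVENT_CENSORED] * n})
    lam = -math.log(survival_3m) / horizon_days
    death = rng.exponential(1.0 / lam, size=n)
    observed = np.minimum(death, censor)
    events = np.where(censor < death, EVENT_CENSORED, "death")
    return pd.DataFrame({"time": observed, "event": events})
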