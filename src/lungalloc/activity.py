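"""Supply/demand accounting and dispersion summaries.

Supply is counted in lungs (grafts recovered and transplanted), not
donors.  The central quantity is the supply/demand ratio of a transplant
centre: lungs recovered inside its local allocation unit divided by all
transplants it performed over the period.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from lungalloc.errors import AccountingError, ValidationError
from lungalloc.geography import ROLE_LTC, ROLE_OPC

ACTIVITY_COLUMNS = ("id", "role", "lungs_recovered", "transplants", "candidates", "offers")


class ActivityTable:
    """Per-OPC supply counts and per-LTC demand counts over a period."""

    def __init__(
        self,
        lungs_recovered: Mapping[str, int],
        transplants: Mapping[str, int],
        candidates: Mapping[str, int] | None = None,
        offers: Mapping[str, int] | None = None,
    ):
        self._lungs = {str(k): int(v) for k, v in lungs_recovered.items()}
        self._transplants = {str(k): int(v) for k, v in transplants.items()}
        self._candidates = {str(k): int(v) for k, v in (candidates or {}).items()}
        self._offers = {str(k): int(v) for k, v in (offers or {}).items()}
        for label, counts in (
            ("lungs_recovered", self._lungs),
            ("transplants", self._transplants),
            ("candidates", self._candidates),
            ("offers", self._offers),
        ):
            bad = {k: v for k, v in counts.items() if v < 0}
            if bad:
                raise ValidationError(f"negative {label} counts: {bad}")
        zero_tx = [k for k, v in self._transplants.items() if v < 1]
        if zero_tx:
            raise ValidationError(
                f"transplants must be >= 1 for every LTC (ratio denominator); got 0 for {zero_tx}"
            )

    @property
    def opcs(self) -> list[str]:
        return sorted(self._lungs)

    @property
    def ltcs(self) -> list[str]:
        return sorted(self._transplants)

    def lungs_recovered(self, opc: str) -> int:
        try:
            return self._lungs[opc]
        except KeyError:
            raise AccountingError(f"OPC {opc!r} absent from activity table") from None

    def transplants(self, ltc: str) -> int:
        try:
            return self._transplants[ltc]
        except KeyError:
            raise AccountingError(f"LTC {ltc!r} absent from activity table") from None

    def candidates(self, ltc: str) -> int:
        try:
            return self._candidates[ltc]
        except KeyError:
            raise AccountingError(f"no candidate count for LTC {ltc!r}") from None

    def offers(self, ltc: str) -> int:
        return self._offers.get(ltc, 0)

    def with_offers(self, offers: Mapping[str, int]) -> "ActivityTable":
        """Copy of the table with simulator-produced offer counts attached."""
        return ActivityTable(self._lungs, self._transplants, self._candidates, offers)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for opc in self.opcs:
            rows.append(
                {"id": opc, "role": ROLE_OPC, "lungs_recovered": self._lungs[opc],
                 "transplants": None, "candidates": None, "offers": None}
            )
        for ltc in self.ltcs:
            rows.append(
                {"id": ltc, "role": ROLE_LTC, "lungs_recovered": None,
                 "transplants": self._transplants[ltc],
                 "candidates": self._candidates.get(ltc),
                 "offers": self._offers.get(ltc)}
            )
        return pd.DataFrame(rows, columns=list(ACTIVITY_COLUMNS))

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        path = Path(path)
        with path.open("w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ActivityTable":
        missing = [c for c in ("id", "role") if c not in frame.columns]
        if missing:
            raise ValidationError(f"activity table missing columns: {missing}")
        opc_rows = frame[frame["role"] == ROLE_OPC]
        ltc_rows = frame[frame["role"] == ROLE_LTC]
        if opc_rows["id"].duplicated().any() or ltc_rows["id"].duplicated().any():
            raise ValidationError("duplicate centre id in activity table")

        def col(rows: pd.DataFrame, name: str) -> dict[str, int]:
            if name not in rows.columns:
                return {}
            series = rows.set_index("id")[name].dropna()
            return {str(k): int(v) for k, v in series.items()}

        return cls(
            lungs_recovered=col(opc_rows, "lungs_recovered"),
            transplants=col(ltc_rows, "transplants"),
            candidates=col(ltc_rows, "candidates") or None,
            offers=col(ltc_rows, "offers") or None,
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "ActivityTable":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        return cls.from_frame(pd.read_csv(path, dtype={"id": str}, comment="#"))


class AllocationMap:
    """Disjoint partial assignment of OPCs to LTC local allocation units.

    Each OPC maps to at most one LTC; unassigned OPCs offer nationally.
    """

    def __init__(self, assignment: Mapping[str, str] | None = None):
        self._assignment = {str(o): str(l) for o, l in (assignment or {}).items()}

    def __len__(self) -> int:
        return len(self._assignment)

    def __contains__(self, opc: str) -> bool:
        return opc in self._assignment

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AllocationMap) and self._assignment == other._assignment

    def ltc_for(self, opc: str) -> str | None:
        return self._assignment.get(opc)

    def unit(self, ltc: str) -> tuple[str, ...]:
        """Sorted member OPCs of the unit serving ``ltc`` (possibly empty)."""
        return tuple(sorted(o for o, l in self._assignment.items() if l == ltc))

    def units(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for o, l in self._assignment.items():
            out.setdefault(l, []).append(o)
        return {l: tuple(sorted(v)) for l, v in sorted(out.items())}

    @property
    def assignment(self) -> dict[str, str]:
        return dict(self._assignment)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self._assignment.items())
        return pd.DataFrame(rows, columns=["opc_id", "ltc_id"])

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        path = Path(path)
        with path.open("w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AllocationMap":
        required = {"opc_id", "ltc_id"}
        if not required <= set(frame.columns):
            raise ValidationError(f"allocation map needs columns {sorted(required)}")
        dup = frame["opc_id"][frame["opc_id"].duplicated()]
        if not dup.empty:
            raise ValidationError(
                f"OPC {dup.iloc[0]!r} assigned to more than one unit (units must be disjoint)"
            )
        return cls(dict(zip(frame["opc_id"].astype(str), frame["ltc_id"].astype(str))))

    @classmethod
    def read_csv(cls, path: str | Path) -> "AllocationMap":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        return cls.from_frame(pd.read_csv(path, dtype=str, comment="#"))


@dataclass(frozen=True)
class DispersionSummary:
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class RatioProfile:
    """Per-LTC supply/demand ratios with their dispersion summary."""

    ratios: dict[str, float]
    summary: DispersionSummary


def unit_supply(ltc: str, alloc_map: AllocationMap, activity: ActivityTable) -> int:
    """Lungs recovered inside the unit serving ``ltc``; 0 for an empty unit."""
    return sum(activity.lungs_recovered(opc) for opc in alloc_map.unit(ltc))


def supply_demand_ratio(ltc: str, alloc_map: AllocationMap, activity: ActivityTable) -> float:
    """unit_supply / transplants; transplants must be >= 1 (enforced at load)."""
    transplants = activity.transplants(ltc)
    if transplants < 1:
        raise ValidationError(f"LTC {ltc!r} has zero transplants; ratio undefined")
    return unit_supply(ltc, alloc_map, activity) / transplants


def offers_per_candidate(ltc: str, activity: ActivityTable) -> float:
    candidates = activity.candidates(ltc)
    if candidates < 1:
        raise ValidationError(f"LTC {ltc!r} has zero candidates; offers per candidate undefined")
    return activity.offers(ltc) / candidates


def dispersion_summary(values: Iterable[float], sd_mode: str = "sample") -> DispersionSummary:
    """Mean, sd, min, max of a list of reals.

    ``sd_mode`` selects the n-1 (``"sample"``) or n (``"population"``)
    denominator; both conventions occur in published centre-level tables,
    so the choice is explicit rather than hidden.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValidationError("dispersion_summary needs at least one value")
    if sd_mode not in {"sample", "population"}:
        raise ValidationError(f"unknown sd_mode {sd_mode!r}")
    n = len(vals)
    if sd_mode == "sample" and n < 2:
        raise ValidationError("sample sd needs at least two values")
    mean = sum(vals) / n
    ss = sum((v - mean) ** 2 for v in vals)
    denom = n - 1 if sd_mode == "sample" else n
    sd = math.sqrt(ss / denom) if denom else 0.0
    return DispersionSummary(mean=mean, sd=sd, min=min(vals), max=max(vals))


def ratio_profile(
    alloc_map: AllocationMap,
    activity: ActivityTable,
    ltcs: Iterable[str] | None = None,
    sd_mode: str = "population",
) -> RatioProfile:
    """Supply/demand ratio of every LTC plus mean/sd/min/max.

    Defaults to the population sd: the LTC set is the complete,
    fixed collection of units being scored, not a sample.
    """
    targets = sorted(ltcs) if ltcs is not None else activity.ltcs
    ratios = {ltc: supply_demand_ratio(ltc, alloc_map, activity) for ltc in targets}
    return RatioProfile(ratios=ratios, summary=dispersion_summary(ratios.values(), sd_mode))
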