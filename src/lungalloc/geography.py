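"""Centres, travel-time matrices and travel-time eligibility pools.

Centres are kept in a plain :class:`pandas.DataFrame` with columns
``id, name, role, x, y, region``; the frame's ``attrs["coordinate_system"]``
records the declared unit of the coordinates (``"km"`` for planar
kilometres, ``"degrees"`` for lon/lat).  Travel times are directed
OPC -> LTC driving minutes: the graft travels to the transplant centre
and no symmetry is assumed.
"""

from __future__ import annotations

import json
import math
from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd

from lungalloc.errors import ValidationError

ROLE_OPC = "OPC"
ROLE_LTC = "LTC"
ROLES = frozenset({ROLE_OPC, ROLE_LTC})

CENTRE_COLUMNS = ("id", "name", "role", "x", "y", "region")

#: Default eligibility threshold: driving time of no more than two hours.
DEFAULT_MAX_MINUTES = 120.0

EARTH_RADIUS_KM = 6371.0


def validate_centres(centres: pd.DataFrame) -> pd.DataFrame:
    """Validate a centre table in place and return it.

    Raises :class:`ValidationError` naming the offending row on duplicate
    ids or unknown roles.
    """
    missing = [c for c in CENTRE_COLUMNS if c not in centres.columns]
    if missing:
        raise ValidationError(f"centre table missing columns: {missing}")
    dup = centres["id"][centres["id"].duplicated()]
    if not dup.empty:
        row = int(dup.index[0])
        raise ValidationError(f"duplicate centre id {dup.iloc[0]!r} (row {row})")
    bad_role = centres.loc[~centres["role"].isin(ROLES)]
    if not bad_role.empty:
        row = int(bad_role.index[0])
        raise ValidationError(
            f"unknown role {bad_role['role'].iloc[0]!r} for centre "
            f"{bad_role['id'].iloc[0]!r} (row {row}); expected one of {sorted(ROLES)}"
        )
    if centres[["x", "y"]].isna().any().any():
        raise ValidationError("centre table has missing coordinates")
    return centres


def load_centres(path: str | Path, coordinate_system: str = "km") -> pd.DataFrame:
    """Load a validated centre table from CSV or GeoJSON.

    CSV files need columns ``id,name,role,x,y,region``; GeoJSON files must
    be point features carrying ``id``/``name``/``role``/``region``
    properties.  ``coordinate_system`` declares the unit of ``x``/``y``
    (``"km"`` planar or ``"degrees"`` lon/lat) and is stored in
    ``DataFrame.attrs``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        frame = _centres_from_geojson(path)
    else:
        frame = pd.read_csv(path, dtype={"id": str}, comment="#")
        if frame.empty and not set(CENTRE_COLUMNS) <= set(frame.columns):
            # header-only file parsed with no rows still needs columns
            raise ValidationError(f"centre table missing columns: {list(CENTRE_COLUMNS)}")
    frame = frame.reset_index(drop=True)
    validate_centres(frame)
    frame.attrs["coordinate_system"] = coordinate_system
    return frame


def _centres_from_geojson(path: Path) -> pd.DataFrame:
    payload = json.loads(path.read_text())
    rows = []
    for feature in payload.get("features", []):
        geom = feature.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValidationError(f"non-point geometry in {path}")
        x, y = geom["coordinates"][:2]
        props = feature.get("properties", {})
        rows.append(
            {
                "id": str(props.get("id")),
                "name": props.get("name", ""),
                "role": props.get("role"),
                "x": float(x),
                "y": float(y),
                "region": props.get("region", ""),
            }
        )
    return pd.DataFrame(rows, columns=list(CENTRE_COLUMNS))


def opc_ids(centres: pd.DataFrame) -> list[str]:
    return sorted(centres.loc[centres["role"] == ROLE_OPC, "id"])


def ltc_ids(centres: pd.DataFrame) -> list[str]:
    return sorted(centres.loc[centres["role"] == ROLE_LTC, "id"])


def euclidean_km(x1: float, y1: float, x2: float, y2: float) -> float:
    """Planar distance, coordinates in km."""
    return math.hypot(x2 - x1, y2 - y1)


def great_circle_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Haversine great-circle distance for lon/lat degree coordinates."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def centre_distance_km(centres: pd.DataFrame, id_a: str, id_b: str) -> float:
    """Distance between two centres, honouring the declared coordinate system."""
    lookup = centres.set_index("id")
    try:
        a, b = lookup.loc[id_a], lookup.loc[id_b]
    except KeyError as exc:
        raise KeyError(f"unknown centre id {exc.args[0]!r}") from exc
    if centres.attrs.get("coordinate_system", "km") == "degrees":
        return great_circle_km(a["x"], a["y"], b["x"], b["y"])
    return euclidean_km(a["x"], a["y"], b["x"], b["y"])


class TravelTimeMatrix:
    """Directed OPC -> LTC driving times in minutes.

    Backed by a dense frame (rows = OPC ids, columns = LTC ids); every
    pair must be present, finite and non-negative.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.isna().any().any():
            raise ValidationError("travel matrix has missing (OPC, LTC) entries")
        values = frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("travel matrix entries must be finite")
        if (values < 0).any():
            raise ValidationError("travel matrix entries must be non-negative")
        if frame.index.duplicated().any() or frame.columns.duplicated().any():
            raise ValidationError("travel matrix has duplicated OPC or LTC ids")
        self._frame = frame.astype(float)
        self._frame.index = self._frame.index.astype(str)
        self._frame.columns = self._frame.columns.astype(str)
        self._frame.index.name = "opc_id"
        self._frame.columns.name = "ltc_id"

    @property
    def opcs(self) -> list[str]:
        return list(self._frame.index)

    @property
    def ltcs(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def minutes(self, opc: str, ltc: str) -> float:
        try:
            return float(self._frame.at[opc, ltc])
        except KeyError as exc:
            raise KeyError(f"unknown centre id {exc.args[0]!r} in travel matrix") from exc

    def to_long(self) -> pd.DataFrame:
        long = self._frame.stack().rename("minutes").reset_index()
        long.columns = ["opc_id", "ltc_id", "minutes"]
        return long

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        path = Path(path)
        with path.open("w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_long().to_csv(fh, index=False)

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "TravelTimeMatrix":
        required = {"opc_id", "ltc_id", "minutes"}
        if not required <= set(long.columns):
            raise ValidationError(f"travel matrix CSV needs columns {sorted(required)}")
        if long.duplicated(["opc_id", "ltc_id"]).any():
            raise ValidationError("duplicate (OPC, LTC) pair in travel matrix")
        wide = long.pivot(index="opc_id", columns="ltc_id", values="minutes")
        return cls(wide)

    @classmethod
    def read_csv(cls, path: str | Path) -> "TravelTimeMatrix":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        return cls.from_long(pd.read_csv(path, dtype={"opc_id": str, "ltc_id": str}, comment="#"))


def synthetic_travel_matrix(
    centres: pd.DataFrame,
    speed_kmh: float = 70.0,
    noise_sd_min: float = 0.0,
    seed: int = 0,
) -> TravelTimeMatrix:
    """Straight-line travel-time surrogate for a real road-network matrix.

    time(o, l) = 60 * distance(o, l) / speed_kmh + eps with
    eps ~ Normal(0, noise_sd_min); the total is clipped at zero so times
    stay non-negative.  Deterministic for a fixed seed.
    """
    if speed_kmh <= 0:
        raise ValidationError("speed_kmh must be positive")
    if noise_sd_min < 0:
        raise ValidationError("noise_sd_min must be non-negative")
    opcs, ltcs = opc_ids(centres), ltc_ids(centres)
    if not opcs or not ltcs:
        raise ValidationError("need at least one OPC and one LTC to build a travel matrix")
    lookup = centres.set_index("id")
    degrees = centres.attrs.get("coordinate_system", "km") == "degrees"
    rng = np.random.default_rng(seed)
    base = np.empty((len(opcs), len(ltcs)))
    for i, o in enumerate(opcs):
        for j, l in enumerate(ltcs):
            if degrees:
                d = great_circle_km(
                    lookup.at[o, "x"], lookup.at[o, "y"], lookup.at[l, "x"], lookup.at[l, "y"]
                )
            else:
                d = euclidean_km(
                    lookup.at[o, "x"], lookup.at[o, "y"], lookup.at[l, "x"], lookup.at[l, "y"]
                )
            base[i, j] = 60.0 * d / speed_kmh
    if noise_sd_min > 0:
        base = base + rng.normal(0.0, noise_sd_min, size=base.shape)
    np.clip(base, 0.0, None, out=base)
    return TravelTimeMatrix(pd.DataFrame(base, index=opcs, columns=ltcs))


def eligible_pool(
    ltc: str,
    matrix: TravelTimeMatrix,
    max_minutes: float = DEFAULT_MAX_MINUTES,
) -> frozenset[str]:
    """OPCs within ``max_minutes`` driving time of ``ltc`` (inclusive threshold)."""
    if ltc not in matrix.ltcs:
        raise KeyError(f"unknown LTC id {ltc!r} in travel matrix")
    col = matrix.frame[ltc]
    return frozenset(col.index[col <= max_minutes])


def eligible_pools(
    matrix: TravelTimeMatrix,
    max_minutes: float = DEFAULT_MAX_MINUTES,
    ltcs: Iterable[str] | None = None,
) -> dict[str, frozenset[str]]:
    """Eligibility pool for every LTC (or a chosen subset)."""
    targets = list(ltcs) if ltcs is not None else matrix.ltcs
    return {ltc: eligible_pool(ltc, matrix, max_minutes) for ltc in targets}
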