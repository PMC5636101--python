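"""On-disk artifacts: fix tables (CSV), house points (CSV/GeoJSON), habitat polygons (GeoJSON).

The canonical delimited dialect is comma-separated, "." decimal, UTF-8.
Fix tables carry one row per GPS acquisition with columns

    animal_id, timestamp, x, y [, sex, body_mass_kg, activity_fraction, odba_kcal_per_kg]

where ``timestamp`` is ISO-8601 UTC and ``x, y`` are projected meters.
Validation is total: every malformed input raises :class:`ValidationError`
naming the offending row; nothing is silently skipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, shape

HABITAT_CLASSES = ("forest", "shrubland")

REQUIRED_FIX_COLUMNS = ("animal_id", "timestamp", "x", "y")
OPTIONAL_FIX_COLUMNS = ("sex", "body_mass_kg", "activity_fraction", "odba_kcal_per_kg")


class ValidationError(ValueError):
    """Raised for any malformed on-disk input, with a row/feature diagnostic."""


@dataclass
class HouseLayer:
    """Point layer of house/building locations in projected meters; may be empty."""

    points: np.ndarray  # (n, 2) float array

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValidationError("house coordinates must be finite")
        self.points = pts
        self._tree: cKDTree | None = None

    def __len__(self) -> int:
        return len(self.points)

    @property
    def tree(self) -> cKDTree | None:
        """KD-tree over the points (None when the layer is empty)."""
        if len(self.points) == 0:
            return None
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree


@dataclass
class HabitatLayer:
    """Polygon mosaic with two-class habitat labels (forest / shrubland)."""

    polygons: list = field(default_factory=list)  # list of (shapely Polygon, label)

    def __post_init__(self) -> None:
        for i, (poly, label) in enumerate(self.polygons):
            if label not in HABITAT_CLASSES:
                raise ValidationError(
                    f"habitat polygon {i}: label {label!r} not in {HABITAT_CLASSES}"
                )
            if not isinstance(poly, Polygon) or not poly.is_valid or poly.is_empty:
                raise ValidationError(f"habitat polygon {i}: invalid or empty geometry")

    def __len__(self) -> int:
        return len(self.polygons)


def read_fixes(path, config=None) -> pd.DataFrame:
    """Read and validate a fix table.

    Returns a DataFrame sorted as stored, with parsed UTC timestamps.  Input
    must be time-ordered within each animal; duplicate or backwards
    timestamps raise :class:`ValidationError` naming the offending row
    (1-based, excluding the header).
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"{path}: cannot parse fix table: {exc}") from exc
    missing = [c for c in REQUIRED_FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return validate_fixes(df, source=str(path))


def validate_fixes(df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    """Validate an in-memory fix table (see :func:`read_fixes`)."""
    df = df.copy()
    try:
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        # retry row by row to name the culprit
        for i, raw in enumerate(df["timestamp"]):
            try:
                pd.to_datetime(raw, utc=True)
            except (ValueError, TypeError) as exc:
                raise ValidationError(
                    f"{source}: row {i + 1}: unparseable timestamp {raw!r}"
                ) from exc
        raise
    df["timestamp"] = ts
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"{source}: row {row + 1}: non-finite {col!r}")
        df[col] = vals.astype(float)
    if "activity_fraction" in df.columns:
        frac = pd.to_numeric(df["activity_fraction"], errors="coerce")
        bad = frac.notna() & ((frac < 0) | (frac > 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"{source}: row {row + 1}: activity_fraction outside [0, 1]"
            )
        df["activity_fraction"] = frac
    # strictly increasing time within each animal, in file order
    for animal, idx in df.groupby("animal_id", sort=False).groups.items():
        t = df.loc[idx, "timestamp"].to_numpy()
        if len(t) < 2:
            continue
        nonpos = np.flatnonzero(np.diff(t).astype("timedelta64[ns]").astype(np.int64) <= 0)
        if nonpos.size:
            row = int(np.asarray(idx)[nonpos[0] + 1])
            kind = "duplicate" if t[nonpos[0] + 1] == t[nonpos[0]] else "non-monotone"
            raise ValidationError(
                f"{source}: row {row + 1}: {kind} timestamp for animal {animal!r}"
            )
    return df


def write_fixes(df: pd.DataFrame, path) -> None:
    """Write a fix table; coordinates round-trip to better than 1e-9 m."""
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S%z"
    )
    out.to_csv(path, index=False, float_format="%.17g")


def read_houses(path) -> HouseLayer:
    """Read house points from x,y CSV or RFC 7946 point GeoJSON."""
    text = open(path, "r", encoding="utf-8").read()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        try:
            gj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: malformed GeoJSON: {exc}") from exc
        pts = []
        for i, feat in enumerate(gj.get("features", [])):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise ValidationError(f"{path}: feature {i}: expected Point geometry")
            pts.append(geom["coordinates"][:2])
        return HouseLayer(np.array(pts, dtype=float).reshape(-1, 2))
    if not stripped:
        return HouseLayer(np.empty((0, 2)))
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return HouseLayer(np.empty((0, 2)))
    if not {"x", "y"} <= set(df.columns):
        raise ValidationError(f"{path}: house CSV needs x and y columns")
    return HouseLayer(df[["x", "y"]].to_numpy(dtype=float))


def write_houses(layer: HouseLayer, path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {},
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
        }
        for x, y in layer.points
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_habitat(path) -> HabitatLayer:
    """Read a habitat polygon GeoJSON; each feature needs a ``habitat`` property."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            gj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: malformed GeoJSON: {exc}") from exc
    polys = []
    for i, feat in enumerate(gj.get("features", [])):
        label = (feat.get("properties") or {}).get("habitat")
        if label not in HABITAT_CLASSES:
            raise ValidationError(
                f"{path}: feature {i}: habitat label {label!r} not in {HABITAT_CLASSES}"
            )
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise ValidationError(f"{path}: feature {i}: expected Polygon geometry")
        poly = shape(geom)
        if not poly.is_valid or poly.is_empty:
            raise ValidationError(f"{path}: feature {i}: invalid polygon ring")
        polys.append((poly, label))
    return HabitatLayer(polys)


def write_habitat(layer: HabitatLayer, path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"habitat": label},
            "geometry": json.loads(json.dumps(poly.__geo_interface__)),
        }
        for poly, label in layer.polygons
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
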