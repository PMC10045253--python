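"""Spherical geodesy and lightweight GeoJSON I/O.

All coordinates are WGS84 longitude/latitude in decimal degrees. Distances use
a spherical Earth with the IUGG mean radius. Two local azimuthal projections
are provided for metric operations on small (sub-100-km) geometries:
equidistant (preserves distance from the projection centre; used for metric
buffering) and Lambert equal-area (preserves area; used for centroids).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape

EARTH_RADIUS_KM = 6371.0088
EARTH_RADIUS_M = EARTH_RADIUS_KM * 1000.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points (vectorised).

    Symmetric, non-negative, and zero only for coincident points.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def validate_lonlat(lon, lat):
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    bad = ~((lon >= -180.0) & (lon <= 180.0) & (lat >= -90.0) & (lat <= 90.0))
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"invalid coordinate at index {idx}: lon={np.ravel(lon)[idx] if lon.ndim else float(lon)}, "
            f"lat={np.ravel(lat)[idx] if lat.ndim else float(lat)}"
        )


class LocalProjection:
    """Azimuthal projection about a local centre, in metres.

    kind='equidistant' preserves great-circle distance from the centre;
    kind='equal-area' (Lambert azimuthal) preserves area. Both are accurate to
    O((extent/R)^2) relative error for geometries much smaller than Earth.
    """

    def __init__(self, lon0: float, lat0: float, kind: str = "equidistant"):
        if kind not in ("equidistant", "equal-area"):
            raise ValueError(f"unknown projection kind: {kind}")
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self.kind = kind
        self._l0 = np.radians(lon0)
        self._p0 = np.radians(lat0)

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dl = lam - self._l0
        cosc = np.sin(self._p0) * np.sin(phi) + np.cos(self._p0) * np.cos(phi) * np.cos(dl)
        cosc = np.clip(cosc, -1.0, 1.0)
        if self.kind == "equidistant":
            c = np.arccos(cosc)
            # k = c / sin(c), with the removable singularity at c == 0
            sinc = np.sin(c)
            k = np.where(sinc > 1e-15, c / np.where(sinc > 1e-15, sinc, 1.0), 1.0)
        else:  # Lambert azimuthal equal-area
            k = np.sqrt(2.0 / np.clip(1.0 + cosc, 1e-15, None))
        x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(dl)
        y = EARTH_RADIUS_M * k * (np.cos(self._p0) * np.sin(phi) - np.sin(self._p0) * np.cos(phi) * np.cos(dl))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_M
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_M
        rho = np.hypot(x, y)
        safe_rho = np.where(rho > 1e-15, rho, 1.0)
        if self.kind == "equidistant":
            c = rho
        else:
            c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
        sinc, cosc = np.sin(c), np.cos(c)
        phi = np.arcsin(np.clip(cosc * np.sin(self._p0) + y * sinc * np.cos(self._p0) / safe_rho, -1.0, 1.0))
        lam = self._l0 + np.arctan2(x * sinc, safe_rho * np.cos(self._p0) * cosc - y * np.sin(self._p0) * sinc)
        phi = np.where(rho > 1e-15, phi, self._p0)
        lam = np.where(rho > 1e-15, lam, self._l0)
        return np.degrees(lam), np.degrees(phi)

    def transform_geometry(self, geom):
        def fn(coords):
            x, y = self.forward(coords[:, 0], coords[:, 1])
            return np.column_stack([x, y])

        return shapely.transform(geom, fn)

    def inverse_geometry(self, geom):
        def fn(coords):
            lon, lat = self.inverse(coords[:, 0], coords[:, 1])
            return np.column_stack([lon, lat])

        return shapely.transform(geom, fn)


def geometry_centroid_lonlat(geom) -> tuple[float, float]:
    """Area-weighted centroid of a lon/lat geometry, reported in lon/lat.

    Computed in a Lambert azimuthal equal-area projection about the geometry's
    bounding-box centre so that planar area weighting is meaningful.
    """
    minx, miny, maxx, maxy = geom.bounds
    proj = LocalProjection((minx + maxx) / 2.0, (miny + maxy) / 2.0, kind="equal-area")
    c = proj.transform_geometry(geom).centroid
    lon, lat = proj.inverse(c.x, c.y)
    return float(lon), float(lat)


def read_geojson(path) -> list[dict]:
    """Read a GeoJSON FeatureCollection into [{'geometry': shapely, **properties}]."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection, got {doc.get('type')!r}")
    out = []
    for feat in doc.get("features", []):
        rec = dict(feat.get("properties") or {})
        rec["geometry"] = shape(feat["geometry"])
        out.append(rec)
    return out


def write_geojson(path, records: list[dict]) -> None:
    """Write [{'geometry': shapely, **properties}] as a FeatureCollection."""
    feats = []
    for rec in records:
        props = {k: v for k, v in rec.items() if k != "geometry"}
        feats.append({"type": "Feature", "geometry": mapping(rec["geometry"]), "properties": props})
    doc = {"type": "FeatureCollection", "features": feats}
    Path(path).write_text(json.dumps(doc, sort_keys=True))
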