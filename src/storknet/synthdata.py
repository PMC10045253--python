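"""Synthetic landscapes, ground-truthed commuting trajectories, and
ERGM-distributed networks.

The generator emulates the statistical structure the pipeline assumes about
wintering white-stork telemetry: multi-month fix streams at a nominal 5-min
interval with ~10 m GPS noise, two-state commuting movement (slow dwell inside
habitat sites, straight transits at 25-60 km/h between them, landfill-weighted
site choice decaying with distance), seasonal windows, and transmission gaps.
Every transit is recorded in a ground-truth trip log so flight extraction can
be validated exactly. Dyadic count networks with known generating coefficients
come from exact simulation of the valued ERGM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from . import vergm
from .geo import haversine_km
from .trackio import DEFAULT_DIALECT

M_PER_DEG_LAT = 111_320.0


@dataclass(frozen=True)
class LandscapeSpec:
    """Habitat-site layout inside a lon/lat box.

    Sites are 24-gon quasi-circles; centres are rejection-sampled so that
    every pair is at least ``min_separation_km`` apart (farther than the
    default 10 km node-merge radius, so one polygon maps to one node).
    """

    n_sites: dict = field(default_factory=lambda: {"Landfills": 3, "Marshes": 3, "Rice fields": 2})
    bbox: tuple[float, float, float, float] = (-6.8, 36.4, -4.6, 38.2)  # lon_min, lat_min, lon_max, lat_max
    radius_m: tuple[float, float] = (300.0, 800.0)
    min_separation_km: float = 15.0
    seed: int = 0


def gen_landscape(spec: LandscapeSpec = LandscapeSpec()) -> pd.DataFrame:
    """Generate non-overlapping habitat polygons (columns like sites.load_polygons)."""
    rng = np.random.default_rng(spec.seed)
    lon_min, lat_min, lon_max, lat_max = spec.bbox
    habitats = [h for h, k in sorted(spec.n_sites.items()) for _ in range(int(k))]
    centers: list[tuple[float, float]] = []
    for _ in habitats:
        for _attempt in range(10_000):
            lon = rng.uniform(lon_min, lon_max)
            lat = rng.uniform(lat_min, lat_max)
            if all(haversine_km(lon, lat, c[0], c[1]) >= spec.min_separation_km for c in centers):
                centers.append((lon, lat))
                break
        else:
            raise RuntimeError(
                f"could not pack {len(habitats)} sites at {spec.min_separation_km} km separation; enlarge bbox"
            )
    rows = []
    for pid, (habitat, (lon, lat)) in enumerate(zip(habitats, centers)):
        r_m = rng.uniform(*spec.radius_m)
        ang = np.linspace(0.0, 2.0 * math.pi, 24, endpoint=False)
        dlat = r_m / M_PER_DEG_LAT
        dlon = r_m / (M_PER_DEG_LAT * math.cos(math.radians(lat)))
        poly = shapely.Polygon(np.column_stack([lon + dlon * np.cos(ang), lat + dlat * np.sin(ang)]))
        rows.append({"polygon_id": pid, "habitat": habitat, "geometry": poly, "lon": lon, "lat": lat, "radius_m": r_m})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MovementSpec:
    """Two-state (dwell/transit) commuting movement model."""

    n_birds: int = 3
    season_start: str = "2020-09-01"
    season_end: str = "2021-03-31"
    fix_interval_s: float = 300.0
    fix_jitter_s: float = 30.0
    dwell_median_h: float = 3.0
    dwell_sigma: float = 0.5  # log-normal sigma of dwell duration
    delta_km: float = 20.0  # distance decay of site choice
    habitat_preference: dict = field(default_factory=lambda: {"Landfills": 3.0})
    transit_speed_kmh: tuple[float, float] = (25.0, 60.0)
    gps_noise_m: float = 10.0
    gap_per_day: float = 0.05  # per-day probability of a transmission gap
    gap_hours: tuple[float, float] = (2.0, 24.0)
    seed: int = 0


@dataclass
class GroundTruth:
    """Ordered trip log per bird; the oracle for flight extraction."""

    trips: pd.DataFrame  # bird_id, origin_polygon_id, dest_polygon_id, depart, arrive

    def trip_matrix(self, polygon_ids) -> pd.DataFrame:
        ids = list(polygon_ids)
        mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
        for row in self.trips.itertuples():
            mat.loc[row.origin_polygon_id, row.dest_polygon_id] += 1
        return mat


def gen_tracks(landscape: pd.DataFrame, spec: MovementSpec = MovementSpec()) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate commuting GPS fix streams over a landscape.

    Returns (fixes in Movebank-dialect columns, GroundTruth). Departures are
    anchored to fix times so that at zero noise the flight-extraction
    automaton recovers the trip log exactly: dwell fixes always imply speeds
    far below the 10 km/h flight threshold and sit inside their site, transit
    fixes imply the sampled cruise speed. Transmission gaps (2-24 h) are
    placed inside dwell phases only, away from dwell edges.
    """
    if len(landscape) < 2:
        raise ValueError("need at least 2 sites to generate trips")
    rng = np.random.default_rng(spec.seed)
    centers = landscape[["lon", "lat"]].to_numpy()
    radius = landscape["radius_m"].to_numpy() if "radius_m" in landscape else np.full(len(landscape), 400.0)
    pids = landscape["polygon_id"].to_numpy()
    pref = np.array([spec.habitat_preference.get(h, 1.0) for h in landscape["habitat"]])
    dist_km = haversine_km(centers[:, 0][:, None], centers[:, 1][:, None], centers[None, :, 0], centers[None, :, 1])

    t0 = pd.Timestamp(spec.season_start, tz="UTC")
    t1 = pd.Timestamp(spec.season_end, tz="UTC")
    total_s = (t1 - t0).total_seconds()
    dwell_mu = math.log(spec.dwell_median_h * 3600.0)
    min_dwell_s = 2.5 * spec.fix_interval_s

    all_rows = []
    trip_rows = []
    for b in range(spec.n_birds):
        bird = f"S{b + 1:03d}"
        # fix schedule for the whole season
        n_max = int(total_s / (spec.fix_interval_s - spec.fix_jitter_s)) + 2
        steps = spec.fix_interval_s + rng.uniform(-spec.fix_jitter_s, spec.fix_jitter_s, size=n_max)
        fix_s = np.cumsum(steps)
        fix_s = fix_s[fix_s < total_s]

        site = int(rng.choice(len(landscape), p=pref / pref.sum()))
        events = []  # (kind, start_s, end_s, payload)
        t = 0.0
        while t < total_s:
            dwell = max(min_dwell_s, rng.lognormal(dwell_mu, spec.dwell_sigma))
            # anchor departure to the first fix time after the nominal dwell end
            k = np.searchsorted(fix_s, t + dwell, side="right")
            depart = fix_s[k] + 1.0 if k < len(fix_s) else total_s
            events.append(("dwell", t, min(depart, total_s), site))
            if depart >= total_s:
                break
            w = pref * np.exp(-dist_km[site] / spec.delta_km)
            w[site] = 0.0
            nxt = int(rng.choice(len(landscape), p=w / w.sum()))
            speed = rng.uniform(*spec.transit_speed_kmh)
            dur = dist_km[site, nxt] / speed * 3600.0
            arrive = depart + dur
            if arrive >= total_s:
                break
            events.append(("transit", depart, arrive, (site, nxt)))
            trip_rows.append(
                {
                    "bird_id": bird,
                    "origin_polygon_id": int(pids[site]),
                    "dest_polygon_id": int(pids[nxt]),
                    "depart": t0 + pd.Timedelta(seconds=depart),
                    "arrive": t0 + pd.Timedelta(seconds=arrive),
                }
            )
            site = nxt
            t = arrive

        # dwell-phase transmission gaps
        drop_mask = np.zeros(len(fix_s), dtype=bool)
        for kind, es, ee, _payload in events:
            if kind != "dwell":
                continue
            dur_days = (ee - es) / 86_400.0
            if rng.random() < spec.gap_per_day * dur_days:
                gap = rng.uniform(*spec.gap_hours) * 3600.0
                margin = 2.0 * spec.fix_interval_s
                lo, hi = es + margin, ee - margin
                if hi - lo <= 0:
                    continue
                gap = min(gap, hi - lo)
                gs = rng.uniform(lo, hi - gap)
                drop_mask |= (fix_s >= gs) & (fix_s <= gs + gap)
        keep_s = fix_s[~drop_mask]

        # positions at fix times
        lonlat = np.empty((len(keep_s), 2))
        walk = np.zeros(2)  # dwell random-walk offset, metres
        ev_idx = 0
        for fi, ts in enumerate(keep_s):
            while ev_idx + 1 < len(events) and ts >= events[ev_idx][2]:
                ev_idx += 1
            kind, es, ee, payload = events[ev_idx]
            if kind == "dwell":
                s = payload
                step = rng.uniform(-150.0, 150.0, size=2)
                walk = walk + step
                rmax = 0.5 * radius[s]
                norm = np.hypot(*walk)
                if norm > rmax:
                    walk *= rmax / norm
                base = centers[s]
                off = walk
            else:
                s, nx = payload
                frac = np.clip((ts - es) / (ee - es), 0.0, 1.0)
                base = centers[s] + frac * (centers[nx] - centers[s])
                off = np.zeros(2)
                walk = np.zeros(2)
            noise = rng.normal(0.0, spec.gps_noise_m, size=2) if spec.gps_noise_m > 0 else np.zeros(2)
            dxy = off + noise
            lat = base[1] + dxy[1] / M_PER_DEG_LAT
            lon = base[0] + dxy[0] / (M_PER_DEG_LAT * math.cos(math.radians(base[1])))
            lonlat[fi] = (lon, lat)

        ts_abs = t0 + pd.to_timedelta(np.round(keep_s).astype(int), unit="s")
        all_rows.append(
            pd.DataFrame(
                {
                    DEFAULT_DIALECT["bird_id"]: bird,
                    DEFAULT_DIALECT["timestamp"]: ts_abs.strftime("%Y-%m-%d %H:%M:%S").to_numpy(),
                    DEFAULT_DIALECT["lon"]: lonlat[:, 0],
                    DEFAULT_DIALECT["lat"]: lonlat[:, 1],
                }
            )
        )
    fixes = pd.concat(all_rows, ignore_index=True)
    trips = pd.DataFrame(trip_rows, columns=["bird_id", "origin_polygon_id", "dest_polygon_id", "depart", "arrive"])
    return fixes, GroundTruth(trips=trips)


# ---------------------------------------------------------------------------
# ERGM study configurations
# ---------------------------------------------------------------------------

#: 34-node habitat inventory for a southern-Spain-like regional network:
#: 5 landfills, 3 of each of the 8 wetland classes, and 10 default-habitat
#: (terrestrial) nodes.
SPAIN_INVENTORY: tuple[str, ...] = (
    ("Landfills",) * 5
    + ("Rice fields",) * 3
    + ("Fish aquaculture",) * 3
    + ("Irrigation ponds",) * 3
    + ("Dams",) * 3
    + ("Salines",) * 3
    + ("Marshes",) * 3
    + ("Lakes and ponds",) * 3
    + ("Water courses",) * 3
    + ("Urban areas",) * 2
    + ("Non-irrigated arable land",) * 1
    + ("Permanently irrigated land",) * 1
    + ("Agro-forestry areas",) * 1
)

#: 31-node inventory for a northern-Morocco-like regional network (no fish
#: aquaculture, irrigation ponds, dams or salines).
MOROCCO_INVENTORY: tuple[str, ...] = (
    ("Landfills",) * 5
    + ("Rice fields",) * 4
    + ("Marshes",) * 4
    + ("Lakes and ponds",) * 4
    + ("Water courses",) * 4
    + ("Urban areas",) * 3
    + ("Non-irrigated arable land",) * 3
    + ("Permanently irrigated land",) * 2
    + ("Agro-forestry areas",) * 2
)

SPAIN_TERMS: tuple[str, ...] = (
    "sum",
    "nodeofactor:Landfills",
    "nodeifactor:Rice fields",
    "nodeifactor:Fish aquaculture",
    "nodeifactor:Irrigation ponds",
    "nodeifactor:Dams",
    "nodeifactor:Salines",
    "nodeifactor:Marshes",
    "nodeifactor:Lakes and ponds",
    "nodeifactor:Water courses",
    "edgecov:distance_km",
    "mutuality",
)

#: Generating coefficients for the southern-Spain configuration (aligned with
#: SPAIN_TERMS): intercept-like sum, landfill out-factor, the eight wetland
#: in-factors, distance decay per km, and mutuality on -|y_ij - y_ji|.
SPAIN_THETA: tuple[float, ...] = (4.75, 1.49, 2.53, -0.05, -2.32, -1.28, 1.66, -1.45, -0.06, 0.04, -0.15, 0.85)

MOROCCO_TERMS: tuple[str, ...] = (
    "sum",
    "nodeofactor:Landfills",
    "nodeifactor:Rice fields",
    "nodeifactor:Marshes",
    "nodeifactor:Lakes and ponds",
    "nodeifactor:Water courses",
    "edgecov:distance_km",
    "mutuality",
)

#: Generating coefficients for the northern-Morocco configuration.
MOROCCO_THETA: tuple[float, ...] = (5.56, 0.39, 0.01, 0.08, -0.28, -0.78, -0.19, 0.08)


def random_distance_matrix(n: int, rng: np.random.Generator, low_km: float = 2.0, high_km: float = 200.0) -> np.ndarray:
    """Symmetric pairwise distances drawn uniformly on [low_km, high_km]."""
    d = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    d[iu] = rng.uniform(low_km, high_km, size=len(iu[0]))
    return d + d.T


def gen_ergm_network(
    theta,
    habitats,
    terms,
    seed: int | np.random.Generator = 0,
    distances_km: np.ndarray | None = None,
) -> tuple[np.ndarray, vergm.ErgmModel]:
    """Materialise a model (habitats + distances) and draw exact counts."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if distances_km is None:
        distances_km = random_distance_matrix(len(habitats), rng)
    model = vergm.ErgmModel(terms, habitats, covariates={"distance_km": distances_km})
    y = vergm.simulate_network(np.asarray(theta, dtype=float), model, seed=rng)
    return y, model
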