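"""GPS track ingestion, kinematics, and the five-stage quality filter cascade.

Fixes live in a pandas DataFrame with canonical columns ``bird_id``,
``timestamp`` (tz-aware UTC), ``lon``, ``lat`` plus derived kinematics
``dt_min``, ``dist_km``, ``speed_kmh`` (NaN on the first fix of a bird or
segment start carries-in values; the kinematics of fix k describe the step
from fix k-1 to fix k) and a boolean ``segment_start`` flag marking fixes that
follow a transmission gap of at least ``max_dt_min`` minutes.

The cascade mirrors a standard telemetry-cleaning protocol for wintering-range
studies: (1) keep birds whose mid-winter median position lies in the study
box, (2) keep non-breeding-season fixes (September-March), (3) thin to a
minimum fix spacing, (4) delete biologically impossible speeds to a fixed
point, (5) drop sparsely sampled bird-years.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import haversine_km, validate_lonlat

DEFAULT_DIALECT = {
    "bird_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
}

SEASON_MONTHS = (9, 10, 11, 12, 1, 2, 3)
WINTER_MONTHS = (12, 1, 2)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the five-filter cascade."""

    lat_box: tuple[float, float] = (30.0, 42.5)
    lon_box: tuple[float, float] = (-10.0, 3.5)
    season_months: tuple[int, ...] = SEASON_MONTHS
    min_dt_min: float = 4.0  # keep fixes strictly more than this far apart
    max_dt_min: float = 61.0  # gaps at/above this start a new segment
    max_speed_kmh: float = 100.0
    min_fixes_per_birdyear: int = 1000

    def __post_init__(self):
        if not (0 < self.min_dt_min < self.max_dt_min):
            raise ValueError("require 0 < min_dt_min < max_dt_min")
        if self.max_speed_kmh <= 0 or self.min_fixes_per_birdyear <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ReadReport:
    n_rows: int
    n_duplicates_dropped: int
    n_birds: int


@dataclass
class FilterReport:
    """Per-stage accounting of the cascade; drops + survivors = input, per bird."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: int, name: str, n_in: int, n_out: int, per_bird_dropped: dict):
        self.stages.append(
            {
                "stage": stage,
                "name": name,
                "n_in": int(n_in),
                "n_out": int(n_out),
                "n_dropped": int(n_in - n_out),
                "per_bird_dropped": {str(k): int(v) for k, v in per_bird_dropped.items()},
            }
        )

    def to_json(self, path=None) -> str:
        text = json.dumps({"stages": self.stages}, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def read_fixes(path, dialect: dict | None = None) -> tuple[pd.DataFrame, ReadReport]:
    """Read a Movebank-dialect CSV into canonical fix columns.

    Rows are sorted by (bird_id, timestamp); duplicate (bird, timestamp) rows
    keep the first occurrence. Unparseable timestamps and out-of-range
    coordinates raise with the offending (1-based data) row number.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path)
    missing = [v for v in dialect.values() if v not in raw.columns]
    if missing:
        raise KeyError(f"{path}: missing mandatory column(s) {missing}; available: {list(raw.columns)}")
    df = pd.DataFrame(
        {
            "bird_id": raw[dialect["bird_id"]].astype(str),
            "timestamp": pd.to_datetime(raw[dialect["timestamp"]], utc=True, errors="coerce", format="mixed"),
            "lon": pd.to_numeric(raw[dialect["lon"]], errors="coerce"),
            "lat": pd.to_numeric(raw[dialect["lat"]], errors="coerce"),
        }
    )
    bad_ts = df["timestamp"].isna()
    if bad_ts.any():
        row = int(np.flatnonzero(bad_ts.to_numpy())[0]) + 1
        raise ValueError(f"{path}: unparseable timestamp at data row {row}")
    bad_coord = (
        df["lon"].isna()
        | df["lat"].isna()
        | (df["lon"].abs() > 180.0)
        | (df["lat"].abs() > 90.0)
    )
    if bad_coord.any():
        row = int(np.flatnonzero(bad_coord.to_numpy())[0]) + 1
        raise ValueError(f"{path}: invalid coordinate at data row {row}")
    n_rows = len(df)
    df = df.sort_values(["bird_id", "timestamp"], kind="mergesort")
    dup = df.duplicated(subset=["bird_id", "timestamp"], keep="first")
    df = df.loc[~dup].reset_index(drop=True)
    report = ReadReport(n_rows=n_rows, n_duplicates_dropped=int(dup.sum()), n_birds=df["bird_id"].nunique())
    return df, report


def annotate_kinematics(df: pd.DataFrame, max_dt_min: float = 61.0) -> pd.DataFrame:
    """Recompute dt_min, dist_km, speed_kmh and segment_start per bird.

    The step to the first fix of each bird is undefined (NaN kinematics).
    segment_start is True on a bird's first fix and on any fix arriving after
    a gap of at least ``max_dt_min`` minutes.
    """
    df = df.sort_values(["bird_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    validate_lonlat(df["lon"].to_numpy(), df["lat"].to_numpy())
    same_bird = df["bird_id"].to_numpy()
    prev_same = np.zeros(len(df), dtype=bool)
    prev_same[1:] = same_bird[1:] == same_bird[:-1]

    ts = df["timestamp"].to_numpy()
    dt_min = np.full(len(df), np.nan)
    if len(df) > 1:
        dt_min[1:] = (ts[1:] - ts[:-1]) / np.timedelta64(1, "s") / 60.0
    dt_min[~prev_same] = np.nan
    if np.any(dt_min[prev_same] <= 0):
        raise ValueError("non-increasing timestamps within a bird after deduplication")

    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    dist_km = np.full(len(df), np.nan)
    if len(df) > 1:
        dist_km[1:] = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    dist_km[~prev_same] = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        speed = dist_km / (dt_min / 60.0)
    df = df.copy()
    df["dt_min"] = dt_min
    df["dist_km"] = dist_km
    df["speed_kmh"] = speed
    df["segment_start"] = ~prev_same | (dt_min >= max_dt_min)
    return df


def _per_bird_drop(before: pd.DataFrame, after: pd.DataFrame) -> dict:
    b = before.groupby("bird_id").size()
    a = after.groupby("bird_id").size()
    diff = b.sub(a, fill_value=0).astype(int)
    return {k: int(v) for k, v in diff.items() if v > 0}


def split_bird_years(df: pd.DataFrame) -> pd.DataFrame:
    """Label each fix with its bird-year '<bird_id>-<season_start_year>'.

    September-December fixes take the calendar year; January-March fixes
    belong to the season that started the previous September.
    """
    month = df["timestamp"].dt.month
    if not month.isin(SEASON_MONTHS).all():
        raise ValueError("split_bird_years requires season-filtered fixes (Sep-Mar)")
    year = df["timestamp"].dt.year.to_numpy()
    start_year = np.where(month.to_numpy() >= 9, year, year - 1)
    df = df.copy()
    df["season_start_year"] = start_year
    df["birdyear"] = df["bird_id"].astype(str) + "-" + pd.Series(start_year, index=df.index).astype(str)
    return df


def _speed_filter_pass(df: pd.DataFrame, max_speed_kmh: float) -> pd.DataFrame:
    """Greedy forward speed filter: drop a fix whose speed from the last
    *retained* fix exceeds the cap, re-linking neighbours on the fly (so one
    displaced fix does not drag its successor down with it)."""
    keep = np.ones(len(df), dtype=bool)
    ts = df["timestamp"].astype("int64").to_numpy() / 1_000_000_000.0
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    for _, idx in df.groupby("bird_id", sort=False).indices.items():
        last = idx[0]
        for i in idx[1:]:
            dt_h = (ts[i] - ts[last]) / 3600.0
            if float(haversine_km(lon[last], lat[last], lon[i], lat[i])) / dt_h > max_speed_kmh:
                keep[i] = False
            else:
                last = i
    return df.loc[keep]


def _thin_min_spacing(df: pd.DataFrame, min_dt_min: float) -> pd.DataFrame:
    """Greedy forward thinning: keep a fix only if it is more than
    ``min_dt_min`` minutes after the previously kept fix of the same bird."""
    keep = np.zeros(len(df), dtype=bool)
    ts = df["timestamp"].astype("int64").to_numpy() / 1_000_000_000.0
    for _, idx in df.groupby("bird_id", sort=False).indices.items():
        last = None
        for i in idx:
            if last is None or (ts[i] - last) / 60.0 > min_dt_min:
                keep[i] = True
                last = ts[i]
    return df.loc[keep]


def filter_cascade(df: pd.DataFrame, config: FilterConfig = FilterConfig()) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the five-stage quality cascade; returns filtered fixes + report.

    Stages: (1) drop birds whose December-February median position falls
    outside the study box; (2) keep season months; (3) thin fixes to a spacing
    greater than ``min_dt_min`` (gap arrivals of >= ``max_dt_min`` are kept and
    flagged as segment starts); (4) iteratively delete fixes implying speeds
    above ``max_speed_kmh``, recomputing kinematics after each pass, to a
    fixed point (at most 10 passes); (5) drop bird-years with fewer than
    ``min_fixes_per_birdyear`` fixes. Kinematics are recomputed after each
    fix-removing stage.
    """
    report = FilterReport()
    df = annotate_kinematics(df, config.max_dt_min)

    # Stage 1: winter-range box, per-bird Dec-Feb median position (birds with
    # no mid-winter fixes are judged on their full-track median instead).
    n_in = len(df)
    month = df["timestamp"].dt.month
    winter = df.loc[month.isin(WINTER_MONTHS)]
    med = winter.groupby("bird_id")[["lon", "lat"]].median()
    rest = df.loc[~df["bird_id"].isin(med.index)]
    if len(rest):
        med = pd.concat([med, rest.groupby("bird_id")[["lon", "lat"]].median()])
    ok = med.loc[
        (med["lat"] >= config.lat_box[0])
        & (med["lat"] <= config.lat_box[1])
        & (med["lon"] >= config.lon_box[0])
        & (med["lon"] <= config.lon_box[1])
    ].index
    out = df.loc[df["bird_id"].isin(ok)]
    report.add(1, "winter_box", n_in, len(out), _per_bird_drop(df, out))
    df = out

    # Stage 2: non-breeding season months.
    n_in = len(df)
    out = df.loc[df["timestamp"].dt.month.isin(config.season_months)]
    report.add(2, "season", n_in, len(out), _per_bird_drop(df, out))
    df = annotate_kinematics(out, config.max_dt_min) if len(out) else out

    # Stage 3: minimum fix spacing (sampling-effort standardisation).
    n_in = len(df)
    out = _thin_min_spacing(df, config.min_dt_min) if len(df) else df
    report.add(3, "min_spacing", n_in, len(out), _per_bird_drop(df, out))
    df = annotate_kinematics(out, config.max_dt_min) if len(out) else out

    # Stage 4: unrealistic speeds, repeated to a fixed point.
    n_in = len(df)
    before4 = df
    for _ in range(10):
        out = _speed_filter_pass(df, config.max_speed_kmh) if len(df) else df
        dropped = len(df) - len(out)
        df = annotate_kinematics(out, config.max_dt_min) if len(out) else out
        if dropped == 0:
            break
    report.add(4, "max_speed", n_in, len(df), _per_bird_drop(before4, df))

    # Stage 5: sparse bird-years.
    n_in = len(df)
    if len(df):
        df = split_bird_years(df)
        sizes = df.groupby("birdyear")["birdyear"].transform("size")
        out = df.loc[sizes >= config.min_fixes_per_birdyear]
    else:
        out = df
    report.add(5, "min_fixes_per_birdyear", n_in, len(out), _per_bird_drop(df, out))
    df = out.reset_index(drop=True)
    return df, report


def write_fixes_csv(df: pd.DataFrame, path, dialect: dict | None = None) -> None:
    """Write fixes in the input CSV dialect plus derived columns."""
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    out = pd.DataFrame(
        {
            dialect["bird_id"]: df["bird_id"],
            dialect["timestamp"]: df["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S"),
            dialect["lon"]: df["lon"],
            dialect["lat"]: df["lat"],
        }
    )
    for col in ("dt_min", "dist_km", "speed_kmh", "segment_start", "birdyear", "node_id"):
        if col in df.columns:
            out[col] = df[col].to_numpy()
    out.to_csv(path, index=False, float_format="%.10g")
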