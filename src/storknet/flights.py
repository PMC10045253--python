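"""Direct (non-stop) flight extraction and edge-list pooling.

A fix is *stationary* when its incoming speed is below the flight threshold
(or when it starts a new segment, including each bird-year's first fix);
otherwise it is *flying*. A maximal run of flying fixes bounded by two
stationary fixes becomes a direct flight when the bounding fixes sit inside
two different nodes and every inter-fix time step of the bounded run
(including the two bounding steps) is at most the gap limit. Intermediate
node crossings at flying speed do not split a flight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FLIGHT_COLUMNS = [
    "birdyear",
    "origin_node_id",
    "dest_node_id",
    "start_time",
    "end_time",
    "n_flight_fixes",
    "max_gap_min",
]


@dataclass(frozen=True)
class FlightConfig:
    fly_speed_kmh: float = 10.0
    max_gap_min: float = 60.0

    def __post_init__(self):
        if self.fly_speed_kmh <= 0 or self.max_gap_min <= 0:
            raise ValueError("fly_speed_kmh and max_gap_min must be positive")


def extract_direct_flights(fixes: pd.DataFrame, config: FlightConfig = FlightConfig()) -> pd.DataFrame:
    """Segment node-assigned, speed-annotated fixes into direct flights.

    Requires columns birdyear, timestamp, speed_kmh, node_id (nullable),
    segment_start. Returns one row per flight (FLIGHT_COLUMNS). The flight's
    start/end times are the timestamps of the bounding stationary fixes.
    """
    required = {"birdyear", "timestamp", "speed_kmh", "node_id", "segment_start"}
    missing = required - set(fixes.columns)
    if missing:
        raise ValueError(f"fixes missing required columns: {sorted(missing)}")

    rows = []
    for birdyear, grp in fixes.groupby("birdyear", sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        speed = grp["speed_kmh"].to_numpy(dtype=float)
        seg = grp["segment_start"].to_numpy(dtype=bool)
        node = grp["node_id"].to_numpy(dtype=object)
        ts = grp["timestamp"].to_numpy()
        n = len(grp)
        if n == 0:
            continue
        dt = np.full(n, np.nan)
        dt[1:] = (ts[1:] - ts[:-1]) / np.timedelta64(1, "m")

        # stationary: below threshold, or no incoming step (segment start)
        stationary = seg | (speed < config.fly_speed_kmh)
        s_idx = np.flatnonzero(stationary)
        for k in range(len(s_idx) - 1):
            a, b = s_idx[k], s_idx[k + 1]
            run = b - a - 1  # flying fixes strictly between the bounds
            if run < 1:
                continue
            origin, dest = node[a], node[b]
            if pd.isna(origin) or pd.isna(dest) or origin == dest:
                continue
            steps = dt[a + 1 : b + 1]  # bounded run incl. both bounding steps
            if np.any(seg[a + 1 : b + 1]) or np.nanmax(steps) > config.max_gap_min:
                continue
            rows.append(
                {
                    "birdyear": birdyear,
                    "origin_node_id": int(origin),
                    "dest_node_id": int(dest),
                    "start_time": ts[a],
                    "end_time": ts[b],
                    "n_flight_fixes": int(run),
                    "max_gap_min": float(np.max(steps)),
                }
            )
    return pd.DataFrame(rows, columns=FLIGHT_COLUMNS)


def flights_to_edgelist(flights: pd.DataFrame) -> pd.DataFrame:
    """Pool flights over bird-years into a directed weighted edge list."""
    if len(flights) == 0:
        return pd.DataFrame(columns=["origin_node_id", "dest_node_id", "weight"]).astype(
            {"origin_node_id": int, "dest_node_id": int, "weight": int}
        )
    edges = (
        flights.groupby(["origin_node_id", "dest_node_id"], sort=True)
        .size()
        .rename("weight")
        .reset_index()
        .astype({"origin_node_id": int, "dest_node_id": int, "weight": int})
    )
    return edges


def write_flights_csv(flights: pd.DataFrame, path) -> None:
    out = flights.copy()
    for col in ("start_time", "end_time"):
        out[col] = pd.to_datetime(out[col], utc=True).dt.strftime("%Y-%m-%d %H:%M:%S")
    out.to_csv(path, index=False, float_format="%.10g")
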