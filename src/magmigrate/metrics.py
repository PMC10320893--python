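"""Metrics, summaries and file IO for simulation experiments.

Fitness of an orientation program is the long-term geometric mean of yearly
arrival success, p-bar = (prod p_y)^(1/n): geometric (not arithmetic)
averaging penalizes catastrophic years, which is the appropriate survival
statistic. This module also provides the declination-binned heading-shift
curve, replicate aggregation, and versioned CSV/JSON/GeoJSON output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import circular
from .geodesy import wrap_angle

__all__ = [
    "FORMAT_VERSION",
    "geometric_mean_success",
    "yearly_metrics_frame",
    "heading_shift_by_declination_bin",
    "replicate_summary",
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_run_summary",
    "read_run_summary",
    "tracks_to_frame",
    "tracks_to_geojson",
]

FORMAT_VERSION = 1


def geometric_mean_success(series) -> float:
    """Geometric mean of yearly arrival fractions, computed in log space.

    Any zero year collapses the mean to exactly 0 (a year with no survivors
    means extinction regardless of other years).
    """
    p = np.asarray(series, dtype=float)
    if p.size == 0:
        raise ValueError("empty success series")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("success fractions must lie in [0, 1]")
    if np.any(p == 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(p))))


def yearly_metrics_frame(result) -> pd.DataFrame:
    """Tabulate a :class:`~magmigrate.evolution.SimulationResult` per year."""
    return pd.DataFrame({
        "year": result.years,
        "p_y": result.p_y,
        "overwater_mortality": result.overwater,
        "mean_theta1_deg": result.mean_theta1,
        "dispersion_theta1_deg": result.dispersion_theta1,
        "mean_signpost": result.mean_signpost,
        "mean_zugknick_lat_deg": result.mean_zugknick_lat,
        "switched_fraction": result.switched_fraction,
    })


def heading_shift_by_declination_bin(dheading, ddecl, dsignpost=None,
                                     bin_width: float = 5.0) -> pd.DataFrame:
    """Mean heading change per bin of natal declination change.

    ``dheading`` are per-individual heading changes since year 0 (degrees,
    reported in (-180, 180]); ``ddecl`` the declination changes at their
    natal sites. Rows are 5-degree declination bins; empty bins are omitted.
    The heading column is the circular mean of the changes.
    """
    dheading = np.asarray(wrap_angle(dheading))
    ddecl = np.asarray(ddecl, dtype=float)
    edges = np.arange(np.floor(ddecl.min() / bin_width) * bin_width,
                      np.ceil(ddecl.max() / bin_width) * bin_width + bin_width, bin_width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (ddecl >= lo) & (ddecl < hi)
        if not np.any(sel):
            continue
        mean_dh = circular.circular_mean(dheading[sel])
        row = {
            "decl_bin_lo": lo,
            "decl_bin_hi": hi,
            "n": int(sel.sum()),
            "mean_dheading_deg": float(wrap_angle(mean_dh)),
        }
        if dsignpost is not None:
            row["mean_dsignpost"] = float(np.mean(np.asarray(dsignpost)[sel]))
        rows.append(row)
    return pd.DataFrame(rows)


def replicate_summary(runs: pd.DataFrame, by=None) -> pd.DataFrame:
    """Mean and between-replicate SD of each numeric metric.

    ``runs`` has one row per replicate; optional ``by`` columns (e.g.
    population size) group the table. SD uses the sample (ddof=1) estimator
    and requires at least two replicates per group.
    """
    numeric = runs.select_dtypes("number")
    group_cols = [by] if isinstance(by, str) else list(by or [])
    if group_cols:
        grouped = runs.groupby(group_cols)
        counts = grouped.size()
        if (counts < 2).any():
            raise ValueError("need >= 2 replicates per group")
        agg = grouped[[c for c in numeric.columns if c not in group_cols]].agg(["mean", "std"])
        return agg
    if len(runs) < 2:
        raise ValueError("need >= 2 replicates")
    return numeric.agg(["mean", "std"])


# ---------------------------------------------------------------------------
# File IO (all formats carry a version marker and round-trip exactly)
# ---------------------------------------------------------------------------


def write_timeseries_csv(path, frame: pd.DataFrame):
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# magmigrate timeseries v{FORMAT_VERSION}\n")
        frame.to_csv(fh, index=False)


def read_timeseries_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_run_summary(path, summary: dict):
    """JSON run summary; includes the format version and passes through config."""
    payload = {"format_version": FORMAT_VERSION, **summary}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify))


def read_run_summary(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def tracks_to_frame(tracks) -> pd.DataFrame:
    """Tabulate engine track logs: one row per landing/decision event."""
    return pd.DataFrame(tracks, columns=["individual", "day", "lat", "lon", "event"])


def tracks_to_geojson(tracks) -> dict:
    """Convert engine track logs [(individual, day, lat, lon, event), ...]
    into a GeoJSON FeatureCollection of per-individual LineStrings."""
    features = {}
    for ind, day, lat, lon, event in tracks:
        features.setdefault(ind, []).append((day, lon, lat, event))
    collection = []
    for ind, pts in sorted(features.items()):
        pts.sort()
        collection.append({
            "type": "Feature",
            "properties": {
                "individual": ind,
                "events": [{"day": p[0], "event": p[3]} for p in pts],
            },
            "geometry": {
                "type": "LineString",
                "coordinates": [[p[1], p[2]] for p in pts],
            },
        })
    return {"type": "FeatureCollection",
            "properties": {"format_version": FORMAT_VERSION},
            "features": collection}
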