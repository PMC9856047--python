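"""CSV readers/writers and configuration for the pipeline.

All dates are ISO 8601.  Dialects:

* temperature CSV: ``date``, optional ``hour`` (0-23), ``temp_c``
* capture CSV: ``interval_start``, ``interval_end``, ``count``; optional
  ``season`` column to carry several breeding years in one file
* rearing CSV: ``temperature`` (number or the literal ``AC``), ``hatch_d``,
  ``l1_d``, ``l2_d``, ``l3_d``, ``pupa_d``, ``adult_d``, optional
  ``ambient_total_dd``; missing stages as empty cells
* metrics CSV: ``season``, ``onset_day``, ``peak_day``, ``end_day``, the
  corresponding dates, ``included``, ``exclusion_reason``
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .degree_days import SeasonDDResult, TemperatureSeries
from .phenology import CaptureSeries, PhenologyMetrics
from .thermal import AMBIENT_LABEL, STAGES, StageDurationTable, StageRow


class MalformedInputError(ValueError):
    """A CSV row failed validation; the message names the line."""


# ---------------------------------------------------------------------------
# temperature


def read_temperature_csv(path) -> TemperatureSeries:
    df = pd.read_csv(path)
    required = {"date", "temp_c"}
    if not required.issubset(df.columns):
        raise MalformedInputError(f"{path}: need columns {sorted(required)}")
    bad = pd.to_datetime(df["date"], errors="coerce").isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:5]
        raise MalformedInputError(f"{path}: unparseable date on line(s) {lines}")
    resolution = "hourly" if "hour" in df.columns else "daily"
    return TemperatureSeries(data=df, resolution=resolution)


def write_temperature_csv(series: TemperatureSeries, path) -> int:
    df = series.data.copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format="%.6g")
    return len(df)


# ---------------------------------------------------------------------------
# captures


def read_capture_csv(path) -> list[CaptureSeries]:
    """Read one or more breeding years of capture intervals.

    Without a ``season`` column the whole file is one series labelled by the
    first interval's year.  A season whose rows all have an empty ``count``
    is interpreted as a closed-trap year.
    """
    df = pd.read_csv(path)
    required = {"interval_start", "interval_end", "count"}
    if not required.issubset(df.columns):
        raise MalformedInputError(f"{path}: need columns {sorted(required)}")
    for col in ("interval_start", "interval_end"):
        bad = pd.to_datetime(df[col], errors="coerce").isna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]
            raise MalformedInputError(f"{path}: unparseable {col} on line(s) {lines}")
    if "season" not in df.columns:
        df["season"] = pd.to_datetime(df["interval_start"]).dt.year.iloc[0]
    out = []
    for season, sub in df.groupby("season", sort=True):
        if sub["count"].isna().all():
            out.append(CaptureSeries(season=int(season),
                                     data=sub.iloc[0:0][list(required)],
                                     trap_closed=True))
            continue
        try:
            out.append(CaptureSeries(season=int(season),
                                     data=sub[list(required)].reset_index(drop=True)))
        except ValueError as exc:
            lines = (sub.index + 2).tolist()
            raise MalformedInputError(
                f"{path}: season {season} (lines {lines[0]}-{lines[-1]}): {exc}"
            ) from exc
    return out


def write_capture_csv(series_list: list[CaptureSeries], path) -> int:
    frames = []
    for s in series_list:
        df = s.data.copy()
        if s.trap_closed:
            df = pd.DataFrame({"interval_start": [pd.NaT], "interval_end": [pd.NaT],
                               "count": [np.nan]})
        df["season"] = s.season
        frames.append(df[["season", "interval_start", "interval_end", "count"]])
    out = pd.concat(frames, ignore_index=True)
    for col in ("interval_start", "interval_end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return len(out)


# ---------------------------------------------------------------------------
# rearing tables

_STAGE_COLS = [f"{s}_d" for s in STAGES]


def read_rearing_csv(path) -> StageDurationTable:
    df = pd.read_csv(path)
    if "temperature" not in df.columns or not set(_STAGE_COLS).issubset(df.columns):
        raise MalformedInputError(
            f"{path}: need columns ['temperature'] + {_STAGE_COLS}")
    rows = []
    for i, rec in df.iterrows():
        raw_t = str(rec["temperature"]).strip()
        temp = None if raw_t.upper() == AMBIENT_LABEL else float(raw_t)
        days = {s: (None if pd.isna(rec[f"{s}_d"]) else float(rec[f"{s}_d"]))
                for s in STAGES}
        ambient_dd = None
        if "ambient_total_dd" in df.columns and not pd.isna(rec.get("ambient_total_dd")):
            ambient_dd = float(rec["ambient_total_dd"])
        try:
            rows.append(StageRow(temperature=temp, days=days,
                                 ambient_total_dd=ambient_dd))
        except ValueError as exc:
            raise MalformedInputError(f"{path}: line {i + 2}: {exc}") from exc
    return StageDurationTable(rows=rows)


def write_rearing_csv(table: StageDurationTable, path) -> int:
    recs = []
    for row in table:
        rec = {"temperature": AMBIENT_LABEL if row.is_ambient
               else f"{row.temperature:g}"}
        rec.update({f"{s}_d": row.days.get(s) for s in STAGES})
        rec["ambient_total_dd"] = row.ambient_total_dd
        recs.append(rec)
    pd.DataFrame(recs).to_csv(path, index=False, float_format="%.6g")
    return len(recs)


# ---------------------------------------------------------------------------
# season / metrics / trend outputs


def write_season_dd_csv(results: list[SeasonDDResult], path) -> int:
    recs = [{
        "season": r.season,
        "total_dd": None if r.total_dd is None else round(r.total_dd, 3),
        "complete": r.complete,
        "emergence_date": r.emergence_date.isoformat() if r.emergence_date else "",
        "emergence_doy_from_start": r.emergence_doy_from_start,
    } for r in results]
    pd.DataFrame(recs).to_csv(path, index=False)
    return len(recs)


def write_metrics_csv(metrics: list[PhenologyMetrics], path) -> int:
    recs = []
    for m in metrics:
        recs.append({
            "season": m.season,
            "onset_day": m.onset_day, "peak_day": m.peak_day, "end_day": m.end_day,
            "onset_date": m.onset_date.isoformat() if m.onset_date else "",
            "peak_date": m.peak_date.isoformat() if m.peak_date else "",
            "end_date": m.end_date.isoformat() if m.end_date else "",
            "included": m.included,
            "exclusion_reason": m.exclusion_reason,
        })
    pd.DataFrame(recs).to_csv(path, index=False)
    return len(recs)


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = df.rename(columns={"season": "year"})
    return df


# ---------------------------------------------------------------------------
# configuration


DEFAULT_CONFIG = {
    "t_min": 2.0,
    "t_max": 28.0,
    "dd_req": 439.0,
    "season_start_doy": 200,
    "season_end": "end_of_february",
    "max_gap_days": 7,
    "fractions": [0.10, 0.50, 0.90],
    "min_weeks": 2,
    "split_year": None,
    "seed": 0,
}


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> dict:
    """Merge defaults, an optional YAML file, and CLI overrides (in that order)."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        unknown = set(loaded) - set(cfg) - {"scenario"}
        if unknown:
            raise MalformedInputError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg.update(loaded)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    if not all(0 < f < 1 for f in cfg["fractions"]) or \
            list(cfg["fractions"]) != sorted(set(cfg["fractions"])):
        raise MalformedInputError("fractions must be strictly increasing in (0,1)")
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
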