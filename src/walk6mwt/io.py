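"""Readers and writers for walk traces (CSV, JSON) and GPX 1.1 export.

CSV schema (header mandatory)::

    t,lat,lon,alt,acc,heading,speed,steps,accel_mag

An empty cell means the channel is absent for that sample. The JSON form
is an object with a ``meta`` block (participant_id, path_type, label,
reference_distance_m) and a ``samples`` array of records with the same
keys. CSV/JSON round-trips preserve every field exactly.
"""

from __future__ import annotations

import csv
import json
import math
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union
from xml.etree import ElementTree as ET

from .trace import GnssSample, WalkTrace

CSV_COLUMNS = ["t", "lat", "lon", "alt", "acc", "heading", "speed", "steps", "accel_mag"]
_OPTIONAL = {"alt", "heading", "speed", "steps", "accel_mag"}

PathLike = Union[str, Path]


class TraceParseError(ValueError):
    """Raised when a trace file is malformed; names the offending row/column."""


def _parse_cell(row_no: int, col: str, raw: str) -> Optional[float]:
    raw = raw.strip()
    if raw == "":
        if col in _OPTIONAL:
            return None
        raise TraceParseError(f"row {row_no}: mandatory column {col!r} is empty")
    try:
        return float(raw)
    except ValueError as exc:
        raise TraceParseError(f"row {row_no}: cannot parse column {col!r} value {raw!r}") from exc


def _sample_from_record(row_no: int, rec: dict) -> GnssSample:
    steps = rec.get("steps")
    return GnssSample(
        t=rec["t"],
        lat=rec["lat"],
        lon=rec["lon"],
        alt=rec.get("alt"),
        acc=rec.get("acc") if rec.get("acc") is not None else 0.0,
        heading=rec.get("heading"),
        speed=rec.get("speed"),
        steps=None if steps is None else int(steps),
        accel_mag=rec.get("accel_mag"),
    )


def read_trace_csv(path: PathLike) -> WalkTrace:
    path = Path(path)
    samples: list[GnssSample] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TraceParseError(f"{path}: empty file")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise TraceParseError(f"{path}: missing mandatory columns {missing}")
        for row_no, row in enumerate(reader, start=2):
            rec = {col: _parse_cell(row_no, col, row.get(col) or "") for col in CSV_COLUMNS}
            samples.append(_sample_from_record(row_no, rec))
    return WalkTrace(samples=samples)


def write_trace_csv(trace: WalkTrace, path: PathLike) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for s in trace.samples:
            writer.writerow(
                [
                    _fmt(s.t),
                    _fmt(s.lat),
                    _fmt(s.lon),
                    _fmt(s.alt),
                    _fmt(s.acc),
                    _fmt(s.heading),
                    _fmt(s.speed),
                    "" if s.steps is None else s.steps,
                    _fmt(s.accel_mag),
                ]
            )


def _fmt(v: Optional[float]) -> str:
    if v is None:
        return ""
    return repr(float(v))  # repr round-trips float64 exactly


def read_trace_json(path: PathLike) -> WalkTrace:
    path = Path(path)
    with path.open() as fh:
        doc = json.load(fh)
    meta = doc.get("meta", {})
    samples = [
        _sample_from_record(i, rec) for i, rec in enumerate(doc.get("samples", []), start=1)
    ]
    return WalkTrace(
        samples=samples,
        participant_id=meta.get("participant_id", ""),
        path_type=meta.get("path_type", "unknown"),
        label=meta.get("label", "unknown"),
        reference_distance_m=meta.get("reference_distance_m"),
    )


def write_trace_json(trace: WalkTrace, path: PathLike) -> None:
    doc = {
        "meta": {
            "participant_id": trace.participant_id,
            "path_type": trace.path_type,
            "label": trace.label,
            "reference_distance_m": trace.reference_distance_m,
        },
        "samples": [
            {
                "t": s.t,
                "lat": s.lat,
                "lon": s.lon,
                "alt": s.alt,
                "acc": s.acc,
                "heading": s.heading,
                "speed": s.speed,
                "steps": s.steps,
                "accel_mag": s.accel_mag,
            }
            for s in trace.samples
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_trace(path: PathLike) -> WalkTrace:
    """Dispatch on file extension (.csv or .json)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_trace_csv(path)
    if path.suffix.lower() == ".json":
        return read_trace_json(path)
    raise ValueError(f"unsupported trace format {path.suffix!r}")


def write_trace(trace: WalkTrace, path: PathLike) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        write_trace_csv(trace, path)
    elif path.suffix.lower() == ".json":
        write_trace_json(trace, path)
    else:
        raise ValueError(f"unsupported trace format {path.suffix!r}")


def export_gpx(trace: WalkTrace, path: PathLike) -> None:
    """Write a GPX 1.1 track with one trkpt per sample (time and ele included)."""
    gpx = ET.Element(
        "gpx",
        attrib={
            "version": "1.1",
            "creator": "walk6mwt",
            "xmlns": "http://www.topografix.com/GPX/1/1",
        },
    )
    trk = ET.SubElement(gpx, "trk")
    name = ET.SubElement(trk, "name")
    name.text = trace.participant_id or "walk"
    seg = ET.SubElement(trk, "trkseg")
    for s in trace.samples:
        pt = ET.SubElement(seg, "trkpt", attrib={"lat": repr(s.lat), "lon": repr(s.lon)})
        if s.alt is not None and math.isfinite(s.alt):
            ele = ET.SubElement(pt, "ele")
            ele.text = repr(s.alt)
        tm = ET.SubElement(pt, "time")
        tm.text = (
            datetime.fromtimestamp(s.t, tz=timezone.utc).strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3]
            + "Z"
        )
    ET.ElementTree(gpx).write(Path(path), encoding="unicode", xml_declaration=True)
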