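"""Readers and writers for the pipeline's tabular formats, plus the packaged
session-summary fixtures transcribed from the published inactivation tables
(46 SC sessions, 23 FEF sessions, chronological order).

All files are comma-separated UTF-8 with a mandatory header and "." decimal.
Optional numeric fields round-trip through empty cells.
"""
from __future__ import annotations

import math
from importlib import resources
from typing import List, Literal, Sequence, Union

import pandas as pd

from .datatypes import (AttentionTrial, ChangeSide, Epoch, SaccadeRecord,
                        SessionSummary, Structure, ValidationError)

SESSION_COLUMNS = [
    "session_id", "structure", "subject",
    "hit_in_before", "hit_out_before", "hit_in_during", "hit_out_during",
    "latency_asym_ms", "velocity_asym_degps", "delta_det_asym_pct",
    "scotoma_area_deg2", "overlap_pct", "center_dist_deg",
    "scotoma_x_deg", "scotoma_y_deg", "injection_ul", "significant_deficit",
]
ATTENTION_COLUMNS = [
    "session_id", "epoch", "change_side", "change_magnitude_deg",
    "delay_s", "responded", "reaction_time_s", "valid",
]
SACCADE_COLUMNS = [
    "session_id", "epoch", "target_x_deg", "target_y_deg",
    "endpoint_x_deg", "endpoint_y_deg", "latency_ms", "peak_velocity_degps",
]

_FIXTURES = {Structure.SC: "sc_sessions.csv", Structure.FEF: "fef_sessions.csv"}
_FIXTURE_ROWS = {Structure.SC: 46, Structure.FEF: 23}

Schema = Literal["summary", "attention_trials", "saccades"]


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def load_fixture(table_id: Union[str, Structure]) -> List[SessionSummary]:
    """Packaged per-session summaries for the SC or FEF inactivation series."""
    table_id = Structure(table_id)
    if table_id not in _FIXTURES:
        raise ValueError("fixtures exist only for SC and FEF")
    ref = resources.files("covattn.data") / _FIXTURES[table_id]
    try:
        with resources.as_file(ref) as path:
            rows = _read_summary(pd.read_csv(path))
    except (FileNotFoundError, pd.errors.ParserError) as exc:
        raise RuntimeError(f"packaged fixture for {table_id.value} is missing "
                           f"or corrupt: {exc}") from exc
    if len(rows) != _FIXTURE_ROWS[table_id]:
        raise RuntimeError(
            f"fixture for {table_id.value} has {len(rows)} rows, "
            f"expected {_FIXTURE_ROWS[table_id]}")
    return rows


def _require_columns(df: pd.DataFrame, expected: Sequence[str], what: str) -> None:
    unknown = [c for c in df.columns if c not in expected]
    missing = [c for c in expected if c not in df.columns]
    if unknown or missing:
        raise ValidationError(
            f"{what}: unknown columns {unknown}, missing columns {missing}")


def _read_summary(df: pd.DataFrame) -> List[SessionSummary]:
    _require_columns(df, SESSION_COLUMNS, "sessions table")
    seen = set()
    out = []
    for i, row in df.iterrows():
        sid = str(row["session_id"])
        if sid in seen:
            raise ValidationError(f"row {i}: duplicate session_id {sid!r}")
        seen.add(sid)
        try:
            sig = _opt(row["significant_deficit"])
            out.append(SessionSummary(
                session_id=sid,
                structure=Structure(row["structure"]),
                subject=str(row["subject"]),
                hit_in_before=_opt(row["hit_in_before"]),
                hit_out_before=_opt(row["hit_out_before"]),
                hit_in_during=_opt(row["hit_in_during"]),
                hit_out_during=_opt(row["hit_out_during"]),
                latency_asym_ms=float(row["latency_asym_ms"]),
                velocity_asym_degps=_opt(row["velocity_asym_degps"]),
                delta_det_asym_pct=float(row["delta_det_asym_pct"]),
                scotoma_area_deg2=float(row["scotoma_area_deg2"]),
                overlap_pct=float(row["overlap_pct"]),
                center_dist_deg=float(row["center_dist_deg"]),
                scotoma_center=(float(row["scotoma_x_deg"]),
                                float(row["scotoma_y_deg"])),
                injection_ul=float(row["injection_ul"]),
                significant_deficit=None if sig is None else int(sig),
            ))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"sessions row {i} ({sid}): {exc}") from exc
    return out


def _read_attention(df: pd.DataFrame) -> List[AttentionTrial]:
    _require_columns(df, ATTENTION_COLUMNS, "attention-trials table")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(AttentionTrial(
                session_id=str(row["session_id"]),
                epoch=Epoch(row["epoch"]),
                change_side=ChangeSide(row["change_side"]),
                change_magnitude_deg=float(row["change_magnitude_deg"]),
                delay_s=float(row["delay_s"]),
                responded=bool(row["responded"]),
                reaction_time_s=_opt(row["reaction_time_s"]),
                valid=bool(row["valid"]),
            ))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"attention-trials row {i}: {exc}") from exc
    return out


def _read_saccades(df: pd.DataFrame) -> List[SaccadeRecord]:
    _require_columns(df, SACCADE_COLUMNS, "saccades table")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(SaccadeRecord(
                session_id=str(row["session_id"]),
                epoch=Epoch(row["epoch"]),
                target=(float(row["target_x_deg"]), float(row["target_y_deg"])),
                endpoint=(float(row["endpoint_x_deg"]),
                          float(row["endpoint_y_deg"])),
                latency_ms=float(row["latency_ms"]),
                peak_velocity_degps=float(row["peak_velocity_degps"]),
            ))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"saccades row {i}: {exc}") from exc
    return out


_READERS = {"summary": _read_summary,
            "attention_trials": _read_attention,
            "saccades": _read_saccades}


def read_sessions(path, schema: Schema):
    """Read and validate a delimited file of one of the pipeline's schemas."""
    if schema not in _READERS:
        raise ValueError(f"unknown schema {schema!r}")
    return _READERS[schema](pd.read_csv(path))


def _fmt(value) -> object:
    return "" if value is None else value


def records_to_frame(records) -> pd.DataFrame:
    """Flatten typed records to a DataFrame in canonical column order."""
    if not records:
        raise ValueError("empty record list has no schema; use write_sessions")
    first = records[0]
    if isinstance(first, SessionSummary):
        rows = [{
            "session_id": r.session_id, "structure": r.structure.value,
            "subject": r.subject,
            "hit_in_before": _fmt(r.hit_in_before),
            "hit_out_before": _fmt(r.hit_out_before),
            "hit_in_during": _fmt(r.hit_in_during),
            "hit_out_during": _fmt(r.hit_out_during),
            "latency_asym_ms": r.latency_asym_ms,
            "velocity_asym_degps": _fmt(r.velocity_asym_degps),
            "delta_det_asym_pct": r.delta_det_asym_pct,
            "scotoma_area_deg2": r.scotoma_area_deg2,
            "overlap_pct": r.overlap_pct,
            "center_dist_deg": r.center_dist_deg,
            "scotoma_x_deg": r.scotoma_center[0],
            "scotoma_y_deg": r.scotoma_center[1],
            "injection_ul": r.injection_ul,
            "significant_deficit": _fmt(r.significant_deficit),
        } for r in records]
        return pd.DataFrame(rows, columns=SESSION_COLUMNS)
    if isinstance(first, AttentionTrial):
        rows = [{
            "session_id": r.session_id, "epoch": r.epoch.value,
            "change_side": r.change_side.value,
            "change_magnitude_deg": r.change_magnitude_deg,
            "delay_s": r.delay_s, "responded": r.responded,
            "reaction_time_s": _fmt(r.reaction_time_s), "valid": r.valid,
        } for r in records]
        return pd.DataFrame(rows, columns=ATTENTION_COLUMNS)
    if isinstance(first, SaccadeRecord):
        rows = [{
            "session_id": r.session_id, "epoch": r.epoch.value,
            "target_x_deg": r.target[0], "target_y_deg": r.target[1],
            "endpoint_x_deg": r.endpoint[0], "endpoint_y_deg": r.endpoint[1],
            "latency_ms": r.latency_ms,
            "peak_velocity_degps": r.peak_velocity_degps,
        } for r in records]
        return pd.DataFrame(rows, columns=SACCADE_COLUMNS)
    raise TypeError(f"unsupported record type {type(first).__name__}")


def write_sessions(records, path, schema: Schema | None = None) -> None:
    """Write typed records as CSV, re-readable by :func:`read_sessions`.

    An empty record list needs an explicit ``schema`` so the header can be
    emitted.
    """
    if not records:
        if schema is None:
            raise ValueError("schema required to write an empty table")
        cols = {"summary": SESSION_COLUMNS,
                "attention_trials": ATTENTION_COLUMNS,
                "saccades": SACCADE_COLUMNS}[schema]
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return
    records_to_frame(records).to_csv(path, index=False, float_format="%.12g")
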