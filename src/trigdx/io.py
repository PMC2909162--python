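"""Reading and writing subject-record tables.

Subject tables are plain CSV (or JSON records) with one row per subject:

    subject_id, group, reference_side, reference_side_kind,
    jj_ip_ref, jj_ip_contra, mep_ref, mep_contra [, unit]

Amplitudes are stored in mV; a ``unit`` column of ``uV`` is converted on
load.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .classifier import SubjectRecord

__all__ = ["read_subjects", "write_subjects", "records_to_frame"]

_AMP_COLS = ("jj_ip_ref", "jj_ip_contra", "mep_ref", "mep_contra")
_UV_ALIASES = {"uv", "µv", "μv"}


def _row_to_record(row: pd.Series) -> SubjectRecord:
    scale = 1e-3 if str(row.get("unit", "mV")).lower() in _UV_ALIASES else 1.0
    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        jj_ip_ref=float(row["jj_ip_ref"]) * scale,
        jj_ip_contra=float(row["jj_ip_contra"]) * scale,
        mep_ref=float(row["mep_ref"]) * scale,
        mep_contra=float(row["mep_contra"]) * scale,
        group=row.get("group", "unknown"),
        reference_side=row.get("reference_side", "right"),
        reference_side_kind=row.get("reference_side_kind", "pain_side"),
    )


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    """Read subject records from a CSV or JSON file (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(path.read_text()))
    else:
        frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("subject_id",) + _AMP_COLS
               if c not in frame.columns]
    if missing:
        raise ValueError(f"subject table missing columns: {missing}")
    return [_row_to_record(row) for _, row in frame.iterrows()]


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([{
        "subject_id": r.subject_id,
        "group": r.group,
        "reference_side": r.reference_side,
        "reference_side_kind": r.reference_side_kind,
        "jj_ip_ref": r.jj_ip_ref,
        "jj_ip_contra": r.jj_ip_contra,
        "mep_ref": r.mep_ref,
        "mep_contra": r.mep_contra,
    } for r in records])
    frame["unit"] = "mV"
    return frame


def write_subjects(records: Sequence[SubjectRecord],
                   path: str | Path) -> None:
    """Write subject records as CSV or JSON (by extension), in mV."""
    path = Path(path)
    frame = records_to_frame(records)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"),
                                   indent=1) + "\n")
    else:
        frame.to_csv(path, index=False, float_format="%.17g")
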