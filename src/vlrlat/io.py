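"""Readers and writers for the tabular session format and YAML config.

Two text dialects are supported:

* ``long``: one row per (patient, exam, task, session, ROI) with columns
  ``patient_id, exam_id, task, session, roi, activation``;
* ``wide``: one row per session with columns
  ``patient_id, exam_id, task, session`` followed by the ten ROI columns.

Values are ``L | R | B | none``. Separator is inferred from the extension
(tab for ``.tsv``, comma otherwise). Missing values are errors, never a
silent "none": a defaulted rating would corrupt concordance denominators.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
import yaml

from .model import (
    Activation,
    AnalysisConfig,
    Cohort,
    ROI_ORDER,
    Roi,
    SessionRecord,
    Task,
    ValidationError,
    VlrSet,
)

LONG_COLUMNS = ["patient_id", "exam_id", "task", "session", "roi", "activation"]
WIDE_COLUMNS = ["patient_id", "exam_id", "task", "session"] + [r.value for r in ROI_ORDER]


def _sep_for(path: str | os.PathLike) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _parse_task(token: str) -> Task:
    try:
        return Task(str(token).strip())
    except ValueError:
        raise ValidationError(f"unknown task value: {token!r}") from None


def _parse_roi(token: str) -> Roi:
    try:
        return Roi(str(token).strip())
    except ValueError:
        raise ValidationError(f"unknown ROI value: {token!r}") from None


def _read_frame(path: str | os.PathLike) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty session file: {path}") from None
    if df.empty:
        raise ValidationError(f"session file has no data rows: {path}")
    return df


def read_sessions(path: str | os.PathLike, dialect: str = "wide") -> Cohort:
    """Read a session table into a validated :class:`Cohort`."""
    if dialect not in ("long", "wide"):
        raise ValidationError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")
    df = _read_frame(path)
    expected = LONG_COLUMNS if dialect == "long" else WIDE_COLUMNS
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise ValidationError(
            f"{dialect} file {path} is missing columns: {', '.join(missing_cols)}"
        )

    records: list[SessionRecord] = []
    if dialect == "wide":
        for _, row in df.iterrows():
            activations = {r: Activation.parse(row[r.value]) for r in Roi}
            records.append(
                SessionRecord(
                    patient_id=str(row["patient_id"]),
                    exam_id=str(row["exam_id"]),
                    task=_parse_task(row["task"]),
                    session_index=_parse_int(row["session"], row),
                    activations=activations,
                )
            )
    else:
        keys = ["patient_id", "exam_id", "task", "session"]
        for key, group in df.groupby(keys, sort=False):
            pid, eid, task_s, sess_s = (str(k) for k in key)
            seen: dict[Roi, Activation] = {}
            for _, row in group.iterrows():
                roi = _parse_roi(row["roi"])
                if roi in seen:
                    raise ValidationError(
                        f"duplicate ROI row {roi.value} for session "
                        f"({pid}, {eid}, {task_s}, {sess_s})"
                    )
                seen[roi] = Activation.parse(row["activation"])
            absent = [r.value for r in Roi if r not in seen]
            if absent:
                raise ValidationError(
                    f"session ({pid}, {eid}, {task_s}, {sess_s}) is missing ROI rows: "
                    f"{', '.join(absent)}"
                )
            records.append(
                SessionRecord(
                    patient_id=pid,
                    exam_id=eid,
                    task=_parse_task(task_s),
                    session_index=_parse_int(sess_s, key),
                    activations=seen,
                )
            )
    return Cohort(tuple(records), {"source": str(path), "dialect": dialect})


def _parse_int(token, context) -> int:
    try:
        return int(str(token).strip())
    except ValueError:
        raise ValidationError(f"non-integer session index {token!r} in {context}") from None


def sessions_frame(cohort: Cohort, dialect: str = "wide") -> pd.DataFrame:
    """Render a cohort as a DataFrame in the given dialect (deterministic order)."""
    rows: list[dict] = []
    if dialect == "wide":
        for rec in cohort:
            row = {
                "patient_id": rec.patient_id,
                "exam_id": rec.exam_id,
                "task": rec.task.value,
                "session": rec.session_index,
            }
            row.update({r.value: rec.activations[r].value for r in ROI_ORDER})
            rows.append(row)
        return pd.DataFrame(rows, columns=WIDE_COLUMNS)
    if dialect == "long":
        for rec in cohort:
            for roi in ROI_ORDER:
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "exam_id": rec.exam_id,
                        "task": rec.task.value,
                        "session": rec.session_index,
                        "roi": roi.value,
                        "activation": rec.activations[roi].value,
                    }
                )
        return pd.DataFrame(rows, columns=LONG_COLUMNS)
    raise ValidationError(f"unknown dialect {dialect!r}")


def write_sessions(cohort: Cohort, path: str | os.PathLike, dialect: str = "wide") -> None:
    sessions_frame(cohort, dialect).to_csv(path, sep=_sep_for(path), index=False)


def parse_vlr_member(token: str) -> tuple[Task, Roi]:
    """Parse a ``TASK:ROI`` string into a (Task, Roi) cell."""
    parts = str(token).split(":")
    if len(parts) != 2:
        raise ValidationError(f"VLR member must be 'TASK:ROI', got {token!r}")
    return _parse_task(parts[0]), _parse_roi(parts[1])


def format_vlr_member(cell: tuple[Task, Roi]) -> str:
    return f"{cell[0].value}:{cell[1].value}"


def read_vlr_set(path: str | os.PathLike) -> VlrSet:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "members" not in data:
        raise ValidationError(f"VLR set file {path} must map 'name' and 'members'")
    members = frozenset(parse_vlr_member(m) for m in data["members"])
    return VlrSet(str(data.get("name", "custom")), members)


def write_vlr_set(vlr: VlrSet, path: str | os.PathLike) -> None:
    data = {
        "name": vlr.name,
        "members": [format_vlr_member(c) for c in vlr.sorted_members()],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_analysis_config(path: str | os.PathLike) -> AnalysisConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} must be a mapping")
    allowed = {"min_vlr_activations", "min_vlr_sessions", "li_inner", "vlr_set", "seed"}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)
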