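"""File formats, schema-validated table reading and run manifests.

All tabular inputs and outputs are plain CSV (UTF-8, dot decimal); configs
are YAML or JSON; reports are JSON.  ``read_table`` validates rows against a
lightweight column schema and collects violations into a rejects report
instead of silently dropping them.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Optional, Sequence

import pandas as pd

__all__ = [
    "ColumnSpec",
    "SchemaError",
    "RejectedRow",
    "read_table",
    "write_scores_csv",
    "assessments_to_frame",
    "write_manifest",
    "weighting_schema",
    "resident_schema",
    "assessment_schema",
]


class SchemaError(ValueError):
    """A required column is missing or the file cannot be parsed."""


@dataclass(frozen=True)
class ColumnSpec:
    """One expected column: a converter plus an optional value check."""

    name: str
    convert: Callable[[str], object] = str
    check: Optional[Callable[[object], bool]] = None
    required: bool = True


@dataclass(frozen=True)
class RejectedRow:
    row_number: int  # 1-based, excluding header
    column: str
    value: object
    reason: str


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_table(
    path: str | Path,
    schema: Sequence[ColumnSpec],
    *,
    autodetect_delimiter: bool = True,
) -> tuple[pd.DataFrame, list[RejectedRow]]:
    """Read and validate a CSV against a column schema.

    Rows violating a converter or check are collected into the rejects list
    (with row number and reason) and excluded from the returned frame; a
    missing required column raises ``SchemaError`` naming it.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    text = path.read_text(encoding="utf-8")
    delim = _sniff_delimiter(text[:4096]) if autodetect_delimiter else ","
    try:
        raw = pd.read_csv(io.StringIO(text), sep=delim, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"cannot parse {path}: {exc}") from exc

    for col in schema:
        if col.required and col.name not in raw.columns:
            raise SchemaError(f"missing required column {col.name!r} in {path}")

    rejects: list[RejectedRow] = []
    rows: list[dict[str, object]] = []
    for i, (_, r) in enumerate(raw.iterrows(), start=1):
        parsed: dict[str, object] = {}
        ok = True
        for col in schema:
            if col.name not in raw.columns:
                continue
            cell = r[col.name]
            try:
                value = col.convert(cell)
            except (ValueError, TypeError):
                rejects.append(RejectedRow(i, col.name, cell, "unparseable value"))
                ok = False
                break
            if col.check is not None and not col.check(value):
                rejects.append(RejectedRow(i, col.name, value, "out of range"))
                ok = False
                break
            parsed[col.name] = value
        if ok:
            for extra in raw.columns:
                if extra not in parsed:
                    parsed[extra] = r[extra]
            rows.append(parsed)
    return pd.DataFrame(rows, columns=list(raw.columns)), rejects


def assessment_schema(item_ids: Sequence[str], items_by_id=None) -> list[ColumnSpec]:
    """Schema for an assessment sheet: area_id plus one column per item."""
    cols = [ColumnSpec("area_id", str, lambda v: bool(v))]
    for item_id in item_ids:
        if items_by_id is not None and item_id in items_by_id:
            it = items_by_id[item_id]
            cols.append(
                ColumnSpec(item_id, float, (lambda it: it.value_in_range)(it))
            )
        else:
            cols.append(ColumnSpec(item_id, float))
    return cols


def weighting_schema() -> list[ColumnSpec]:
    from .thurstone import MAGNITUDES

    return [
        ColumnSpec("respondent_id", str, lambda v: bool(v)),
        ColumnSpec("item_id", str, lambda v: bool(v)),
        ColumnSpec("present", str, lambda v: v in ("yes", "no", ""), required=False),
        ColumnSpec("valence", str, lambda v: v in ("positive", "negative", "")),
        ColumnSpec("magnitude", str, lambda v: v in MAGNITUDES),
    ]


def resident_schema() -> list[ColumnSpec]:
    def _age(v: str) -> float:
        return float("nan") if v == "" else float(v)

    cols = [
        ColumnSpec("respondent_id", str, lambda v: bool(v)),
        ColumnSpec("area_id", str),
        ColumnSpec("age", _age),
    ]
    from .psychometrics import ATTACHMENT_ITEMS, PERCEPTION_ITEMS

    for p in PERCEPTION_ITEMS:
        cols.append(ColumnSpec(p, int, lambda v: 1 <= v <= 6))
    for p in ATTACHMENT_ITEMS:
        cols.append(ColumnSpec(p, int, lambda v: 1 <= v <= 5))
    return cols


def assessments_to_frame(spec, assessments) -> pd.DataFrame:
    """Flatten AreaAssessments (and covariates, if any) to a DataFrame."""
    rows = []
    for a in assessments:
        row: dict[str, object] = {"area_id": a.area_id}
        row.update({i: a.observations[i] for i in spec.item_ids})
        if a.covariates is not None:
            row["deprivation_index"] = a.covariates.deprivation_index
            row["deprivation_quintile"] = a.covariates.deprivation_quintile
            row["settlement_type"] = a.covariates.settlement_type
        rows.append(row)
    return pd.DataFrame(rows)


def write_scores_csv(path: str | Path, frame: pd.DataFrame) -> None:
    """Write a scores table, numbers rounded to 2 decimals for presentation."""
    out = frame.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].round(2)
    out.to_csv(path, index=False)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    command: str,
    inputs: Sequence[str | Path],
    seed: Optional[int] = None,
    extra: Optional[dict] = None,
) -> Path:
    """Write the run manifest (command, input digests, seed, version, time)."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "inputs": {
            str(p): _digest(Path(p)) for p in inputs if Path(p).exists()
        },
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return path
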