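"""Readers and writers for the tabular and geometric formats the pipeline
touches.

Islet tables are CSV/TSV with fixed lower_snake_case columns
(``donor_id, group, islet_id, area_mm2, n_cells, insulin_status, cd3_count,
cd3cd8pos_count, cd3cd8neg_count``); donor tables carry section-level
measurements (``donor_id, group, total_area_mm2, endocrine_area_mm2,
exocrine_cd3, exocrine_cd3cd8pos, exocrine_cd3cd8neg``).  A header-mapping
option tolerates synonym headers from digital-pathology exports.  Islet
boundaries are GeoJSON FeatureCollections of Polygons with an ``islet_id``
property, coordinates in micrometres.

Schema validation collects and reports *all* violations with their row
indices, not just the first.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .metrics import DonorSummary, summaries_frame
from .records import (
    UM2_PER_MM2,
    DonorRecord,
    Group,
    InsulinStatus,
    IsletBoundary,
    IsletRecord,
    ValidationError,
)

__all__ = [
    "SchemaError",
    "ISLET_COLUMNS",
    "DONOR_COLUMNS",
    "read_islet_table",
    "read_donor_table",
    "write_islet_table",
    "write_donor_table",
    "read_boundaries",
    "write_boundaries",
    "write_summary",
    "read_summary",
]

ISLET_COLUMNS = (
    "donor_id", "group", "islet_id", "area_mm2", "n_cells",
    "insulin_status", "cd3_count", "cd3cd8pos_count", "cd3cd8neg_count",
)
DONOR_COLUMNS = (
    "donor_id", "group", "total_area_mm2", "endocrine_area_mm2",
    "exocrine_cd3", "exocrine_cd3cd8pos", "exocrine_cd3cd8neg",
)

#: float format preserving round-trips to 17 significant digits
_FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """The file header does not provide the required columns."""


def _read_frame(path, dialect: str | None, header_map: dict[str, str] | None,
                required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    df = pd.read_csv(path, sep="\t" if dialect == "tsv" else ",")
    if header_map:
        df = df.rename(columns={k: v for k, v in header_map.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    return df


def read_islet_table(
    path,
    dialect: str | None = None,
    header_map: dict[str, str] | None = None,
    donor_table=None,
) -> list[DonorRecord]:
    """Read a per-islet table into donor records.

    Rows are grouped by ``donor_id`` (row order preserved within donor).
    When ``donor_table`` (a path) is given, section-level and exocrine
    measurements are merged in; otherwise they are left unset (NaN areas).
    Invariant violations are raised together as one :class:`ValidationError`
    listing every offending row index.
    """
    df = _read_frame(path, dialect, header_map, ISLET_COLUMNS)
    donors: dict[str, DonorRecord] = {}
    errors: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        did = str(row.donor_id)
        if did not in donors:
            try:
                group = Group(str(row.group))
            except ValueError:
                errors.append(f"row {idx}: unknown group {row.group!r}")
                continue
            donors[did] = DonorRecord(donor_id=did, group=group)
        status = str(row.insulin_status) if not _isna(row.insulin_status) else "UNKNOWN"
        try:
            islet = IsletRecord(
                donor_id=did,
                islet_id=str(row.islet_id),
                area_mm2=float(row.area_mm2),
                n_cells=int(row.n_cells),
                insulin_status=InsulinStatus(status),
                cd3_count=int(row.cd3_count),
                cd3cd8pos_count=int(row.cd3cd8pos_count),
                cd3cd8neg_count=int(row.cd3cd8neg_count),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {idx}: {exc}")
            continue
        errors.extend(f"row {idx}: {v}" for v in islet.violations())
        donors[did].islets.append(islet)
    if errors:
        raise ValidationError(errors)
    records = list(donors.values())
    if donor_table is not None:
        section = {d.donor_id: d for d in read_donor_table(donor_table, dialect, header_map)}
        for rec in records:
            src = section.get(rec.donor_id)
            if src is None:
                continue
            rec.total_area_mm2 = src.total_area_mm2
            rec.endocrine_area_mm2 = src.endocrine_area_mm2
            rec.exocrine_cd3 = src.exocrine_cd3
            rec.exocrine_cd3cd8pos = src.exocrine_cd3cd8pos
            rec.exocrine_cd3cd8neg = src.exocrine_cd3cd8neg
            rec.metadata.update(src.metadata)
        verrs = [e for rec in records for e in rec.violations()]
        if verrs:
            raise ValidationError(verrs)
    return records


def _isna(v) -> bool:
    try:
        return v is None or (isinstance(v, float) and math.isnan(v))
    except TypeError:  # pragma: no cover
        return False


def read_donor_table(
    path, dialect: str | None = None, header_map: dict[str, str] | None = None
) -> list[DonorRecord]:
    """Read a per-donor section table (no islets attached)."""
    df = _read_frame(path, dialect, header_map, DONOR_COLUMNS)
    extra = [c for c in df.columns if c not in DONOR_COLUMNS]
    records, errors = [], []
    for idx, row in df.iterrows():
        try:
            rec = DonorRecord(
                donor_id=str(row["donor_id"]),
                group=Group(str(row["group"])),
                total_area_mm2=float(row["total_area_mm2"]),
                endocrine_area_mm2=float(row["endocrine_area_mm2"]),
                exocrine_cd3=int(row["exocrine_cd3"]),
                exocrine_cd3cd8pos=int(row["exocrine_cd3cd8pos"]),
                exocrine_cd3cd8neg=int(row["exocrine_cd3cd8neg"]),
                metadata={c: row[c] for c in extra if not pd.isna(row[c])},
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {idx}: {exc}")
            continue
        errors.extend(f"row {idx}: {v}" for v in rec.violations())
        records.append(rec)
    if errors:
        raise ValidationError(errors)
    return records


def write_islet_table(donors: list[DonorRecord], path, dialect: str | None = None) -> None:
    """Write donor islets as a per-islet CSV/TSV (round-trips with
    :func:`read_islet_table`)."""
    rows = [
        {
            "donor_id": d.donor_id,
            "group": d.group.value,
            "islet_id": i.islet_id,
            "area_mm2": i.area_mm2,
            "n_cells": i.n_cells,
            "insulin_status": i.insulin_status.value,
            "cd3_count": i.cd3_count,
            "cd3cd8pos_count": i.cd3cd8pos_count,
            "cd3cd8neg_count": i.cd3cd8neg_count,
        }
        for d in donors
        for i in d.islets
    ]
    df = pd.DataFrame(rows, columns=list(ISLET_COLUMNS))
    sep = "\t" if (dialect == "tsv" or str(path).endswith((".tsv", ".tab"))) else ","
    df.to_csv(path, index=False, sep=sep, float_format=_FLOAT_FMT)


def write_donor_table(donors: list[DonorRecord], path, dialect: str | None = None) -> None:
    """Write section-level donor measurements as CSV/TSV."""
    rows = [
        {
            "donor_id": d.donor_id,
            "group": d.group.value,
            "total_area_mm2": d.total_area_mm2,
            "endocrine_area_mm2": d.endocrine_area_mm2,
            "exocrine_cd3": d.exocrine_cd3,
            "exocrine_cd3cd8pos": d.exocrine_cd3cd8pos,
            "exocrine_cd3cd8neg": d.exocrine_cd3cd8neg,
        }
        for d in donors
    ]
    df = pd.DataFrame(rows, columns=list(DONOR_COLUMNS))
    sep = "\t" if (dialect == "tsv" or str(path).endswith((".tsv", ".tab"))) else ","
    df.to_csv(path, index=False, sep=sep, float_format=_FLOAT_FMT)


def read_cell_table(path, dialect: str | None = None,
                    header_map: dict[str, str] | None = None) -> list:
    """Read spatial-mode cell detections (columns x_um, y_um, is_cd3, is_cd8)."""
    from .records import CellDetection

    df = _read_frame(path, dialect, header_map, ("x_um", "y_um", "is_cd3", "is_cd8"))
    cells = [
        CellDetection(
            x_um=float(r.x_um), y_um=float(r.y_um),
            is_cd3=bool(r.is_cd3), is_cd8=bool(r.is_cd8),
        )
        for r in df.itertuples(index=False)
    ]
    errors = [e for c in cells for e in c.violations()]
    if errors:
        raise ValidationError(errors)
    return cells


# --------------------------------------------------------------------------
# GeoJSON boundaries


def read_boundaries(path) -> list[IsletBoundary]:
    """Read islet boundary polygons from a GeoJSON FeatureCollection.

    Features must be Polygons with an ``islet_id`` property (optional
    ``insulin_status``); coordinates are micrometres.  Boundaries are
    returned in file order with coordinates preserved.
    """
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    out, errors = [], []
    for k, feat in enumerate(data.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise ValueError(
                f"{path}: feature {k} has geometry type "
                f"{geom.get('type')!r}; only Polygon is supported"
            )
        props = feat.get("properties") or {}
        islet_id = props.get("islet_id", f"islet-{k}")
        status = InsulinStatus(props.get("insulin_status", "UNKNOWN"))
        ring = [tuple(map(float, xy)) for xy in geom["coordinates"][0]]
        b = IsletBoundary(islet_id=str(islet_id), ring_um=ring, insulin_status=status)
        errors.extend(b.violations())
        out.append(b)
    if errors:
        raise ValidationError(errors)
    return out


def write_boundaries(boundaries: list[IsletBoundary], path) -> None:
    """Write boundaries as a GeoJSON FeatureCollection (round-trips)."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [[list(xy) for xy in b.ring_um]]},
            "properties": {"islet_id": b.islet_id,
                           "insulin_status": b.insulin_status.value},
        }
        for b in boundaries
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh,
                  sort_keys=True)


# --------------------------------------------------------------------------
# summary reports


def write_summary(summaries: list[DonorSummary], path) -> dict[str, Path]:
    """Write per-donor summaries as machine JSON + CSV reports.

    ``path`` is a stem: ``<stem>.json`` holds full-precision values plus a
    4-decimal ``display`` block per donor, with deterministic key ordering;
    ``<stem>.csv`` is the tidy per-donor table.  Returns the paths written.
    """
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")

    df = summaries_frame(summaries)
    if df.empty:
        df = pd.DataFrame(columns=["donor_id", "group"])
    df.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)

    payload = []
    for s in summaries:
        flat = s.flat()
        payload.append({
            "donor_id": s.donor_id,
            "group": s.group.value,
            "metrics": {k: _jsonable(v) for k, v in sorted(flat.items())},
            "display": {k: _rounded(v) for k, v in sorted(flat.items())},
        })
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return {"csv": csv_path, "json": json_path}


def _jsonable(v):
    if isinstance(v, float) and math.isnan(v):
        return None
    return v


def _rounded(v):
    if isinstance(v, float):
        return None if math.isnan(v) else round(v, 4)
    return v


def read_summary(path) -> pd.DataFrame:
    """Read back the CSV half of :func:`write_summary`."""
    return pd.read_csv(Path(path).with_suffix(".csv"))
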