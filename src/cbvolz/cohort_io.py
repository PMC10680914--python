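"""Reading, validation, and filtering of subject-level cohort tables.

The canonical in-memory container is :class:`CohortTable`: a pandas
DataFrame with fixed metadata columns (``subject_id``, ``group``, ``age``,
``sex``, ``duration``, ``sara``, ``etiv``) plus one raw-volume column (mm^3)
per cerebellar region, optionally split as ``<region>_left`` /
``<region>_right`` until :func:`combine_hemispheres` is applied.  One group
label is flagged as the healthy-control reference; only the reference group
is allowed (and required) to have missing ataxia duration and SARA score.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError, ValidationError
from .regions import BASE_REGIONS, HEMISPHERIC_REGIONS

METADATA_COLUMNS = ("subject_id", "group", "age", "sex", "duration", "sara", "etiv")

#: strings treated as missing in input cells
DEFAULT_NA_VALUES = ("", "n.a.", "na", "NA", "NaN", "nan", "n/a", "N/A")

SARA_MAX = 40.0  # scale maximum of the SARA sum score


@dataclass
class ColumnMap:
    """Mapping from input-file column names to the canonical schema.

    ``regions`` maps a canonical region name either to a single column name
    (already-combined volume) or to ``{"left": col, "right": col}`` for
    hemispheric volumes delivered per side.
    """

    subject_id: str = "subject_id"
    group: str = "group"
    reference_group: str = "HC"
    age: str = "age"
    sex: str | None = "sex"
    duration: str | None = "duration"
    sara: str | None = "sara"
    etiv: str = "etiv"
    regions: dict[str, Any] = field(
        default_factory=lambda: {r: r for r in BASE_REGIONS}
    )
    na_values: tuple[str, ...] = DEFAULT_NA_VALUES

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ColumnMap":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known - {"id"}
        if unknown:
            raise SchemaError(f"unknown column-mapping keys: {sorted(unknown)}")
        d = dict(d)
        if "id" in d:  # accepted alias
            d["subject_id"] = d.pop("id")
        if "na_values" in d:
            d["na_values"] = tuple(d["na_values"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CohortTable:
    """Validated subject-level table plus its provenance log."""

    data: pd.DataFrame
    region_schema: list[str]
    reference_group: str
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = self.data["subject_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate subject_id values: {dupes}")

    @property
    def n(self) -> int:
        return len(self.data)

    def is_reference(self) -> pd.Series:
        return self.data["group"] == self.reference_group

    def reference(self) -> pd.DataFrame:
        return self.data[self.is_reference()]

    def patients(self) -> pd.DataFrame:
        return self.data[~self.is_reference()]

    def disease_groups(self) -> list[str]:
        return [g for g in self.data["group"].unique() if g != self.reference_group]

    def with_data(self, data: pd.DataFrame, note: dict | None = None) -> "CohortTable":
        prov = list(self.provenance) + ([note] if note else [])
        return CohortTable(
            data=data,
            region_schema=list(self.region_schema),
            reference_group=self.reference_group,
            provenance=prov,
        )


def _region_columns(colmap: ColumnMap) -> dict[str, str]:
    """Flatten the region mapping to canonical-column -> source-column."""
    out: dict[str, str] = {}
    for region, spec in colmap.regions.items():
        if isinstance(spec, Mapping):
            missing = {"left", "right"} - set(spec)
            if missing:
                raise SchemaError(
                    f"region '{region}': hemispheric mapping needs both sides, "
                    f"missing {sorted(missing)}"
                )
            out[f"{region}_left"] = spec["left"]
            out[f"{region}_right"] = spec["right"]
        else:
            out[region] = spec
    return out


def read_cohort(path: str | Path, colmap: ColumnMap | None = None) -> CohortTable:
    """Read a CSV/TSV cohort table, map columns, and validate rows.

    Rows violating hard invariants (non-positive age/eTIV/volume, volume
    >= eTIV, SARA outside [0, 40], unparsable numeric cells, clinical scores
    on reference subjects) are rejected with row-indexed diagnostics kept in
    the provenance log.  Missing optional fields are preserved as NaN.

    Raises
    ------
    SchemaError
        if a mandatory mapped column is absent from the header.
    ValidationError
        on duplicate subject ids.
    """
    colmap = colmap or ColumnMap()
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    region_cols = _region_columns(colmap)
    mandatory = {
        "subject_id": colmap.subject_id,
        "group": colmap.group,
        "age": colmap.age,
        "etiv": colmap.etiv,
        **region_cols,
    }
    for canonical, source in mandatory.items():
        if source not in raw.columns:
            raise SchemaError(
                f"mandatory column '{source}' (-> {canonical}) not in header"
            )

    optional = {"sex": colmap.sex, "duration": colmap.duration, "sara": colmap.sara}
    notes: list[str] = []

    df = pd.DataFrame(index=raw.index)
    df["subject_id"] = raw[colmap.subject_id].str.strip()
    df["group"] = raw[colmap.group].str.strip()
    for canonical, source in optional.items():
        if source is not None and source in raw.columns:
            df[canonical] = raw[source].str.strip()
        else:
            df[canonical] = np.nan
            notes.append(f"optional column '{canonical}' absent; filled as missing")

    numeric_cols = ["age", "duration", "sara", "etiv"] + list(region_cols)
    df["age"] = raw[colmap.age]
    df["etiv"] = raw[colmap.etiv]
    for canonical, source in region_cols.items():
        df[canonical] = raw[source]

    rejected: list[dict] = []

    def reject(idx: int, reason: str) -> None:
        rejected.append({"row": int(idx) + 2, "reason": reason})  # 1-based + header

    na = set(colmap.na_values)

    def parse_cell(v: str) -> float:
        # float() is correctly rounded, so full-precision CSV round-trips
        try:
            return float(v)
        except ValueError:
            return np.inf  # sentinel; infinities are not legal inputs

    for col in numeric_cols:
        if col not in df.columns:
            continue
        s = df[col].astype(str).str.strip()
        is_na = s.isin(na)
        parsed = s.where(~is_na).map(lambda v: np.nan if pd.isna(v) else parse_cell(v))
        parsed = parsed.astype(float)
        bad = np.isinf(parsed)
        for idx in df.index[bad]:
            reject(idx, f"unparsable numeric cell in '{col}': {s[idx]!r}")
        df[col] = parsed.where(~bad)

    ref = df["group"] == colmap.reference_group
    checks = [
        (~(df["age"] > 0), "age_at_scan must be > 0"),
        (~(df["etiv"] > 0), "etiv must be > 0"),
        (df["sara"].notna() & ~df["sara"].between(0, SARA_MAX), f"sara outside [0, {SARA_MAX:g}]"),
        (df["duration"].notna() & (df["duration"] < 0), "negative ataxia duration"),
        (ref & (df["sara"].notna() | df["duration"].notna()),
         "reference subject carries SARA/duration"),
    ]
    for col in region_cols:
        checks.append((df[col].notna() & ~(df[col] > 0), f"volume '{col}' must be > 0"))
        checks.append((df[col].notna() & (df[col] >= df["etiv"]), f"volume '{col}' >= etiv"))
    for mask, reason in checks:
        mask = mask.fillna(False) if mask.dtype != bool else mask
        for idx in df.index[mask]:
            reject(idx, reason)

    bad_rows = sorted({r["row"] - 2 for r in rejected})
    clean = df.drop(index=bad_rows).reset_index(drop=True)

    region_schema = list(colmap.regions)
    provenance = [
        {
            "stage": "read_cohort",
            "source": str(path),
            "n_read": int(len(raw)),
            "n_kept": int(len(clean)),
            "rejected": rejected,
            "notes": notes,
        }
    ]
    return CohortTable(
        data=clean,
        region_schema=region_schema,
        reference_group=colmap.reference_group,
        provenance=provenance,
    )


def apply_inclusion_filters(
    cohort: CohortTable,
    min_sara: float = 3.0,
    max_duration: float | None = None,
) -> CohortTable:
    """Apply the clinical inclusion rules to non-reference subjects.

    Patients with SARA sum score below ``min_sara`` (the clinical ataxia
    cut-off, default 3) are removed; if ``max_duration`` is given, patients
    with longer reported ataxia duration are removed as outliers.  Reference
    subjects are never touched.  Idempotent.
    """
    if min_sara < 0 or (max_duration is not None and max_duration < 0):
        raise ValueError("filter thresholds must be non-negative")
    df = cohort.data
    ref = cohort.is_reference()
    drop_sara = ~ref & df["sara"].notna() & (df["sara"] < min_sara)
    drop_dur = pd.Series(False, index=df.index)
    if max_duration is not None:
        drop_dur = ~ref & df["duration"].notna() & (df["duration"] > max_duration)
    kept = df[~(drop_sara | drop_dur)].reset_index(drop=True)
    note = {
        "stage": "apply_inclusion_filters",
        "min_sara": min_sara,
        "max_duration": max_duration,
        "removed_sara": int(drop_sara.sum()),
        "removed_duration": int(drop_dur.sum()),
        "n_kept": int(len(kept)),
        "empty_result": bool(len(kept) == 0),
    }
    return cohort.with_data(kept, note)


def combine_hemispheres(cohort: CohortTable) -> CohortTable:
    """Replace ``<region>_left``/``<region>_right`` columns by their sum.

    Already-combined regions pass through unchanged (idempotent).  A lone
    side raises a :class:`ValidationError` naming the region and side.
    """
    df = cohort.data.copy()
    combined = 0
    for region in cohort.region_schema:
        left, right = f"{region}_left", f"{region}_right"
        has_l, has_r = left in df.columns, right in df.columns
        if has_l != has_r:
            side = "right" if has_l else "left"
            raise ValidationError(f"region '{region}/{side}' column missing")
        if has_l and region in df.columns:
            raise ValidationError(
                f"region '{region}': both combined and per-side columns present"
            )
        if has_l:
            df[region] = df[left] + df[right]
            df = df.drop(columns=[left, right])
            combined += 1
    note = {"stage": "combine_hemispheres", "regions_combined": combined}
    out = cohort.with_data(df, note)
    # keep region columns in schema order after metadata
    cols = [c for c in df.columns if c in METADATA_COLUMNS]
    cols += [r for r in out.region_schema if r in df.columns]
    out.data = df[cols]
    return out


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the canonical table as CSV at full numeric precision."""
    cohort.data.to_csv(path, index=False)


def write_provenance(cohort: CohortTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(cohort.provenance, fh, indent=2)
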