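"""Head-size normalization and grey-matter aggregation.

Normalized volumes are the dimensionless ratio raw volume / eTIV (the ratio
method of head-size correction).  The aggregate cerebellar grey matter (cGM)
is the exact sum of the four hemispheric lobes plus the vermis, computed on
normalized volumes; by linearity of the ratio this equals the normalized sum
of the raw constituents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort_io import CohortTable, METADATA_COLUMNS
from .exceptions import SchemaError
from .regions import CGM, GM_REGIONS


@dataclass
class NormalizedVolumeTable:
    """Per-subject normalized (raw/eTIV) regional volumes with metadata."""

    data: pd.DataFrame
    region_schema: list[str]
    reference_group: str
    provenance: list[dict] = field(default_factory=list)

    def is_reference(self) -> pd.Series:
        return self.data["group"] == self.reference_group

    def disease_groups(self) -> list[str]:
        return [g for g in self.data["group"].unique() if g != self.reference_group]


def normalize_by_etiv(cohort: CohortTable) -> NormalizedVolumeTable:
    """Divide every raw regional volume by the subject's eTIV."""
    missing = [r for r in cohort.region_schema if r not in cohort.data.columns]
    if missing:
        raise SchemaError(
            f"regions not combined/present before normalization: {missing}"
        )
    df = cohort.data.copy()
    for region in cohort.region_schema:
        df[region] = df[region] / df["etiv"]
    note = {"stage": "normalize_by_etiv", "n": int(len(df))}
    return NormalizedVolumeTable(
        data=df,
        region_schema=list(cohort.region_schema),
        reference_group=cohort.reference_group,
        provenance=list(cohort.provenance) + [note],
    )


def aggregate_cgm(table: NormalizedVolumeTable) -> NormalizedVolumeTable:
    """Add the cGM column as the exact sum of the five grey-matter regions.

    A subject missing any constituent gets a missing cGM; a constituent
    column absent from the table altogether is a schema error naming it.
    """
    for region in GM_REGIONS:
        if region not in table.data.columns:
            raise SchemaError(f"cGM constituent region '{region}' missing")
    df = table.data.copy()
    df[CGM] = df[list(GM_REGIONS)].sum(axis=1, skipna=False)
    schema = list(table.region_schema)
    if CGM not in schema:
        schema.append(CGM)
    note = {"stage": "aggregate_cgm", "constituents": list(GM_REGIONS)}
    return NormalizedVolumeTable(
        data=df,
        region_schema=schema,
        reference_group=table.reference_group,
        provenance=list(table.provenance) + [note],
    )


def write_normalized(table: NormalizedVolumeTable, path) -> None:
    cols = [c for c in table.data.columns if c in METADATA_COLUMNS]
    cols += [r for r in table.region_schema if r in table.data.columns]
    table.data[cols].to_csv(path, index=False)
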