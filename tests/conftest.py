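from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cbvolz import (
    GeneratorConfig,
    aggregate_cgm,
    fit_all_normative,
    generate_cohort,
    normalize_by_etiv,
    z_transform,
)

HEADER = (
    "subject_id,group,age,sex,duration,sara,etiv,"
    "anterior,superior_posterior,inferior_posterior,flocculonodular,vermis,cwm"
)

WELL_FORMED_ROWS = [
    "s1,HC,60.0,F,,,1500000,12000,45000,30000,2500,9500,25000",
    "s2,HC,72.5,M,,,1600000,12500,46000,31000,2600,9700,26000",
    "s3,SCA3,50.0,F,10.0,12.0,1450000,11000,40000,28000,2300,8800,20000",
    "s4,SCA6,64.0,M,7.5,13.0,1550000,10000,38000,27000,2200,8500,24000",
    "s5,MSA-C,66.0,F,4.0,17.0,1500000,9000,36000,26000,2100,8000,18000",
]


@pytest.fixture
def well_formed_csv(tmp_path: Path) -> Path:
    p = tmp_path / "cohort.csv"
    p.write_text("\n".join([HEADER, *WELL_FORMED_ROWS]) + "\n")
    return p


@pytest.fixture
def make_csv(tmp_path: Path):
    def _make(rows, header=HEADER, name="table.csv"):
        p = tmp_path / name
        p.write_text("\n".join([header, *rows]) + "\n")
        return p

    return _make


@pytest.fixture(scope="session")
def default_cohort():
    cohort, truth = generate_cohort(GeneratorConfig(seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def ztable(default_cohort):
    cohort, _ = default_cohort
    normalized = aggregate_cgm(normalize_by_etiv(cohort))
    models = fit_all_normative(normalized)
    return z_transform(normalized, models)


def cohort_from_frame(df: pd.DataFrame, regions, reference="HC"):
    from cbvolz.cohort_io import CohortTable

    return CohortTable(
        data=df.reset_index(drop=True),
        region_schema=list(regions),
        reference_group=reference,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
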