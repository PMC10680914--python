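"""Normative age models and z-transformation.

For each region an ordinary-least-squares model of normalized volume on age
is fitted on the healthy-control (reference) group; every subject's z-score
is then

    z = (observed - predicted(age)) / residual_sd

so that z = 0 is the expected mean in controls of the same age and z = -1 is
one residual standard deviation below it.  The residual sd uses denominator
n - p (p = number of coefficients), i.e. the square root of the usual
unbiased residual variance.  The default model is linear in age; constant
and quadratic forms are available to bracket alternatives.  Sex is not a
covariate by default but can be added as a binary term via ``sex_term``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import FitError, InsufficientDataError
from .volume_prep import NormalizedVolumeTable

MODEL_FORMS = {"constant": 0, "linear": 1, "quadratic": 2}


def _age_design(age: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(np.asarray(age, dtype=float), degree + 1, increasing=True)


@dataclass
class NormativeModel:
    """Per-region reference model: age polynomial + homoscedastic residual sd."""

    region: str
    model_form: str
    coefficients: np.ndarray  # ascending powers of age
    residual_sd: float
    n_reference: int
    age_range: tuple[float, float]
    sex_levels: tuple[str, ...] = ()  # non-empty iff a sex term was fitted
    sex_coef: float = 0.0

    def predict(self, age, sex=None) -> np.ndarray:
        degree = MODEL_FORMS[self.model_form]
        age = np.atleast_1d(np.asarray(age, dtype=float))
        mu = _age_design(age, degree) @ self.coefficients
        if self.sex_levels:
            ind = (np.atleast_1d(sex) == self.sex_levels[1]).astype(float)
            mu = mu + self.sex_coef * ind
        return mu

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "model_form": self.model_form,
            "coefficients": list(map(float, self.coefficients)),
            "residual_sd": float(self.residual_sd),
            "n_reference": int(self.n_reference),
            "age_range": [float(self.age_range[0]), float(self.age_range[1])],
            "sex_levels": list(self.sex_levels),
            "sex_coef": float(self.sex_coef),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModel":
        return cls(
            region=d["region"],
            model_form=d["model_form"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            residual_sd=float(d["residual_sd"]),
            n_reference=int(d["n_reference"]),
            age_range=(d["age_range"][0], d["age_range"][1]),
            sex_levels=tuple(d.get("sex_levels", ())),
            sex_coef=float(d.get("sex_coef", 0.0)),
        )


@dataclass
class ZScoreTable:
    """Per-subject, per-region age-adjusted z-scores plus metadata.

    ``data`` holds the metadata columns and one z column per region;
    ``extrapolated`` is a parallel boolean frame flagging subjects whose age
    lies outside the reference age range of that region's model.
    """

    data: pd.DataFrame
    extrapolated: pd.DataFrame
    region_schema: list[str]
    reference_group: str
    provenance: list[dict] = field(default_factory=list)

    def is_reference(self) -> pd.Series:
        return self.data["group"] == self.reference_group

    def disease_groups(self) -> list[str]:
        return [g for g in self.data["group"].unique() if g != self.reference_group]


def fit_normative(
    table: NormalizedVolumeTable,
    region: str,
    model_form: str = "linear",
    sex_term: bool = False,
) -> NormativeModel:
    """OLS fit of a region's normalized volume on age in the reference group.

    Requires at least p + 2 reference records with the region value and age
    present; residual variance must be positive.
    """
    if model_form not in MODEL_FORMS:
        raise ValueError(f"model_form must be one of {sorted(MODEL_FORMS)}")
    degree = MODEL_FORMS[model_form]
    ref = table.data[table.is_reference()]
    ref = ref.dropna(subset=[region, "age"])
    sex_levels: tuple[str, ...] = ()
    if sex_term:
        ref = ref.dropna(subset=["sex"])
        levels = tuple(sorted(ref["sex"].unique()))
        if len(levels) != 2:
            raise FitError(f"sex term requires exactly 2 levels, got {levels}")
        sex_levels = levels
    p = degree + 1 + (1 if sex_term else 0)
    n = len(ref)
    if n < p + 2:
        raise InsufficientDataError(
            f"region '{region}': {n} reference records < required {p + 2}"
        )
    age = ref["age"].to_numpy(dtype=float)
    y = ref[region].to_numpy(dtype=float)
    X = _age_design(age, degree)
    if sex_term:
        X = np.column_stack([X, (ref["sex"] == sex_levels[1]).to_numpy(float)])
    if degree > 0 and np.ptp(age) == 0:
        raise FitError(f"region '{region}': zero age variance in reference group")
    res = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(res.ssr / (n - p)))
    if resid_sd <= 0 or not np.isfinite(resid_sd):
        raise FitError(f"region '{region}': zero residual variance")
    coef = np.asarray(res.params[: degree + 1], dtype=float)
    return NormativeModel(
        region=region,
        model_form=model_form,
        coefficients=coef,
        residual_sd=resid_sd,
        n_reference=n,
        age_range=(float(age.min()), float(age.max())),
        sex_levels=sex_levels,
        sex_coef=float(res.params[-1]) if sex_term else 0.0,
    )


def fit_all_normative(
    table: NormalizedVolumeTable, model_form: str = "linear", sex_term: bool = False
) -> dict[str, NormativeModel]:
    return {
        region: fit_normative(table, region, model_form, sex_term)
        for region in table.region_schema
    }


def z_transform(
    table: NormalizedVolumeTable, models: dict[str, NormativeModel]
) -> ZScoreTable:
    """z-score all subjects (including the reference group) per region.

    Ages outside a model's reference age range are flagged, never dropped;
    subjects with missing age get missing z-scores, flagged.
    """
    missing = [r for r in table.region_schema if r not in models]
    if missing:
        raise FitError(f"no normative model for regions: {missing}")
    meta = [c for c in table.data.columns if c not in table.region_schema]
    df = table.data[meta].copy()
    flags = pd.DataFrame(index=table.data.index)
    age = table.data["age"].to_numpy(dtype=float)
    sex = table.data["sex"] if "sex" in table.data.columns else None
    for region in table.region_schema:
        m = models[region]
        mu = m.predict(age, sex)
        df[region] = (table.data[region].to_numpy(dtype=float) - mu) / m.residual_sd
        lo, hi = m.age_range
        out_of_range = (age < lo) | (age > hi) | np.isnan(age)
        flags[region] = out_of_range
    note = {"stage": "z_transform", "regions": list(table.region_schema)}
    return ZScoreTable(
        data=df,
        extrapolated=flags,
        region_schema=list(table.region_schema),
        reference_group=table.reference_group,
        provenance=list(table.provenance) + [note],
    )


def save_models(models: dict[str, NormativeModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({r: m.to_dict() for r, m in models.items()}, fh, indent=2)


def load_models(path: str | Path) -> dict[str, NormativeModel]:
    with open(path) as fh:
        return {r: NormativeModel.from_dict(d) for r, d in json.load(fh).items()}
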