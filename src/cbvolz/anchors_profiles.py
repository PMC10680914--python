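"""Clinical anchor points and per-disease atrophy profiles.

Diseases differ in how long and how severely their patients have been
ataxic, so fitted z-score trajectories are compared at common anchor values
of the covariate: 0 (extrapolation to ataxia onset / absence of ataxia) and
the cohort-derived mean.  The derived anchor is the unweighted mean of the
per-disease group means, rounded to the nearest integer; both raw and
rounded values are retained.  Read-outs below a disease's observed covariate
range (e.g. SARA 0, which every included patient exceeds by the cut-off)
are computed but always flagged as extrapolations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd

from .cohort_io import CohortTable
from .exceptions import FitError, InsufficientDataError
from .regions import ANALYSIS_REGIONS
from .trajectory import COVARIATES, TrajectoryFit


@dataclass
class AnchorDerivation:
    """Cohort-derived anchor: unweighted mean of group means, rounded."""

    covariate: str
    value: int
    raw: float
    group_means: dict[str, float]


@dataclass
class AnchorSet:
    covariate: str
    values: list[float]
    derivation: str = "user"  # or "extrapolation_zero+mean_of_group_means"

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError("anchor values must be finite")


@dataclass
class AnchorReadout:
    z: float
    extrapolated: bool


@dataclass
class AnchorProfile:
    """Radar-plot content: one disease's z-score over the 7 regions at one anchor."""

    disease: str
    covariate: str
    anchor: float
    regions: tuple[str, ...]
    z: list[float]  # NaN for skipped regions (rendered as gaps, never zero)
    extrapolated: list[bool]


def derive_anchor(cohort: CohortTable, covariate: str) -> AnchorDerivation:
    """Unweighted mean of per-disease group means, rounded half-up to integer."""
    if covariate not in COVARIATES:
        raise ValueError(f"covariate must be one of {COVARIATES}")
    pts = cohort.patients().dropna(subset=[covariate])
    if pts.empty:
        raise InsufficientDataError(f"no patients with non-missing {covariate}")
    means = pts.groupby("group")[covariate].mean()
    raw = float(means.mean())
    return AnchorDerivation(
        covariate=covariate,
        value=int(math.floor(raw + 0.5)),
        raw=raw,
        group_means={g: float(v) for g, v in means.items()},
    )


def default_anchor_set(cohort: CohortTable, covariate: str) -> AnchorSet:
    """0 (extrapolation) plus the cohort-derived mean anchor."""
    d = derive_anchor(cohort, covariate)
    return AnchorSet(
        covariate=covariate,
        values=[0.0, float(d.value)],
        derivation="extrapolation_zero+mean_of_group_means",
    )


def readout_at_anchor(fit: TrajectoryFit, anchor: float) -> AnchorReadout:
    """Evaluate a degree-1 trajectory at the anchor covariate value.

    Returns intercept + slope * anchor; the read-out is flagged when the
    anchor lies outside the disease's observed covariate range.
    """
    if fit.degree != 1:
        raise FitError("anchor read-outs are defined on the linear model only")
    lo, hi = fit.x_range
    z = float(fit.coefficients[0] + fit.coefficients[1] * anchor)
    return AnchorReadout(z=z, extrapolated=not (lo <= anchor <= hi))


def assemble_profiles(
    fits: list[TrajectoryFit],
    anchors: AnchorSet,
    regions: tuple[str, ...] = ANALYSIS_REGIONS,
) -> list[AnchorProfile]:
    """One profile per disease per anchor value, axes in fixed region order.

    Regions without a degree-1 fit (skipped groups) appear as missing axes.
    """
    by_key = {
        (f.disease, f.region): f
        for f in fits
        if f.covariate == anchors.covariate and f.degree == 1
    }
    diseases = sorted({d for d, _ in by_key})
    profiles = []
    for disease in diseases:
        for anchor in anchors.values:
            zs: list[float] = []
            flags: list[bool] = []
            for region in regions:
                fit = by_key.get((disease, region))
                if fit is None:
                    zs.append(float("nan"))
                    flags.append(False)
                else:
                    r = readout_at_anchor(fit, anchor)
                    zs.append(r.z)
                    flags.append(r.extrapolated)
            profiles.append(
                AnchorProfile(
                    disease=disease,
                    covariate=anchors.covariate,
                    anchor=float(anchor),
                    regions=tuple(regions),
                    z=zs,
                    extrapolated=flags,
                )
            )
    return profiles


def profiles_to_frame(profiles: list[AnchorProfile]) -> pd.DataFrame:
    """Tidy CSV layout: disease, covariate, anchor, region, z, extrapolated."""
    rows = []
    for p in profiles:
        for region, z, ex in zip(p.regions, p.z, p.extrapolated):
            rows.append(
                {
                    "disease": p.disease,
                    "covariate": p.covariate,
                    "anchor": p.anchor,
                    "region": region,
                    "z": z,
                    "extrapolated": ex,
                }
            )
    return pd.DataFrame(rows)
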