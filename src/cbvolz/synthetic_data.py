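"""Synthetic ataxia cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* healthy-control (HC) normalized volumes decline linearly with age around a
  region-specific norm with homoscedastic Gaussian residuals;
* each patient draws an age, an (ataxia duration, SARA sum score) pair, and
  an eTIV; the subject's true z-deviation in each region is the disease's
  trajectory line evaluated at the driving covariate (duration by default)
  plus Gaussian z-noise; volumes are recovered by inverting the z-definition
  through the TRUE norm and multiplying by eTIV.

Clinical marginals are truncated normals whose TRUNCATED mean and sd equal
the configured targets (the underlying location/scale are solved
numerically), joined by a Gaussian copula with correlation ``rho`` — so
sample moments converge to the configured values even near the truncation
bounds (duration >= 0, SARA in [floor, 40], age >= 18).  Default group
sizes and clinical moments mirror a multicentre cross-sectional ataxia
cohort: 292 HC plus SCA1/SCA3/SCA6/MSA-C groups of 12/62/14/16 patients.

Everything is deterministic under the seed, and every cohort ships with a
:class:`GroundTruth` recording the realized parameters for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .cohort_io import CohortTable
from .exceptions import GenerationError
from .normative import NormativeModel
from .regions import BASE_REGIONS, CGM, GM_REGIONS, HEMISPHERIC_REGIONS
from .trajectory import TrajectoryFit


@dataclass(frozen=True)
class RegionNorm:
    """HC norm for one region: v = intercept + age_slope * age + N(0, resid_sd)."""

    intercept: float  # normalized-volume units at age 0
    age_slope: float  # per year
    resid_sd: float


@dataclass(frozen=True)
class Line:
    intercept: float  # z-units at covariate 0
    slope: float  # z-units per covariate unit


@dataclass
class GroupSpec:
    n: int
    age_mean: float
    age_sd: float
    female_frac: float = 0.5


@dataclass
class DiseaseSpec(GroupSpec):
    duration_mean: float = 7.0
    duration_sd: float = 4.0
    sara_mean: float = 14.0
    sara_sd: float = 5.0


def _default_regions() -> dict[str, RegionNorm]:
    # plausible normalized volumes (bilateral, /eTIV) around age 60 with a
    # mild ageing decline and ~8% residual scatter; illustrative, not cohort
    # estimates
    mean60 = {
        "anterior": 8.0e-3,
        "superior_posterior": 3.00e-2,
        "inferior_posterior": 2.00e-2,
        "flocculonodular": 1.7e-3,
        "vermis": 6.3e-3,
        "cwm": 1.70e-2,
    }
    slope = {
        "anterior": -8e-6,
        "superior_posterior": -3e-5,
        "inferior_posterior": -2e-5,
        "flocculonodular": -1.5e-6,
        "vermis": -6e-6,
        "cwm": -1.2e-5,
    }
    return {
        r: RegionNorm(
            intercept=mean60[r] - 60.0 * slope[r],
            age_slope=slope[r],
            resid_sd=0.08 * mean60[r],
        )
        for r in BASE_REGIONS
    }


def _default_trajectories() -> dict[str, dict[str, dict[str, Line]]]:
    # Illustrative z-unit lines per covariate reproducing the qualitative
    # ordering seen in degenerative ataxias: steepest decline in MSA-C;
    # SCA6 grey-matter-dominant with spared white matter; white-matter
    # involvement in SCA1/SCA3/MSA-C; a few slight non-significant volume
    # increases in SCA1/SCA3.
    gm = list(GM_REGIONS)

    def lines(gm_i, gm_s, wm_i, wm_s, overrides=None):
        out = {r: Line(gm_i, gm_s) for r in gm}
        out["cwm"] = Line(wm_i, wm_s)
        for r, ln in (overrides or {}).items():
            out[r] = ln
        return out

    duration = {
        "SCA1": lines(-1.2, -0.06, -1.5, -0.12,
                      {"anterior": Line(-1.2, 0.02),
                       "superior_posterior": Line(-1.2, 0.01),
                       "flocculonodular": Line(-1.0, 0.02)}),
        "SCA3": lines(-1.0, -0.05, -1.8, -0.10,
                      {"anterior": Line(-1.0, 0.01),
                       "superior_posterior": Line(-1.0, 0.01),
                       "flocculonodular": Line(-0.8, 0.01)}),
        "SCA6": lines(-0.8, -0.20, -0.10, -0.02),
        "MSA-C": lines(-0.5, -0.30, -0.50, -0.35),
    }
    sara = {
        "SCA1": lines(-1.3, -0.03, -1.8, -0.05,
                      {"anterior": Line(-1.3, 0.01),
                       "superior_posterior": Line(-1.3, 0.005)}),
        "SCA3": lines(-1.2, -0.03, -2.0, -0.06,
                      {"flocculonodular": Line(-0.9, 0.01),
                       "vermis": Line(-1.0, 0.01)}),
        "SCA6": lines(-0.5, -0.15, -0.2, 0.01),
        "MSA-C": lines(-0.8, -0.12, -0.9, -0.15),
    }
    return {"duration": duration, "sara": sara}


def _default_diseases() -> dict[str, DiseaseSpec]:
    return {
        "SCA1": DiseaseSpec(12, 45.1, 9.6, 7 / 12, 3.9, 3.3, 12.1, 3.9),
        "SCA3": DiseaseSpec(62, 50.7, 10.6, 25 / 62, 10.8, 6.5, 12.8, 6.2),
        "SCA6": DiseaseSpec(14, 64.2, 8.6, 4 / 14, 7.8, 5.5, 13.3, 4.9),
        "MSA-C": DiseaseSpec(16, 64.5, 8.2, 6 / 16, 4.4, 2.1, 17.2, 5.2),
    }


@dataclass
class GeneratorConfig:
    seed: int = 0
    hc: GroupSpec = field(default_factory=lambda: GroupSpec(292, 63.5, 12.6, 160 / 292))
    diseases: dict[str, DiseaseSpec] = field(default_factory=_default_diseases)
    regions: dict[str, RegionNorm] = field(default_factory=_default_regions)
    trajectories: dict[str, dict[str, dict[str, Line]]] = field(
        default_factory=_default_trajectories
    )
    driving_covariate: str = "duration"
    z_noise_sd: float = 0.8
    etiv_mean: float = 1.55e6
    etiv_sd: float = 1.4e5
    rho: float = 0.5  # duration-SARA copula correlation within patients
    age_min: float = 18.0
    sara_floor: float = 3.0  # set below 3 to inject sub-threshold patients
    sara_max: float = 40.0
    split_hemispheres: bool = False

    def __post_init__(self) -> None:
        if not -1 < self.rho < 1:
            raise GenerationError("rho must lie in (-1, 1)")
        if self.z_noise_sd < 0 or self.etiv_sd <= 0:
            raise GenerationError("noise sds must be positive (z_noise_sd >= 0)")
        if self.driving_covariate not in ("duration", "sara"):
            raise GenerationError("driving_covariate must be 'duration' or 'sara'")


@dataclass
class GroundTruth:
    """Realized generating parameters for one cohort (recovery-test oracle)."""

    seed: int
    driving_covariate: str
    norms: dict[str, RegionNorm]
    trajectories: dict[str, dict[str, Line]]  # disease -> region -> driving line
    z_noise_sd: float
    group_sizes: dict[str, int]

    def true_normative_models(self) -> dict[str, NormativeModel]:
        """The TRUE norms as NormativeModel objects (bypassing estimation).

        Includes the implied cGM norm: constituents sum linearly and their
        independent HC residuals add in quadrature.
        """
        models = {}
        for region, nm in self.norms.items():
            models[region] = NormativeModel(
                region=region,
                model_form="linear",
                coefficients=np.array([nm.intercept, nm.age_slope]),
                residual_sd=nm.resid_sd,
                n_reference=self.group_sizes.get("HC", 0),
                age_range=(0.0, 120.0),
            )
        cgm_i = sum(self.norms[r].intercept for r in GM_REGIONS)
        cgm_s = sum(self.norms[r].age_slope for r in GM_REGIONS)
        cgm_sd = float(np.sqrt(sum(self.norms[r].resid_sd ** 2 for r in GM_REGIONS)))
        models[CGM] = NormativeModel(
            region=CGM,
            model_form="linear",
            coefficients=np.array([cgm_i, cgm_s]),
            residual_sd=cgm_sd,
            n_reference=self.group_sizes.get("HC", 0),
            age_range=(0.0, 120.0),
        )
        return models

    def implied_cgm_line(self, disease: str) -> Line:
        """Trajectory line of the aggregate cGM z-score implied by the
        per-region lines (weights = region residual sds; denominator is the
        quadrature sum, the TRUE cGM residual sd)."""
        sds = np.array([self.norms[r].resid_sd for r in GM_REGIONS])
        a = np.array([self.trajectories[disease][r].intercept for r in GM_REGIONS])
        b = np.array([self.trajectories[disease][r].slope for r in GM_REGIONS])
        denom = float(np.sqrt((sds ** 2).sum()))
        return Line(float(sds @ a / denom), float(sds @ b / denom))

    def to_json(self, path: str | Path) -> None:
        d = {
            "seed": self.seed,
            "driving_covariate": self.driving_covariate,
            "z_noise_sd": self.z_noise_sd,
            "group_sizes": self.group_sizes,
            "norms": {r: dataclasses.asdict(nm) for r, nm in self.norms.items()},
            "trajectories": {
                dis: {r: dataclasses.asdict(ln) for r, ln in regs.items()}
                for dis, regs in self.trajectories.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            seed=d["seed"],
            driving_covariate=d["driving_covariate"],
            norms={r: RegionNorm(**nm) for r, nm in d["norms"].items()},
            trajectories={
                dis: {r: Line(**ln) for r, ln in regs.items()}
                for dis, regs in d["trajectories"].items()
            },
            z_noise_sd=d["z_noise_sd"],
            group_sizes={g: int(n) for g, n in d["group_sizes"].items()},
        )


@lru_cache(maxsize=256)
def _truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Location/scale of a truncated normal whose truncated moments hit
    (mean, sd) on [lo, hi].  Returns (loc, scale, a, b)."""
    if sd == 0:
        if not lo <= mean <= hi:
            raise GenerationError(f"degenerate target {mean} outside [{lo}, {hi}]")
        return mean, 0.0, 0.0, 0.0

    def moments(params):
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = scipy.stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = scipy.optimize.root(moments, x0=[mean, np.log(sd)], method="hybr")
    resid = np.abs(moments(sol.x)).max()
    if not sol.success or resid > 1e-6 * max(sd, 1.0):
        raise GenerationError(
            f"cannot match truncated moments mean={mean}, sd={sd} on [{lo}, {hi}]"
        )
    loc, scale = float(sol.x[0]), float(np.exp(sol.x[1]))
    return loc, scale, (lo - loc) / scale, (hi - loc) / scale


def _sample_truncnorm(rng, n, mean, sd, lo, hi):
    loc, scale, a, b = _truncnorm_params(mean, sd, lo, hi)
    if scale == 0.0:
        return np.full(n, loc)
    u = rng.standard_normal(n)
    return scipy.stats.truncnorm.ppf(scipy.stats.norm.cdf(u), a, b, loc=loc, scale=scale)


def _sample_clinical_pair(rng, spec: DiseaseSpec, cfg: GeneratorConfig):
    """(duration, sara) via Gaussian copula with correlation rho."""
    n = spec.n
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, cfg.rho], [cfg.rho, 1.0]], size=n
    )
    u = scipy.stats.norm.cdf(z)

    def ppf(u_col, mean, sd, lo, hi):
        loc, scale, a, b = _truncnorm_params(mean, sd, lo, hi)
        if scale == 0.0:
            return np.full(n, loc)
        return scipy.stats.truncnorm.ppf(u_col, a, b, loc=loc, scale=scale)

    dur = ppf(u[:, 0], spec.duration_mean, spec.duration_sd, 0.0, np.inf)
    sara = ppf(u[:, 1], spec.sara_mean, spec.sara_sd, cfg.sara_floor, cfg.sara_max)
    return dur, sara


def generate_cohort(config: GeneratorConfig | None = None) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort; deterministic under ``config.seed``."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    regions = list(cfg.regions)
    frames = []

    def volumes(age, dev):
        """dev: per-subject x per-region z-deviation from the age norm."""
        out = {}
        for j, r in enumerate(regions):
            nm = cfg.regions[r]
            out[r] = nm.intercept + nm.age_slope * age + nm.resid_sd * dev[:, j]
        return out

    # healthy controls
    n_hc = cfg.hc.n
    age = _sample_truncnorm(rng, n_hc, cfg.hc.age_mean, cfg.hc.age_sd, cfg.age_min, np.inf)
    dev = rng.standard_normal((n_hc, len(regions)))
    vols = volumes(age, dev)
    etiv = rng.normal(cfg.etiv_mean, cfg.etiv_sd, n_hc)
    sex = np.where(rng.random(n_hc) < cfg.hc.female_frac, "F", "M")
    frames.append(
        pd.DataFrame(
            {
                "subject_id": [f"HC{i:04d}" for i in range(n_hc)],
                "group": "HC",
                "age": age,
                "sex": sex,
                "duration": np.nan,
                "sara": np.nan,
                "etiv": etiv,
                **{r: vols[r] * etiv for r in regions},
            }
        )
    )

    traj = cfg.trajectories[cfg.driving_covariate]
    for disease, spec in cfg.diseases.items():
        if disease not in traj:
            raise GenerationError(f"no trajectory lines configured for '{disease}'")
        n = spec.n
        age = _sample_truncnorm(rng, n, spec.age_mean, spec.age_sd, cfg.age_min, np.inf)
        dur, sara = _sample_clinical_pair(rng, spec, cfg)
        x = dur if cfg.driving_covariate == "duration" else sara
        noise = rng.standard_normal((n, len(regions))) * cfg.z_noise_sd
        dev = np.empty((n, len(regions)))
        for j, r in enumerate(regions):
            ln = traj[disease][r]
            dev[:, j] = ln.intercept + ln.slope * x + noise[:, j]
        vols = volumes(age, dev)
        etiv = rng.normal(cfg.etiv_mean, cfg.etiv_sd, n)
        sex = np.where(rng.random(n) < spec.female_frac, "F", "M")
        tag = disease.replace("-", "")
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{tag}{i:03d}" for i in range(n)],
                    "group": disease,
                    "age": age,
                    "sex": sex,
                    "duration": dur,
                    "sara": sara,
                    "etiv": etiv,
                    **{r: vols[r] * etiv for r in regions},
                }
            )
        )

    df = pd.concat(frames, ignore_index=True)
    if (df[regions] <= 0).any().any():
        raise GenerationError(
            "configuration produced non-positive volumes; reduce slopes or noise"
        )

    if cfg.split_hemispheres:
        for r in HEMISPHERIC_REGIONS:
            if r not in regions:
                continue
            frac = np.clip(rng.normal(0.5, 0.01, len(df)), 0.45, 0.55)
            df[f"{r}_left"] = df[r] * frac
            df[f"{r}_right"] = df[r] * (1 - frac)
            df = df.drop(columns=[r])

    truth = GroundTruth(
        seed=cfg.seed,
        driving_covariate=cfg.driving_covariate,
        norms=dict(cfg.regions),
        trajectories={d: dict(traj[d]) for d in cfg.diseases},
        z_noise_sd=cfg.z_noise_sd,
        group_sizes={"HC": n_hc, **{d: s.n for d, s in cfg.diseases.items()}},
    )
    cohort = CohortTable(
        data=df,
        region_schema=regions,
        reference_group="HC",
        provenance=[{"stage": "generate_cohort", "seed": cfg.seed}],
    )
    return cohort, truth


def recovery_report(
    cohort: CohortTable,
    truth: GroundTruth,
    fits: list[TrajectoryFit],
    level: float = 0.95,
) -> pd.DataFrame:
    """Estimated vs true trajectory parameters with CI-coverage flags.

    Only degree-1 fits against the generator's driving covariate have a
    defined truth; others are ignored.  The cGM truth is the implied line of
    the summed grey-matter regions.
    """
    sizes = cohort.data["group"].value_counts().to_dict()
    for g, n in truth.group_sizes.items():
        if sizes.get(g, 0) != n:
            raise GenerationError(
                f"cohort/truth mismatch: group '{g}' has {sizes.get(g, 0)} rows, "
                f"truth says {n}"
            )
    rows = []
    for f in fits:
        if f.degree != 1 or f.covariate != truth.driving_covariate:
            continue
        if f.disease not in truth.trajectories:
            continue
        if f.region == CGM:
            line = truth.implied_cgm_line(f.disease)
        elif f.region in truth.trajectories[f.disease]:
            line = truth.trajectories[f.disease][f.region]
        else:
            continue
        lo, hi = f.slope_ci(level)
        rows.append(
            {
                "disease": f.disease,
                "region": f.region,
                "covariate": f.covariate,
                "slope_true": line.slope,
                "slope_est": float(f.coefficients[1]),
                "slope_ci_low": lo,
                "slope_ci_high": hi,
                "slope_covered": bool(lo <= line.slope <= hi),
                "intercept_true": line.intercept,
                "intercept_est": float(f.coefficients[0]),
                "n": f.n,
            }
        )
    return pd.DataFrame(rows)
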