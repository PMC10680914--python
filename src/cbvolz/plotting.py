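"""Figure rendering: trajectory scatter sheets and radar atrophy profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .anchors_profiles import AnchorProfile
from .normative import ZScoreTable
from .regions import ANALYSIS_REGIONS
from .trajectory import TrajectoryFit, confidence_band

COVARIATE_LABELS = {"duration": "ataxia duration (years)", "sara": "SARA sum score"}

_DISEASE_COLOURS = ["tab:blue", "tab:red", "tab:olive", "tab:green",
                    "tab:purple", "tab:cyan"]


def _colour_map(diseases: list[str]) -> dict[str, str]:
    return {d: _DISEASE_COLOURS[i % len(_DISEASE_COLOURS)] for i, d in enumerate(sorted(diseases))}


def scatter_sheet(
    z: ZScoreTable,
    fits: list[TrajectoryFit],
    covariate: str,
    path: str | Path,
    level: float = 0.95,
) -> None:
    """One multi-panel sheet per covariate: per-region scatter of z-scores
    with per-disease linear fits, mean-response CI bands, and R^2 / p
    annotations."""
    fits = [f for f in fits if f.covariate == covariate and f.degree == 1]
    regions = [r for r in ANALYSIS_REGIONS if r in z.region_schema]
    diseases = sorted({f.disease for f in fits})
    colours = _colour_map(diseases)
    ncol = 2
    nrow = int(np.ceil(len(regions) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(9, 3 * nrow), squeeze=False)
    by_key = {(f.disease, f.region): f for f in fits}
    pts = z.data[~z.is_reference()]
    for k, region in enumerate(regions):
        ax = axes[k // ncol][k % ncol]
        notes = []
        for disease in diseases:
            sub = pts[pts["group"] == disease].dropna(subset=[region, covariate])
            c = colours[disease]
            ax.scatter(sub[covariate], sub[region], s=12, color=c, alpha=0.7,
                       label=disease if k == 0 else None)
            fit = by_key.get((disease, region))
            if fit is None:
                continue
            grid = np.linspace(fit.x_range[0], fit.x_range[1], 50)
            ax.plot(grid, fit.predict(grid), color=c, lw=1.5)
            if fit.df_resid > 0:
                lo, hi = confidence_band(fit, grid, level)
                ax.fill_between(grid, lo, hi, color="grey", alpha=0.25, lw=0)
            notes.append(
                f"{disease}: $R^2$={fit.r_squared:.2f}, p={fit.slope_p:.3g}"
            )
        ax.set_title(region)
        ax.set_xlabel(COVARIATE_LABELS.get(covariate, covariate))
        ax.set_ylabel("z-score")
        ax.axhline(0, color="k", lw=0.5, ls=":")
        if notes:
            ax.text(0.02, 0.98, "\n".join(notes), transform=ax.transAxes,
                    fontsize=6, va="top")
    for k in range(len(regions), nrow * ncol):
        axes[k // ncol][k % ncol].set_visible(False)
    if diseases:
        axes[0][0].legend(fontsize=7, loc="lower left")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def radar_figure(
    profiles: list[AnchorProfile],
    path: str | Path,
    atrophy_outward: bool = True,
) -> None:
    """Radar plot of one anchor's per-disease z-score profiles.

    All profiles must share covariate, anchor, and region order.  With
    ``atrophy_outward`` (default) the radial axis is the negated z-score so
    a larger polygon means more atrophy; missing axes are left as gaps,
    never drawn as zero.
    """
    if not profiles:
        return
    regions = profiles[0].regions
    assert all(p.regions == regions for p in profiles)
    n = len(regions)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    colours = _colour_map([p.disease for p in profiles])
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(111, polar=True)
    for p in profiles:
        r = np.array(p.z, dtype=float)
        if atrophy_outward:
            r = -r
        theta = np.concatenate([angles, angles[:1]])
        rr = np.concatenate([r, r[:1]])
        ax.plot(theta, rr, color=colours[p.disease], lw=1.5, label=p.disease)
    ax.set_xticks(angles)
    ax.set_xticklabels(regions, fontsize=7)
    direction = "-z (atrophy outward)" if atrophy_outward else "z"
    p0 = profiles[0]
    ax.set_title(
        f"{COVARIATE_LABELS.get(p0.covariate, p0.covariate)} = {p0.anchor:g} "
        f"[radial: {direction}]",
        fontsize=9,
    )
    ax.legend(fontsize=7, loc="upper right", bbox_to_anchor=(1.25, 1.1))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
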