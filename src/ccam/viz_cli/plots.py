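"""Triplot coordinate computation and static rendering.

The testable artifacts are plain-text coordinate tables; images are static
exports of the same coordinates. Group summaries use centroids plus 95%
confidence ellipses from the bivariate-normal chi-square quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import chi2

from ..cca_core import CCAResult

logger = logging.getLogger(__name__)

__all__ = [
    "Ellipse",
    "TriplotLayout",
    "group_centroid_ellipse",
    "angular_assignment",
    "render_triplot",
    "overlay_clinical",
]

FLOAT_FMT = "%.6g"


@dataclass
class Ellipse:
    center: np.ndarray
    semi_axes: np.ndarray  # descending, >= 0
    rotation: float  # radians, orientation of the major axis

    def __post_init__(self) -> None:
        if (self.semi_axes < 0).any():
            raise ValueError("semi-axes must be nonnegative")


@dataclass
class TriplotLayout:
    genes: pd.DataFrame
    samples: pd.DataFrame
    arrows: pd.DataFrame
    centroids: pd.DataFrame
    ellipses: dict[str, Ellipse]
    axis_labels: list[str]
    dims: int


def group_centroid_ellipse(
    points: pd.DataFrame, labels: pd.Series, confidence: float = 0.95
) -> tuple[pd.DataFrame, dict[str, Ellipse]]:
    """Per-group centroid and confidence ellipse of 2-D coordinates.

    The ellipse comes from the eigendecomposition of the group covariance
    scaled by the chi-square(2) quantile at ``confidence``. Groups with
    fewer than 3 points get a centroid only (logged); rank-deficient
    covariances yield a zero semi-axis.
    """
    labels = labels.reindex(points.index)
    scale = chi2.ppf(confidence, df=2)
    centroids, ellipses = {}, {}
    for g in pd.unique(labels.dropna()):
        pts = points[labels == g].to_numpy()[:, :2]
        centre = pts.mean(axis=0)
        centroids[g] = centre
        if len(pts) < 3:
            logger.info("group %r has %d points; centroid only", g, len(pts))
            continue
        cov = np.cov(pts.T)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
        ellipses[g] = Ellipse(
            center=centre,
            semi_axes=np.sqrt(evals * scale),
            rotation=float(np.arctan2(evecs[1, 0], evecs[0, 0])),
        )
    frame = pd.DataFrame(centroids).T
    frame.columns = list(points.columns[:2])
    frame.index.name = "group"
    return frame, ellipses


def angular_assignment(
    sample_scores: pd.DataFrame, arrows: pd.DataFrame
) -> pd.DataFrame:
    """Nearest environment arrow per sample by angular distance.

    Euclidean distance is not meaningful across the sample and environment
    levels; the angle between a sample's position vector and each arrow is.
    Returns per-sample nearest arrow and the angle (radians) to it.
    """
    S = sample_scores.to_numpy()
    A = arrows.to_numpy()
    sn = np.linalg.norm(S, axis=1, keepdims=True)
    an = np.linalg.norm(A, axis=1, keepdims=True)
    if (sn == 0).any() or (an == 0).any():
        raise ValueError("zero-length vector has no direction")
    cos = np.clip((S / sn) @ (A / an).T, -1.0, 1.0)
    angles = np.arccos(cos)
    nearest = angles.argmin(axis=1)
    return pd.DataFrame(
        {
            "nearest_arrow": [arrows.index[j] for j in nearest],
            "angle": angles[np.arange(len(S)), nearest],
        },
        index=sample_scores.index.rename("sample_id"),
    )


def _layout(res: CCAResult, groups: pd.Series | None, dims: int) -> TriplotLayout:
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    if dims > res.n_axes:
        raise ValueError(f"requested {dims} dims but only {res.n_axes} positive axes")
    axes = [f"Axis{k + 1}" for k in range(dims)]
    samples = res.sample_scores[axes]
    genes = res.gene_scores_wa[axes]
    arrows = res.env_biplot[axes]
    if groups is not None:
        centroids, ellipses = group_centroid_ellipse(samples, groups)
    else:
        centroids, ellipses = pd.DataFrame(), {}
    return TriplotLayout(
        genes=genes,
        samples=samples,
        arrows=arrows,
        centroids=centroids,
        ellipses=ellipses,
        axis_labels=res.axis_labels()[:dims],
        dims=dims,
    )


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def _draw_2d(layout: TriplotLayout, colors: pd.Series | None, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(
        layout.genes.iloc[:, 0], layout.genes.iloc[:, 1],
        s=6, c="0.75", label="genes", zorder=1,
    )
    if colors is None:
        ax.scatter(
            layout.samples.iloc[:, 0], layout.samples.iloc[:, 1],
            s=18, c="tab:blue", label="samples", zorder=2,
        )
    else:
        levels = list(pd.unique(colors.dropna()))
        try:
            levels = sorted(levels)  # legend in rank order for ordinal covariates
        except TypeError:
            levels = sorted(levels, key=str)
        cmap = plt.get_cmap("tab10")
        for i, lev in enumerate(levels):
            mask = (colors == lev).reindex(layout.samples.index, fill_value=False)
            ax.scatter(
                layout.samples.loc[mask].iloc[:, 0],
                layout.samples.loc[mask].iloc[:, 1],
                s=18, color=cmap(i % 10), label=str(lev), zorder=2,
            )
        missing = colors.reindex(layout.samples.index).isna()
        if missing.any():
            ax.scatter(
                layout.samples.loc[missing].iloc[:, 0],
                layout.samples.loc[missing].iloc[:, 1],
                s=18, color="0.5", label="(missing)", zorder=2,
            )
    for name, row in layout.arrows.iterrows():
        ax.annotate(
            "", xy=(row.iloc[0], row.iloc[1]), xytext=(0, 0),
            arrowprops={"arrowstyle": "->", "color": "tab:red"},
        )
        ax.text(row.iloc[0], row.iloc[1], str(name), color="tab:red", fontsize=9)
    for g, ell in layout.ellipses.items():
        theta = np.linspace(0, 2 * np.pi, 200)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        rot = np.array(
            [
                [np.cos(ell.rotation), -np.sin(ell.rotation)],
                [np.sin(ell.rotation), np.cos(ell.rotation)],
            ]
        )
        xy = rot @ (ell.semi_axes[:, None] * circle) + ell.center[:, None]
        ax.plot(xy[0], xy[1], color="black", lw=0.8)
    if not layout.centroids.empty:
        ax.scatter(
            layout.centroids.iloc[:, 0], layout.centroids.iloc[:, 1],
            s=60, c="black", marker="o", zorder=3,
        )
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel(layout.axis_labels[0])
    ax.set_ylabel(layout.axis_labels[1])
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": "ccam"})
    plt.close(fig)


def _draw_3d(layout: TriplotLayout, path: Path) -> None:
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    ax.scatter(*[layout.genes.iloc[:, k] for k in range(3)], s=4, c="0.75")
    ax.scatter(*[layout.samples.iloc[:, k] for k in range(3)], s=14, c="tab:blue")
    for name, row in layout.arrows.iterrows():
        ax.plot([0, row.iloc[0]], [0, row.iloc[1]], [0, row.iloc[2]], c="tab:red")
        ax.text(row.iloc[0], row.iloc[1], row.iloc[2], str(name), color="tab:red")
    for k, setter in enumerate((ax.set_xlabel, ax.set_ylabel, ax.set_zlabel)):
        setter(layout.axis_labels[k])
    fig.savefig(path, dpi=150, metadata={"Software": "ccam"})
    plt.close(fig)


def render_triplot(
    res: CCAResult,
    out_dir,
    groups: pd.Series | None = None,
    dims: int = 2,
    prefix: str = "triplot",
) -> TriplotLayout:
    """Export a triplot image plus coordinate TSVs (the testable artifact).

    Writes ``<prefix>.png``, coordinate tables for genes/samples/arrows
    (plus centroids when groups are given) and the per-sample nearest-arrow
    angular assignment.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = _layout(res, groups, dims)
    _write_tsv(layout.genes.rename_axis("gene_id"), out_dir / f"{prefix}_genes.tsv")
    _write_tsv(
        layout.samples.rename_axis("sample_id"), out_dir / f"{prefix}_samples.tsv"
    )
    _write_tsv(
        layout.arrows.rename_axis("population"), out_dir / f"{prefix}_arrows.tsv"
    )
    if not layout.centroids.empty:
        _write_tsv(layout.centroids, out_dir / f"{prefix}_centroids.tsv")
    assignment = angular_assignment(layout.samples, layout.arrows)
    _write_tsv(assignment, out_dir / f"{prefix}_nearest_arrow.tsv")
    if dims == 2:
        _draw_2d(layout, groups, out_dir / f"{prefix}.png")
    else:
        _draw_3d(layout, out_dir / f"{prefix}.png")
    return layout


def overlay_clinical(
    res: CCAResult,
    covariate: pd.Series,
    out_dir,
    prefix: str = "overlay",
) -> pd.DataFrame:
    """Recolor the 2-D sample map by a clinical covariate.

    Missing values render neutral grey and are logged. Returns the plotted
    coordinate/covariate table (also written as TSV).
    """
    covariate = covariate.reindex(res.sample_scores.index)
    if covariate.isna().all():
        raise ValueError("covariate missing for every plotted sample")
    n_missing = int(covariate.isna().sum())
    if n_missing:
        logger.info("%d samples lack the covariate; rendered neutral", n_missing)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = _layout(res, None, 2)
    _draw_2d(layout, covariate, out_dir / f"{prefix}.png")
    table = layout.samples.copy()
    table[covariate.name or "covariate"] = covariate
    _write_tsv(table.rename_axis("sample_id"), out_dir / f"{prefix}.tsv")
    return table
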