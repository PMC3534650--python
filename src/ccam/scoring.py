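"""Axis-derived prognostic scores and percentile stratification.

An axis of a fitted ordination is turned into a per-patient score: take the
top and bottom genes by weighted-average score on that axis, summarise each
sample as the mean z-scored expression over the top genes minus the bottom
genes, z-scale across samples, and cut at chosen percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cca_core import CCAResult
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["AxisScoreModel", "StratifiedScores", "build_axis_score",
           "score_samples", "stratify"]

#: per-sample combination rule identifier stored with every exported model
COMBINATION_RULE = "mean_difference"


@dataclass
class AxisScoreModel:
    """Top/bottom gene lists for one ordination axis (1-based)."""

    axis: int
    top_genes: list[str]
    bottom_genes: list[str]
    combination: str = COMBINATION_RULE

    def __post_init__(self) -> None:
        if set(self.top_genes) & set(self.bottom_genes):
            raise ValueError("top and bottom gene lists overlap")
        if not self.top_genes or not self.bottom_genes:
            raise ValueError("need at least one top and one bottom gene")


@dataclass
class StratifiedScores:
    """Z-scaled per-sample scores with ordinal strata and recorded cuts."""

    table: pd.DataFrame  # columns: score, stratum (may be absent pre-stratify)
    cut_percentiles: list[float]
    cut_values: list[float]


def build_axis_score(
    res: CCAResult, axis: int = 1, n_top: int = 100, n_bottom: int = 100
) -> AxisScoreModel:
    """Rank genes by weighted-average score on ``axis`` and keep the extremes.

    Ties are broken lexicographically by gene id. If fewer than
    ``n_top + n_bottom`` genes exist, all genes are split by the sign of
    their score instead and a warning is logged.
    """
    if not 1 <= axis <= res.n_axes:
        raise ValueError(f"axis must be in [1, {res.n_axes}]")
    return build_axis_score_from_table(res.gene_scores_wa, axis, n_top, n_bottom)


def build_axis_score_from_table(
    wa_table: pd.DataFrame, axis: int = 1, n_top: int = 100, n_bottom: int = 100
) -> AxisScoreModel:
    """Like :func:`build_axis_score` but from an exported wa-score table."""
    col = f"Axis{axis}"
    if col not in wa_table.columns:
        raise ValueError(f"no column {col!r} in wa-score table")
    wa = wa_table[col]
    ranked = wa.to_frame("wa").reset_index(names="gene_id").sort_values(
        ["wa", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    if n_top + n_bottom > len(ranked):
        logger.warning(
            "requested %d genes but only %d exist; splitting all by sign",
            n_top + n_bottom, len(ranked),
        )
        top = ranked[ranked["wa"] >= 0]["gene_id"].tolist()
        bottom = ranked[ranked["wa"] < 0]["gene_id"].tolist()[::-1]
    else:
        top = ranked["gene_id"].head(n_top).tolist()
        bottom = ranked["gene_id"].tail(n_bottom).tolist()[::-1]
    return AxisScoreModel(axis=axis, top_genes=top, bottom_genes=bottom)


def score_samples(model: AxisScoreModel, x: ExpressionMatrix) -> StratifiedScores:
    """Score every sample: mean z-scored expression of top genes minus bottom.

    Expression is z-scored per gene across samples first, so the score is
    invariant to affine rescaling of the input matrix; the resulting scores
    are themselves z-scaled across samples.
    """
    present = set(x.gene_ids)
    top = [g for g in model.top_genes if g in present]
    bottom = [g for g in model.bottom_genes if g in present]
    if not top or not bottom:
        raise ValueError("no top or no bottom genes present in the matrix")
    if len(top) < len(model.top_genes) or len(bottom) < len(model.bottom_genes):
        logger.warning(
            "scoring with %d/%d top and %d/%d bottom genes present",
            len(top), len(model.top_genes), len(bottom), len(model.bottom_genes),
        )
    sub = x.select_genes(top + bottom)
    sd = sub.values.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        keep = sd[:, 0] > 0
        sub = sub.select_genes([g for g, k in zip(sub.gene_ids, keep) if k])
        top = [g for g in top if g in set(sub.gene_ids)]
        bottom = [g for g in bottom if g in set(sub.gene_ids)]
        if not top or not bottom:
            raise ValueError("all usable score genes are constant")
        sd = sub.values.std(axis=1, ddof=1, keepdims=True)
    z = (sub.values - sub.values.mean(axis=1, keepdims=True)) / sd
    zf = pd.DataFrame(z, index=sub.gene_ids, columns=sub.sample_ids)
    raw = zf.loc[top].mean(axis=0) - zf.loc[bottom].mean(axis=0)
    sd_raw = raw.std(ddof=1)
    if sd_raw == 0 or not np.isfinite(sd_raw):
        raise ValueError("all samples score identically; z-scaling is degenerate")
    scaled = (raw - raw.mean()) / sd_raw
    table = pd.DataFrame({"score": scaled})
    table.index.name = "sample_id"
    return StratifiedScores(table=table, cut_percentiles=[], cut_values=[])


def stratify(
    scores: StratifiedScores, cuts: list[float] | None = None
) -> StratifiedScores:
    """Assign ordinal strata 1..k+1 by percentile cuts of the score.

    Samples exactly at a cut value go to the lower stratum. Cut percentiles
    must be strictly increasing within (0, 100); the realised cut values are
    recorded on the result.
    """
    if cuts is None:
        cuts = [50.0]
    cuts = [float(q) for q in cuts]
    if any(not 0 < q < 100 for q in cuts) or any(
        b <= a for a, b in zip(cuts, cuts[1:])
    ):
        raise ValueError("cuts must be strictly increasing within (0, 100)")
    vals = scores.table["score"].to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("scores must be finite before stratification")
    cut_values = [float(np.percentile(vals, q)) for q in cuts]
    strata = np.ones(len(vals), dtype=int)
    for cv in cut_values:
        strata += (vals > cv).astype(int)
    table = scores.table.copy()
    table["stratum"] = strata
    return StratifiedScores(
        table=table, cut_percentiles=cuts, cut_values=cut_values
    )
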