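"""Loading, alignment and normalisation of gene-expression matrices.

This module prepares a pair of gene x sample matrices (a "dataset to be
explained" and a reference "dataset to explain") so that they are mutually
comparable at the gene level: parsing delimited text, intersecting gene
identifiers, per-gene z-scoring, shifting to nonnegative values (required by
the chi-square metric downstream) and empirical-Bayes batch adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "load_expression",
    "load_annotation",
    "write_expression",
    "align_genes",
    "zscore_genes",
    "shift_nonnegative",
    "batch_adjust",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of continuous expression values.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers, one per matrix row.
    sample_ids : list of str
        Unique column identifiers, one per matrix column.
    values : ndarray of shape (n_genes, n_samples)
        Finite float values on a log-like scale.
    provenance : str
        Free-text label describing where the matrix came from.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "") -> "ExpressionMatrix":
        return cls(
            gene_ids=list(frame.index),
            sample_ids=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            provenance=provenance,
        )

    def select_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``gene_ids`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows].copy(),
            provenance=self.provenance,
        )

    def select_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, cols].copy(),
            provenance=self.provenance,
        )


@dataclass
class SampleAnnotation:
    """Per-sample group membership plus optional batch and clinical columns.

    Backed by a DataFrame indexed by sample id with a mandatory ``group``
    column, an optional ``batch`` column, and any further columns treated as
    clinical covariates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise ValueError("annotation table requires a 'group' column")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in annotation: {dupes[:5]}")
        if self.table["group"].isna().any():
            raise ValueError("every sample needs a non-empty group")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def batches(self) -> pd.Series | None:
        if "batch" in self.table.columns:
            return self.table["batch"]
        return None

    def samples_in_group(self, group: str) -> list[str]:
        return [str(s) for s in self.table.index[self.table["group"] == group]]

    def clinical(self) -> pd.DataFrame:
        drop = [c for c in ("group", "batch") if c in self.table.columns]
        return self.table.drop(columns=drop)


def load_expression(
    path, sep: str = "\t", provenance: str | None = None
) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix.

    First column holds gene identifiers, header row holds sample identifiers,
    and the body must be numeric. Duplicate gene rows are collapsed by their
    mean (logged).

    Raises
    ------
    ValueError
        If a cell is non-numeric (the offending row/column is named) or the
        matrix is empty.
    """
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if frame.empty:
        raise ValueError(f"{path}: empty expression matrix")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna()
    if bad.to_numpy().any() or frame.isna().to_numpy().any():
        nan_mask = numeric.isna().to_numpy()
        i, j = np.argwhere(nan_mask)[0]
        raise ValueError(
            f"{path}: non-numeric value at gene {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r}"
        )
    if frame.index.has_duplicates:
        n_before = len(numeric)
        numeric = numeric.groupby(level=0, sort=False).mean()
        logger.info(
            "collapsed %d duplicate gene rows by mean", n_before - len(numeric)
        )
    return ExpressionMatrix.from_frame(
        numeric, provenance=provenance if provenance is not None else str(path)
    )


def load_annotation(path, sep: str = "\t") -> SampleAnnotation:
    """Read a sample annotation table (columns: sample_id, group, [batch], ...)."""
    table = pd.read_csv(path, sep=sep, index_col=0)
    table.index = table.index.map(str)
    return SampleAnnotation(table)


def write_expression(x: ExpressionMatrix, path, sep: str = "\t") -> None:
    """Write a matrix in the same layout :func:`load_expression` reads."""
    frame = x.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep=sep, float_format="%.6g")


def align_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common genes in one canonical order.

    The shared order is sorted lexicographically so alignment is deterministic
    and idempotent regardless of input ordering.

    Raises
    ------
    ValueError
        If the gene sets are disjoint.
    """
    common = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not common:
        raise ValueError("no genes shared between the two matrices")
    logger.info(
        "gene intersection: %d of %d / %d", len(common), a.n_genes, b.n_genes
    )
    return a.select_genes(common), b.select_genes(common)


def zscore_genes(x: ExpressionMatrix) -> ExpressionMatrix:
    """Standardise each gene row to mean 0, sd 1 (ddof=1).

    Constant rows (sd == 0) are dropped and logged.
    """
    if x.n_samples < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    mean = x.values.mean(axis=1, keepdims=True)
    sd = x.values.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = [g for g, k in zip(x.gene_ids, keep) if not k]
        logger.info("dropped %d constant genes: %s", n_dropped, dropped[:5])
    vals = (x.values[keep] - mean[keep]) / sd[keep]
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(x.gene_ids, keep) if k],
        sample_ids=list(x.sample_ids),
        values=vals,
        provenance=x.provenance,
    )


def shift_nonnegative(
    x: ExpressionMatrix, mode: Literal["global_min", "clip_zero"] = "global_min"
) -> ExpressionMatrix:
    """Make all values nonnegative.

    ``global_min`` subtracts the (negative) global minimum from every entry;
    ``clip_zero`` truncates negatives at 0. Either way the applied change is
    logged. Matrices that are already nonnegative are returned unchanged.
    """
    lo = float(x.values.min())
    if lo >= 0:
        return x
    if mode == "global_min":
        logger.info("shifting matrix by %+.6g to enforce nonnegativity", -lo)
        vals = x.values - lo
    elif mode == "clip_zero":
        n_neg = int((x.values < 0).sum())
        logger.info("clipping %d negative entries to zero", n_neg)
        vals = np.clip(x.values, 0.0, None)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return replace(x, values=vals)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2 if s2 > 0 else np.inf


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2 if s2 > 0 else np.inf


def batch_adjust(
    x: ExpressionMatrix,
    ann: SampleAnnotation,
    *,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per gene and batch, batch means are shrunk toward a normal prior and
    batch variances toward an inverse-gamma prior (both moment-matched across
    genes); the data are then recentred and rescaled to the pooled reference.
    A single batch (or absent batch column) returns the input unchanged.

    Raises
    ------
    ValueError
        If any batch has a single sample (the batch is named).
    """
    batches = ann.batches
    if batches is None:
        return x
    batches = batches.reindex(x.sample_ids)
    if batches.isna().any():
        missing = [s for s, b in zip(x.sample_ids, batches) if pd.isna(b)]
        raise ValueError(f"samples without batch label: {missing[:5]}")
    levels = list(pd.unique(batches))
    if len(levels) == 1:
        return x
    masks = {b: (batches == b).to_numpy() for b in levels}
    for b, m in masks.items():
        if m.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")

    vals = x.values
    n = vals.shape[1]
    n_b = {b: int(m.sum()) for b, m in masks.items()}

    # Pooled reference: grand mean weighted by batch size, residual variance
    # about per-batch means.
    batch_means = np.column_stack([vals[:, masks[b]].mean(axis=1) for b in levels])
    weights = np.array([n_b[b] / n for b in levels])
    alpha = batch_means @ weights
    resid = vals.copy()
    for k, b in enumerate(levels):
        resid[:, masks[b]] -= batch_means[:, [k]]
    sigma2 = (resid**2).mean(axis=1)
    sigma2 = np.maximum(sigma2, 1e-12)  # guard: zero within-batch noise
    sigma = np.sqrt(sigma2)

    z = (vals - alpha[:, None]) / sigma[:, None]
    adjusted = z.copy()
    for b in levels:
        m = masks[b]
        gamma_hat = z[:, m].mean(axis=1)
        delta_hat = np.maximum(z[:, m].var(axis=1, ddof=1), 1e-12)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        a_pr, b_pr = _aprior(delta_hat), _bprior(delta_hat)

        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        if not (np.isfinite(a_pr) and np.isfinite(b_pr)):
            # no spread in observed variances: degenerate inverse-gamma
            # prior, keep the observed variances and shrink means only
            gamma_star = (n_b[b] * tau2 * gamma_hat + delta_hat * gamma_bar) / (
                n_b[b] * tau2 + delta_hat
            )
            adjusted[:, m] = (z[:, m] - gamma_star[:, None]) / np.sqrt(
                delta_star[:, None]
            )
            continue
        for _ in range(max_iter):
            g_new = (n_b[b] * tau2 * gamma_hat + delta_star * gamma_bar) / (
                n_b[b] * tau2 + delta_star
            )
            ss = ((z[:, m] - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (b_pr + 0.5 * ss) / (n_b[b] / 2 + a_pr - 1)
            change = max(
                np.abs(g_new - gamma_star).max(), np.abs(d_new - delta_star).max()
            )
            gamma_star, delta_star = g_new, d_new
            if change < tol:
                break
        adjusted[:, m] = (z[:, m] - gamma_star[:, None]) / np.sqrt(
            delta_star[:, None]
        )

    out = adjusted * sigma[:, None] + alpha[:, None]
    logger.info("batch-adjusted %d samples across %d batches", n, len(levels))
    return replace(x, values=out)
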