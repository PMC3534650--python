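"""Constrained correspondence analysis of a gene x sample matrix.

The main matrix is standardised in the chi-square metric (rows weighted by
their sums), regressed onto per-population environmental variables, and the
projected residual matrix is decomposed by SVD. The module exposes the full
set of ordination scores (constrained and weighted-average gene scores,
sample scores, environment arrows) together with the inertia decomposition
used to judge how much of the original variation the constraints explain.

Conventions
-----------
* Axes are numbered from 1.
* Each axis is oriented so that the environment variable with the largest
  absolute arrow loading points positive (SVD signs are otherwise arbitrary).
* ``scaling=1`` multiplies gene scores by the singular values, ``scaling=2``
  (default) multiplies sample scores, ``scaling=0`` leaves both raw.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "ChiSquareForm",
    "EnvironmentMatrix",
    "CCAResult",
    "chi_square_form",
    "build_environment",
    "check_env_collinearity",
    "cca_fit",
    "env_arrow_scores",
    "percent_visualised",
    "decompose_inertia",
]

#: singular values below this fraction of the largest are treated as zero
RANK_TOL = 1e-12


@dataclass
class ChiSquareForm:
    """Chi-square-metric standardisation of a nonnegative matrix.

    ``P`` is the matrix divided by its grand total, ``r``/``c`` the row and
    column masses, and ``Qbar = D_r^{-1/2} (P - r c^T) D_c^{-1/2}`` the
    standardised residual whose squared sum is the total inertia.
    """

    P: np.ndarray
    r: np.ndarray
    c: np.ndarray
    Qbar: np.ndarray
    grand_total: float


def chi_square_form(values: np.ndarray) -> ChiSquareForm:
    """Compute the chi-square form of a nonnegative matrix.

    Raises
    ------
    ValueError
        On negative entries (pointing at ``shift_nonnegative``), zero grand
        total, or an all-zero row/column.
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError(
            "matrix has negative entries; apply preprocess.shift_nonnegative first"
        )
    total = values.sum()
    if total <= 0:
        raise ValueError("matrix grand total must be positive")
    P = values / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any():
        raise ValueError(f"all-zero gene rows at indices {np.flatnonzero(r == 0)[:5]}")
    if (c == 0).any():
        raise ValueError(
            f"all-zero sample columns at indices {np.flatnonzero(c == 0)[:5]}"
        )
    Qbar = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return ChiSquareForm(P=P, r=r, c=c, Qbar=Qbar, grand_total=float(total))


@dataclass
class EnvironmentMatrix:
    """Per-population averages of (z-scored) reference expression.

    ``Z`` holds one column per population; row-mass-weighted standardisation
    happens lazily at fit time because the weights come from the main matrix.
    """

    gene_ids: list[str]
    population_ids: list[str]
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape != (len(self.gene_ids), len(self.population_ids)):
            raise ValueError("Z shape does not match gene/population ids")
        if not self.population_ids:
            raise ValueError("need at least one population")

    def standardized(self, r: np.ndarray) -> np.ndarray:
        """``Z`` with each column given r-weighted mean 0 and variance 1."""
        r = np.asarray(r, dtype=float)
        mean = r @ self.Z
        centred = self.Z - mean
        var = r @ centred**2
        if (var <= 0).any():
            bad = [p for p, v in zip(self.population_ids, var) if v <= 0]
            raise ValueError(f"environment columns with zero weighted variance: {bad}")
        return centred / np.sqrt(var)


@dataclass
class CCAResult:
    """Everything a fit produces: SVD factors, scores and inertia budget."""

    gene_ids: list[str]
    sample_ids: list[str]
    population_ids: list[str]
    U: np.ndarray
    V: np.ndarray
    lambdas: np.ndarray
    eigenvalues: np.ndarray
    gene_scores_lc: pd.DataFrame
    gene_scores_wa: pd.DataFrame
    sample_scores: pd.DataFrame
    env_biplot: pd.DataFrame
    inertia_total: float
    inertia_constrained: float
    percent_explained: float
    axis_fractions: np.ndarray
    scaling: int
    # fit internals retained for downstream score computations
    r: np.ndarray = field(repr=False, default=None)
    c: np.ndarray = field(repr=False, default=None)
    P: np.ndarray = field(repr=False, default=None)
    Zstd: np.ndarray = field(repr=False, default=None)
    fingerprint: str = ""

    @property
    def n_axes(self) -> int:
        return len(self.lambdas)

    def axis_labels(self) -> list[str]:
        return [
            f"Axis{k + 1} ({100 * f:.1f}%)"
            for k, f in enumerate(self.axis_fractions)
        ]


def build_environment(
    ref: ExpressionMatrix,
    ann: SampleAnnotation,
    populations: list[str] | None = None,
) -> EnvironmentMatrix:
    """Average the (z-scored) reference matrix per population.

    Raises
    ------
    ValueError
        If a requested population has no samples in the annotation.
    """
    groups = ann.groups.reindex(ref.sample_ids)
    if populations is None:
        populations = list(pd.unique(groups.dropna()))
    cols = []
    for pop in populations:
        mask = (groups == pop).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"population {pop!r} has no samples")
        cols.append(ref.values[:, mask].mean(axis=1))
    return EnvironmentMatrix(
        gene_ids=list(ref.gene_ids),
        population_ids=[str(p) for p in populations],
        Z=np.column_stack(cols),
    )


@dataclass
class CollinearityReport:
    correlations: pd.DataFrame
    vif: pd.Series
    flagged_pairs: list[tuple[str, str, float]]
    flagged_vif: list[str]

    @property
    def ok(self) -> bool:
        return not self.flagged_pairs and not self.flagged_vif


def check_env_collinearity(
    env: EnvironmentMatrix,
    corr_threshold: float = 0.95,
    vif_threshold: float = 10.0,
) -> CollinearityReport:
    """Screen environment columns for redundancy before fitting.

    Reports the pairwise Pearson correlation matrix and a variance inflation
    factor per column (exact linear dependence is reported as infinite VIF).
    """
    if len(env.population_ids) < 2:
        raise ValueError("collinearity check needs >=2 populations")
    Z = env.Z
    corr = pd.DataFrame(
        np.corrcoef(Z.T), index=env.population_ids, columns=env.population_ids
    )
    vifs = {}
    n = Z.shape[1]
    for j in range(n):
        others = np.delete(Z, j, axis=1)
        X = np.column_stack([np.ones(Z.shape[0]), others])
        y = Z[:, j]
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        ss_res = float(resid @ resid)
        yc = y - y.mean()
        ss_tot = float(yc @ yc)
        if ss_tot == 0:
            vifs[env.population_ids[j]] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        vifs[env.population_ids[j]] = (
            np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        )
    vif = pd.Series(vifs, name="vif")
    flagged_pairs = [
        (env.population_ids[i], env.population_ids[j], float(corr.iloc[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if abs(corr.iloc[i, j]) > corr_threshold
    ]
    flagged_vif = [p for p, v in vif.items() if v > vif_threshold]
    return CollinearityReport(
        correlations=corr,
        vif=vif,
        flagged_pairs=flagged_pairs,
        flagged_vif=flagged_vif,
    )


def _weighted_corr(z: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Pearson correlation with observation weights ``w`` (summing to 1)."""
    zm = z - w @ z
    ym = y - w @ y
    denom = np.sqrt((w @ zm**2) * (w @ ym**2))
    if denom == 0:
        return 0.0
    return float((w * zm) @ ym / denom)


def cca_fit(
    s: ExpressionMatrix,
    env: EnvironmentMatrix,
    scaling: int = 2,
) -> CCAResult:
    """Fit constrained correspondence analysis of ``s`` on ``env``.

    Steps: chi-square form of ``s``; r-weighted standardisation of the
    environment columns; weighted projection ``H = Zw (Zw^T Zw)^-1 Zw^T``
    with ``Zw = D_r^{1/2} Zstd``; SVD of the constrained matrix
    ``Qc = H Qbar`` keeping positive singular values; score systems and the
    inertia decomposition.

    Raises
    ------
    ValueError
        On negative entries, as many environment variables as samples
        (overfit), mismatched genes, or linearly dependent environment
        columns.
    """
    if scaling not in (0, 1, 2):
        raise ValueError("scaling must be 0, 1 or 2")
    if s.gene_ids != env.gene_ids:
        raise ValueError("matrix and environment genes differ; align first")
    n_env, n_samples = len(env.population_ids), s.n_samples
    if n_env >= n_samples:
        raise ValueError(
            f"{n_env} environment variables for {n_samples} samples would "
            "overfit; the number of explanatory variables must be smaller"
        )
    form = chi_square_form(s.values)
    r, c, P, Qbar = form.r, form.c, form.P, form.Qbar

    Zstd = env.standardized(r)
    Zw = np.sqrt(r)[:, None] * Zstd
    G = Zw.T @ Zw
    cond = np.linalg.cond(G)
    if cond > 1e12:
        raise ValueError(
            "environment columns are linearly dependent "
            f"(Gram condition number {cond:.3g}); run check_env_collinearity"
        )
    H = Zw @ np.linalg.solve(G, Zw.T)
    Qc = H @ Qbar

    U, lam, Vt = np.linalg.svd(Qc, full_matrices=False)
    keep = lam > RANK_TOL * (lam[0] if lam.size else 1.0)
    U, lam, V = U[:, keep], lam[keep], Vt[keep].T
    if lam.size == 0:
        raise ValueError("no positive singular values; constrained matrix is null")

    # standard (unscaled) coordinates
    V0 = V / np.sqrt(c)[:, None]
    U0 = U / np.sqrt(r)[:, None]
    wa0 = (P @ V0) / r[:, None] / lam[None, :]

    # deterministic sign: largest-|loading| environment arrow positive per axis
    B0 = np.array(
        [
            [_weighted_corr(Zstd[:, j], wa0[:, k], r) for k in range(lam.size)]
            for j in range(n_env)
        ]
    )
    for k in range(lam.size):
        j = int(np.argmax(np.abs(B0[:, k])))
        if B0[j, k] < 0:
            U[:, k] *= -1
            V[:, k] *= -1
            U0[:, k] *= -1
            V0[:, k] *= -1
            wa0[:, k] *= -1
            B0[:, k] *= -1

    gene_mult = lam if scaling == 1 else np.ones_like(lam)
    sample_mult = lam if scaling == 2 else np.ones_like(lam)
    sample_scores = V0 * sample_mult
    gene_lc = U0 * gene_mult
    # weighted averages of (scaled) sample scores, normalised per axis
    gene_wa = (P @ sample_scores) / r[:, None] / lam[None, :] * gene_mult

    eig = lam**2
    inertia_total = float((Qbar**2).sum())
    inertia_constrained = float(eig.sum())
    axis_fractions = eig / inertia_constrained
    percent = (
        100.0 * inertia_constrained / inertia_total if inertia_total > 0 else 0.0
    )

    axes = [f"Axis{k + 1}" for k in range(lam.size)]
    fingerprint = hashlib.sha256(
        np.ascontiguousarray(s.values).tobytes()
        + ("|".join(s.gene_ids)).encode()
    ).hexdigest()[:16]
    logger.info(
        "CCA fit: %d genes x %d samples, %d env vars, %d axes, %%explained=%.2f",
        s.n_genes, n_samples, n_env, lam.size, percent,
    )
    return CCAResult(
        gene_ids=list(s.gene_ids),
        sample_ids=list(s.sample_ids),
        population_ids=list(env.population_ids),
        U=U,
        V=V,
        lambdas=lam,
        eigenvalues=eig,
        gene_scores_lc=pd.DataFrame(gene_lc, index=s.gene_ids, columns=axes),
        gene_scores_wa=pd.DataFrame(gene_wa, index=s.gene_ids, columns=axes),
        sample_scores=pd.DataFrame(sample_scores, index=s.sample_ids, columns=axes),
        env_biplot=pd.DataFrame(B0, index=env.population_ids, columns=axes),
        inertia_total=inertia_total,
        inertia_constrained=inertia_constrained,
        percent_explained=percent,
        axis_fractions=axis_fractions,
        scaling=scaling,
        r=r,
        c=c,
        P=P,
        Zstd=Zstd,
        fingerprint=fingerprint,
    )


def env_arrow_scores(res: CCAResult, env: EnvironmentMatrix | None = None) -> pd.DataFrame:
    """Arrow coordinates: r-weighted correlation of each environment column
    with each axis's weighted-average gene scores.

    For a single regressor this equals the standardised regression
    coefficient of the axis on the (standardised) environment variable.
    """
    Zstd = res.Zstd if env is None else env.standardized(res.r)
    # correlation is invariant to the per-axis display scaling of wa scores
    wa0 = res.gene_scores_wa.to_numpy()
    B = np.array(
        [
            [_weighted_corr(Zstd[:, j], wa0[:, k], res.r) for k in range(res.n_axes)]
            for j in range(Zstd.shape[1])
        ]
    )
    ids = res.population_ids if env is None else env.population_ids
    return pd.DataFrame(B, index=ids, columns=list(res.sample_scores.columns))


def percent_visualised(res: CCAResult, dims: int) -> float:
    """Share (%) of constrained inertia retained in the first ``dims`` axes."""
    if not 1 <= dims <= res.n_axes:
        raise ValueError(f"dims must be in [1, {res.n_axes}]")
    return float(100.0 * res.eigenvalues[:dims].sum() / res.inertia_constrained)


def decompose_inertia(res: CCAResult) -> dict:
    """Total / constrained / unconstrained inertia budget.

    The percentage explained is only comparable across fits that used the
    same genes and main matrix, so the report carries the gene count and a
    fingerprint of the fitted matrix.
    """
    return {
        "inertia_total": res.inertia_total,
        "inertia_constrained": res.inertia_constrained,
        "inertia_unconstrained": res.inertia_total - res.inertia_constrained,
        "percent_explained": res.percent_explained,
        "axis_eigenvalues": [float(e) for e in res.eigenvalues],
        "axis_fractions": [float(f) for f in res.axis_fractions],
        "n_genes": len(res.gene_ids),
        "matrix_fingerprint": res.fingerprint,
    }
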