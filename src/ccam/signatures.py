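"""Per-population gene signatures via an empirical-Bayes moderated t-statistic.

One-vs-rest contrasts on the reference matrix identify genes enriched in each
cell population; disease samples are then scored by Pearson correlation with
the signature's mean profile, and signatures can be clustered by their score
profiles across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "ModeratedTStats",
    "SignatureSet",
    "SignatureScoreMatrix",
    "moderated_t",
    "select_signature",
    "signature_score",
    "cluster_signatures",
]


@dataclass
class ModeratedTStats:
    """Per-gene moderated-t results for one one-vs-rest contrast.

    ``table`` columns: gene_id (index), mean_target, mean_rest, mean_diff,
    s2_g, d_g, t_mod, p_raw, p_adj. ``d0`` and ``s0_sq`` are the shared prior
    degrees of freedom and prior variance.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    target: str

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior degrees of freedom must be >= 0")
        if self.s0_sq <= 0:
            raise ValueError("prior variance must be positive")


@dataclass
class SignatureSet:
    """Genes over-expressed in one population, ordered by moderated t."""

    population: str
    gene_ids: list[str]
    threshold_used: float
    mean_profile: pd.Series  # indexed by gene_id

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("signature gene list is empty")


@dataclass
class SignatureScoreMatrix:
    """Populations x samples matrix of z-scaled Pearson signature scores."""

    values: pd.DataFrame  # rows: populations, columns: samples


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior on log sample variances.

    Returns ``(d0, s0_sq)``; ``d0`` may be ``inf`` when the observed
    log-variance spread is no wider than sampling noise alone.
    """
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2)
    if e_var > 0:
        d0 = 2 * _trigamma_inverse(e_var)
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2))
    else:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    return float(d0), float(s0_sq)


def moderated_t(
    x: ExpressionMatrix,
    ann: SampleAnnotation,
    target: str,
    *,
    d0_override: float | None = None,
) -> ModeratedTStats:
    """One-vs-rest moderated t-statistics for every gene.

    Ordinary equal-variance two-sample statistics are computed per gene; the
    prior ``(d0, s0_sq)`` is estimated by moment-matching on the log sample
    variances (digamma/trigamma inversion), per-gene variances are shrunk to
    their posterior mean, and two-sided p-values use ``d0 + d_g`` degrees of
    freedom with Benjamini-Hochberg adjustment across genes.

    Parameters
    ----------
    d0_override : float, optional
        Force the prior degrees of freedom (0 disables shrinkage entirely;
        very large values collapse all variances to the prior). Mainly for
        validation.
    """
    groups = ann.groups.reindex(x.sample_ids)
    in_target = (groups == target).to_numpy()
    n1, n2 = int(in_target.sum()), int((~in_target).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"need >=2 samples in target ({n1}) and rest ({n2}) for {target!r}"
        )
    a = x.values[:, in_target]
    b = x.values[:, ~in_target]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    d_g = n1 + n2 - 2
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2_g = ss / d_g

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.exp(np.log(np.maximum(s2_g, 1e-300)).mean()))
    else:
        d0, s0_sq = _fit_f_dist(s2_g, d_g)

    if np.isinf(d0):
        s2_post = np.full_like(s2_g, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2_g
        df_total = float(d_g)
    else:
        s2_post = (d0 * s0_sq + d_g * s2_g) / (d0 + d_g)
        df_total = d0 + d_g

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = (mean_a - mean_b) / se
    if np.isinf(df_total):
        p_raw = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2 * stats.t.sf(np.abs(t_mod), df_total)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "mean_target": mean_a,
            "mean_rest": mean_b,
            "mean_diff": mean_a - mean_b,
            "s2_g": s2_g,
            "d_g": float(d_g),
            "t_mod": t_mod,
            "p_raw": p_raw,
            "p_adj": p_adj,
        },
        index=pd.Index(x.gene_ids, name="gene_id"),
    )
    return ModeratedTStats(table=table, d0=d0, s0_sq=s0_sq, target=target)


def select_signature(
    stats_: ModeratedTStats,
    max_p_adj: float = 1e-5,
    top_k: int = 200,
) -> SignatureSet:
    """Pick the provisional signature for the contrast's target population.

    Keeps genes with positive moderated t and adjusted p <= ``max_p_adj``,
    truncated to ``top_k`` by moderated t (ties broken by gene id).
    """
    t = stats_.table
    passing = t[(t["t_mod"] > 0) & (t["p_adj"] <= max_p_adj)]
    if passing.empty:
        raise ValueError(
            f"no genes pass p_adj <= {max_p_adj} for {stats_.target!r}; "
            "relax the threshold"
        )
    ranked = passing.sort_values(
        ["t_mod", "gene_id"], ascending=[False, True], kind="mergesort"
    ).head(top_k)
    return SignatureSet(
        population=stats_.target,
        gene_ids=list(ranked.index),
        threshold_used=max_p_adj,
        mean_profile=ranked["mean_target"].copy(),
    )


def signature_score(x: ExpressionMatrix, sig: SignatureSet) -> pd.Series:
    """Correlation of each sample with the signature's mean profile, z-scaled.

    The per-sample Pearson correlation over signature genes is standardised
    across samples (mean 0, sd 1). Samples whose signature-gene vector has
    zero variance get NaN and are logged.
    """
    genes = [g for g in sig.gene_ids if g in set(x.gene_ids)]
    if len(genes) < 3:
        raise ValueError(
            f"only {len(genes)} signature genes present in matrix (need >=3)"
        )
    sub = x.select_genes(genes)
    profile = sig.mean_profile.reindex(genes).to_numpy()
    pc = profile - profile.mean()
    denom_p = np.sqrt((pc**2).sum())
    if denom_p == 0:
        raise ValueError("signature mean profile has zero variance")
    centred = sub.values - sub.values.mean(axis=0, keepdims=True)
    denom_s = np.sqrt((centred**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (centred.T @ pc) / (denom_s * denom_p)
    undefined = denom_s == 0
    if undefined.any():
        bad = [s for s, u in zip(x.sample_ids, undefined) if u]
        logger.warning("signature score undefined for samples: %s", bad[:5])
        raw[undefined] = np.nan
    ok = ~undefined
    mu = raw[ok].mean()
    sd = raw[ok].std(ddof=1)
    if sd == 0:
        raise ValueError("all defined signature scores identical; cannot scale")
    scaled = (raw - mu) / sd
    return pd.Series(scaled, index=x.sample_ids, name=sig.population)


def score_all_signatures(
    x: ExpressionMatrix, sigs: list[SignatureSet]
) -> SignatureScoreMatrix:
    """Stack :func:`signature_score` over several signatures."""
    rows = [signature_score(x, s) for s in sigs]
    return SignatureScoreMatrix(values=pd.DataFrame(rows))


def cluster_signatures(
    scores: SignatureScoreMatrix, height: float = 0.5
) -> tuple[np.ndarray, pd.Series]:
    """Average-linkage clustering of populations by 1 - Pearson distance.

    Returns the scipy linkage matrix and flat cluster labels cut at
    ``height``.
    """
    vals = scores.values
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 populations to cluster")
    corr = np.corrcoef(vals.to_numpy())
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    flat = hierarchy.fcluster(linkage, t=height, criterion="distance")
    return linkage, pd.Series(flat, index=vals.index, name="cluster")
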