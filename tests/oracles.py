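"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit loops / direct formulas, separate
from the package code paths it validates.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def weighted_pearson(z: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Direct weighted correlation (weights normalised internally)."""
    w = np.asarray(w, dtype=float)
    w = w / w.sum()
    mz = sum(wi * zi for wi, zi in zip(w, z))
    my = sum(wi * yi for wi, yi in zip(w, y))
    cov = sum(wi * (zi - mz) * (yi - my) for wi, zi, yi in zip(w, z, y))
    vz = sum(wi * (zi - mz) ** 2 for wi, zi in zip(w, z))
    vy = sum(wi * (yi - my) ** 2 for wi, yi in zip(w, y))
    return cov / math.sqrt(vz * vy)


def cca_brute_force(X: np.ndarray, Z: np.ndarray, tol: float = 1e-12) -> dict:
    """Explicit-projection CCA oracle: forms H and eigendecomposes Qc^T Qc."""
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, m = X.shape
    total = X.sum()
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Qbar = np.empty_like(P)
    for i in range(n):
        for j in range(m):
            Qbar[i, j] = (P[i, j] - r[i] * c[j]) / math.sqrt(r[i] * c[j])

    Zstd = np.empty_like(Z, dtype=float)
    for k in range(Z.shape[1]):
        mean = sum(r[i] * Z[i, k] for i in range(n))
        var = sum(r[i] * (Z[i, k] - mean) ** 2 for i in range(n))
        Zstd[:, k] = (Z[:, k] - mean) / math.sqrt(var)

    Zw = np.diag(np.sqrt(r)) @ Zstd
    H = Zw @ np.linalg.inv(Zw.T @ Zw) @ Zw.T
    Qc = H @ Qbar

    evals, evecs = np.linalg.eigh(Qc.T @ Qc)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > tol * max(evals[0], tol)
    evals, V = evals[keep], evecs[:, keep]
    lam = np.sqrt(evals)
    U = Qc @ V / lam

    V0 = V / np.sqrt(c)[:, None]
    U0 = U / np.sqrt(r)[:, None]
    wa = (P @ V0) / r[:, None] / lam[None, :]
    B = np.array(
        [
            [weighted_pearson(Zstd[:, j], wa[:, k], r) for k in range(lam.size)]
            for j in range(Z.shape[1])
        ]
    )
    return {
        "P": P,
        "r": r,
        "c": c,
        "Qbar": Qbar,
        "H": H,
        "Qc": Qc,
        "eigenvalues": evals,
        "lambdas": lam,
        "U0": U0,
        "V0": V0,
        "wa": wa,
        "B": B,
        "inertia_total": float((Qbar**2).sum()),
        "inertia_constrained": float(evals.sum()),
    }


def align_signs(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Flip columns of ``other`` to maximise agreement with ``ref``."""
    out = other.copy()
    for k in range(out.shape[1]):
        if np.dot(ref[:, k], out[:, k]) < 0:
            out[:, k] *= -1
    return out


def km_by_hand(times, events):
    """Product-limit estimate via the textbook recursion."""
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=int)[order]
    surv = 1.0
    out_t, out_s = [], []
    for t in sorted(set(times[events == 1])):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        surv *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(surv)
    return np.array(out_t), np.array(out_s)


def logrank_by_hand(times, events, groups):
    """k-sample log-rank chi-square via direct O-E / hypergeometric variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    k = len(levels)
    O = np.zeros(k)
    E = np.zeros(k)
    Vmat = np.zeros((k, k))
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n_t = int(at_risk.sum())
        d_t = int(((times == t) & (events == 1)).sum())
        for a, ga in enumerate(levels):
            n_a = int((at_risk & (groups == ga)).sum())
            d_a = int(((times == t) & (events == 1) & (groups == ga)).sum())
            O[a] += d_a
            E[a] += d_t * n_a / n_t
        if n_t > 1:
            for a, ga in enumerate(levels):
                n_a = int((at_risk & (groups == ga)).sum())
                for b, gb in enumerate(levels):
                    n_b = int((at_risk & (groups == gb)).sum())
                    same = 1.0 if a == b else 0.0
                    Vmat[a, b] += (
                        d_t * (n_a / n_t) * (same - n_b / n_t) * (n_t - d_t) / (n_t - 1)
                    )
    z = (O - E)[:-1]
    V = Vmat[:-1, :-1]
    return float(z @ np.linalg.pinv(V) @ z)


def mann_whitney_exact_p(a, b):
    """Two-sided exact p by enumerating every group assignment."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    mean_u = n1 * len(b) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for x in ga for y in gb if x > y) + 0.5 * sum(
            1 for x in ga for y in gb if x == y
        )
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


def average_linkage_by_hand(dist: np.ndarray):
    """Step-by-step agglomeration with unweighted average linkage.

    Returns merge records ``(height, frozenset_of_leaves_a, frozenset_of_leaves_b)``.
    """
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    d = {
        (i, j): float(dist[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((h, clusters[i], clusters[j]))
        merged = clusters[i] | clusters[j]
        active -= {i, j}
        newd = {}
        for (a, b), v in d.items():
            if i in (a, b) or j in (a, b):
                continue
            newd[(a, b)] = v
        for k in active:
            # unweighted average of all leaf pairs
            acc = [
                dist[p, q] if p < q else dist[q, p]
                for p in merged
                for q in clusters[k]
            ]
            key = (min(k, next_id), max(k, next_id))
            newd[key] = float(np.mean(acc))
        clusters[next_id] = merged
        active.add(next_id)
        d = newd
        next_id += 1
    return merges
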