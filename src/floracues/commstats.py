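"""Rank-based multivariate group comparison and ordination.

ANOSIM tests whether samples within a priori groups are more similar to
each other than to samples of other groups, operating on the ranks of a
dissimilarity matrix: R = (mean between-group rank - mean within-group
rank) / (M/2) with M = n(n-1)/2 pairs; R = 1 means complete separation,
R ~ 0 random grouping. Significance comes from relabelling samples.
Pairwise post-hoc tests enumerate all distinct relabellings exactly
whenever there are fewer of them than the requested permutation count.

NMDS embeds a dissimilarity matrix in k dimensions by non-metric SMACOF
(iterative majorisation with isotonic regression), reporting Kruskal
stress-1 for the best of several starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.manifold import smacof


@dataclass
class AnosimResult:
    """Global ANOSIM outcome, optionally with a per-pair post-hoc table."""

    R: float
    p: float
    n_perm: int
    exact: bool  # p from exhaustive enumeration of relabellings
    seed: int | None = None
    pairwise: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {"R": self.R, "p": self.p, "n_perm": self.n_perm,
             "exact": self.exact, "seed": self.seed}
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        return d


@dataclass
class NMDSResult:
    """Best NMDS configuration and its Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    converged: bool
    seed: int | None = None


def standardize_curves(vectors: np.ndarray) -> np.ndarray:
    """Scale each row so its maximum equals 100 (shape preserved)."""
    V = np.asarray(vectors, dtype=float)
    if V.ndim == 1:
        V = V[None, :]
    mx = V.max(axis=1)
    if (mx <= 0).any():
        raise ValueError("cannot standardise an all-zero curve")
    return V / mx[:, None] * 100.0


def _check_dist(dist: np.ndarray) -> np.ndarray:
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("dissimilarity diagonal must be zero")
    if D.min() < -1e-12:
        raise ValueError("dissimilarities must be non-negative")
    return D


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    M = len(ranks)
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return float((rb - rw) / (M / 2.0))


def anosim(
    dist: np.ndarray,
    groups,
    n_perm: int = 10_000,
    seed: int | None = None,
    exact_if_small: bool = True,
) -> AnosimResult:
    """Global ANOSIM on a dissimilarity matrix.

    Dissimilarities are ranked once with mid-ranks for ties; the test is
    one-tailed toward large R. For two groups the distinct relabellings
    are enumerated exhaustively when there are no more of them than
    ``n_perm``; otherwise ``n_perm`` random relabellings are drawn and
    p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).
    """
    D = _check_dist(dist)
    g = np.asarray(list(groups))
    n = D.shape[0]
    if len(g) != n:
        raise ValueError("group labels must match the matrix size")
    uniq, counts = np.unique(g, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if len(uniq) == 2 and (counts < 2).any():
        raise ValueError("a two-group ANOSIM needs both groups of size >= 2")
    if (counts < 2).any():
        warnings.warn("groups of size 1 contribute no within-group pairs")

    ranks = rankdata(squareform(D, checks=False))  # mid-ranks
    iu, ju = np.triu_indices(n, k=1)
    within_obs = g[iu] == g[ju]
    if not within_obs.any() or within_obs.all():
        raise ValueError("need both within- and between-group pairs")
    R_obs = _anosim_r(ranks, within_obs)

    n_exact = _n_distinct_relabellings(counts)
    if exact_if_small and len(uniq) == 2 and n_exact <= n_perm:
        R_all = _enumerate_two_group(ranks, iu, ju, n, int(counts[0]))
        # the observed labelling is one of the enumerated relabellings
        p = float(np.sum(R_all >= R_obs - 1e-12) / len(R_all))
        return AnosimResult(R=R_obs, p=p, n_perm=len(R_all), exact=True,
                            seed=seed)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    G = g[perms]  # (n_perm, n)
    W = G[:, iu] == G[:, ju]  # (n_perm, M) within masks
    M = len(ranks)
    n_within = W.sum(axis=1).astype(float)
    sum_within = W @ ranks
    total = ranks.sum()
    rw = sum_within / n_within
    rb = (total - sum_within) / (M - n_within)
    R_perm = (rb - rw) / (M / 2.0)
    p = float((1 + np.sum(R_perm >= R_obs - 1e-12)) / (1 + n_perm))
    return AnosimResult(R=R_obs, p=p, n_perm=n_perm, exact=False, seed=seed)


def _n_distinct_relabellings(counts: np.ndarray) -> int:
    n = int(counts.sum())
    total = 1
    rem = n
    for c in counts:
        total *= comb(rem, int(c))
        rem -= int(c)
    return total


def _enumerate_two_group(ranks, iu, ju, n, n1) -> np.ndarray:
    out = np.empty(comb(n, n1))
    for k, idx in enumerate(combinations(range(n), n1)):
        lab = np.zeros(n, dtype=int)
        lab[list(idx)] = 1
        within = lab[iu] == lab[ju]
        out[k] = _anosim_r(ranks, within)
    return out


def pairwise_anosim(
    dist: np.ndarray,
    groups,
    n_perm: int = 10_000,
    seed: int | None = None,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Post-hoc ANOSIM for every unordered pair of groups.

    Each pair is tested on its sub-matrix; exact enumeration replaces
    sampling whenever the pair admits at most ``n_perm`` distinct
    relabellings (so with groups of sizes 2 and 3 all C(5,2) = 10
    relabellings are scored and the smallest attainable p is 1/10).
    """
    D = _check_dist(dist)
    g = np.asarray(list(groups))
    uniq = list(dict.fromkeys(g))
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in combinations(uniq, 2):
        sel = np.flatnonzero((g == a) | (g == b))
        sub = D[np.ix_(sel, sel)]
        res = anosim(sub, g[sel], n_perm=n_perm,
                     seed=int(rng.integers(2**31 - 1)))
        rows.append({"group_a": a, "group_b": b, "R": res.R, "p": res.p,
                     "n_perm": res.n_perm, "exact": res.exact})
    table = pd.DataFrame(rows)
    if bonferroni:
        table["p_bonferroni"] = np.minimum(table["p"] * len(table), 1.0)
    return table


def nmds(
    dist: np.ndarray,
    k: int = 2,
    n_starts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
    labels=None,
) -> NMDSResult:
    """Non-metric multidimensional scaling by SMACOF majorisation.

    Runs ``n_starts`` random initialisations plus one metric (classical
    scaling) initialisation and keeps the configuration with the lowest
    Kruskal stress-1. Stress is non-increasing within each run by the
    majorisation property.
    """
    D = _check_dist(dist)
    n = D.shape[0]
    if n <= k:
        raise ValueError("need more samples than embedding dimensions")
    rng = np.random.default_rng(seed)
    inits = [_classical_mds(D, k)]
    scale = max(D.max(), 1e-12)
    for _ in range(n_starts):
        inits.append(rng.normal(scale=scale, size=(n, k)))
    best = None
    for init in inits:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X, stress, n_iter = smacof(
                D, metric=False, n_components=k, init=init, n_init=1,
                max_iter=max_iter, eps=tol, normalized_stress=True,
                random_state=0, return_n_iter=True,
            )
        if best is None or stress < best[1]:
            best = (X, float(stress), n_iter)
    X, stress, n_iter = best
    converged = n_iter < max_iter
    if not converged:
        warnings.warn("NMDS did not converge; returning best configuration")
    coords = pd.DataFrame(
        X, columns=[f"NMDS{i + 1}" for i in range(k)],
        index=labels if labels is not None else range(n),
    )
    return NMDSResult(coordinates=coords, stress=stress,
                      converged=converged, seed=seed)


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling used as the metric start."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:k]
    L = np.sqrt(np.clip(evals[idx], 0.0, None))
    return evecs[:, idx] * L
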