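"""Phylogenetic-signal statistics.

Implements the Moran's-I form of Abouheif's test (Cmean) with tip
permutation, Pagel's lambda by profile maximum likelihood with a
likelihood-ratio test, univariate Blomberg's K, and the multivariate
generalisation Kmult with a row-permutation test.

All permutation p-values are one-tailed (large statistic) with the
+1/+1 correction, p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm),
and are bit-reproducible given (seed, n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from floracues.phylo import PhyloTree, lambda_transform


@dataclass
class SignalTestResult:
    """Outcome of one phylogenetic-signal test.

    ``nuisance`` holds auxiliary estimates where applicable (sigma^2 and
    log-likelihoods for the lambda fit, permutation quantiles for the
    permutation tests).
    """

    statistic_name: str
    value: float
    p: float
    n_perm: int | None = None
    df: int | None = None
    nuisance: dict = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "value": self.value,
            "p": self.p,
            "n_perm": self.n_perm,
            "df": self.df,
            "nuisance": self.nuisance,
            "seed": self.seed,
        }


def _perm_p(stat_obs: float, stat_perm: np.ndarray) -> float:
    return float((1 + np.sum(stat_perm >= stat_obs)) / (1 + len(stat_perm)))


# ------------------------------------------------------------------ Cmean


def morans_i(x: np.ndarray, W: np.ndarray) -> float:
    """Moran's index I = (z'Wz)/(z'z) with z the centred trait vector.

    ``W`` must be row-normalised with zero diagonal (as produced by
    :meth:`PhyloTree.abouheif_proximity` with ``normalize="row"``).
    """
    x = np.asarray(x, dtype=float)
    z = x - x.mean()
    denom = z @ z
    if denom == 0:
        raise ValueError("Moran's I undefined for a constant trait")
    return float(z @ W @ z / denom)


def cmean_test(
    x: np.ndarray,
    tree: PhyloTree,
    n_perm: int = 999,
    seed: int | None = None,
    normalize: str = "row",
) -> SignalTestResult:
    """Abouheif's Cmean: Moran's I with Abouheif proximity, tip permutation.

    The statistic is computed on the trait vector given in tree tip
    order; significance comes from randomly permuting trait values
    across tips.
    """
    W, _ = tree.abouheif_proximity(normalize=normalize)
    x = np.asarray(x, dtype=float)
    obs = morans_i(x, W)
    rng = np.random.default_rng(seed)
    n = len(x)
    z = x - x.mean()
    denom = z @ z
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Z = z[perms]  # (n_perm, n)
    stat_perm = np.einsum("bi,ij,bj->b", Z, W, Z) / denom
    return SignalTestResult(
        statistic_name="Cmean",
        value=obs,
        p=_perm_p(obs, stat_perm),
        n_perm=n_perm,
        nuisance={
            "perm_mean": float(stat_perm.mean()),
            "perm_q95": float(np.quantile(stat_perm, 0.95)),
        },
        seed=seed,
    )


# ------------------------------------------------------------ Blomberg K


def _k_ingredients(C: np.ndarray):
    n = C.shape[0]
    Ci = np.linalg.inv(C)
    w = Ci @ np.ones(n)
    s = w.sum()  # 1'C^-1 1
    denom_const = (np.trace(C) - n / s) / (n - 1)
    return Ci, w, s, denom_const


def blomberg_k(x: np.ndarray, tree: PhyloTree | None = None, C=None) -> float:
    """Univariate Blomberg's K.

    K compares the observed ratio of tip variance to phylogenetically
    corrected variance against its Brownian-motion expectation; K = 1
    under BM on the given tree, K = 1 exactly on an equal-branch star
    tree for any data.
    """
    if C is None:
        C, _ = tree.bm_covariance()
    x = np.asarray(x, dtype=float)
    n = len(x)
    Ci, w, s, denom_const = _k_ingredients(C)
    ahat = w @ x / s
    r = x - ahat
    mse0 = r @ r / (n - 1)
    mse = r @ Ci @ r / (n - 1)
    return float((mse0 / mse) / denom_const)


def _kmult_stat(X: np.ndarray, Ci: np.ndarray, w: np.ndarray, s: float,
                denom_const: float) -> float:
    ahat = w @ X / s  # per-column GLS mean
    R = X - ahat
    mse0 = np.sum(R * R)
    mse = np.sum(R * (Ci @ R))
    return float((mse0 / mse) / denom_const)


def kmult(
    X: np.ndarray,
    tree: PhyloTree | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    C=None,
) -> SignalTestResult:
    """Multivariate Blomberg's K (Kmult).

    The univariate quadratic forms are summed over the p trait columns;
    the normalising constant is unchanged, so for p = 1 the statistic
    equals :func:`blomberg_k` exactly. The p-value permutes whole rows
    of X across tips.
    """
    if C is None:
        C, _ = tree.bm_covariance()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != C.shape[0]:
        raise ValueError("rows of X must match the number of tips")
    n = X.shape[0]
    Ci, w, s, denom_const = _k_ingredients(C)
    obs = _kmult_stat(X, Ci, w, s, denom_const)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Xp = X[perms]  # (n_perm, n, p)
    ahat = np.einsum("i,bip->bp", w, Xp) / s
    R = Xp - ahat[:, None, :]
    mse0 = np.einsum("bip,bip->b", R, R)
    mse = np.einsum("bip,ij,bjp->b", R, Ci, R)
    stat_perm = (mse0 / mse) / denom_const
    return SignalTestResult(
        statistic_name="Kmult",
        value=obs,
        p=_perm_p(obs, stat_perm),
        n_perm=n_perm,
        nuisance={
            "perm_mean": float(stat_perm.mean()),
            "perm_q95": float(np.quantile(stat_perm, 0.95)),
        },
        seed=seed,
    )


# ---------------------------------------------------------- Pagel lambda


def _lambda_loglik(x: np.ndarray, C: np.ndarray, lam: float) -> float:
    """Profile log-likelihood of Normal(mu 1, sigma^2 C(lambda)).

    mu and sigma^2 are profiled analytically: mu is the GLS mean and
    sigma^2 = r'C^-1 r / n at that mean.
    """
    n = len(x)
    Cl = lambda_transform(C, lam)
    cho = linalg.cho_factor(Cl, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    one = np.ones(n)
    Ci_one = linalg.cho_solve(cho, one)
    mu = Ci_one @ x / Ci_one.sum()
    r = x - mu
    s2 = r @ linalg.cho_solve(cho, r) / n
    if not np.isfinite(s2) or s2 <= 0:
        raise FloatingPointError("non-finite profiled variance")
    return float(-0.5 * (n * np.log(2 * np.pi * s2) + logdet + n))


def pagel_lambda_fit(
    x: np.ndarray,
    tree: PhyloTree,
    lam_max: float = 1.0,
    grid_points: int = 21,
    tol: float = 1e-6,
) -> SignalTestResult:
    """Maximum-likelihood Pagel's lambda with a likelihood-ratio test.

    The profile likelihood is scanned on a uniform grid over
    [0, lam_max] to bracket the optimum, then refined with bounded
    scalar optimisation. The p-value refers the LR statistic
    2(lnL(lam_hat) - lnL(0)) to chi-square with 1 df; a boundary fit
    lam_hat = 0 therefore gives p = 1.

    The tree must be ultrametric: on ultrametric trees C(lambda) stays
    positive definite across the whole [0, 1] search interval.
    """
    if not tree.is_ultrametric():
        raise ValueError("lambda fitting requires an ultrametric tree")
    C, _ = tree.bm_covariance()
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("lambda undefined for a constant trait")

    grid = np.linspace(0.0, lam_max, grid_points)
    ll_grid = np.array([_lambda_loglik(x, C, l) for l in grid])
    ibest = int(np.argmax(ll_grid))
    lo = grid[max(ibest - 1, 0)]
    hi = grid[min(ibest + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        lambda l: -_lambda_loglik(x, C, l),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol},
    )
    # candidates: boundaries of the search range and the interior optimum;
    # the boundary lam = 0 wins ties so a flat likelihood reports no signal
    lnl0 = float(ll_grid[0])
    cands = [
        (0.0, lnl0),
        (float(lam_max), float(ll_grid[-1])),
        (float(res.x), -float(res.fun)),
    ]
    lam_hat, lnl_hat = max(cands, key=lambda t: (t[1] - lnl0 > 1e-9, t[1]))
    if lnl_hat - lnl0 <= 1e-9:
        lam_hat, lnl_hat = 0.0, lnl0
    lr = max(0.0, 2.0 * (lnl_hat - lnl0))
    p = float(stats.chi2.sf(lr, df=1)) if lam_hat > 0 else 1.0

    # nuisance sigma^2 at the optimum
    Cl = lambda_transform(C, lam_hat)
    cho = linalg.cho_factor(Cl, lower=True)
    Ci_one = linalg.cho_solve(cho, np.ones(len(x)))
    mu = Ci_one @ x / Ci_one.sum()
    r = x - mu
    s2 = float(r @ linalg.cho_solve(cho, r) / len(x))

    return SignalTestResult(
        statistic_name="lambda",
        value=float(lam_hat),
        p=p,
        df=1,
        nuisance={"sigma2": s2, "lnL_hat": lnl_hat, "lnL_0": lnl0, "mu": float(mu)},
    )
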