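"""Phylogenetic principal component analysis (pPCA).

pPCA finds trait combinations that maximise the absolute product of
variance and phylogenetic autocorrelation (Moran's I with Abouheif
proximity). Axes with large positive eigenvalues carry *global*
structure — trait combinations shared within clades; axes with large
negative eigenvalues carry *local* structure — combinations on which
close relatives diverge. For an n-tip table the spectrum has at most
min(p, n - 1) non-null axes, so the local axis is conventionally the
last one (e.g. PC13 for 14 tips).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from floracues.phylo import PhyloTree, align_to_tree
from floracues.phylosignal import morans_i


@dataclass
class PPCAResult:
    """Fitted pPCA: eigenvalues sorted most-positive to most-negative.

    ``axis_table`` decomposes every eigenvalue into variance x Moran's I
    of its score vector (the defining identity of the method).
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # variables x axes
    scores: pd.DataFrame  # tips x axes
    axis_table: pd.DataFrame  # per-axis variance, moran_index, product
    global_axis: str
    local_axis: str
    local_axis_rank: int  # 1-based index of the local axis (= n_axes)

    @property
    def axes(self) -> list[str]:
        return list(self.loadings.columns)


def ppca_fit(
    X: pd.DataFrame,
    tree: PhyloTree,
    scale: bool = False,
    proximity_normalize: str = "row",
) -> PPCAResult:
    """Fit a pPCA of a tips-by-variables trait table on a tree.

    Parameters
    ----------
    X:
        DataFrame indexed by tip label (one row per species). Columns
        with zero variance are dropped with a warning.
    tree:
        Tree whose tip set must equal the row index of ``X``.
    scale:
        Divide each column by its standard deviation after centring
        (correlation-style pPCA). Default is covariance-style, which
        suits commensurate units such as percent reflectance.

    Notes
    -----
    Rows are weighted uniformly (1/n). The proximity is the symmetrised
    row-normalised Abouheif matrix; the decomposition diagonalises
    (1/n) Xc' W_sym Xc, whose k-th eigenvalue equals
    var(score_k) * I(score_k) by construction.
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame indexed by tip label")
    if X.shape[0] < 3:
        raise ValueError("pPCA needs at least 3 tips")
    order = align_to_tree(list(X.index), tree.tip_labels)
    X = X.iloc[order]

    sd = X.std(axis=0, ddof=0)
    dead = list(X.columns[sd == 0])
    if dead:
        warnings.warn(f"dropping zero-variance columns: {dead}")
        X = X.drop(columns=dead)
        sd = sd.drop(dead)
    if X.shape[1] < 1:
        raise ValueError("no variable with positive variance")

    n, p = X.shape
    Xc = X.to_numpy(dtype=float) - X.to_numpy(dtype=float).mean(axis=0)
    if scale:
        Xc = Xc / sd.to_numpy()

    W, _ = tree.abouheif_proximity(normalize=proximity_normalize)
    Ws = 0.5 * (W + W.T)
    H = Xc.T @ Ws @ Xc / n
    evals, evecs = np.linalg.eigh(H)

    # keep the min(p, n-1) informative axes: the centring null space
    # contributes exactly p - (n - 1) numerically-zero eigenvalues
    r = min(p, n - 1)
    idx = np.argsort(evals)[::-1]
    if p > r:
        drop = set(np.argsort(np.abs(evals))[: p - r])
        idx = np.array([i for i in idx if i not in drop])
    evals = evals[idx]
    evecs = evecs[:, idx]

    # sign convention: largest-|loading| element of each axis positive
    for k in range(evecs.shape[1]):
        jmax = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[jmax, k] < 0:
            evecs[:, k] = -evecs[:, k]

    axes = [f"PC{k + 1}" for k in range(len(evals))]
    scores = Xc @ evecs
    var = (scores**2).mean(axis=0)
    moran = np.array([morans_i(scores[:, k], W) for k in range(len(evals))])

    loadings = pd.DataFrame(evecs, index=X.columns, columns=axes)
    scores_df = pd.DataFrame(scores, index=X.index, columns=axes)
    axis_table = pd.DataFrame(
        {
            "eigenvalue": evals,
            "variance": var,
            "moran_index": moran,
            "product": var * moran,
        },
        index=axes,
    )
    return PPCAResult(
        eigenvalues=evals,
        loadings=loadings,
        scores=scores_df,
        axis_table=axis_table,
        global_axis=axes[0],
        local_axis=axes[-1],
        local_axis_rank=len(axes),
    )


def structure_report(
    res: PPCAResult, top_m: int = 10, axes: list[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Top-loading variables and species scores for selected axes.

    For each requested axis (default: the global and local axes) the
    report lists the ``top_m`` variables ranked by absolute loading,
    with sign, plus every species score with its sign and magnitude
    (the usual black/white-circle display convention).
    """
    if axes is None:
        axes = [res.global_axis, res.local_axis]
    bad = [a for a in axes if a not in res.axes]
    if bad:
        raise ValueError(f"axes not in fit: {bad}")
    top_m = min(top_m, res.loadings.shape[0])
    out: dict[str, pd.DataFrame] = {}
    for axis in axes:
        lo = res.loadings[axis]
        top = lo.reindex(lo.abs().sort_values(ascending=False).index[:top_m])
        var_tbl = pd.DataFrame(
            {"loading": top, "abs_loading": top.abs(), "sign": np.sign(top)}
        )
        sc = res.scores[axis]
        sp_tbl = pd.DataFrame(
            {"score": sc, "abs_score": sc.abs(), "sign": np.sign(sc)}
        )
        out[axis] = var_tbl
        out[f"{axis}_scores"] = sp_tbl
    return out
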