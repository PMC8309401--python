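"""Floral-volatile composition tables and similarity indices.

A :class:`CompoundTable` is a samples x compounds abundance matrix with
species labels. The analysis chain mirrors standard GC/MS practice for
floral headspace data: remove compounds that are not genuinely floral
(the 10-fold vegetative-control rule), rescale each sample to relative
amounts, fourth-root the relative amounts for semi-quantitative
comparison or binarise for qualitative comparison, then compute
Bray-Curtis or Sorensen similarities (in percent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

COMPOUND_CLASSES = (
    "monoterpene",
    "sesquiterpene",
    "aromatic",
    "aliphatic",
    "spiroacetal",
    "N-compound",
    "irregular terpene",
)

FLORAL_FOLD = 10.0


@dataclass
class CompoundTable:
    """Samples x compounds abundance matrix with species labels.

    ``values``: DataFrame indexed by sample id, columns are compound
    names, entries non-negative peak areas or relative amounts.
    ``species``: Series mapping sample id -> species label.
    ``classes``: optional Series mapping compound -> compound class.
    """

    values: pd.DataFrame
    species: pd.Series
    classes: pd.Series | None = None

    def __post_init__(self):
        v = self.values
        if (v.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if not v.index.equals(self.species.index):
            self.species = self.species.reindex(v.index)
        if self.species.isna().any() or (self.species == "").any():
            raise ValueError("every sample needs a non-empty species label")
        if (v.sum(axis=1) <= 0).any():
            bad = list(v.index[v.sum(axis=1) <= 0])
            raise ValueError(f"samples with no positive entry: {bad}")

    # ------------------------------------------------------------- I/O

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        classes: pd.Series | None = None,
    ) -> "CompoundTable":
        """Build from long format with columns sample, species, compound, area."""
        need = {"sample", "species", "compound", "area"}
        if not need.issubset(df.columns):
            raise ValueError(f"long table needs columns {sorted(need)}")
        wide = (
            df.pivot_table(
                index="sample", columns="compound", values="area",
                aggfunc="sum", fill_value=0.0,
            )
        )
        sp = df.drop_duplicates("sample").set_index("sample")["species"]
        sp = sp.reindex(wide.index)
        return cls(values=wide, species=sp, classes=classes)

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack().rename("area").reset_index()
        long.columns = ["sample", "compound", "area"]
        long.insert(1, "species", self.species.reindex(long["sample"]).values)
        return long[long["area"] > 0].reset_index(drop=True)

    # ------------------------------------------------------ derived views

    @property
    def compounds(self) -> list[str]:
        return list(self.values.columns)

    @property
    def species_list(self) -> list[str]:
        return list(dict.fromkeys(self.species))

    def species_mean(self) -> pd.DataFrame:
        """Species x compound matrix of per-species mean values."""
        return self.values.groupby(self.species).mean()

    def subset_compounds(self, keep: list[str]) -> "CompoundTable":
        vals = self.values[keep]
        ok = vals.sum(axis=1) > 0
        if not ok.all():
            warnings.warn(
                f"dropping samples with no retained compound: "
                f"{list(vals.index[~ok])}"
            )
        return CompoundTable(
            values=vals.loc[ok], species=self.species.loc[ok],
            classes=None if self.classes is None else self.classes,
        )


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity (percent) or dissimilarity matrix."""

    values: pd.DataFrame
    kind: str  # {"similarity-percent", "dissimilarity"}

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("matrix must be symmetric")
        if self.kind == "similarity-percent":
            if not np.allclose(np.diag(v), 100.0):
                raise ValueError("similarity diagonal must be 100")
            if v.min() < -1e-8 or v.max() > 100 + 1e-8:
                raise ValueError("similarities must lie in [0, 100]")
        elif self.kind == "dissimilarity":
            if not np.allclose(np.diag(v), 0.0):
                raise ValueError("dissimilarity diagonal must be 0")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    def to_dissimilarity(self) -> pd.DataFrame:
        if self.kind == "dissimilarity":
            return self.values
        return 100.0 - self.values


# ----------------------------------------------------------- operations


def floral_filter(
    floral: CompoundTable,
    vegetative: CompoundTable,
    fold: float = FLORAL_FOLD,
    per_sample: bool = False,
) -> tuple[CompoundTable, dict]:
    """Keep only genuinely floral volatiles, species by species.

    A compound counts as floral for a species when its mean floral peak
    area is at least ``fold`` (default 10) times its mean vegetative
    peak area, or when it never appears in that species' vegetative
    samples. Entries failing the rule are zeroed for that species;
    compounds retained by no species are dropped. A species without
    vegetative controls keeps everything, with a warning.

    With ``per_sample=True`` each floral sample is compared with the
    species' vegetative mean individually instead of via the floral mean.

    Returns the filtered table and a log dict with the kept compounds
    per species and any uncontrolled species.
    """
    vals = floral.values.copy()
    veg_mean = vegetative.values.groupby(vegetative.species).mean()
    log: dict = {"kept": {}, "removed": {}, "no_controls": []}
    for sp in floral.species_list:
        rows = floral.species == sp
        if sp not in veg_mean.index:
            warnings.warn(
                f"no vegetative controls for species {sp!r}; keeping all "
                f"compounds for it"
            )
            log["no_controls"].append(sp)
            log["kept"][sp] = [
                c for c in vals.columns if vals.loc[rows, c].sum() > 0
            ]
            continue
        vm = veg_mean.loc[sp].reindex(vals.columns).fillna(0.0)
        fm = vals.loc[rows].mean(axis=0)
        keep = (vm == 0) | (fm >= fold * vm)
        if per_sample:
            # every sample row must individually clear the rule
            sub = vals.loc[rows]
            keep = (vm == 0) | (sub >= fold * vm).all(axis=0)
        removed = list(vals.columns[(~keep) & (fm > 0)])
        vals.loc[rows, list(vals.columns[~keep])] = 0.0
        log["removed"][sp] = removed
        log["kept"][sp] = [c for c in vals.columns if vals.loc[rows, c].sum() > 0]
    alive = list(vals.columns[vals.sum(axis=0) > 0])
    if not alive:
        raise ValueError("no compound survives the floral filter")
    kept_vals = vals[alive]
    ok = kept_vals.sum(axis=1) > 0
    if not ok.all():
        warnings.warn(
            f"samples with no retained floral compound were dropped: "
            f"{list(kept_vals.index[~ok])}"
        )
    filtered = CompoundTable(
        values=kept_vals.loc[ok],
        species=floral.species.loc[ok],
        classes=floral.classes,
    )
    return filtered, log


def relative_amounts(table: CompoundTable) -> CompoundTable:
    """Rescale every sample so its compounds sum to 100 percent."""
    totals = table.values.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("sample with zero total abundance")
    return CompoundTable(
        values=table.values.div(totals, axis=0) * 100.0,
        species=table.species,
        classes=table.classes,
    )


def fourth_root(table: CompoundTable) -> CompoundTable:
    """Element-wise fourth root (compresses dominance, keeps ranking)."""
    v = table.values.to_numpy(dtype=float)
    if (v < 0).any():
        raise ValueError("negative abundance")
    return CompoundTable(
        values=pd.DataFrame(
            np.power(v, 0.25), index=table.values.index,
            columns=table.values.columns,
        ),
        species=table.species,
        classes=table.classes,
    )


def binarise(table: CompoundTable) -> CompoundTable:
    """Presence/absence view (strictly positive -> 1)."""
    return CompoundTable(
        values=(table.values > 0).astype(float),
        species=table.species,
        classes=table.classes,
    )


def bray_curtis_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Bray-Curtis similarity in percent: 100 (1 - sum|a-b| / sum(a+b))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    tot = (a + b).sum()
    if tot == 0:
        raise ValueError("similarity undefined for two all-zero vectors")
    return float(100.0 * (1.0 - np.abs(a - b).sum() / tot))


def sorensen_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Sorensen similarity in percent: 100 * 2|A&B| / (|A| + |B|)."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    na, nb = a.sum(), b.sum()
    if na + nb == 0:
        raise ValueError("similarity undefined for two empty sets")
    return float(100.0 * 2.0 * (a & b).sum() / (na + nb))


def similarity_matrix(table: CompoundTable, kind: str) -> SimilarityMatrix:
    """All pairwise sample similarities.

    ``kind``: "bray-curtis" (on the abundances as given) or "sorensen"
    (on presence/absence).
    """
    fn = {"bray-curtis": bray_curtis_similarity,
          "sorensen": sorensen_similarity}.get(kind)
    if fn is None:
        raise ValueError(f"unknown similarity kind {kind!r}")
    V = table.values.to_numpy(dtype=float)
    n = V.shape[0]
    S = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = fn(V[i], V[j])
    return SimilarityMatrix(
        values=pd.DataFrame(S, index=table.values.index,
                            columns=table.values.index),
        kind="similarity-percent",
    )


def top_k_share(table: CompoundTable, species: str, k: int = 5) -> float:
    """Mean summed relative amount of a species' k dominant compounds.

    Compounds are ranked by their species-mean relative amount; the
    share of that fixed top-k set is averaged over the species' samples.
    ``table`` must already hold relative amounts (rows sum to 100).
    """
    rows = table.species == species
    if not rows.any():
        raise ValueError(f"unknown species {species!r}")
    sub = table.values.loc[rows]
    mean_profile = sub.mean(axis=0)
    k = min(k, sub.shape[1])
    top = mean_profile.sort_values(ascending=False).index[:k]
    return float(sub[top].sum(axis=1).mean())
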