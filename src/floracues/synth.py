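"""Synthetic trees, traits, reflectance spectra and scent tables.

The generator reproduces the statistical structure the analyses assume
for a clade of bellflower-like, bee-pollinated species: an ultrametric
pure-birth (Yule) phylogeny of 11-14 tips; flower reflectance curves
with a violet-blue peak (400-440 nm), an orange-red peak (600-700 nm)
and a variable UV shoulder, measured as tip and base of three flowers
per species; and volatile bouquets of roughly 10-55 compounds per
species drawn from a ~150-compound pool across seven compound classes,
with species-specific profiles dominated by few compounds (top-5 share
around 43-93%) and 2-12 samples per species, plus matched low-level
vegetative control samples to exercise the floral-volatile filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from floracues.colorvision import ReflectanceSpectrum, DEFAULT_GRID
from floracues.phylo import PhyloTree, lambda_transform
from floracues.scent import CompoundTable, COMPOUND_CLASSES


@dataclass
class SynthConfig:
    """Knobs of the generator, with study-like defaults."""

    n_species: int = 14
    n_color_replicates: int = 3
    # reflectance peaks (percent units)
    violet_blue_center: tuple[float, float] = (400.0, 440.0)
    orange_red_center: tuple[float, float] = (620.0, 690.0)
    peak_height: tuple[float, float] = (20.0, 55.0)
    uv_fraction: float = 0.5  # fraction of species with a UV shoulder
    noise_sd: float = 1.0  # percent reflectance
    # scent
    n_compounds_pool: int = 150
    compounds_per_species: tuple[int, int] = (10, 55)
    samples_per_species: tuple[int, int] = (2, 12)
    top5_share_range: tuple[float, float] = (43.0, 93.0)
    marker_loss_prob: float = 0.1
    exclusive_profiles: bool = False  # disjoint per-species compound sets
    # trait evolution
    lambda_true: float = 1.0
    sigma2_bm: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        for rng_pair in (self.compounds_per_species, self.samples_per_species,
                         self.top5_share_range, self.peak_height):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError(f"range out of order: {rng_pair}")
        if self.n_species < 3 or self.n_color_replicates < 1:
            raise ValueError("counts must be positive (and >= 3 species)")


# ------------------------------------------------------------------ trees


def gen_yule_tree(n_tips: int, seed: int | None = None,
                  rng: np.random.Generator | None = None) -> PhyloTree:
    """Pure-birth tree scaled to unit root-to-tip depth.

    Tips are labelled sp01, sp02, ... in birth order; the same seed
    always yields the identical Newick string.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = rng if rng is not None else np.random.default_rng(seed)
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    # the root splits at time 0; afterwards each lineage splits at rate 1
    t = 0.0
    lineages = [(root, 0.0)]
    node, birth = lineages.pop()
    children = [dendropy.Node(), dendropy.Node()]
    for ch in children:
        node.add_child(ch)
    lineages = [(ch, 0.0) for ch in children]
    while len(lineages) < n_tips:
        t += rng.exponential(1.0 / len(lineages))
        i = int(rng.integers(len(lineages)))
        node, birth = lineages.pop(i)
        node.edge.length = t - birth
        kids = [dendropy.Node(), dendropy.Node()]
        for ch in kids:
            node.add_child(ch)
        lineages.extend((ch, t) for ch in kids)
    t_end = t + rng.exponential(1.0 / n_tips)
    for k, (node, birth) in enumerate(lineages):
        node.edge.length = t_end - birth
        node.taxon = taxon_ns.new_taxon(label=f"sp{k + 1:02d}")
    # rescale to unit depth
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= t_end
    return PhyloTree(tree)


def sim_traits(
    tree: PhyloTree,
    p: int = 1,
    sigma2: float = 1.0,
    lam: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Traits from Normal(0, sigma^2 C(lambda)), independent columns.

    ``lam = 1`` is pure Brownian motion on the tree; ``lam = 0`` removes
    all phylogenetic covariance.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    C, labels = tree.bm_covariance()
    Cl = sigma2 * lambda_transform(C, lam)
    L = np.linalg.cholesky(Cl + 1e-12 * np.eye(len(labels)))
    X = L @ rng.standard_normal((len(labels), p))
    return pd.DataFrame(X, index=labels,
                        columns=[f"trait{j + 1}" for j in range(p)])


# ------------------------------------------------------------- spectra


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((wl - center) / width) ** 2))


def gen_reflectance_set(
    tree: PhyloTree,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReflectanceSpectrum], pd.DataFrame]:
    """Replicated flower spectra for every tip of the tree.

    Species mean curves are sums of Gaussian peaks whose log-heights
    evolve by Brownian motion on the tree (scaled by ``lambda_true``);
    a UV shoulder is present in a configurable fraction of species.
    Each flower contributes a tip and a base measurement: the base is a
    slightly damped copy of the tip, and both carry iid Gaussian noise,
    clipped at zero. Returns the spectra plus a manifest of the true
    per-species peak parameters.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    wl = DEFAULT_GRID
    labels = tree.tip_labels
    n = len(labels)
    # species-level peak parameters, evolved on the tree
    bm = sim_traits(tree, p=3, sigma2=0.04, lam=cfg.lambda_true, rng=rng)
    h_lo, h_hi = cfg.peak_height
    base_vb = rng.uniform(h_lo, h_hi)
    base_or = rng.uniform(h_lo, h_hi)
    c_vb = rng.uniform(*cfg.violet_blue_center, size=n)
    c_or = rng.uniform(*cfg.orange_red_center, size=n)
    uv_on = rng.random(n) < cfg.uv_fraction
    records, spectra = [], []
    for i, sp in enumerate(labels):
        h_vb = float(np.clip(base_vb * np.exp(bm.iloc[i, 0]), 5.0, 90.0))
        h_or = float(np.clip(base_or * np.exp(bm.iloc[i, 1]), 5.0, 90.0))
        h_uv = float(np.clip(25.0 * np.exp(bm.iloc[i, 2]), 5.0, 60.0)) \
            if uv_on[i] else 0.0
        mean_curve = (
            2.0
            + h_vb * _gauss(wl, c_vb[i], 22.0)
            + h_or * _gauss(wl, c_or[i], 45.0)
            + h_uv * _gauss(wl, 350.0, 28.0)
        )
        records.append({"species": sp, "h_violet_blue": h_vb,
                        "h_orange_red": h_or, "h_uv": h_uv,
                        "center_violet_blue": c_vb[i],
                        "center_orange_red": c_or[i]})
        for r in range(cfg.n_color_replicates):
            rid = f"{sp}_f{r + 1}"
            for part, factor in (("tip", 1.0), ("base", 0.92)):
                noisy = np.clip(
                    mean_curve * factor
                    + rng.normal(scale=cfg.noise_sd, size=wl.shape),
                    0.0, None,
                )
                spectra.append(ReflectanceSpectrum(
                    species=sp, replicate_id=rid, part=part,
                    wavelengths_nm=wl, reflectance=noisy,
                ))
    return spectra, pd.DataFrame(records).set_index("species")


# --------------------------------------------------------------- scent


def _compound_pool(cfg: SynthConfig) -> pd.Series:
    """Compound names with classes, sized like a bellflower volatile pool."""
    weights = np.array([40, 30, 12, 8, 6, 4, 2], dtype=float)
    counts = np.maximum(
        1, np.round(weights / weights.sum() * cfg.n_compounds_pool)
    ).astype(int)
    while counts.sum() > cfg.n_compounds_pool:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < cfg.n_compounds_pool:
        counts[np.argmax(weights)] += 1
    names, classes = [], []
    for cls, cnt in zip(COMPOUND_CLASSES, counts):
        tag = cls.split()[0][:5].replace("-", "")
        for k in range(cnt):
            names.append(f"{tag}_{k + 1:03d}")
            classes.append(cls)
    return pd.Series(classes, index=names, name="class")


def _dominance_decay(rng, cfg: SynthConfig, n_comp: int) -> np.ndarray:
    """Geometric profile whose top-5 share lands in the configured band."""
    lo, hi = cfg.top5_share_range
    target = rng.uniform(lo, hi) / 100.0
    # top-5 share of geometric weights q^r is 1 - q^5; invert for q
    q = (1.0 - target) ** (1.0 / 5.0) if n_comp > 5 else 0.5
    w = q ** np.arange(n_comp)
    return w / w.sum()


def gen_scent_table(
    tree: PhyloTree,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CompoundTable, CompoundTable, dict]:
    """Floral and matched vegetative volatile tables for the tree's tips.

    The compound pool is split into clade-marker compounds, inherited by
    all descendants of an internal clade (lost independently with
    ``marker_loss_prob``), and idiosyncratic compounds. Per-species
    profiles are geometric-dominance weights shuffled into a Dirichlet
    draw per sample, so each sample's relative amounts vary around the
    species profile while the expected top-5 share stays in the
    configured band. Vegetative samples contain a small subset of
    compounds at low areas, including some shared with flowers below
    the 10-fold rule, plus ubiquitous leaf compounds.

    With ``cfg.exclusive_profiles`` every species draws from a disjoint
    compound subset, giving fully species-specific bouquets.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pool = _compound_pool(cfg)
    all_names = list(pool.index)
    labels = tree.tip_labels
    n = len(labels)

    # assign compound sets per species
    comp_sets: dict[str, list[str]] = {}
    markers: dict[str, list[str]] = {sp: [] for sp in labels}
    if cfg.exclusive_profiles:
        shuffled = list(rng.permutation(all_names))
        per = max(1, len(shuffled) // n)
        lo, hi = cfg.compounds_per_species
        for i, sp in enumerate(labels):
            chunk = shuffled[i * per:(i + 1) * per]
            want = int(rng.integers(lo, min(hi, max(lo, len(chunk))) + 1))
            comp_sets[sp] = chunk[:max(2, min(want, len(chunk)))]
    else:
        # clade markers: one small marker set per internal clade
        clades = _internal_clades(tree)
        marker_names = list(rng.permutation(all_names))
        used = set()
        for clade in clades:
            take = [marker_names.pop() for _ in range(2) if marker_names]
            used.update(take)
            for sp in clade:
                for cname in take:
                    if rng.random() >= cfg.marker_loss_prob:
                        markers[sp].append(cname)
        rest = [c for c in all_names if c not in used]
        lo, hi = cfg.compounds_per_species
        for sp in labels:
            want = int(rng.integers(lo, hi + 1))
            n_idio = max(1, want - len(markers[sp]))
            idio = list(rng.choice(rest, size=min(n_idio, len(rest)),
                                   replace=False))
            comp_sets[sp] = markers[sp] + idio

    # per-sample abundance draws
    lo_s, hi_s = cfg.samples_per_species
    floral_rows, floral_samples, floral_species = [], [], []
    for sp in labels:
        comps = comp_sets[sp]
        profile = _dominance_decay(rng, cfg, len(comps))
        order = rng.permutation(len(comps))
        profile = profile[np.argsort(order)]  # random compound <-> rank map
        n_samp = int(rng.integers(lo_s, hi_s + 1))
        for s in range(n_samp):
            conc = 150.0
            rel = rng.dirichlet(profile * conc + 1e-3)
            total_area = rng.lognormal(mean=13.0, sigma=0.4)
            row = pd.Series(0.0, index=all_names)
            row[comps] = rel * total_area
            floral_rows.append(row)
            floral_samples.append(f"{sp}_s{s + 1}")
            floral_species.append(sp)
    floral_vals = pd.DataFrame(floral_rows, index=floral_samples)
    floral_vals = floral_vals.loc[:, floral_vals.sum(axis=0) > 0]
    floral = CompoundTable(
        values=floral_vals,
        species=pd.Series(floral_species, index=floral_samples),
        classes=pool,
    )

    # vegetative controls: 3 per species; green-leaf compounds plus a few
    # floral compounds at areas that defeat the 10-fold rule
    leaf_comps = [c for c in all_names if c.startswith("aliph")][:5]
    veg_rows, veg_samples, veg_species = [], [], []
    floral_mean = floral.values.groupby(floral.species).mean()
    for sp in labels:
        shared = [c for c in comp_sets[sp]
                  if rng.random() < 0.15 and floral_mean.loc[sp, c] > 0]
        for s in range(3):
            row = pd.Series(0.0, index=all_names)
            for c in leaf_comps:
                row[c] = rng.lognormal(mean=10.0, sigma=0.5)
            for c in shared:
                # around 1/5 of the floral mean: fails the 10-fold rule
                row[c] = floral_mean.loc[sp, c] * rng.uniform(0.15, 0.4)
            veg_rows.append(row)
            veg_samples.append(f"{sp}_veg{s + 1}")
            veg_species.append(sp)
    veg_vals = pd.DataFrame(veg_rows, index=veg_samples)
    veg_vals = veg_vals.loc[:, veg_vals.sum(axis=0) > 0]
    vegetative = CompoundTable(
        values=veg_vals,
        species=pd.Series(veg_species, index=veg_samples),
        classes=pool,
    )
    manifest = {
        "compound_sets": comp_sets,
        "markers": markers,
        "exclusive": cfg.exclusive_profiles,
    }
    return floral, vegetative, manifest


def _internal_clades(tree: PhyloTree) -> list[list[str]]:
    """Tip-label sets of non-root, non-trivial internal nodes."""
    clades = []
    dtree = tree._tree
    for node in dtree.preorder_internal_node_iter():
        if node is dtree.seed_node:
            continue
        tips = [lf.taxon.label for lf in node.leaf_iter()]
        if 2 <= len(tips) < tree.n_tips:
            clades.append(tips)
    return clades
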