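"""End-to-end orchestration of the colour, scent and signal analyses.

``run_color`` reproduces the colour workflow: curve standardisation,
Euclidean distances between individual flower curves, global and
pairwise ANOSIM, NMDS, hexagon loci/categories/distances and
background detectability, then pPCA of the per-10 nm species mean
reflectance (41 wavelength variables) with Cmean and Pagel's lambda on
the global and local axis scores and Kmult on the full matrix.

``run_scent`` mirrors it for volatiles: floral filter against the
vegetative controls, qualitative (Sorensen) and semi-quantitative
(fourth-root Bray-Curtis) similarity matrices, ANOSIM and NMDS on both,
pPCA of species-mean relative amounts, signal tests, plus compound-class
and top-5-dominance summaries.

Every stochastic result carries its seed and permutation count, and
identical configs reproduce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from floracues import __version__, io as fio
from floracues.colorvision import (
    VisionContext,
    hexagon_distance,
    mean_species_spectrum,
    discriminability,
    detectable_against_background,
    spectrum_locus,
)
from floracues.commstats import anosim, nmds, pairwise_anosim, standardize_curves
from floracues.phylo import PhyloTree, TreeError
from floracues.phylosignal import cmean_test, kmult, pagel_lambda_fit
from floracues.ppca import ppca_fit, structure_report
from floracues.scent import (
    binarise,
    floral_filter,
    fourth_root,
    relative_amounts,
    similarity_matrix,
    top_k_share,
)


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run (loadable from YAML)."""

    tree: str | None = None
    spectra: str | None = None
    scent: str | None = None
    vegetative: str | None = None
    out_dir: str = "floracues_out"
    run_color: bool = True
    run_scent: bool = True
    anosim_permutations: int = 10_000
    signal_permutations: int = 999
    ppca_scale: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.anosim_permutations < 99 or self.signal_permutations < 99:
            raise ValueError("permutation counts must be >= 99")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        # analytic identity of the run; where the outputs land is not part
        # of it, so re-runs into different directories hash identically
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_pruned_tree(path, labels) -> PhyloTree:
    tree = PhyloTree.from_file(path)
    tips = set(tree.tip_labels)
    wanted = [l for l in labels if l in tips]
    missing = sorted(set(labels) - tips)
    if len(wanted) < 3:
        raise TreeError(
            "trait and tree species sets share fewer than 3 labels"
        )
    if missing:
        warnings.warn(f"species absent from tree are dropped: {missing}")
    if set(wanted) != tips:
        tree = tree.prune_to(wanted)
    return tree


def _signal_block(matrix_df, tree, cfg: RunConfig):
    """Cmean + lambda on global/local axis scores, Kmult on the matrix."""
    res = ppca_fit(matrix_df, tree, scale=cfg.ppca_scale)
    order = [res.scores.index.get_loc(l) for l in tree.tip_labels]
    out = {
        "ppca": {
            "eigenvalues": [float(v) for v in res.eigenvalues],
            "global_axis": res.global_axis,
            "local_axis": res.local_axis,
            "local_axis_rank": res.local_axis_rank,
        },
        "axes": {},
    }
    for name, axis in (("global", res.global_axis),
                       ("local", res.local_axis)):
        x = res.scores[axis].to_numpy()[order]
        cm = cmean_test(x, tree, n_perm=cfg.signal_permutations,
                        seed=cfg.seed)
        lam = pagel_lambda_fit(x, tree)
        out["axes"][name] = {
            "axis": axis,
            "cmean": cm.to_dict(),
            "lambda": lam.to_dict(),
        }
    X = matrix_df.to_numpy()[
        [list(matrix_df.index).index(l) for l in tree.tip_labels]
    ]
    km = kmult(X, tree, n_perm=cfg.signal_permutations, seed=cfg.seed)
    out["kmult"] = km.to_dict()
    return out, res


def run_color(cfg: RunConfig) -> dict:
    """Colour analysis: ANOSIM/NMDS on curves, hexagon model, signal tests."""
    if cfg.spectra is None or cfg.tree is None:
        raise ValueError("colour analysis needs spectra and tree paths")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spectra = fio.read_spectra(cfg.spectra)

    by_species: dict[str, list] = {}
    for sp in spectra:
        by_species.setdefault(sp.species, []).append(sp)
    species = sorted(by_species)
    tree = _load_pruned_tree(cfg.tree, species)
    species = [s for s in species if s in set(tree.tip_labels)]

    # per-flower mean curves (tip/base averaged), for ANOSIM on individuals
    flower_curves, flower_species, flower_ids = [], [], []
    mean_spectra = {}
    for sp_name in species:
        reps = by_species[sp_name]
        mean_spectra[sp_name] = mean_species_spectrum(reps)
        flowers: dict[str, list] = {}
        for m in reps:
            flowers.setdefault(m.replicate_id, []).append(m)
        for rid, parts in sorted(flowers.items()):
            curve = np.mean([p.reflectance for p in parts], axis=0)
            flower_curves.append(curve)
            flower_species.append(sp_name)
            flower_ids.append(rid)
    V = standardize_curves(np.array(flower_curves))
    D = np.sqrt(
        ((V[:, None, :] - V[None, :, :]) ** 2).sum(axis=-1)
    )
    glob = anosim(D, flower_species, n_perm=cfg.anosim_permutations,
                  seed=cfg.seed)
    pw = pairwise_anosim(D, flower_species, n_perm=cfg.anosim_permutations,
                         seed=cfg.seed)
    ord_res = nmds(D, seed=cfg.seed, labels=flower_ids)

    # hexagon modelling on species mean spectra
    ctx = VisionContext.default(mean_spectra[species[0]].wavelengths_nm)
    loci = {s: spectrum_locus(mean_spectra[s], ctx) for s in species}
    loci_rows = []
    for s in species:
        l = loci[s]
        loci_rows.append({
            "species": s, "E_U": l.E_U, "E_B": l.E_B, "E_G": l.E_G,
            "x": l.x, "y": l.y, "category": l.category,
            "distance_to_background": float(np.hypot(l.x, l.y)),
            "detectable": detectable_against_background(l),
        })
    loci_df = pd.DataFrame(loci_rows).set_index("species")
    dist_df = pd.DataFrame(
        [[hexagon_distance(loci[a], loci[b]) for b in species]
         for a in species],
        index=species, columns=species,
    )
    discr_df = dist_df.map(discriminability)

    # pPCA on species-mean reflectance, one variable per 10 nm step
    wl = mean_spectra[species[0]].wavelengths_nm
    M = pd.DataFrame(
        {f"wl_{int(w)}": [mean_spectra[s].reflectance[i] for s in species]
         for i, w in enumerate(wl)},
        index=species,
    )
    signal, ppca_res = _signal_block(M, tree, cfg)

    fio.write_matrix(loci_df, out_dir / "color_loci.csv")
    fio.write_matrix(dist_df, out_dir / "color_hexagon_distances.csv")
    fio.write_matrix(discr_df, out_dir / "color_discriminability.csv")
    fio.write_matrix(ord_res.coordinates, out_dir / "color_nmds.csv")
    fio.write_matrix(ppca_res.scores, out_dir / "color_ppca_scores.csv")
    fio.write_matrix(ppca_res.loadings, out_dir / "color_ppca_loadings.csv")
    pw.to_csv(out_dir / "color_anosim_pairwise.csv", index=False)

    report = {
        "analysis": "color",
        "n_species": len(species),
        "anosim": {"global": glob.to_dict(),
                   "pairwise": pw.to_dict(orient="records")},
        "nmds_stress": ord_res.stress,
        "hexagon": {
            "loci": loci_df.reset_index().to_dict(orient="records"),
            "all_detectable": bool(loci_df["detectable"].all()),
        },
        "signal": signal,
        "seed": cfg.seed,
    }
    with open(out_dir / "color_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_scent(cfg: RunConfig) -> dict:
    """Scent analysis: filter, similarities, ANOSIM/NMDS, signal tests."""
    if cfg.scent is None or cfg.vegetative is None or cfg.tree is None:
        raise ValueError("scent analysis needs scent, vegetative and tree")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    floral = fio.read_scent(cfg.scent)
    veg = fio.read_scent(cfg.vegetative)
    tree = _load_pruned_tree(cfg.tree, floral.species_list)
    keep = set(tree.tip_labels)
    mask = floral.species.isin(keep)
    floral = type(floral)(values=floral.values.loc[mask],
                          species=floral.species.loc[mask],
                          classes=floral.classes)

    filtered, filter_log = floral_filter(floral, veg)
    rel = relative_amounts(filtered)
    semi = fourth_root(rel)
    qual = binarise(filtered)

    sim_bc = similarity_matrix(semi, "bray-curtis")
    sim_so = similarity_matrix(qual, "sorensen")
    groups = list(filtered.species)
    results = {}
    for name, sim in (("semi_quantitative", sim_bc), ("qualitative", sim_so)):
        Dm = sim.to_dissimilarity().to_numpy()
        glob = anosim(Dm, groups, n_perm=cfg.anosim_permutations,
                      seed=cfg.seed)
        pw = pairwise_anosim(Dm, groups, n_perm=cfg.anosim_permutations,
                             seed=cfg.seed)
        ordn = nmds(Dm, seed=cfg.seed, labels=sim.labels)
        results[name] = {"global": glob.to_dict(),
                         "pairwise": pw.to_dict(orient="records"),
                         "nmds_stress": ordn.stress}
        fio.write_matrix(sim.values, out_dir / f"scent_similarity_{name}.csv")
        fio.write_matrix(ordn.coordinates, out_dir / f"scent_nmds_{name}.csv")
        pw.to_csv(out_dir / f"scent_anosim_pairwise_{name}.csv", index=False)

    # species summaries
    shares = {s: top_k_share(rel, s, k=5) for s in filtered.species_list}
    class_counts = {}
    if filtered.classes is not None:
        pres = filtered.species_mean() > 0
        for s in filtered.species_list:
            comps = pres.columns[pres.loc[s]]
            class_counts[s] = (
                filtered.classes.reindex(comps).value_counts().to_dict()
            )
    n_comp = {s: int((filtered.species_mean().loc[s] > 0).sum())
              for s in filtered.species_list}

    # pPCA on species-mean semi-quantitative composition
    M = semi.species_mean()
    M = M.loc[[l for l in tree.tip_labels]]
    signal, ppca_res = _signal_block(M, tree, cfg)
    fio.write_matrix(ppca_res.scores, out_dir / "scent_ppca_scores.csv")
    fio.write_matrix(ppca_res.loadings, out_dir / "scent_ppca_loadings.csv")

    report = {
        "analysis": "scent",
        "n_species": len(filtered.species_list),
        "n_compounds_retained": filtered.values.shape[1],
        "filter": {"no_controls": filter_log["no_controls"],
                   "removed": {k: len(v) for k, v in
                               filter_log["removed"].items()}},
        "anosim": results,
        "top5_share": shares,
        "compounds_per_species": n_comp,
        "compound_classes": class_counts,
        "signal": signal,
        "seed": cfg.seed,
    }
    with open(out_dir / "scent_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_all(cfg: RunConfig) -> dict:
    """Run the enabled analyses and merge their reports with provenance."""
    report: dict = {"provenance": {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "version": __version__,
        "anosim_permutations": cfg.anosim_permutations,
        "signal_permutations": cfg.signal_permutations,
    }}
    if cfg.run_color:
        if cfg.spectra is None:
            raise ValueError("colour analysis enabled but no spectra path")
        report["color"] = run_color(cfg)
    if cfg.run_scent:
        if cfg.scent is None:
            raise ValueError("scent analysis enabled but no scent path")
        report["scent"] = run_scent(cfg)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "combined_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
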