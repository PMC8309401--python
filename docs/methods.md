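# Methods

This note documents the models implemented in `floracues`, the choices
made where conventions genuinely differ between software packages, and
what the synthetic data generator does and does not emulate.

## Bee colour-hexagon model

A reflectance spectrum is reduced to three receptor quantum catches by
rectangle-rule summation on the common 10 nm grid:

P_i = Σ I_S(λ) S_i(λ) D(λ) / Σ I_B(λ) S_i(λ) D(λ).

The denominator is the catch of the adapting background (von Kries
adaptation), so the background itself always has P = 1 and maps to the
hexagon centre, and any positive rescaling of the illuminant cancels.
The rectangle rule rather than the trapezoid was fixed for
bit-reproducibility; on a uniform 10 nm grid the two differ only through
the half-weighting of the two end points, which is far below measurement
noise. Excitation follows the hyperbolic transduction E = P/(P+1)
(half-maximal at the adapted background), and loci are
x = (√3/2)(E_G − E_U), y = E_B − (E_U + E_G)/2.

Defaults shipped with the package, all overridable with user curve
files:

- **Receptor sensitivities** — Govardovskii rhodopsin templates (alpha
  plus beta band, peak-normalised) at λmax = 344/436/544 nm, a standard
  honeybee-like parameterisation. Bees vary little in these peaks, which
  is why one set of curves serves a whole bee-pollinated genus.
- **Illuminant** — CIE D65 tabulated at 10 nm.
- **Background** — a smooth analytic "typical green leaf": 4% base
  reflectance, a Gaussian chlorophyll bump at 550 nm (amplitude 0.11,
  width 45 nm) and a logistic red-edge rise centred at 715 nm. This is a
  synthetic stand-in with the qualitative shape of measured foliage; it
  is not a digitised measurement.

Colour categories partition the hexagon by angle with the blue axis at
90°, UV at 210°, green at 330°, and boundaries on the midlines at
0°, 60°, …, 300°; the six sectors are blue [60°, 120°), UV-blue
[120°, 180°), UV [180°, 240°), UV-green [240°, 300°), green
[300°, 360°) and blue-green [0°, 60°). Loci within 1e−9 of the centre
are labelled achromatic. The boundary convention (half-open sectors,
receptor axes at sector centres) is a package choice; the category names
are the field's standard six.

Species loci are computed from the species mean spectrum (per-flower
tip/base mean, then unweighted mean over flowers), not by averaging
per-replicate loci; with three flowers per species the two routes differ
well below the 0.05 discrimination threshold, and the mean-spectrum
route keeps the locus consistent with the curve used in the multivariate
analyses. Percent vs fraction reflectance is auto-detected (max > 1.5 ⇒
percent) and normalised internally.

## Scent processing

The floral-volatile filter keeps a compound, species by species, when
its mean floral peak area is ≥ 10× its mean vegetative peak area or when
it is absent from that species' vegetative samples. The 10-fold rule is
evaluated on species means by default (a per-sample variant is exposed
via `per_sample=True`); species without vegetative controls keep all
compounds, with a warning. Entries failing the rule are zeroed for that
species, so a compound can be floral in one species and vegetative
contamination in another; applying the filter twice is a no-op. Samples
left with no retained compound are dropped with a warning.

Transforms are fixed in the order filter → relative amounts (rows sum to
100%) → fourth root (semi-quantitative) or binarise (qualitative).
Presence/absence uses strictly > 0 after the filter; no trace-level cut
is applied. Unidentified compounds are ordinary named unknowns and take
part in every analysis. Similarities are reported in percent:
Bray–Curtis 100(1 − Σ|a−b|/Σ(a+b)), Sørensen 100·2|A∩B|/(|A|+|B|);
Sørensen equals Bray–Curtis on binarised data, which the tests assert.

## ANOSIM and NMDS

ANOSIM ranks all n(n−1)/2 dissimilarities once (mid-ranks for ties) and
computes R = (r̄_between − r̄_within)/(M/2). The test is one-tailed toward
large R, with p = (1 + #{R_perm ≥ R_obs})/(1 + n_perm) under random
relabellings that preserve group sizes. For two groups with at most
n_perm distinct relabellings, all C(n, n₁) of them are enumerated and
p = #{R ≥ R_obs}/C(n, n₁) exactly (the observed labelling is one of
them); pairwise post-hoc tests therefore become exact automatically for
the small per-pair sample sizes typical of this kind of study. Post-hoc
p-values are reported unadjusted, with an optional Bonferroni column.
Because R depends only on ranks, any monotone transform of the
dissimilarities leaves it unchanged — asserted as a property test.

NMDS minimises Kruskal stress-1 by non-metric SMACOF (majorisation with
isotonic regression, via scikit-learn) from one classical-scaling
(Torgerson) start plus `n_starts` random starts, returning the best
configuration; non-convergence returns the best-so-far with a warning.

Colour curves enter ANOSIM as one vector per measured flower (tip/base
averaged), standardised so each curve's maximum is 100%, compared by
Euclidean distance.

## Trees and tree-derived matrices

Newick I/O is handled by dendropy; trees must have unique tip labels
and branch lengths everywhere (a missing root length is taken as 0).
Ultrametricity is checked as equal root-to-tip depths within a relative
1e−6. Alignment between trees and trait tables is strictly by label,
with a hard error on mismatch.

- **Brownian covariance** C_ij = depth of the MRCA of tips i, j;
  diagonal = tip depths.
- **Pagel transform** scales the off-diagonal of C by λ; on ultrametric
  trees C(λ) stays positive definite on the whole [0, 1] interval, so
  the λ search is bounded there and non-ultrametric trees are rejected
  for λ fitting.
- **Abouheif proximity** W_ij = 1/Π dd_v over internal nodes on the
  i–j path, where dd_v counts the node's children (polytomies therefore
  dilute proximity). It is purely topological — invariant to branch
  lengths and child order. The default matrix is zero-diagonal and
  row-normalised, which is what the Moran's-I form of the Abouheif test
  uses; the original formulation with diagonal terms making each row sum
  to 1 is available as `normalize="ori"`. The pPCA uses the symmetrised
  row-normalised matrix.

## Signal statistics

**Cmean** is Moran's I, I = z'Wz/z'z with z centred, under Abouheif
proximity, tested by permuting trait values across tips (default 999
permutations). **Blomberg's K** follows the standard ratio-of-ratios
with the GLS phylogenetic mean â = (1'C⁻¹x)/(1'C⁻¹1):

K = [(x−â)'(x−â) / (x−â)'C⁻¹(x−â)] / [(tr C − n/(1'C⁻¹1)) / (n−1)].

**Kmult** replaces the two quadratic forms by sums over the p trait
columns with the same normalising constant, so p = 1 reduces to K
exactly (asserted to 1e−10); the test permutes whole rows of the trait
matrix across tips (999 permutations — the univariate default is applied
to the multivariate test as well, since no separate convention exists).
Both permutation tests share the one-tailed, +1/+1-corrected p
convention and are bit-reproducible given (seed, n_perm).

**Pagel's λ** maximises the profile log-likelihood of
Normal(μ1, σ²C(λ)) with μ and σ² profiled analytically; a 21-point grid
scan brackets the optimum before bounded scalar refinement (xatol 1e−6),
and the boundary candidates λ = 0 and λ = λ_max are always compared
against the interior optimum, with ties going to λ = 0 so a flat
likelihood reports no signal. The p-value refers 2(lnL(λ̂) − lnL(0)) to
χ² with 1 df without a boundary correction — matching the default of the
common fitting software, and producing the characteristic "λ = 0, p = 1"
signature at the boundary. (A 50:50 boundary mixture would halve
p-values for λ̂ > 0; the uncorrected convention was chosen for
comparability and is conservative.) The univariate implementation was
verified against an independent R implementation (phytools) to ~1e−5 in
λ̂ and lnL on the same data.

Signal tests on pPCA structures run on the raw PC score vectors of the
global axis (PC1) and the local axis (last PC), not re-standardised.

## Phylogenetic PCA

Columns are centred with uniform row weights 1/n (optionally divided by
their sd; the covariance-style default suits commensurate units such as
percent reflectance or fourth-root relative amounts, and a `scale` flag
is provided). The decomposition diagonalises H = (1/n)X_c'W_sym X_c, so
the k-th eigenvalue equals var(score_k) × I(score_k) identically — the
package asserts this within 1e−8 for every axis. Since centring reduces
the row space to rank n − 1, the spectrum is truncated to
min(p, n − 1) axes by dropping the numerically null eigenvalues; with
more variables than species the local structure is therefore the
(n − 1)-th axis (PC13 for 14 species, PC10 for 11). Each loading column
is oriented so its largest-magnitude element is positive, making reports
reproducible under eigenvector sign indeterminacy.

## Synthetic data

The generator produces the study conditions end to end:

- **Trees**: pure-birth (Yule) trees, root splitting at time 0, unit
  rate, final extension past the last speciation, rescaled to unit
  depth; 11–14 tips in the presets.
- **Traits**: Normal(0, σ²C(λ)) by Cholesky, independent columns.
- **Spectra**: species mean curves are sums of Gaussian peaks — a
  violet-blue peak (centre 400–440 nm, width 22 nm), an orange-red peak
  (centre 620–690 nm, width 45 nm) and an optional UV shoulder at
  350 nm in half the species — with log-heights evolved by BM on the
  tree (σ² = 0.04) so colour covaries with phylogeny when λ_true = 1.
  Each of 3 flowers per species contributes a tip measurement and a
  slightly damped (×0.92) base measurement with iid Gaussian noise
  (sd 1% reflectance), clipped at 0.
- **Scent**: a 150-compound pool partitioned over the seven compound
  classes in study-like proportions (40/30/12/8/6/4/2 monoterpenes
  through irregular terpenes, the remainder named unknowns). Internal
  clades contribute marker compounds inherited by descendants with 10%
  loss; species add idiosyncratic compounds to reach 10–55 compounds.
  Per-species profiles are geometric-decay weights whose expected top-5
  share is drawn uniformly from 43–93%, realised per sample by a
  Dirichlet draw (concentration 150) times a lognormal total peak area;
  2–12 samples per species. Vegetative controls (3 per species) carry
  ubiquitous leaf aliphatics plus ~15% of each species' floral compounds
  at 15–40% of the floral mean, which the 10-fold filter must remove.
  A species-exclusive preset assigns disjoint compound subsets, the
  regime in which ANOSIM must return R = 1 globally and for all pairs.

What the generator does **not** emulate: chemically meaningful compound
identities and co-occurrence constraints, retention-time or
mass-spectral structure, instrument drift, correlated (non-iid) spectral
noise, or non-Brownian trait evolution (no Ornstein–Uhlenbeck pull, no
rate shifts). Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative models, not robustness
to every failure mode of real spectra or chromatograms.

## Numerical conventions and problem sizes

All randomness flows through `numpy.random.default_rng` seeds recorded
in every result object and report. Likelihoods use Cholesky
factorisations; singular covariances raise rather than regularise.
Calibration checks in the test suite use sizes chosen for tight Monte
Carlo error at desk scale: 500 replicates for the Kmult-under-BM mean
(±0.1 band), 500 null datasets for type-I error (binomial 2σ ≈ 0.02 at
α = 0.05), 200 replicates at n = 50 tips for λ recovery, and exhaustive
enumeration (≤ 70 relabellings) as the ANOSIM oracle.

## Known limitations

- ANOSIM exact enumeration is implemented for two groups (the post-hoc
  case); multi-group global tests always sample.
- The λ likelihood assumes a single trait; multivariate λ is not
  implemented (Kmult covers the multivariate question).
- pPCA axis truncation assumes the only null eigenvalues come from
  centring; a genuinely rank-deficient trait table with fewer than
  n − 1 informative dimensions will still report min(p, n − 1) axes,
  some with near-zero eigenvalues.
- The hexagon model is the only colour space offered; receptor-noise
  limited models are out of scope.
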