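# Methods

This note records the models, defaults and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
numerical conventions.

## Synthetic multi-species atlas

The generator produces, per species, a sparse gene-by-cell count
matrix with a class → type hierarchy and full ground-truth records.

**Phylogeny.** `simulate_tree` draws a random ultrametric binary tree:
n−2 merge heights uniform on (0, depth) plus the root pinned at
`depth`, with random pair joins. Branch lengths are interpreted as
substitutions per 100 bp; the default depth of 17.5 puts the maximum
pairwise distance at 35, spanning a vertebrate-scale range.

**Divergence of class programs.** Each class's mean log-expression
program evolves by independent Gaussian increments per branch. For a
target pairwise curve f(t) — f(t) = a·t (brownian), a·t^b (powerlaw,
default a = 0.4, b = 0.3), or a(1 − e^(−bt)) (OU) — branch variances
are set to differences of the depth potential G(τ) = −f(2(D−τ))/2, so
that the summed variance along the path between any two leaves at
distance t equals f(t) *exactly*. The per-gene expected squared
difference between two species is then f(t) and the mean over genes
converges to it; no asymptotic approximation is involved. All three
models are generated by this one second-moment construction; the OU
option matches the OU divergence curve rather than simulating an
actual mean-reverting process, which is sufficient because all
downstream fitting uses second moments only. The construction requires
f to be increasing, which holds for all three models.

**Conserved class markers.** Canonical class markers are, by
definition, genes whose class-specific expression is conserved across
vertebrates; the generator therefore excludes the class-signature
gene blocks from divergence increments. Everything else — type
markers, attribute genes, background — drifts.

**Counts.** Per cell, the mean log expression is class program + type
offset + attribute effects + species shift + replicate batch effect.
Type offsets (default: 25 marker genes elevated by 1.2 log-units) are
shared across species, so the planted orthotype map is the identity on
type names; a per-species global shift (sd 0.4 per gene) is the
translation GAGE models; replicate batch effects default to sd 0.1.
Counts are negative binomial around the exponentiated mean scaled to a
lognormal library size (mean 5,000, σ = 0.3), with dispersion
(size) 10 — var = m + m²/10, a moderately overdispersed droplet-like
regime; a Poisson-lognormal observation model is available. The
dispersion is a free choice (configurable) since no canonical value
exists for such data.

**Attributes.** Types of one class (default RGC) carry a polarity
(ON/OFF) and kinetics (sustained/transient) assignment, cycling
through the four quadrants or following explicit `quadrant_sizes`.
Each attribute acts additively (±effect/2) on its own disjoint
30-gene block, which makes planted-axis recovery well defined.

**Ohnologs.** A chosen fraction of one species' genes is split into
`g+'a'`/`g+'b'` pairs whose counts sum cell-wise to the original
(binomial thinning with a per-gene split probability uniform on
0.3–0.7), with the orthology table updated to a 1:2 mapping plus an
ohnolog-group record.

**What the generator does not emulate:** read-level noise, doublets,
ambient RNA, dropout beyond the count model, unbalanced type
abundances, many-to-many non-ohnolog paralogy, and non-additive
attribute × species interactions. Passing recovery tests therefore
demonstrates correctness of the algorithms under a clean generative
model, not performance on real tissue data.

## Shared feature space

1:1 orthologue selection is strict: a reference gene is kept only if
every species in the comparison set has exactly one orthologue for it
(after ohnolog collapsing; a collapsed pair counts as one composite
orthologue only when its members were the gene's sole orthologues).
Cardinality is always inferred by grouping the pair table, never
trusted from file annotations. Adding species can only shrink the
list. Many-to-many non-ohnolog paralogues are excluded (a flag
controls whether collapsing is attempted at all).

## Per-species classification

QC removes cells with total counts outside mean ± 2 s.d. (boundaries
kept; the s.d. = 0 degenerate case keeps everything) and replicates
with fewer than 50 cells of the class of interest. Normalization is
counts-per-10,000 followed by log(x+1). Clustering is 2,000 HVGs →
20 PCs → k = 20 SNN graph → Leiden, all seeded. Class assignment
scores each cluster by the mean normalized expression of each class's
marker panel (case-insensitive symbol matching) and assigns the argmax
class, labelling clusters under a 0.25 score floor as "other".

Type refinement overclusters at resolution 1.1, prunes clusters, and
merges indistinguishable ones. Published workflows leave the pruning
criteria qualitative; ours are configurable defaults: a
cluster is pruned when (i) its top marker's log-fold-change is below
the DE threshold or over 90% of outside cells exceed the midpoint
between inside and outside mean expression ("widely expressed"
markers); (ii) its mean library size is below 0.5× the median cluster
mean; or (iii) at least 3 of its top-20 markers are canonical markers
of a contaminant class. If pruning removes more than 20% of cells,
clustering is re-run once. Merging tests mutual-nearest centroid
pairs with a two-sided Wilcoxon rank-sum: a gene "distinguishes" a
pair if |Δ log-expression| ≥ 0.5, BH-adjusted p < 0.01, and detection
≥ 25% in the higher cluster; pairs with no such gene merge, iterated
to a fixpoint.

## Divergence fitting

Pseudobulk profiles are cell-averaged normalized log expression per
(species, class), z-scored across genes (mean 0, s.d. 1). MSD defaults
to the mean over genes of squared differences, with the raw sum
‖a−b‖² exposed — the two differ by the gene count, which rescales
only the fitted amplitude, not exponents, rates or R². The power law
is fitted by nonlinear least squares initialized from log-log OLS; OU
by nonlinear least squares; linear in closed form. R² is computed as
1 − SS_res/SS_tot on the original (untransformed) scale for all three
models so they are comparable; fits are performed separately per
class. Non-convergence raises an error carrying the initializer fit
(`fit_all_models` falls back to it).

## Orthotype inference

Cells are downsampled to ≤200 per species cluster, combined on the
shared feature space, and reduced by per-species HVG selection
(features variable in ≥2 species), scaling, and joint PCA. Batch
correction is a self-contained mutual-nearest-neighbour shift: batches
are merged into a reference pool largest-first; for each incoming
batch, MNN pairs (k = 20 both ways) define anchor difference vectors,
and each cell is corrected by a Gaussian-kernel-weighted average of
anchor corrections (bandwidth 2× the median nearest-anchor distance,
with kernel weights stabilized so every cell is corrected by at least
its nearest anchors). Any external embedding can be substituted; the
contract is behavioural (orthologous types end up mutual nearest
neighbours more often than non-orthologous ones).

Orthotypes are Leiden clusters of the integrated embedding at
resolution 0.5. "Transcriptomically proximal" orthotypes are sister
leaves of an average-linkage dendrogram of orthotype centroids in the
integrated space; a sister pair whose species sets are disjoint is
merged (such disjointness indicates a residual species split), applied
to a fixpoint — merging is idempotent and never increases the count.

A species cluster "maps specifically" when its modal orthotype is
unique and holds ≥50% of its cells (threshold configurable); exact
ties are ambiguous. Orthotype markers are Wilcoxon rank-genes per
orthotype, each annotated with the number of species expressing the
gene in ≥30% of the orthotype's cells. The stability scan repeats
downsample + cluster across trials and resolutions, reporting the
orthotype count, mean pairwise ARI on shared cells, per-cell
reproducibility after optimal cluster matching, and the number of
species-specific orthotypes (>95% of cells from one species).

## FLDA

With attributes A, B, C (polarity, kinetics, species), the total
covariance splits as Σ_T = Σ_A + Σ_B + Σ_C + Σ_e where each Σ_attr is
the cell-count-weighted covariance of that attribute's level means
about the grand mean; interactions and within-group variance remain
in Σ_e, and the split is additive by construction (trace identity
holds to machine precision). The design must populate every
attribute-level combination. Each attribute's axis is the leading
generalized eigenvector of (Σ_attr, sum of all other components +
ridge·I); the ridge defaults to 1e-3 × the mean diagonal of the
denominator, needed when genes are not few relative to cells.
Two-level attributes give rank-one numerators, so the eigenvalue has
the closed form w₊w₋·dᵀ(D + εI)⁻¹d with d the level-mean difference —
`rank_quadruples` uses this identity with per-type sufficient
statistics, and a test pins its equality to the general eigensolver.

Quadruple ranking scores each candidate by the sum of the polarity and
kinetics generalized eigenvalues of the combined 8-type design (the
`min` of the two is available as an alternative; both are reported).
Feature pre-selection ranks genes by variance across type centroids
after centering within each species side, keeping
type-distinguishing genes rather than genes dominated by the global
species shift; the default of 100 features keeps the feature count
well below the cell count, because the eigenvalues are whitened by an
estimated covariance whose sampling noise grows with the
feature-to-cell ratio and would otherwise drown the between-candidate
signal. Ties break by score then lexicographic type names.

The bundled 20-type attribute catalogue is synthetic: quadrant sizes
6/6/2/6 (ON-s/ON-t/OFF-s/OFF-t), with OFF-sustained as the smallest
group, yielding 6·6·2·6 = 432 one-per-quadrant candidates.

## GAGE

The translation fit of a candidate quadruple (m₁..m₄) to a reference
quadruple (p₁..p₄) uses the least-squares translation Δ = mean(m) −
mean(p); residuals rᵢ = (mᵢ − Δ) − pᵢ sum to zero over corners, and
EV = 1 − Σ‖rᵢ‖²/Σ‖pᵢ − p̄‖². The denominator is the *reference* shape's
scatter (a pooled-scatter variant could be added, but the asymmetric
convention matches the question "does the candidate reproduce the
reference geometry"); EV = 1 iff the shapes are exact translates, can
be negative, and is invariant to adding any constant vector to either
centroid set. A degenerate reference (all corners equal) is an error.

The exhaustive search enumerates all ordered assignments of four
distinct types to the four slots — n(n−1)(n−2)(n−3) tuples, 3,575,880
at n = 45 — and scores them in one vectorized pass via Gram-matrix
identities (sub-second enumeration, seconds for scoring). The
constrained mode restricts each slot to attribute-matching types and
agrees exactly with the exhaustive scores on its subset. Ranking is
deterministic (EV descending, then lexicographic names).

## Evaluation conditions

`orthotyper.benchmarks` fixes the reference study conditions:
divergence recovery uses 100 runs of 15 species (105 pairs) × 4,000
genes under a = 0.4, b = 0.3; orthotype recovery uses 14 planted types
× 5 species × 60 cells (≈4,000 cells after QC and balanced
downsampling); GAGE recovery hides a translated quadruple (noise s.d.
0.1 per gene) among 20 decoys; FLDA axis recovery uses a balanced
2×2×2 design with 250 cells per combination, 60 genes and SNR 5, and
ranking success uses 50 two-species atlases with the 20-type
catalogue. These sizes were chosen as a realistic but compact regime
for the respective analyses; all are parameters of the benchmark
functions.

## Known limitations

- The MNN integrator corrects species-level shifts well but does not
  model nonlinear batch distortions; replicate-level batch effects
  within species are tolerated, not corrected.
- Divergence fitting compares models by R² only; no likelihood-ratio
  or information-criterion machinery is provided.
- FLDA supports multi-level attributes in the general eigensolver but
  the ranking fast path assumes two levels per attribute.
- The amacrine class is generated like any other but no
  amacrine-specific orthotyping logic exists; cross-species
  integration of very distant species degrades with the shrinking 1:1
  feature space, which the generator only partially emulates.
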