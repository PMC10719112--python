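# orthotyper

Comparative single-cell transcriptomics of cell types across species.
Given gene-by-cell count matrices from several species, a species
phylogeny, and pairwise orthology tables, the package:

- builds a **shared 1:1 orthologue feature space**, collapsing
  whole-genome-duplication paralogue ("ohnolog") pairs such as
  *rbpms2a*/*rbpms2b* by summing their expression;
- runs a per-species pipeline — QC, library-size normalization to
  10,000 counts and log(x+1), 2,000 highly variable genes, 20 PCs,
  Leiden clustering — assigning clusters to the six retinal cell
  classes by canonical marker panels, and refining within-class type
  clusters by deliberate overclustering (resolution 1.1) followed by
  marker-based pruning and differential-expression-based merging;
- fits **pseudobulk expression divergence against evolutionary
  distance**: for each class, the mean squared divergence (MSD) of
  z-scored pseudobulk profiles between species pairs is modelled as a
  power law (MSD = a·t^b), a linear curve (a + b·t), or an
  Ornstein–Uhlenbeck saturation (a(1 − e^(−bt))), compared by
  R² on the original scale;
- infers **orthotypes** — cross-species conserved types — by
  downsampling to ≤200 cells per cluster, mutual-nearest-neighbour
  species integration, Leiden clustering at resolution 0.5, and
  merging of transcriptomically adjacent orthotypes whose species
  sets are disjoint; species clusters are mapped to orthotypes by
  confusion matrices whose columns sum to 100%;
- matches type quadruples across species with two statistics:
  **FLDA** (factorized linear discriminant analysis), which splits the
  expression covariance as Σ_T = Σ_A + Σ_B + Σ_C + Σ_e over
  polarity/kinetics/species attributes and scores candidates by the
  generalized eigenvalues of the polarity and kinetics axes, and
  **GAGE** (geometric analysis of gene expression), which scores how
  well four candidate centroids reproduce a four-cornered reference
  shape up to a pure translation, by the fraction of explained
  variance EV = 1 − Σᵢ‖(mᵢ−Δ)−pᵢ‖² / Σᵢ‖pᵢ−p̄‖².

A fully parameterized synthetic multi-species generator
(`orthotyper.synthetic`) plants every structure the pipeline is meant
to find — class programs diverging along a random ultrametric tree
under a chosen model, orthologous types shared across species,
factorial ON/OFF × sustained/transient attribute programs, replicate
batch effects, ohnolog duplicates — so each stage is verified by
parameter recovery.

## Worked example

`examples/` contains one short script per capability. Fitting the
three divergence models to 105 simulated species pairs generated under
MSD = 0.4·t^0.3 (`python examples/02_divergence_fit.py`):

```
105 species pairs, distances 1.0-35.0 substitutions/100bp
  powerlaw  a= 0.403 b= 0.298 R^2=0.9594
  linear    a= 0.639 b= 0.015 R^2=0.8810
  ou        a= 1.184 b= 0.102 R^2=0.8860
```

The power law wins on R² and recovers the generating amplitude and
exponent; the linear and OU fits are clearly worse, which is how the
saturating-but-not-plateauing character of between-species expression
divergence is diagnosed. Orthotype recovery
(`python examples/03_orthotype_recovery.py`):

```
planted types: 14 | recovered orthotypes: 14
ARI vs planted labels: 0.997
species clusters mapping specifically: 100%
```

All 14 planted orthologous types are recovered across 5 species after
integration, and every species cluster maps specifically (≥50% of its
cells) to a single orthotype. `04_flda_ranking.py` and
`05_gage_search.py` show the planted orthologous quadruple ranking
first among 432 attribute-consistent FLDA candidates and among 255,024
exhaustive GAGE slot assignments.

A thin CLI wraps the same functions:
`orthotyper {simulate,features,classify-cells,divergence,gage,run}`.

## Layout

```
src/orthotyper/
  synthetic.py   multi-species count simulator with recorded ground truth
  orthology.py   MatrixMarket/TSV/Newick I/O, ohnolog collapsing, 1:1 selection
  classify.py    QC, normalization, clustering, class assignment, type refinement
  divergence.py  pseudobulk, MSD, power/linear/OU fits, correlation structure
  orthotype.py   integration, orthotype clustering, merging, confusion, stability
  flda.py        covariance factorization, discriminant axes, quadruple ranking
  gage.py        centroid shapes, translation fits, exhaustive search
  benchmarks.py  seeded end-to-end evaluation runs
  pipeline.py    config-driven orchestration and fixture generation
  cli.py         thin command-line layer
```
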