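"""Multi-species single-cell count simulator with planted ground truth.

Generates per-species gene-by-cell count matrices with a class/type
hierarchy, class expression programs that diverge along a species
phylogeny under a configurable second-moment model (Brownian, power-law
or Ornstein-Uhlenbeck), planted cross-species orthologous types,
factorial ON/OFF x sustained/transient attribute structure for the
ganglion-cell class, replicate batch effects, and an optional species
with duplicated ("ohnolog") gene pairs.

Every planted parameter is recorded in ``SyntheticAtlas.truth`` so each
downstream stage can be validated by parameter recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal

import anndata as ad
import dendropy
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .orthology import OrthologyTable

__all__ = [
    "SimulationConfig",
    "SyntheticAtlas",
    "simulate_tree",
    "simulate_class_programs",
    "simulate_atlas",
    "simulate_attribute_design",
    "emit_ohnolog_duplicates",
]

DEFAULT_CLASSES = {
    "PR": 40,
    "HC": 40,
    "BC": 40,
    "AC": 40,
    "RGC": 40,
    "MG": 40,
}

QUADRANTS = [
    ("ON", "sustained"),
    ("ON", "transient"),
    ("OFF", "sustained"),
    ("OFF", "transient"),
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-species atlas.

    Defaults emulate a small vertebrate retina survey: six cell
    classes, a handful of types per class shared across species
    (planted orthotypes), class programs diverging under a power law
    with amplitude ``a = 0.4`` and exponent ``b = 0.3`` over tree
    depths on the scale of tens of substitutions per 100 bp, and
    negative-binomial counts with moderate over-dispersion.
    """

    seed: int = 0
    n_species: int = 5
    tree_depth: float = 17.5  # root-to-leaf; max pairwise distance = 2x
    n_genes: int = 2000
    classes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASSES))
    types_per_class: int = 5
    cells_per_type: int = 60
    n_replicates: int = 2
    divergence_model: Literal["brownian", "ou", "powerlaw"] = "powerlaw"
    divergence_params: dict[str, float] = field(
        default_factory=lambda: {"a": 0.4, "b": 0.3}
    )
    class_effect: float = 1.5  # log-expression elevation of class signature genes
    type_effect: float = 1.2  # log-expression elevation of type marker genes
    markers_per_type: int = 25
    attribute_class: str = "RGC"
    attribute_effects: dict[str, float] = field(
        default_factory=lambda: {"polarity": 1.0, "kinetics": 1.0}
    )
    markers_per_attribute: int = 30
    quadrant_sizes: tuple[int, int, int, int] | None = None
    species_shift_sd: float = 0.4  # global per-species log shift (GAGE translation)
    batch_effect_sd: float = 0.1
    library_size_mean: float = 5000.0
    library_size_sigma: float = 0.3  # lognormal sigma of per-cell library sizes
    count_model: Literal["nb", "poisson-lognormal"] = "nb"
    nb_dispersion: float = 10.0  # NB size parameter; var = m + m^2/size
    pln_sigma: float = 0.3
    baseline_mean: float = 1.0
    baseline_sd: float = 0.5
    ohnolog_species: str | None = None
    ohnolog_fraction: float = 0.0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.tree_depth <= 0:
            raise ValueError("tree_depth must be > 0")
        if not 0.0 <= self.ohnolog_fraction <= 1.0:
            raise ValueError("ohnolog_fraction must lie in [0, 1]")
        if self.divergence_model not in ("brownian", "ou", "powerlaw"):
            raise ValueError(f"unknown divergence model {self.divergence_model!r}")
        for key in ("a", "b"):
            if self.divergence_model != "brownian" and self.divergence_params.get(key, 1.0) <= 0:
                raise ValueError(f"divergence parameter {key!r} must be > 0")
        if self.divergence_params.get("a", 1.0) <= 0:
            raise ValueError("divergence parameter 'a' must be > 0")
        needed = self._genes_needed()
        if needed > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for the configured structure "
                f"(needs >= {needed})"
            )
        if self.quadrant_sizes is not None and sum(self.quadrant_sizes) != self.types_per_class:
            raise ValueError("quadrant_sizes must sum to types_per_class")

    def _genes_needed(self) -> int:
        n_sig = sum(self.classes.values())
        n_type = len(self.classes) * self.types_per_class * self.markers_per_type
        n_attr = len(self.attribute_effects) * self.markers_per_attribute
        return n_sig + n_type + n_attr

    def species_names(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]


@dataclass
class SyntheticAtlas:
    """A simulated multi-species expression atlas plus its ground truth."""

    species: dict[str, ad.AnnData]
    tree: dendropy.Tree
    orthology: dict[str, OrthologyTable]
    truth: dict
    config: SimulationConfig

    def combined(self) -> ad.AnnData:
        """Concatenate all species on the shared (reference) gene space."""
        return ad.concat(self.species, label="species", index_unique="-", merge="same")


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_species: int, depth: float, seed: int) -> dendropy.Tree:
    """Simulate a random ultrametric binary species tree.

    Leaves sit at distance ``depth`` from the root, so the maximum
    pairwise leaf distance is ``2 * depth`` (in substitutions per
    100 bp, the unit in which branch lengths are interpreted
    throughout).
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    # merge heights (distance above the leaves), root pinned at `depth`
    if n_species == 2:
        heights = np.array([depth])
    else:
        inner = np.sort(rng.uniform(0.0, depth, size=n_species - 2))
        heights = np.append(inner, depth)

    # each lineage: (newick fragment, height of its top node)
    lineages: list[tuple[str, float]] = [
        (f"sp{i + 1:02d}", 0.0) for i in range(n_species)
    ]
    for h in heights:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (na, ha), (nb, hb) = lineages[i], lineages[j]
        merged = f"({na}:{h - ha:.17g},{nb}:{h - hb:.17g})"
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append((merged, h))
    newick = lineages[0][0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick")


def _node_times_from_root(tree: dendropy.Tree) -> dict:
    times = {}
    for node in tree.preorder_node_iter():
        parent_t = 0.0 if node.parent_node is None else times[node.parent_node]
        times[node] = parent_t + (node.edge.length or 0.0)
    return times


def _divergence_curve(model: str, params: dict[str, float]):
    """Expected MSD between two leaves as a function of tree distance t."""
    a = params["a"]
    b = params.get("b", 1.0)
    if model == "brownian":
        return lambda t: a * np.maximum(t, 0.0)
    if model == "powerlaw":
        return lambda t: a * np.power(np.maximum(t, 0.0), b)
    if model == "ou":
        return lambda t: a * (1.0 - np.exp(-b * np.maximum(t, 0.0)))
    raise ValueError(f"unknown divergence model {model!r}")


# ---------------------------------------------------------------------------
# Class program simulation
# ---------------------------------------------------------------------------

def simulate_class_programs(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    root_programs: dict[str, np.ndarray] | None = None,
    conserved_idx: np.ndarray | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Simulate per-species, per-class mean log-expression programs.

    Programs evolve along the tree by independent Gaussian increments
    per branch. Branch variances are differences of a depth potential
    chosen so that, for *every* leaf pair at tree distance ``t``, the
    summed path variance equals the configured curve ``f(t)`` exactly:
    ``f(t) = a t`` (brownian), ``a t^b`` (powerlaw) or
    ``a (1 - e^{-bt})`` (ou). The per-gene expected squared difference
    between two species therefore equals ``f(t)``, and the mean squared
    divergence over genes converges to it by the law of large numbers.

    Genes listed in ``conserved_idx`` receive no increments — they stay
    at the root program in every species (used for canonical class
    markers, which are conserved across vertebrates by definition).

    Requires an ultrametric tree (all leaves equidistant from the root).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f = _divergence_curve(config.divergence_model, config.divergence_params)

    times = _node_times_from_root(tree)
    leaf_depths = [times[leaf] for leaf in tree.leaf_node_iter()]
    depth = float(np.mean(leaf_depths))
    if not np.allclose(leaf_depths, depth, rtol=1e-6):
        raise ValueError("class-program simulation requires an ultrametric tree")

    # potential G(tau): path variance a->b = 2 * (G(t_lca->leaf span)) = f(t)
    def g(tau: float) -> float:
        return -0.5 * float(f(2.0 * (depth - tau)))

    n_genes = config.n_genes
    if root_programs is None:
        root_programs = {
            c: rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
            for c in config.classes
        }

    programs: dict[str, dict[str, np.ndarray]] = {}
    # independent evolution per class
    for cls in config.classes:
        node_values = {tree.seed_node: root_programs[cls]}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            var = g(times[node]) - g(times[node.parent_node])
            var = max(var, 0.0)
            if var > 0:
                increment = rng.normal(0.0, np.sqrt(var), size=n_genes)
                if conserved_idx is not None:
                    increment[conserved_idx] = 0.0
            else:
                increment = 0.0
            node_values[node] = node_values[node.parent_node] + increment
        for leaf in tree.leaf_node_iter():
            programs.setdefault(leaf.taxon.label, {})[cls] = node_values[leaf]
    return programs


# ---------------------------------------------------------------------------
# Atlas simulation
# ---------------------------------------------------------------------------

def _allocate_genes(config: SimulationConfig) -> dict:
    """Assign disjoint gene index blocks to classes, types and attributes."""
    cursor = 0
    layout: dict = {"class_signature": {}, "type_markers": {}, "attribute": {}}
    for cls, n_sig in config.classes.items():
        layout["class_signature"][cls] = np.arange(cursor, cursor + n_sig)
        cursor += n_sig
    for cls in config.classes:
        for k in range(config.types_per_class):
            idx = np.arange(cursor, cursor + config.markers_per_type)
            layout["type_markers"][(cls, k)] = idx
            cursor += config.markers_per_type
    for attr in config.attribute_effects:
        layout["attribute"][attr] = np.arange(cursor, cursor + config.markers_per_attribute)
        cursor += config.markers_per_attribute
    layout["background"] = np.arange(cursor, config.n_genes)
    return layout


def _type_attributes(config: SimulationConfig) -> list[tuple[str, str]]:
    """Assign a (polarity, kinetics) quadrant to each attribute-class type."""
    if config.quadrant_sizes is not None:
        out = []
        for q, size in zip(QUADRANTS, config.quadrant_sizes):
            out.extend([q] * size)
        return out
    return [QUADRANTS[k % 4] for k in range(config.types_per_class)]


def _draw_counts(rng: np.random.Generator, lam: np.ndarray, config: SimulationConfig) -> np.ndarray:
    if config.count_model == "nb":
        r = config.nb_dispersion
        p = r / (r + lam)
        return rng.negative_binomial(r, p)
    if config.count_model == "poisson-lognormal":
        rate = lam * np.exp(rng.normal(0.0, config.pln_sigma, size=lam.shape))
        return rng.poisson(rate)
    raise ValueError(f"unknown count model {config.count_model!r}")


def simulate_atlas(config: SimulationConfig) -> SyntheticAtlas:
    """Simulate the full multi-species atlas from a :class:`SimulationConfig`.

    The per-cell mean log expression is the sum of the species/class
    program, a planted type offset shared across species (so the truth
    orthotype map is the identity bijection on type names), additive
    polarity/kinetics effects on disjoint gene sets for the attribute
    class, a global per-species shift (the translation GAGE models),
    and a per-replicate batch effect. Counts are drawn from a negative
    binomial (or Poisson-lognormal) around the exponentiated mean,
    scaled to a lognormal per-cell library size.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_species, config.tree_depth, seed=int(rng.integers(2**31)))
    layout = _allocate_genes(config)
    conserved = np.concatenate(list(layout["class_signature"].values()))
    programs = simulate_class_programs(tree, config, rng=rng, conserved_idx=conserved)
    species_names = config.species_names()
    gene_ids = np.array([f"g{i:05d}" for i in range(config.n_genes)])

    # class signatures: elevated in their class in every species
    for cls, idx in layout["class_signature"].items():
        for s in species_names:
            for c2 in config.classes:
                if c2 == cls:
                    programs[s][c2] = programs[s][c2].copy()
                    programs[s][c2][idx] += config.class_effect

    # shared type offsets (planted orthotypes)
    type_offsets: dict[tuple[str, int], np.ndarray] = {}
    for cls in config.classes:
        for k in range(config.types_per_class):
            off = np.zeros(config.n_genes)
            off[layout["type_markers"][(cls, k)]] = config.type_effect
            type_offsets[(cls, k)] = off

    # factorial attribute effects for the attribute class
    attrs = _type_attributes(config)
    attr_vectors: dict[str, np.ndarray] = {}
    for attr, eff in config.attribute_effects.items():
        v = np.zeros(config.n_genes)
        v[layout["attribute"][attr]] = eff
        attr_vectors[attr] = v

    species_shift = {
        s: rng.normal(0.0, config.species_shift_sd, size=config.n_genes)
        for s in species_names
    }
    batch_shift = {
        (s, r): rng.normal(0.0, config.batch_effect_sd, size=config.n_genes)
        for s in species_names
        for r in range(config.n_replicates)
    }

    adatas: dict[str, ad.AnnData] = {}
    for s in species_names:
        blocks, obs_rows = [], []
        for cls in config.classes:
            for k in range(config.types_per_class):
                type_name = f"{cls}_{k + 1}"
                mu = programs[s][cls] + type_offsets[(cls, k)] + species_shift[s]
                polarity = kinetics = ""
                if cls == config.attribute_class:
                    polarity, kinetics = attrs[k]
                    mu = mu + (0.5 if polarity == "ON" else -0.5) * attr_vectors.get("polarity", 0.0)
                    mu = mu + (0.5 if kinetics == "sustained" else -0.5) * attr_vectors.get("kinetics", 0.0)
                for rep in range(config.n_replicates):
                    n_cells = config.cells_per_type // config.n_replicates
                    if rep == 0:
                        n_cells += config.cells_per_type % config.n_replicates
                    mu_rep = mu + batch_shift[(s, rep)]
                    m = np.exp(mu_rep)
                    libs = rng.lognormal(
                        np.log(config.library_size_mean) - config.library_size_sigma**2 / 2,
                        config.library_size_sigma,
                        size=n_cells,
                    )
                    lam = np.outer(libs, m / m.sum())
                    counts = _draw_counts(rng, lam, config)
                    blocks.append(sp.csr_matrix(counts))
                    obs_rows.extend(
                        {
                            "species": s,
                            "replicate": f"rep{rep + 1}",
                            "class": cls,
                            "type": type_name,
                            "polarity": polarity,
                            "kinetics": kinetics,
                        }
                        for _ in range(n_cells)
                    )
        X = sp.vstack(blocks).tocsr()
        obs = pd.DataFrame(obs_rows)
        obs.index = [f"{s}_cell{i:05d}" for i in range(len(obs))]
        adata = ad.AnnData(X=X, obs=obs)
        adata.var_names = gene_ids
        adatas[s] = adata

    orthology = {
        s: OrthologyTable.identity(species=s, genes=list(gene_ids))
        for s in species_names
        if s != species_names[0]
    }

    quadrant_first: dict[tuple[str, str], str] = {}
    for k, q in enumerate(attrs):
        quadrant_first.setdefault(q, f"{config.attribute_class}_{k + 1}")
    truth = {
        "programs": programs,
        "type_offsets": {f"{c}_{k + 1}": v for (c, k), v in type_offsets.items()},
        "gene_layout": layout,
        "attribute_vectors": attr_vectors,
        "species_shift": species_shift,
        "orthotype_map": {
            f"{c}_{k + 1}": f"{c}_{k + 1}"
            for c in config.classes
            for k in range(config.types_per_class)
        },
        "type_attributes": {
            f"{config.attribute_class}_{k + 1}": {"polarity": p, "kinetics": kin}
            for k, (p, kin) in enumerate(attrs)
        },
        "quadruple": [quadrant_first[q] for q in QUADRANTS if q in quadrant_first],
    }

    atlas = SyntheticAtlas(
        species=adatas, tree=tree, orthology=orthology, truth=truth, config=config
    )
    if config.ohnolog_species is not None and config.ohnolog_fraction > 0:
        atlas = emit_ohnolog_duplicates(
            atlas,
            config.ohnolog_species,
            config.ohnolog_fraction,
            seed=int(rng.integers(2**31)),
        )
    return atlas


def marker_panel(atlas: SyntheticAtlas, n_markers: int = 5) -> dict[str, list[str]]:
    """Class marker panel derived from the planted class signatures."""
    layout = atlas.truth["gene_layout"]["class_signature"]
    return {
        cls: [f"g{i:05d}" for i in idx[:n_markers]] for cls, idx in layout.items()
    }


def simulate_attribute_design(
    n_per_combo: int = 250,
    n_genes: int = 60,
    effects: dict[str, float] | None = None,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, dict[str, np.ndarray]]:
    """Simulate a balanced 2x2x2 factorial expression design.

    Each attribute (polarity, kinetics, species by default) acts
    additively along its own planted direction on a disjoint gene set,
    plus isotropic Gaussian noise — the well-specified setting in which
    factorized discriminant axes should recover the planted directions.
    Returns (cells x genes matrix, per-cell attribute table, planted
    effect direction per attribute).
    """
    if effects is None:
        effects = {"polarity": 1.0, "kinetics": 1.0, "species": 1.0}
    rng = np.random.default_rng(seed)
    attrs_levels = {
        "polarity": ("ON", "OFF"),
        "kinetics": ("sustained", "transient"),
        "species": ("mouse", "primate"),
    }
    names = list(effects)
    block = max(1, n_genes // (2 * len(names)))
    dirs: dict[str, np.ndarray] = {}
    for i, a in enumerate(names):
        v = np.zeros(n_genes)
        v[i * block : (i + 1) * block] = effects[a]
        dirs[a] = v
    rows, blocks = [], []
    for combo in itertools.product(*(attrs_levels.get(a, ("+", "-")) for a in names)):
        mu = np.zeros(n_genes)
        for a, level in zip(names, combo):
            sign = 1.0 if level == attrs_levels.get(a, ("+", "-"))[0] else -1.0
            mu = mu + sign * dirs[a]
        blocks.append(mu + rng.normal(0.0, noise_sd, size=(n_per_combo, n_genes)))
        rows.extend([dict(zip(names, combo))] * n_per_combo)
    return np.vstack(blocks), pd.DataFrame(rows), dirs


def emit_ohnolog_duplicates(
    atlas: SyntheticAtlas, species: str, fraction: float, seed: int
) -> SyntheticAtlas:
    """Duplicate a fraction of one species' genes into ohnolog pairs.

    Each selected gene ``g`` is replaced by ``g+'a'`` and ``g+'b'``
    whose counts sum, cell-wise, to the original; the species' orthology
    table maps the reference gene to the pair and records the ohnolog
    group, mirroring whole-genome-duplication paralogues such as the
    zebrafish rbpms2a/rbpms2b pair.
    """
    if species not in atlas.species:
        raise KeyError(f"unknown species {species!r}")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return atlas

    rng = np.random.default_rng(seed)
    adata = atlas.species[species]
    n_genes = adata.n_vars
    chosen = np.flatnonzero(rng.random(n_genes) < fraction)
    if chosen.size == 0:
        return atlas

    X = sp.csc_matrix(adata.X)
    genes = np.asarray(adata.var_names)
    split_p = rng.uniform(0.3, 0.7, size=chosen.size)

    new_cols, new_names, pairs_rows = [], [], []
    chosen_set = set(chosen.tolist())
    table = atlas.orthology.get(species) or OrthologyTable.identity(
        species=species, genes=list(genes)
    )
    kept_pairs = table.pairs[~table.pairs["target_gene"].isin(genes[chosen])]
    ohnolog_groups = dict(table.ohnolog_groups)
    for j in range(n_genes):
        col = X[:, j]
        if j not in chosen_set:
            new_cols.append(col)
            new_names.append(genes[j])
            continue
        i = int(np.searchsorted(chosen, j))
        dense = np.asarray(col.todense()).ravel().astype(np.int64)
        a_counts = rng.binomial(dense, split_p[i])
        b_counts = dense - a_counts
        ga, gb = genes[j] + "a", genes[j] + "b"
        new_cols.append(sp.csc_matrix(a_counts[:, None]))
        new_cols.append(sp.csc_matrix(b_counts[:, None]))
        new_names.extend([ga, gb])
        ref = table.reference_of(genes[j])
        pairs_rows.append({"ref_gene": ref, "target_gene": ga})
        pairs_rows.append({"ref_gene": ref, "target_gene": gb})
        ohnolog_groups[ref] = [ga, gb]

    new_X = sp.hstack(new_cols).tocsr()
    new_adata = ad.AnnData(X=new_X, obs=adata.obs.copy())
    new_adata.var_names = new_names
    new_pairs = pd.concat([kept_pairs, pd.DataFrame(pairs_rows)], ignore_index=True)
    new_table = OrthologyTable(
        species=species, pairs=new_pairs, ohnolog_groups=ohnolog_groups
    )

    new_species = dict(atlas.species)
    new_species[species] = new_adata
    new_orthology = dict(atlas.orthology)
    new_orthology[species] = new_table
    truth = dict(atlas.truth)
    truth.setdefault("ohnologs", {})[species] = {
        genes[j]: [genes[j] + "a", genes[j] + "b"] for j in chosen
    }
    return SyntheticAtlas(
        species=new_species,
        tree=atlas.tree,
        orthology=new_orthology,
        truth=truth,
        config=atlas.config,
    )
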