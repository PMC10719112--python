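"""Cross-species integration and orthotype identification.

One cell class at a time, cells from all species are embedded in a
joint space after batch (species) correction, clustered at resolution
0.5, and the resulting clusters — orthotypes — are interpreted as
evolutionarily conserved types. Species clusters are mapped onto
orthotypes through confusion matrices whose columns sum to 100%;
a species cluster "maps specifically" when at least a threshold
fraction of its cells land in a single orthotype. Orthotypes that are
transcriptomically adjacent but contain disjoint species sets are
merged, since disjointness indicates a residual species split rather
than a genuine type boundary.

Integration is a self-contained mutual-nearest-neighbour (MNN) shift
correction in joint PCA space; any external embedding can be supplied
instead, so other integrators slot in behind the same contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .classify import cluster_cells

__all__ = [
    "OrthotypeAssignment",
    "downsample_clusterwise",
    "integrate_species",
    "cluster_orthotypes",
    "merge_species_disjoint",
    "confusion_and_specificity",
    "orthotype_markers",
    "stability_scan",
]


@dataclass
class OrthotypeAssignment:
    labels: pd.Series  # per-cell orthotype label
    embedding: np.ndarray  # integrated coordinates the labels were derived in
    species: pd.Series  # per-cell species, aligned with labels
    params: dict = field(default_factory=dict)

    def n_orthotypes(self) -> int:
        return int(self.labels.nunique())


def downsample_clusterwise(
    adata: ad.AnnData,
    label_col: str = "type",
    cap: int = 200,
    seed: int = 0,
) -> ad.AnnData:
    """Keep at most ``cap`` cells per cluster, sampled without replacement.

    Equalizes cluster representation before integration so abundant
    types do not dominate the joint embedding.
    """
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for _, idx in adata.obs.groupby(label_col, observed=True).indices.items():
        idx = np.asarray(idx)
        if idx.size > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(np.sort(idx))
    keep_idx = np.sort(np.concatenate(keep))
    return adata[keep_idx].copy()


def _mnn_pairs(A: np.ndarray, B: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    ka = min(k, len(A))
    kb = min(k, len(B))
    nn_ab = NearestNeighbors(n_neighbors=kb).fit(B)
    _, ab = nn_ab.kneighbors(A)
    nn_ba = NearestNeighbors(n_neighbors=ka).fit(A)
    _, ba = nn_ba.kneighbors(B)
    ba_sets = [set(row) for row in ba]
    ia, ib = [], []
    for i, row in enumerate(ab):
        for j in row:
            if i in ba_sets[j]:
                ia.append(i)
                ib.append(j)
    return np.asarray(ia, dtype=int), np.asarray(ib, dtype=int)


def integrate_species(
    adatas: dict[str, ad.AnnData] | ad.AnnData,
    species_col: str = "species",
    n_features: int = 2000,
    n_pcs: int = 20,
    k_mnn: int = 20,
    min_shared_features: int = 30,
    seed: int = 0,
) -> ad.AnnData:
    """Embed cells from several species in a batch-corrected joint space.

    Expects normalized log expression on the shared 1:1 orthologue
    feature space. Features variable in more than one species
    ("repeatedly variable") are kept, a joint PCA is computed, and each
    species batch is corrected by mutual-nearest-neighbour shifts
    toward the growing reference pool (largest batch first): per cell,
    the correction is a Gaussian-kernel-weighted average of its MNN
    anchor difference vectors. Species labels serve only as batch
    identity. The result carries the corrected coordinates in
    ``obsm['X_integrated']``.
    """
    if isinstance(adatas, dict):
        if len(adatas) < 2:
            raise ValueError("need at least 2 species")
        combined = ad.concat(adatas, label=species_col, index_unique="-", merge="same")
    else:
        combined = adatas.copy()
    if combined.var_names.size < min_shared_features:
        raise ValueError(
            f"only {combined.var_names.size} shared features (< {min_shared_features})"
        )
    species = combined.obs[species_col].astype(str)
    n_batches = species.nunique()

    work = combined.copy()
    if work.n_vars > n_features:
        sc.pp.highly_variable_genes(
            work, n_top_genes=n_features, batch_key=species_col
        )
        nb = work.var.get("highly_variable_nbatches")
        repeat = (
            work.var["highly_variable"]
            if nb is None or n_batches < 2
            else (nb >= 2)
        )
        if int(repeat.sum()) >= min_shared_features:
            work = work[:, repeat].copy()
        else:
            work = work[:, work.var["highly_variable"]].copy()
    sc.pp.scale(work, max_value=10)
    n_comps = min(n_pcs, work.n_vars - 1, work.n_obs - 1)
    sc.tl.pca(work, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    Z = np.asarray(work.obsm["X_pca"], dtype=float).copy()

    batches = species.value_counts().index.tolist()  # largest first
    pool = np.flatnonzero(species.to_numpy() == batches[0])
    for b in batches[1:]:
        idx_b = np.flatnonzero(species.to_numpy() == b)
        ia, ib = _mnn_pairs(Z[idx_b], Z[pool], k=k_mnn)
        if ia.size == 0:
            warnings.warn(f"no MNN anchors for batch {b!r}; left uncorrected")
            pool = np.concatenate([pool, idx_b])
            continue
        diffs = Z[pool][ib] - Z[idx_b][ia]
        anchors = Z[idx_b][ia]
        nn = NearestNeighbors(n_neighbors=1).fit(anchors)
        d1, _ = nn.kneighbors(Z[idx_b])
        sigma = 2.0 * float(np.median(d1)) + 1e-12
        # kernel-weighted average of anchor corrections per cell; cells far
        # from every anchor fall back to the global mean shift
        d2 = ((Z[idx_b][:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
        W = np.exp(-(d2 - d2.min(axis=1, keepdims=True)) / (2.0 * sigma**2))
        W_sum = W.sum(axis=1, keepdims=True)
        correction = np.where(
            W_sum > 1e-12,
            (W @ diffs) / np.maximum(W_sum, 1e-300),
            diffs.mean(axis=0),
        )
        Z[idx_b] = Z[idx_b] + correction
        pool = np.concatenate([pool, idx_b])

    combined.obsm["X_pca"] = np.asarray(work.obsm["X_pca"])
    combined.obsm["X_integrated"] = Z
    combined.uns["integration"] = {
        "n_features": int(work.n_vars),
        "n_pcs": int(n_comps),
        "k_mnn": k_mnn,
        "seed": seed,
    }
    return combined


def cluster_orthotypes(
    adata: ad.AnnData,
    resolution: float = 0.5,
    k_neighbors: int = 20,
    seed: int = 0,
    use_rep: str = "X_integrated",
    species_col: str = "species",
) -> OrthotypeAssignment:
    """Leiden clustering of the integrated embedding into orthotypes."""
    if use_rep not in adata.obsm:
        raise KeyError(f"no {use_rep!r} embedding; run integrate_species first")
    Z = np.asarray(adata.obsm[use_rep])
    sc.pp.neighbors(adata, n_neighbors=k_neighbors, use_rep=use_rep, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            flavor="leidenalg",
            key_added="orthotype",
        )
    labels = pd.Series(
        ["OT" + x for x in adata.obs["orthotype"].astype(str)],
        index=adata.obs_names,
        name="orthotype",
    )
    return OrthotypeAssignment(
        labels=labels,
        embedding=Z,
        species=adata.obs[species_col].astype(str),
        params={"resolution": resolution, "k_neighbors": k_neighbors, "seed": seed},
    )


def merge_species_disjoint(assignment: OrthotypeAssignment) -> OrthotypeAssignment:
    """Merge sister orthotypes whose species sets are disjoint.

    Builds an average-linkage dendrogram of orthotype centroids in the
    integrated space; a sister pair with no species in common is a
    residual species split of one conserved type and is merged. Applied
    to a fixpoint; the orthotype count never increases.
    """
    labels = assignment.labels.copy()
    Z = assignment.embedding
    species = assignment.species.to_numpy()
    while labels.nunique() > 1:
        ids = sorted(labels.unique())
        arr = labels.to_numpy()
        cents = np.vstack([Z[arr == c].mean(axis=0) for c in ids])
        link = hierarchy.linkage(cents, method="average")
        merged = False
        n = len(ids)
        for row in link:
            a, b = int(row[0]), int(row[1])
            if a >= n or b >= n:
                continue  # only sister pairs of current orthotypes
            sp_a = set(species[arr == ids[a]])
            sp_b = set(species[arr == ids[b]])
            if sp_a.isdisjoint(sp_b):
                labels = labels.replace({ids[b]: ids[a]})
                merged = True
                break
        if not merged:
            break
    return OrthotypeAssignment(
        labels=labels,
        embedding=Z,
        species=assignment.species,
        params={**assignment.params, "species_disjoint_merged": True},
    )


def confusion_and_specificity(
    assignment: OrthotypeAssignment,
    cluster_labels: pd.Series,
    threshold: float = 50.0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Map species clusters onto orthotypes via percentage confusion matrices.

    For each species, the confusion matrix gives the percentage of each
    species cluster's cells (columns, summing to 100%) landing in each
    orthotype (rows). A cluster is called specific when its modal
    orthotype is unique and holds at least ``threshold`` percent of its
    cells; an exact tie (e.g. an even split over two orthotypes) is
    ambiguous. Returns the per-species matrices and a per-cluster
    specificity table with the overall specific fraction as its mean.
    """
    df = pd.DataFrame(
        {
            "orthotype": assignment.labels.to_numpy(),
            "cluster": np.asarray(cluster_labels),
            "species": assignment.species.to_numpy(),
        }
    )
    matrices: dict[str, pd.DataFrame] = {}
    rows = []
    for s, sub in df.groupby("species", observed=True):
        counts = pd.crosstab(sub["orthotype"], sub["cluster"])
        pct = counts / counts.sum(axis=0) * 100.0
        matrices[s] = pct
        for cluster in pct.columns:
            col = pct[cluster]
            modal = col.idxmax()
            unique_modal = int((col == col.max()).sum()) == 1
            rows.append(
                {
                    "species": s,
                    "cluster": cluster,
                    "modal_orthotype": modal,
                    "max_percent": float(col.max()),
                    "specific": bool(col.max() >= threshold and unique_modal),
                }
            )
    spec = pd.DataFrame(rows)
    return matrices, spec


def orthotype_markers(
    adata: ad.AnnData,
    assignment: OrthotypeAssignment,
    species_col: str = "species",
    min_fraction: float = 0.30,
    n_genes: int = 5,
) -> pd.DataFrame:
    """Top differential genes per orthotype with per-gene species support.

    Support of a gene for an orthotype is the number of species in
    which at least ``min_fraction`` of that orthotype's cells express
    the gene (nonzero normalized counts) — the dot-size statistic of
    orthotype marker dot plots.
    """
    work = adata.copy()
    work.obs["orthotype"] = assignment.labels.reindex(work.obs_names).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.rank_genes_groups(
            work, "orthotype", method="wilcoxon", n_genes=n_genes
        )
    names = pd.DataFrame(work.uns["rank_genes_groups"]["names"])
    species_list = sorted(work.obs[species_col].astype(str).unique())
    gene_index = {g: j for j, g in enumerate(work.var_names)}
    X = work.X
    rows = []
    for ot in names.columns:
        mask_ot = work.obs["orthotype"].to_numpy() == ot
        for rank, gene in enumerate(names[ot], start=1):
            j = gene_index[gene]
            support = 0
            for s in species_list:
                mask = mask_ot & (work.obs[species_col].to_numpy() == s)
                if mask.sum() == 0:
                    continue
                col = X[mask, j]
                frac = float((col > 0).mean()) if not sp.issparse(col) else float(
                    (col.toarray() > 0).mean()
                )
                if frac >= min_fraction:
                    support += 1
            rows.append(
                {
                    "orthotype": ot,
                    "gene": gene,
                    "rank": rank,
                    "n_species_support": support,
                    "n_species_total": len(species_list),
                }
            )
    return pd.DataFrame(rows)


def _matched_agreement(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Fraction of cells co-assigned after best cluster matching."""
    ct = pd.crosstab(pd.Series(labels_a), pd.Series(labels_b))
    r, c = linear_sum_assignment(-ct.to_numpy())
    return float(ct.to_numpy()[r, c].sum() / len(labels_a))


def stability_scan(
    adata: ad.AnnData,
    cluster_col: str,
    resolutions: list[float],
    n_trials: int = 3,
    cap: int = 200,
    seed: int = 0,
    species_col: str = "species",
    species_specific_threshold: float = 95.0,
    use_rep: str = "X_integrated",
) -> pd.DataFrame:
    """Clustering stability across resolutions and downsampling trials.

    For each resolution, repeats cluster-wise downsampling (cap cells
    per species cluster) and orthotype clustering with different
    draws, then reports the mean orthotype count, the mean pairwise
    adjusted Rand index on shared cells, the mean per-cell
    reproducibility (fraction of shared cells co-assigned after
    optimal cluster matching), and the mean number of species-specific
    orthotypes (more than ``species_specific_threshold`` percent of
    cells from one species).
    """
    if len(resolutions) < 2:
        raise ValueError("need at least 2 resolutions")
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    records = []
    for res in resolutions:
        trial_labels: list[pd.Series] = []
        n_ots, n_specific = [], []
        for _ in range(n_trials):
            sub = downsample_clusterwise(
                adata, label_col=cluster_col, cap=cap, seed=int(rng.integers(2**31))
            )
            assign = cluster_orthotypes(
                sub,
                resolution=res,
                seed=int(rng.integers(2**31)),
                use_rep=use_rep,
                species_col=species_col,
            )
            trial_labels.append(assign.labels)
            n_ots.append(assign.n_orthotypes())
            comp = pd.crosstab(assign.labels, assign.species)
            pct = comp.div(comp.sum(axis=1), axis=0) * 100
            n_specific.append(int((pct.max(axis=1) > species_specific_threshold).sum()))
        aris, agreements = [], []
        for i in range(n_trials):
            for j in range(i + 1, n_trials):
                shared = trial_labels[i].index.intersection(trial_labels[j].index)
                if len(shared) < 2:
                    continue
                la = trial_labels[i].loc[shared].to_numpy()
                lb = trial_labels[j].loc[shared].to_numpy()
                aris.append(adjusted_rand_score(la, lb))
                agreements.append(_matched_agreement(la, lb))
        records.append(
            {
                "resolution": res,
                "n_orthotypes_mean": float(np.mean(n_ots)),
                "ari_mean": float(np.mean(aris)) if aris else np.nan,
                "per_cell_reproducibility": float(np.mean(agreements))
                if agreements
                else np.nan,
                "n_species_specific_mean": float(np.mean(n_specific)),
            }
        )
    return pd.DataFrame(records)
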