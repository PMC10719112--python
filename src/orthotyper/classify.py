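"""Per-species QC, normalization, clustering and cell-class assignment.

The workflow mirrors the standard single-cell recipe: remove cells
with outlying library sizes (outside mean +/- 2 s.d. of total counts)
and under-sampled replicates, normalize each cell to 10,000 total
counts and log-transform (x -> log(x + 1)), select 2,000 highly
variable genes, reduce to 20 principal components, build a k = 20
shared-nearest-neighbour graph and cluster with the Leiden algorithm.
Clusters are assigned to one of the six major retinal cell classes by
mean expression of canonical marker panels; within a class, types are
found by deliberate overclustering (resolution 1.1) followed by
marker-based pruning and differential-expression-based merging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "ClusteringResult",
    "EmptyResultError",
    "DEFAULT_MARKER_PANEL",
    "qc_filter",
    "normalize_log",
    "cluster_cells",
    "assign_classes",
    "refine_types",
]

# canonical retinal class markers (mouse symbols)
DEFAULT_MARKER_PANEL: dict[str, list[str]] = {
    "PR": ["Arr3", "Rho", "Crx"],
    "HC": ["Calb1", "Onecut1", "Onecut2", "Lhx1"],
    "BC": ["Vsx1", "Otx2", "Grik1"],
    "AC": ["Gad1", "Gad2", "Tfap2a", "Tfap2b", "Tfap2c"],
    "RGC": ["Rbpms", "Nefl", "Nefm", "Slc17a6"],
    "MG": ["Glul", "Apoe", "Rlpb1"],
}


class EmptyResultError(RuntimeError):
    """All cells were removed by a filtering step."""


@dataclass
class ClusteringResult:
    labels: pd.Series  # per-cell cluster labels (categorical strings)
    embedding: np.ndarray  # cells x n_pcs
    params: dict = field(default_factory=dict)


def qc_filter(
    adata: ad.AnnData,
    n_sd: float = 2.0,
    target_class: str | None = None,
    class_col: str = "class",
    replicate_col: str = "replicate",
    min_cells_per_replicate: int = 50,
) -> ad.AnnData:
    """Remove count outliers and under-represented replicates.

    Cells whose total counts fall outside mean +/- ``n_sd`` standard
    deviations of the per-cell totals are removed (boundaries kept).
    If ``target_class`` is given, replicate batches containing fewer
    than ``min_cells_per_replicate`` cells of that class are dropped.
    """
    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells")
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    mu, sd = totals.mean(), totals.std()
    keep = (totals >= mu - n_sd * sd) & (totals <= mu + n_sd * sd)
    out = adata[keep].copy()
    if target_class is not None and replicate_col in out.obs:
        counts = (
            out.obs.loc[out.obs[class_col] == target_class, replicate_col]
            .value_counts()
        )
        good = set(counts.index[counts >= min_cells_per_replicate])
        out = out[out.obs[replicate_col].isin(good)].copy()
    if out.n_obs == 0:
        raise EmptyResultError("all cells removed by QC filtering")
    return out


def normalize_log(adata: ad.AnnData, target_sum: float = 10_000.0) -> ad.AnnData:
    """Scale each cell to ``target_sum`` total counts, then log(x + 1)."""
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("zero-count cells present; run qc_filter first")
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    out.uns["normalized_target_sum"] = target_sum
    return out


def cluster_cells(
    adata: ad.AnnData,
    n_hvg: int = 2000,
    n_pcs: int = 20,
    resolution: float = 0.5,
    k_neighbors: int = 20,
    seed: int = 0,
) -> ClusteringResult:
    """HVG -> PCA -> SNN graph -> Leiden community detection.

    Expects normalized log expression. Deterministic under a fixed
    seed. With fewer genes than ``n_hvg`` all genes are used with a
    warning.
    """
    if adata.n_obs <= n_pcs:
        raise ValueError("need more cells than principal components")
    work = adata.copy()
    if work.n_vars < n_hvg:
        warnings.warn(
            f"only {work.n_vars} genes available (< {n_hvg} HVGs); using all"
        )
    else:
        sc.pp.highly_variable_genes(work, n_top_genes=n_hvg)
        work = work[:, work.var["highly_variable"]].copy()
    sc.pp.scale(work, max_value=10)
    n_comps = min(n_pcs, work.n_vars - 1, work.n_obs - 1)
    sc.tl.pca(work, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(work, n_neighbors=k_neighbors, n_pcs=n_comps, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            work,
            resolution=resolution,
            random_state=seed,
            flavor="leidenalg",
            key_added="cluster",
        )
    labels = pd.Series(
        work.obs["cluster"].astype(str).to_numpy(), index=adata.obs_names, name="cluster"
    )
    return ClusteringResult(
        labels=labels,
        embedding=np.asarray(work.obsm["X_pca"]),
        params={
            "n_hvg": n_hvg,
            "n_pcs": n_comps,
            "resolution": resolution,
            "k_neighbors": k_neighbors,
            "seed": seed,
        },
    )


def assign_classes(
    result: ClusteringResult,
    adata: ad.AnnData,
    panel: dict[str, list[str]] | None = None,
    min_score: float = 0.25,
) -> dict[str, str]:
    """Assign each cluster to the class whose marker panel scores highest.

    The score of a (cluster, class) pair is the cluster's mean
    normalized expression averaged over the class's panel genes present
    in the data (case-insensitive symbol matching). Clusters whose best
    score is below ``min_score`` are labelled ``'other'`` — the fate of
    contaminant populations such as microglia or endothelium.
    """
    if panel is None:
        panel = DEFAULT_MARKER_PANEL
    lower_index = {g.lower(): g for g in adata.var_names}
    panel_idx: dict[str, list[str]] = {}
    for cls, genes in panel.items():
        present = [lower_index[g.lower()] for g in genes if g.lower() in lower_index]
        if present:
            panel_idx[cls] = present
    if not panel_idx:
        raise ValueError("no marker-panel genes present in the data")

    assignment: dict[str, str] = {}
    for cluster in result.labels.unique():
        idx = np.flatnonzero(result.labels.to_numpy() == cluster)
        mean_expr = np.asarray(adata.X[idx].mean(axis=0)).ravel()
        expr = pd.Series(mean_expr, index=adata.var_names)
        scores = {cls: float(expr[genes].mean()) for cls, genes in panel_idx.items()}
        best = max(scores, key=scores.get)
        assignment[str(cluster)] = best if scores[best] >= min_score else "other"
    return assignment


# ---------------------------------------------------------------------------
# Within-class type refinement: overcluster, prune, merge
# ---------------------------------------------------------------------------

def _distinguishing_genes(
    X1: np.ndarray,
    X2: np.ndarray,
    min_logfc: float = 0.5,
    max_padj: float = 0.01,
    min_fraction: float = 0.25,
) -> int:
    """Count genes that sufficiently distinguish two cell groups.

    A gene qualifies with |mean log-expression difference| >= min_logfc,
    Benjamini-Hochberg adjusted two-sided Wilcoxon rank-sum p < max_padj,
    and detection in >= min_fraction of cells of the higher group.
    """
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    lfc = m1 - m2
    det1 = (X1 > 0).mean(axis=0)
    det2 = (X2 > 0).mean(axis=0)
    det_hi = np.where(lfc >= 0, det1, det2)
    candidate = (np.abs(lfc) >= min_logfc) & (det_hi >= min_fraction)
    if not candidate.any():
        return 0
    cand_idx = np.flatnonzero(candidate)
    res = stats.mannwhitneyu(
        X1[:, cand_idx], X2[:, cand_idx], axis=0, alternative="two-sided"
    )
    padj = stats.false_discovery_control(res.pvalue, method="bh")
    return int(np.sum(padj < max_padj))


def refine_types(
    adata: ad.AnnData,
    resolution: float = 1.1,
    seed: int = 0,
    n_hvg: int = 2000,
    n_pcs: int = 20,
    broad_fraction: float = 0.9,
    low_count_factor: float = 0.5,
    contaminant_markers: list[str] | None = None,
    min_logfc: float = 0.5,
    max_padj: float = 0.01,
    min_fraction: float = 0.25,
    reprune_threshold: float = 0.20,
    _recluster: bool = True,
) -> ClusteringResult:
    """Overcluster one class, then prune artefact clusters and merge
    indistinguishable ones.

    Pruning removes clusters whose top marker is broadly expressed
    outside the cluster (> ``broad_fraction`` of outside cells), whose
    mean library size is below ``low_count_factor`` times the median
    cluster mean, or whose top markers are canonical markers of a
    contaminant class. If pruning removes more than
    ``reprune_threshold`` of cells, clustering is re-run once on the
    retained cells. Cluster pairs that are mutual nearest centroids are
    merged whenever no gene passes the differential-expression
    criterion between them, iterated to a fixpoint.
    """
    if adata.n_obs == 0:
        raise ValueError("class subset is empty")
    result = cluster_cells(
        adata, n_hvg=n_hvg, n_pcs=n_pcs, resolution=resolution, seed=seed
    )
    labels = result.labels.copy()
    if labels.nunique() == 1:
        return result

    X = adata.X
    dense = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    totals = dense.sum(axis=1)

    # --- prune ---
    contam_idx = None
    if contaminant_markers:
        lower = {g.lower(): j for j, g in enumerate(adata.var_names)}
        contam_idx = {lower[g.lower()] for g in contaminant_markers if g.lower() in lower}
    cluster_ids = sorted(labels.unique())
    cluster_mean_total = {
        c: totals[labels.to_numpy() == c].mean() for c in cluster_ids
    }
    median_total = float(np.median(list(cluster_mean_total.values())))
    pruned: set[str] = set()
    for c in cluster_ids:
        mask = labels.to_numpy() == c
        inside, outside = dense[mask], dense[~mask]
        lfc = inside.mean(axis=0) - outside.mean(axis=0)
        top = np.argsort(lfc)[::-1][:5]
        top_marker = top[0]
        # "widely expressed" top markers: either nothing is meaningfully
        # elevated in the cluster, or outside cells commonly reach the
        # cluster's level of its best marker
        level = 0.5 * (inside[:, top_marker].mean() + outside[:, top_marker].mean())
        if lfc[top_marker] < min_logfc or (
            (outside[:, top_marker] > level).mean() > broad_fraction
        ):
            pruned.add(c)
            continue
        if cluster_mean_total[c] < low_count_factor * median_total:
            pruned.add(c)
            continue
        # several of the top markers are canonical contaminant-class markers
        top20 = np.argsort(lfc)[::-1][:20]
        if contam_idx and len(set(top20.tolist()) & contam_idx) >= 3:
            pruned.add(c)
    keep_mask = ~labels.isin(pruned).to_numpy()
    frac_removed = 1.0 - keep_mask.mean()
    if frac_removed >= 1.0:
        warnings.warn("pruning would remove every cluster; skipping pruning")
        pruned = set()
        keep_mask = np.ones(len(labels), dtype=bool)
        frac_removed = 0.0
    if frac_removed > reprune_threshold and _recluster:
        return refine_types(
            adata[keep_mask].copy(),
            resolution=resolution,
            seed=seed,
            n_hvg=n_hvg,
            n_pcs=n_pcs,
            broad_fraction=broad_fraction,
            low_count_factor=low_count_factor,
            contaminant_markers=contaminant_markers,
            min_logfc=min_logfc,
            max_padj=max_padj,
            min_fraction=min_fraction,
            reprune_threshold=reprune_threshold,
            _recluster=False,
        )
    labels = labels[keep_mask]
    dense = dense[keep_mask]
    embedding = result.embedding[keep_mask]

    # --- merge ---
    while labels.nunique() > 1:
        ids = sorted(labels.unique())
        cents = np.vstack(
            [embedding[labels.to_numpy() == c].mean(axis=0) for c in ids]
        )
        D = np.linalg.norm(cents[:, None] - cents[None, :], axis=2)
        np.fill_diagonal(D, np.inf)
        nearest = D.argmin(axis=1)
        merged = False
        for i, c in enumerate(ids):
            j = nearest[i]
            if nearest[j] != i or j <= i:
                continue  # test each mutual-nearest pair once
            m1 = labels.to_numpy() == c
            m2 = labels.to_numpy() == ids[j]
            n_de = _distinguishing_genes(
                dense[m1], dense[m2], min_logfc, max_padj, min_fraction
            )
            if n_de == 0:
                labels = labels.replace({ids[j]: c})
                merged = True
                break
        if not merged:
            break

    return ClusteringResult(
        labels=labels,
        embedding=embedding,
        params={**result.params, "pruned_clusters": sorted(pruned)},
    )
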