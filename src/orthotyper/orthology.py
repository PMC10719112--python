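"""Expression-matrix and orthology-table I/O, shared feature-space
construction (1:1 orthologue selection with ohnolog collapsing), and
phylogenetic distances.

On-disk layouts are the field's plain-text standards: CellRanger-style
MatrixMarket directories (matrix.mtx, genes.tsv, barcodes.tsv plus an
optional metadata.tsv), BioMart-style tab-separated orthology exports,
and Newick trees with branch lengths in substitutions per 100 bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import dendropy
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "FormatError",
    "OrthologyTable",
    "read_matrix",
    "write_matrix",
    "read_tree",
    "write_tree",
    "tree_distance",
    "tree_distance_matrix",
    "collapse_ohnologs",
    "select_one_to_one",
    "map_to_reference",
]


class FormatError(ValueError):
    """Raised when on-disk files are mutually inconsistent."""


# ---------------------------------------------------------------------------
# Count matrices (CellRanger-style MatrixMarket directory)
# ---------------------------------------------------------------------------

def read_matrix(directory: str | Path) -> ad.AnnData:
    """Read a genes x cells MatrixMarket directory into an AnnData.

    Expects ``matrix.mtx`` (genes as rows, the CellRanger layout),
    ``genes.tsv``, ``barcodes.tsv`` and, optionally, ``metadata.tsv``
    (tab-separated, one row per cell, indexed by barcode).
    """
    directory = Path(directory)
    X = sp.csr_matrix(mmread(directory / "matrix.mtx")).T  # -> cells x genes

    def _read_column(path: Path) -> pd.Series:
        lines = [ln for ln in path.read_text().splitlines() if ln]
        return pd.Series([ln.split("\t")[0] for ln in lines], dtype=str)

    genes = _read_column(directory / "genes.tsv")
    barcodes = _read_column(directory / "barcodes.tsv")
    if len(genes) != X.shape[1]:
        raise FormatError(
            f"genes.tsv has {len(genes)} entries but matrix has {X.shape[1]} rows"
        )
    if len(barcodes) != X.shape[0]:
        raise FormatError(
            f"barcodes.tsv has {len(barcodes)} entries but matrix has {X.shape[0]} columns"
        )
    if genes.duplicated().any():
        raise FormatError("duplicate gene ids in genes.tsv")
    obs = pd.DataFrame(index=barcodes.values)
    meta_path = directory / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        if len(meta) != X.shape[0]:
            raise FormatError(
                f"metadata.tsv has {len(meta)} rows but matrix has {X.shape[0]} cells"
            )
        obs = meta.loc[barcodes.values]
    adata = ad.AnnData(X=X, obs=obs)
    adata.var_names = genes.values
    adata.obs_names = barcodes.values
    return adata


def write_matrix(adata: ad.AnnData, directory: str | Path) -> None:
    """Write an AnnData as a genes x cells MatrixMarket directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X).T  # genes x cells on disk
    mmwrite(str(directory / "matrix.mtx"), X, field="integer" if _is_integral(adata.X) else "real")
    pd.Series(adata.var_names).to_csv(
        directory / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if adata.obs.shape[1] > 0:
        adata.obs.to_csv(directory / "metadata.tsv", sep="\t")


def _is_integral(X) -> bool:
    data = X.data if sp.issparse(X) else np.asarray(X)
    return np.issubdtype(np.asarray(data).dtype, np.integer) or bool(
        np.all(np.asarray(data) == np.round(np.asarray(data)))
    )


# ---------------------------------------------------------------------------
# Orthology tables
# ---------------------------------------------------------------------------

@dataclass
class OrthologyTable:
    """Pairwise reference-to-species gene correspondences.

    ``pairs`` holds one row per (reference gene, target gene) pair, as
    in a BioMart export. Cardinality is inferred by grouping, never
    trusted from the file. ``ohnolog_groups`` maps a reference gene to
    the set of whole-genome-duplication paralogues in the target
    species that jointly stand in for it; collapsing such a group by
    summing expression restores a 1:1 correspondence when the group
    members are the gene's only orthologues.
    """

    species: str
    pairs: pd.DataFrame  # columns: ref_gene, target_gene
    ohnolog_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {"ref_gene", "target_gene"} - set(self.pairs.columns)
        if missing:
            raise ValueError(f"pairs table missing columns {sorted(missing)}")
        groups = list(self.ohnolog_groups.values())
        members = [g for grp in groups for g in grp]
        if len(members) != len(set(members)):
            raise ValueError("ohnolog groups must be disjoint")

    @classmethod
    def identity(cls, species: str, genes: list[str]) -> "OrthologyTable":
        pairs = pd.DataFrame({"ref_gene": genes, "target_gene": genes})
        return cls(species=species, pairs=pairs)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        species: str,
        ref_col: str = "ref_gene",
        target_col: str = "target_gene",
        infer_ohnologs: bool = True,
    ) -> "OrthologyTable":
        df = pd.read_csv(path, sep="\t")
        pairs = df[[ref_col, target_col]].rename(
            columns={ref_col: "ref_gene", target_col: "target_gene"}
        ).dropna()
        table = cls(species=species, pairs=pairs.reset_index(drop=True))
        if infer_ohnologs:
            table.ohnolog_groups = table.infer_ohnolog_groups()
        return table

    def to_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    def cardinality(self) -> pd.Series:
        """Number of target orthologues per reference gene."""
        return self.pairs.groupby("ref_gene")["target_gene"].nunique()

    def reference_of(self, target_gene: str) -> str:
        hits = self.pairs.loc[self.pairs["target_gene"] == target_gene, "ref_gene"]
        if hits.empty:
            return target_gene
        return str(hits.iloc[0])

    def infer_ohnolog_groups(self) -> dict[str, list[str]]:
        """Detect a/b-suffixed duplicate pairs (zebrafish naming convention).

        A reference gene whose targets are exactly the reference symbol
        plus distinct single-letter suffixes (case-insensitive, e.g.
        rbpms2 -> rbpms2a + rbpms2b) is treated as an ohnolog group.
        """
        groups: dict[str, list[str]] = {}
        for ref, sub in self.pairs.groupby("ref_gene"):
            targets = sorted(sub["target_gene"].unique())
            if len(targets) < 2:
                continue
            suffixes = set()
            ok = True
            for t in targets:
                if len(t) == len(ref) + 1 and t[:-1].lower() == ref.lower():
                    suffixes.add(t[-1].lower())
                else:
                    ok = False
                    break
            if ok and len(suffixes) == len(targets):
                groups[str(ref)] = targets
        return groups

    def one_to_one_refs(self, after_collapse: bool = True) -> set[str]:
        """Reference genes with a single orthologue in this species.

        With ``after_collapse`` an ohnolog group counts as one composite
        orthologue provided its members are the gene's only orthologues.
        """
        card = self.cardinality()
        ones = set(card.index[card == 1].astype(str))
        if after_collapse:
            for ref, members in self.ohnolog_groups.items():
                targets = set(
                    self.pairs.loc[self.pairs["ref_gene"] == ref, "target_gene"]
                )
                if targets == set(members):
                    ones.add(ref)
        return ones


def collapse_ohnologs(
    adata: ad.AnnData,
    table: OrthologyTable,
    on_missing: str = "warn",
) -> tuple[ad.AnnData, OrthologyTable]:
    """Collapse each ohnolog group by summing member expression cell-wise.

    The composite gene is named after the reference gene; if the
    ohnologs were the gene's only orthologues the composite becomes its
    1:1 orthologue in the updated table. Total counts are conserved.
    """
    if on_missing not in ("warn", "error"):
        raise ValueError("on_missing must be 'warn' or 'error'")
    genes = pd.Index(adata.var_names)
    groups = {}
    for ref, members in table.ohnolog_groups.items():
        present = [m for m in members if m in genes]
        if len(present) < len(members):
            msg = f"ohnolog group {ref!r}: members {set(members) - set(present)} absent"
            if on_missing == "error":
                raise KeyError(msg)
            warnings.warn(msg)
            continue
        groups[ref] = members
    if not groups:
        return adata, table

    member_to_ref = {m: ref for ref, mem in groups.items() for m in mem}
    new_names: list[str] = []
    col_of: dict[str, int] = {}
    assign = np.empty(adata.n_vars, dtype=np.int64)
    for j, g in enumerate(genes):
        name = member_to_ref.get(g, g)
        if name not in col_of:
            col_of[name] = len(new_names)
            new_names.append(name)
        assign[j] = col_of[name]
    S = sp.csr_matrix(
        (np.ones(adata.n_vars), (np.arange(adata.n_vars), assign)),
        shape=(adata.n_vars, len(new_names)),
    )
    X = sp.csr_matrix(adata.X) @ S
    out = ad.AnnData(X=sp.csr_matrix(X), obs=adata.obs.copy())
    out.var_names = new_names

    members_flat = set(member_to_ref)
    pairs = table.pairs[~table.pairs["target_gene"].isin(members_flat)]
    add = pd.DataFrame({"ref_gene": list(groups), "target_gene": list(groups)})
    new_table = OrthologyTable(
        species=table.species,
        pairs=pd.concat([pairs, add], ignore_index=True),
        ohnolog_groups={r: m for r, m in table.ohnolog_groups.items() if r not in groups},
    )
    return out, new_table


def select_one_to_one(
    tables: dict[str, OrthologyTable],
    species_set: set[str] | None = None,
    collapse: bool = True,
) -> list[str]:
    """Reference genes with a 1:1 orthologue in every listed species.

    Ohnolog groups count as collapsed composites when ``collapse`` is
    set. Adding species can only shrink the returned list. An empty
    intersection yields an empty list with a warning, not an error.
    """
    if species_set is None:
        species_set = set(tables)
    missing = species_set - set(tables)
    if missing:
        raise KeyError(f"no orthology table for species {sorted(missing)}")
    shared: set[str] | None = None
    for s in sorted(species_set):
        ones = tables[s].one_to_one_refs(after_collapse=collapse)
        shared = ones if shared is None else shared & ones
    result = sorted(shared or set())
    if not result:
        warnings.warn("no shared 1:1 orthologues across the requested species")
    return result


def map_to_reference(
    adata: ad.AnnData,
    table: OrthologyTable | None,
    shared_genes: list[str],
    collapse: bool = True,
) -> ad.AnnData:
    """Rename a species' genes to reference ids and subset to shared genes.

    Ohnolog groups are collapsed first when requested. Genes mapping to
    the same reference id ambiguously (non-1:1 after collapse) are
    dropped along with any shared gene absent from the species.
    """
    if table is None:  # reference species: already in reference ids
        keep = [g for g in shared_genes if g in set(adata.var_names)]
        return adata[:, keep].copy()
    if collapse:
        adata, table = collapse_ohnologs(adata, table)
    ones = table.one_to_one_refs(after_collapse=False)
    sub = table.pairs[table.pairs["ref_gene"].isin(ones)]
    target_to_ref = dict(zip(sub["target_gene"], sub["ref_gene"]))
    present = {target_to_ref[g]: g for g in adata.var_names if g in target_to_ref}
    keep_refs = [g for g in shared_genes if g in present]
    out = adata[:, [present[r] for r in keep_refs]].copy()
    out.var_names = keep_refs
    return out


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------

def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick")


def tree_distance(tree: dendropy.Tree, sp1: str, sp2: str) -> float:
    """Patristic distance between two leaves, in substitutions per 100 bp."""
    if sp1 == sp2:
        _require_leaf(tree, sp1)
        return 0.0
    pdm = tree.phylogenetic_distance_matrix()
    t1, t2 = _require_leaf(tree, sp1), _require_leaf(tree, sp2)
    return float(pdm.patristic_distance(t1, t2))


def tree_distance_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """All-pairs patristic distance matrix over leaf labels."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(D, index=labels, columns=labels)


def _require_leaf(tree: dendropy.Tree, label: str):
    taxon = tree.taxon_namespace.get_taxon(label)
    if taxon is None:
        raise KeyError(f"unknown leaf {label!r}")
    return taxon
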