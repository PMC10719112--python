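"""I/O round trips, ohnolog collapsing, 1:1 orthologue selection and
patristic distances."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import anndata as ad
import dendropy

from orthotyper.orthology import (
    FormatError,
    OrthologyTable,
    collapse_ohnologs,
    map_to_reference,
    read_matrix,
    select_one_to_one,
    tree_distance,
    tree_distance_matrix,
    write_matrix,
)
from orthotyper.synthetic import simulate_tree


def _adata(counts, genes, cells=None, **obs):
    X = sp.csr_matrix(np.asarray(counts))
    a = ad.AnnData(X=X, obs=pd.DataFrame(obs) if obs else None)
    a.var_names = genes
    if cells is not None:
        a.obs_names = cells
    return a


class TestMatrixIO:
    def test_round_trip(self, tmp_path, rng):
        counts = rng.integers(0, 10, size=(20, 10))  # cells x genes
        a = _adata(counts, [f"g{i}" for i in range(10)],
                   cells=[f"c{i}" for i in range(20)],
                   species=["sp1"] * 20, replicate=["r1"] * 10 + ["r2"] * 10)
        write_matrix(a, tmp_path / "m")
        back = read_matrix(tmp_path / "m")
        assert (back.X != a.X).nnz == 0
        assert list(back.var_names) == list(a.var_names)
        assert list(back.obs["replicate"]) == list(a.obs["replicate"])

    def test_barcode_mismatch_raises(self, tmp_path, rng):
        a = _adata(rng.integers(0, 5, size=(6, 4)), [f"g{i}" for i in range(4)])
        write_matrix(a, tmp_path / "m")
        bc = (tmp_path / "m" / "barcodes.tsv").read_text().splitlines()
        (tmp_path / "m" / "barcodes.tsv").write_text("\n".join(bc[:-1]) + "\n")
        with pytest.raises(FormatError):
            read_matrix(tmp_path / "m")

    def test_empty_matrix_valid(self, tmp_path):
        a = _adata(np.zeros((0, 5)), [f"g{i}" for i in range(5)])
        write_matrix(a, tmp_path / "m")
        back = read_matrix(tmp_path / "m")
        assert back.n_obs == 0
        assert back.n_vars == 5


class TestCollapseOhnologs:
    def test_example_pair_sums(self):
        a = _adata(
            np.array([[1, 0], [2, 3]]),  # cells x (rbpms2a, rbpms2b)
            ["rbpms2a", "rbpms2b"],
        )
        table = OrthologyTable(
            species="zebrafish",
            pairs=pd.DataFrame(
                {"ref_gene": ["rbpms2", "rbpms2"], "target_gene": ["rbpms2a", "rbpms2b"]}
            ),
            ohnolog_groups={"rbpms2": ["rbpms2a", "rbpms2b"]},
        )
        out, new_table = collapse_ohnologs(a, table)
        assert list(out.var_names) == ["rbpms2"]
        assert np.array_equal(np.asarray(out.X.todense()).ravel(), [1, 5])
        assert new_table.cardinality()["rbpms2"] == 1  # composite is now 1:1

    def test_no_groups_unchanged(self):
        a = _adata(np.array([[1, 2]]), ["x", "y"])
        table = OrthologyTable.identity("s", ["x", "y"])
        out, _ = collapse_ohnologs(a, table)
        assert out is a

    def test_triple_group_sums_elementwise(self, rng):
        counts = rng.integers(0, 7, size=(5, 3))
        a = _adata(counts, ["qa", "qb", "qc"])
        table = OrthologyTable(
            species="s",
            pairs=pd.DataFrame(
                {"ref_gene": ["q"] * 3, "target_gene": ["qa", "qb", "qc"]}
            ),
            ohnolog_groups={"q": ["qa", "qb", "qc"]},
        )
        out, _ = collapse_ohnologs(a, table)
        assert np.array_equal(
            np.asarray(out.X.todense()).ravel(), counts.sum(axis=1)
        )

    def test_total_counts_conserved(self, rng):
        counts = rng.integers(0, 5, size=(8, 6))
        genes = ["aa", "ab", "b", "c", "da", "db"]
        a = _adata(counts, genes)
        table = OrthologyTable(
            species="s",
            pairs=pd.DataFrame(
                {
                    "ref_gene": ["a", "a", "b", "c", "d", "d"],
                    "target_gene": genes,
                }
            ),
            ohnolog_groups={"a": ["aa", "ab"], "d": ["da", "db"]},
        )
        out, _ = collapse_ohnologs(a, table)
        assert out.X.sum() == counts.sum()

    def test_missing_member_errors_when_strict(self):
        a = _adata(np.array([[1]]), ["qa"])
        table = OrthologyTable(
            species="s",
            pairs=pd.DataFrame({"ref_gene": ["q", "q"], "target_gene": ["qa", "qb"]}),
            ohnolog_groups={"q": ["qa", "qb"]},
        )
        with pytest.raises(KeyError):
            collapse_ohnologs(a, table, on_missing="error")


def _toy_table(species, mapping):
    rows = [
        {"ref_gene": ref, "target_gene": t}
        for ref, targets in mapping.items()
        for t in targets
    ]
    return OrthologyTable(species=species, pairs=pd.DataFrame(rows))


class TestSelectOneToOne:
    def test_one_to_many_excluded(self):
        tables = {
            "s1": _toy_table("s1", {"G": ["g1"], "H": ["h1"]}),
            "s2": _toy_table("s2", {"G": ["ga", "gb"], "H": ["h2"]}),
        }
        assert select_one_to_one(tables) == ["H"]

    def test_single_species_returns_its_ones(self):
        tables = {"s1": _toy_table("s1", {"A": ["a"], "B": ["b1", "b2"], "C": ["c"]})}
        assert select_one_to_one(tables) == ["A", "C"]

    def test_monotone_under_species_addition(self, rng):
        genes = [f"G{i}" for i in range(30)]
        tables = {}
        for s in range(4):
            mapping = {}
            for g in genes:
                n = rng.choice([1, 1, 1, 2])
                mapping[g] = [f"{g.lower()}_{s}_{k}" for k in range(n)]
            tables[f"s{s}"] = _toy_table(f"s{s}", mapping)
        subsets = [{"s0"}, {"s0", "s1"}, {"s0", "s1", "s2"}, {"s0", "s1", "s2", "s3"}]
        lists = [set(select_one_to_one(tables, ss)) for ss in subsets]
        # brute-force oracle: intersection of per-species 1:1 sets
        for ss, got in zip(subsets, lists):
            expected = set.intersection(
                *(
                    {g for g in genes if len(tables[s].pairs.query("ref_gene == @g")) == 1}
                    for s in ss
                )
            )
            assert got == expected
        for smaller, larger in zip(lists, lists[1:]):
            assert larger <= smaller

    def test_collapsed_ohnologs_count_as_one(self):
        table = _toy_table("z", {"q": ["qa", "qb"], "r": ["r1"]})
        table.ohnolog_groups = {"q": ["qa", "qb"]}
        assert select_one_to_one({"z": table}) == ["q", "r"]
        assert select_one_to_one({"z": table}, collapse=False) == ["r"]


class TestMapToReference:
    def test_renames_and_subsets(self):
        a = _adata(np.array([[1, 2, 3]]), ["x1", "y1", "z1"])
        table = _toy_table("s", {"X": ["x1"], "Y": ["y1"], "Z": ["z1"]})
        out = map_to_reference(a, table, ["X", "Z"])
        assert list(out.var_names) == ["X", "Z"]
        assert np.array_equal(np.asarray(out.X.todense()).ravel(), [1, 3])


class TestTreeDistance:
    def test_cherry_distance(self):
        tree = dendropy.Tree.get(data="(A:1,B:2);", schema="newick")
        assert tree_distance(tree, "A", "B") == pytest.approx(3.0)

    def test_self_distance_zero(self):
        tree = dendropy.Tree.get(data="(A:1,B:2);", schema="newick")
        assert tree_distance(tree, "A", "A") == 0.0

    def test_unknown_leaf_keyerror(self):
        tree = dendropy.Tree.get(data="(A:1,B:2);", schema="newick")
        with pytest.raises(KeyError):
            tree_distance(tree, "A", "C")

    def test_matches_brute_force_path_sum(self):
        tree = simulate_tree(10, 8.0, seed=4)
        # independent oracle: root paths, then shared-prefix removal
        paths = {}
        for leaf in tree.leaf_node_iter():
            path, node = [], leaf
            while node is not None:
                path.append(node)
                node = node.parent_node
            paths[leaf.taxon.label] = path[::-1]  # root -> leaf
        D = tree_distance_matrix(tree)
        labels = list(paths)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                pa, pb = paths[a], paths[b]
                k = 0
                while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
                    k += 1
                expected = sum(n.edge.length for n in pa[k:]) + sum(
                    n.edge.length for n in pb[k:]
                )
                assert D.loc[a, b] == pytest.approx(expected)
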