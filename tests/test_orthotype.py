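"""Integration, orthotype clustering, species-disjoint merging,
confusion/specificity and stability."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from orthotyper.classify import normalize_log, qc_filter
from orthotyper.orthotype import (
    OrthotypeAssignment,
    cluster_orthotypes,
    confusion_and_specificity,
    downsample_clusterwise,
    integrate_species,
    merge_species_disjoint,
    orthotype_markers,
    stability_scan,
)
from orthotyper.synthetic import SimulationConfig, simulate_atlas


@pytest.fixture(scope="module")
def planted_orthotypes():
    """Five planted orthologous types in one class across three species."""
    cfg = SimulationConfig(
        seed=13, n_species=3, classes={"BC": 40}, types_per_class=5,
        cells_per_type=50, n_genes=1200, markers_per_type=20,
        attribute_class="BC", species_shift_sd=0.6,
    )
    atlas = simulate_atlas(cfg)
    norm = {s: normalize_log(qc_filter(a)) for s, a in atlas.species.items()}
    integ = integrate_species(norm, n_features=400, seed=0)
    return atlas, integ


class TestDownsample:
    def _adata(self, rng, sizes):
        labels = np.concatenate([[f"t{i}"] * n for i, n in enumerate(sizes)])
        a = ad.AnnData(
            X=rng.poisson(3, size=(len(labels), 10)).astype(float),
            obs=pd.DataFrame({"type": labels}),
        )
        return a

    def test_small_cluster_fully_kept(self, rng):
        out = downsample_clusterwise(self._adata(rng, [150]), cap=200, seed=0)
        assert out.n_obs == 150

    def test_large_cluster_capped(self, rng):
        out = downsample_clusterwise(self._adata(rng, [1000]), cap=200, seed=0)
        assert out.n_obs == 200

    def test_seeds_differ_sizes_equal(self, rng):
        a = self._adata(rng, [500, 80])
        o1 = downsample_clusterwise(a, cap=200, seed=1)
        o2 = downsample_clusterwise(a, cap=200, seed=2)
        assert o1.obs["type"].value_counts().to_dict() == o2.obs["type"].value_counts().to_dict()
        assert set(o1.obs_names) != set(o2.obs_names)


class TestIntegrateSpecies:
    def test_relabelled_identical_data_stays_mixed(self, rng):
        X = rng.normal(0, 1, size=(400, 60))
        X[:200, :10] += 4  # two genuine populations, present in both "species"
        obs = pd.DataFrame({"species": ["a", "b"] * 200})
        a = ad.AnnData(X=X, obs=obs)
        a.var_names = [f"g{i}" for i in range(60)]
        integ = integrate_species(a, n_features=60, seed=0)
        Z = integ.obsm["X_integrated"]
        # batch mixing: nearest neighbours come from both labels at chance
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=21).fit(Z)
        _, idx = nn.kneighbors(Z)
        sp = obs["species"].to_numpy()
        same = np.mean([np.mean(sp[row[1:]] == sp[row[0]]) for row in idx])
        assert 0.4 < same < 0.6

    def test_planted_species_shift_removed(self, planted_orthotypes):
        atlas, integ = planted_orthotypes
        Z = integ.obsm["X_integrated"]
        raw = integ.obsm["X_pca"]
        sp = integ.obs["species"].to_numpy()
        ty = integ.obs["type"].to_numpy()

        def centroid_spread(M):
            spreads = []
            for t in np.unique(ty):
                cents = np.vstack(
                    [M[(ty == t) & (sp == s)].mean(axis=0) for s in np.unique(sp)]
                )
                spreads.append(np.linalg.norm(cents - cents.mean(axis=0), axis=1).mean())
            return np.mean(spreads)

        assert centroid_spread(Z) < centroid_spread(raw)

    def test_too_few_shared_features_rejected(self, rng):
        a = ad.AnnData(
            X=rng.normal(size=(50, 10)),
            obs=pd.DataFrame({"species": ["a", "b"] * 25}),
        )
        with pytest.raises(ValueError):
            integrate_species(a, n_features=10)


class TestClusterAndMerge:
    def test_planted_types_recovered(self, planted_orthotypes):
        atlas, integ = planted_orthotypes
        assign = merge_species_disjoint(cluster_orthotypes(integ, seed=0))
        truth = integ.obs["type"].to_numpy()
        assert assign.n_orthotypes() == 5
        assert adjusted_rand_score(truth, assign.labels.to_numpy()) > 0.95

    def test_seed_determinism(self, planted_orthotypes):
        _, integ = planted_orthotypes
        a1 = cluster_orthotypes(integ.copy(), seed=4)
        a2 = cluster_orthotypes(integ.copy(), seed=4)
        assert (a1.labels == a2.labels).all()

    def test_merge_is_idempotent_and_monotone(self, planted_orthotypes):
        _, integ = planted_orthotypes
        assign = cluster_orthotypes(integ, seed=0)
        m1 = merge_species_disjoint(assign)
        m2 = merge_species_disjoint(m1)
        assert m1.n_orthotypes() <= assign.n_orthotypes()
        assert (m1.labels == m2.labels).all()

    def test_shared_species_sisters_not_merged(self, rng):
        # two tight clusters, both containing cells of both species
        Z = np.vstack([rng.normal(0, 0.1, (40, 3)), rng.normal(5, 0.1, (40, 3))])
        labels = pd.Series(["A"] * 40 + ["B"] * 40)
        species = pd.Series(["mouse", "human"] * 40)
        assign = OrthotypeAssignment(labels=labels, embedding=Z, species=species)
        merged = merge_species_disjoint(assign)
        assert merged.n_orthotypes() == 2

    def test_split_by_species_merged(self, rng):
        # one type artificially split into species-pure halves
        Z = rng.normal(0, 0.1, (80, 3))
        labels = pd.Series(["A"] * 40 + ["B"] * 40)
        species = pd.Series(["mouse"] * 40 + ["human"] * 40)
        assign = OrthotypeAssignment(labels=labels, embedding=Z, species=species)
        assert merge_species_disjoint(assign).n_orthotypes() == 1


class TestConfusion:
    def test_planted_bijection_diagonal(self, rng):
        labels = pd.Series(["o1"] * 30 + ["o2"] * 30)
        clusters = pd.Series(["c1"] * 30 + ["c2"] * 30)
        species = pd.Series(["m"] * 60)
        assign = OrthotypeAssignment(labels, np.zeros((60, 2)), species)
        mats, spec = confusion_and_specificity(assign, clusters)
        assert np.allclose(mats["m"].sum(axis=0), 100.0)
        assert spec["specific"].all()
        assert np.allclose(mats["m"].to_numpy().max(axis=0), 100.0)

    def test_even_split_at_threshold_is_ambiguous(self):
        labels = pd.Series(["o1"] * 15 + ["o2"] * 15)
        clusters = pd.Series(["c1"] * 30)
        species = pd.Series(["m"] * 30)
        assign = OrthotypeAssignment(labels, np.zeros((30, 2)), species)
        _, spec = confusion_and_specificity(assign, clusters, threshold=50.0)
        assert not spec["specific"].iloc[0]

    def test_label_noise_degrades_specificity_binomially(self, rng):
        n = 400
        true = np.repeat(["o1", "o2", "o3", "o4"], n // 4)
        noisy = true.copy()
        flip = rng.random(n) < 0.10
        noisy[flip] = rng.choice(["o1", "o2", "o3", "o4"], flip.sum())
        assign = OrthotypeAssignment(
            pd.Series(noisy), np.zeros((n, 2)), pd.Series(["m"] * n)
        )
        _, spec = confusion_and_specificity(assign, pd.Series(true))
        # ~90%+ of each cluster still maps to its own orthotype
        assert spec["specific"].all()
        assert (spec["max_percent"] > 85).all()


class TestMarkers:
    def test_planted_signature_supported_in_all_species(self, planted_orthotypes):
        atlas, integ = planted_orthotypes
        assign = merge_species_disjoint(cluster_orthotypes(integ, seed=0))
        table = orthotype_markers(integ, assign, n_genes=5)
        n_species = integ.obs["species"].nunique()
        # top markers of each orthotype are detected in every species
        top = table[table["rank"] == 1]
        assert (top["n_species_support"] == n_species).all()

    def test_detection_fraction_matches_brute_force(self, planted_orthotypes):
        atlas, integ = planted_orthotypes
        assign = cluster_orthotypes(integ, seed=0)
        table = orthotype_markers(integ, assign, n_genes=3)
        row = table.iloc[0]
        X = integ.X
        mask_ot = assign.labels.to_numpy() == row["orthotype"]
        j = list(integ.var_names).index(row["gene"])
        support = 0
        for s in sorted(integ.obs["species"].unique()):
            m = mask_ot & (integ.obs["species"].to_numpy() == s)
            col = X[m, j]
            col = col.toarray() if hasattr(col, "toarray") else col
            if (col > 0).mean() >= 0.30:
                support += 1
        assert row["n_species_support"] == support


class TestStability:
    def test_planted_atlas_stable_over_resolutions(self, planted_orthotypes):
        _, integ = planted_orthotypes
        scan = stability_scan(
            integ, cluster_col="type", resolutions=[0.4, 0.8, 1.2],
            n_trials=2, cap=40, seed=0,
        )
        assert len(scan) == 3
        assert (scan["ari_mean"] > 0.9).all()
        assert (scan["n_orthotypes_mean"].between(3, 7)).all()
        assert (scan["per_cell_reproducibility"] > 0.9).all()

    def test_requires_multiple_resolutions_and_trials(self, planted_orthotypes):
        _, integ = planted_orthotypes
        with pytest.raises(ValueError):
            stability_scan(integ, "type", resolutions=[0.5], n_trials=2)
        with pytest.raises(ValueError):
            stability_scan(integ, "type", resolutions=[0.5, 1.0], n_trials=1)
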