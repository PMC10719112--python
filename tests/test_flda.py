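"""Covariance factorization, discriminant axes, projections and
quadruple ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from orthotyper.flda import (
    QUADRANTS,
    decompose_covariance,
    enumerate_quadrant_candidates,
    project,
    rank_quadruples,
    solve_axes,
    synthetic_mouse_rgc_catalog,
)
from orthotyper.synthetic import simulate_attribute_design


@pytest.fixture(scope="module")
def planted_design():
    X, attrs, dirs = simulate_attribute_design(
        n_per_combo=250, n_genes=60, noise_sd=0.2, seed=3
    )
    return X, attrs, dirs


class TestDecomposeCovariance:
    def test_single_effect_leaves_others_zero(self):
        X, attrs, dirs = simulate_attribute_design(
            n_per_combo=100, n_genes=30,
            effects={"polarity": 1.0, "kinetics": 0.0, "species": 0.0},
            noise_sd=0.0, seed=1,
        )
        sig = decompose_covariance(X, attrs)
        assert np.allclose(sig["kinetics"], 0.0, atol=1e-10)
        assert np.allclose(sig["species"], 0.0, atol=1e-10)
        assert np.trace(sig["polarity"]) > 0

    def test_trace_additivity_identity(self, planted_design):
        X, attrs, _ = planted_design
        sig = decompose_covariance(X, attrs)
        total = np.trace(sig["total"])
        parts = sum(
            np.trace(sig[k]) for k in ("polarity", "kinetics", "species", "residual")
        )
        assert abs(total - parts) < 1e-8

    def test_planted_effect_energy_recovered(self):
        # balanced +/- design along direction d: Sigma_A = d d^T
        X, attrs, dirs = simulate_attribute_design(
            n_per_combo=200, n_genes=40,
            effects={"polarity": 1.5, "kinetics": 0.8, "species": 1.0},
            noise_sd=0.0, seed=2,
        )
        sig = decompose_covariance(X, attrs)
        for a in ("polarity", "kinetics", "species"):
            assert np.trace(sig[a]) == pytest.approx(dirs[a] @ dirs[a], rel=1e-6)

    def test_empty_design_cell_rejected(self, rng):
        X = rng.normal(size=(20, 5))
        attrs = pd.DataFrame(
            {"a": ["x"] * 10 + ["y"] * 10, "b": ["p"] * 10 + ["q"] * 10}
        )  # (x,q) and (y,p) cells empty
        with pytest.raises(ValueError):
            decompose_covariance(X, attrs)


class TestSolveAxes:
    def test_rank_one_isotropic_closed_form(self):
        g = 10
        e1 = np.zeros(g)
        e1[0] = 1.0
        sigmas = {
            "A": np.outer(e1, e1),
            "B": np.zeros((g, g)),
            "C": np.zeros((g, g)),
            "residual": np.eye(g),
            "total": np.outer(e1, e1) + np.eye(g),
        }
        axes = solve_axes(sigmas, ridge=0.0)
        u = axes.axes["A"].to_numpy()
        assert abs(u @ e1) == pytest.approx(1.0, abs=1e-8)

    def test_planted_directions_recovered(self, planted_design):
        X, attrs, dirs = planted_design
        axes = solve_axes(decompose_covariance(X, attrs))
        for a, d in dirs.items():
            cos = abs(axes.axes[a].to_numpy() @ d) / np.linalg.norm(d)
            assert cos > 0.95
        # axes are attribute-specific: low cross-attribute alignment
        for a, b in itertools.permutations(dirs, 2):
            cross = abs(axes.axes[a].to_numpy() @ dirs[b]) / np.linalg.norm(dirs[b])
            assert cross < 0.2

    def test_label_swap_swaps_axes(self, planted_design):
        X, attrs, _ = planted_design
        swapped = attrs.rename(columns={"polarity": "kinetics", "kinetics": "polarity"})
        a1 = solve_axes(decompose_covariance(X, attrs))
        a2 = solve_axes(decompose_covariance(X, swapped))
        assert np.allclose(
            np.abs(a1.axes["polarity"]), np.abs(a2.axes["kinetics"]), atol=1e-8
        )

    def test_singular_denominator_instructs_ridge(self):
        g = 5
        sigmas = {
            "A": np.eye(g),
            "residual": np.zeros((g, g)),
            "total": np.eye(g),
        }
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            solve_axes(sigmas, ridge=0.0)


class TestProject:
    def test_planted_cell_loads_on_own_axis(self, planted_design):
        X, attrs, dirs = planted_design
        axes = solve_axes(decompose_covariance(X, attrs))
        probe = dirs["polarity"][None, :]
        coords = project(np.vstack([probe, -probe]), axes, center=True)
        assert abs(coords["polarity"].iloc[0]) > 10 * abs(coords["kinetics"].iloc[0])
        assert abs(coords["polarity"].iloc[0]) > 10 * abs(coords["species"].iloc[0])

    def test_group_separation_on_attribute_axis(self, planted_design):
        X, attrs, _ = planted_design
        axes = solve_axes(decompose_covariance(X, attrs))
        coords = project(X, axes)
        on = coords.loc[(attrs["polarity"] == "ON").to_numpy(), "polarity"]
        off = coords.loc[(attrs["polarity"] == "OFF").to_numpy(), "polarity"]
        assert (on.min() > off.max()) or (off.min() > on.max())

    def test_gene_set_mismatch_rejected(self, planted_design):
        X, attrs, _ = planted_design
        axes = solve_axes(decompose_covariance(X, attrs))
        with pytest.raises(ValueError):
            project(X[:, :-1], axes)


class TestCatalogue:
    def test_twenty_types_and_432_candidates(self):
        cat = synthetic_mouse_rgc_catalog()
        assert len(cat) == 20
        cands = enumerate_quadrant_candidates(cat)
        sizes = [
            (cat["polarity"].eq(p) & cat["kinetics"].eq(k)).sum()
            for p, k in QUADRANTS
        ]
        assert len(cands) == int(np.prod(sizes)) == 432

    def test_counting_identity_on_arbitrary_quadrants(self):
        rows = []
        sizes = (3, 2, 4, 1)
        for (p, k), n in zip(QUADRANTS, sizes):
            rows += [{"type": f"{p}{k}{i}", "polarity": p, "kinetics": k} for i in range(n)]
        cands = enumerate_quadrant_candidates(pd.DataFrame(rows))
        assert len(cands) == 3 * 2 * 4 * 1


def _ranking_setup(rng, n_genes=40, noise=0.3):
    """Reference 4 types + candidate pool sharing planted offsets."""
    cat = pd.DataFrame(
        [
            {"type": f"m{q[0]}{q[1][0]}{i}", "polarity": q[0], "kinetics": q[1]}
            for q in QUADRANTS
            for i in range(2)
        ]
    )
    base = {q: rng.normal(0, 1, n_genes) for q in QUADRANTS}
    offsets = {t: rng.normal(0, 1, n_genes) for t in cat["type"]}
    X_rows, types = [], []
    ref_types = {}
    planted = []
    for q in QUADRANTS:
        pol, kin = q
        pol_v = (1 if pol == "ON" else -1) * np.r_[np.ones(5), np.zeros(n_genes - 5)]
        kin_v = (1 if kin == "sustained" else -1) * np.r_[
            np.zeros(5), np.ones(5), np.zeros(n_genes - 10)
        ]
        for i in range(2):
            t = f"m{pol}{kin[0]}{i}"
            mu = pol_v + kin_v + offsets[t]
            X_rows.append(mu + rng.normal(0, noise, (30, n_genes)))
            types += [t] * 30
        # reference type shares the offset of candidate i=0 (the orthologue)
        ref = f"p{pol}{kin[0]}"
        ref_types[q] = ref
        planted.append(f"m{pol}{kin[0]}0")
        mu = pol_v + kin_v + offsets[f"m{pol}{kin[0]}0"] + 0.8
        X_rows.append(mu + rng.normal(0, noise, (30, n_genes)))
        types += [ref] * 30
    return (
        np.vstack(X_rows),
        pd.Series(types),
        cat,
        ref_types,
        tuple(planted),
    )


class TestRankQuadruples:
    def test_planted_orthologous_quadruple_ranks_first(self, rng):
        X, types, cat, ref, planted = _ranking_setup(rng)
        out = rank_quadruples(X, types, cat, ref, n_features=40)
        assert len(out) == 16  # 2^4 one-per-quadrant candidates
        assert tuple(out.iloc[0]["types"]) == planted

    def test_closed_form_matches_general_solver(self, rng):
        X, types, cat, ref, planted = _ranking_setup(rng)
        out = rank_quadruples(X, types, cat, ref, candidates=[planted], n_features=40)
        mask = types.isin(list(ref.values()) + list(planted)).to_numpy()
        attr_of = cat.set_index("type")
        rows = []
        for t in types[mask]:
            if t.startswith("p"):
                pol = "ON" if "ON" in t else "OFF"
                kin = "sustained" if t.endswith("s") else "transient"
                side = "reference"
            else:
                pol, kin = attr_of.loc[t, ["polarity", "kinetics"]]
                side = "candidate"
            rows.append({"polarity": pol, "kinetics": kin, "species": side})
        sig = decompose_covariance(X[mask], pd.DataFrame(rows))
        axes = solve_axes(sig)
        assert out.iloc[0]["polarity_eig"] == pytest.approx(
            axes.eigenvalues["polarity"], rel=1e-6
        )
        assert out.iloc[0]["kinetics_eig"] == pytest.approx(
            axes.eigenvalues["kinetics"], rel=1e-6
        )

    def test_attribute_inconsistent_candidate_rejected(self, rng):
        X, types, cat, ref, planted = _ranking_setup(rng)
        bad = (planted[1], planted[0], planted[2], planted[3])  # swapped quadrants
        with pytest.raises(ValueError, match="inconsistent"):
            rank_quadruples(X, types, cat, ref, candidates=[bad])
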