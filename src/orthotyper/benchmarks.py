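"""Self-contained evaluation runs used by the acceptance suite.

Each function regenerates its inputs from a seed, runs the relevant
method end to end, and returns the measured quantities. The problem
sizes are the package's reference study conditions: 15 species (105
pairs) for divergence-model recovery, 14 planted orthologous types
across 5 species for orthotype recovery, a 45-type catalogue for the
exhaustive shape search, and a 20-type attribute-annotated catalogue
(432 one-per-quadrant candidates) for discriminant-based ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import flda, gage
from .classify import normalize_log, qc_filter
from .divergence import fit_all_models
from .orthology import tree_distance_matrix
from .orthotype import (
    cluster_orthotypes,
    confusion_and_specificity,
    integrate_species,
    merge_species_disjoint,
)
from .synthetic import (
    SimulationConfig,
    simulate_atlas,
    simulate_attribute_design,
    simulate_class_programs,
    simulate_tree,
)

__all__ = [
    "divergence_model_recovery",
    "orthotype_planted_recovery",
    "gage_planted_recovery",
    "flda_axis_recovery",
    "flda_ranking_success",
]


def divergence_model_recovery(
    seed: int,
    n_runs: int = 100,
    n_species: int = 15,
    n_genes: int = 4000,
    a: float = 0.4,
    b: float = 0.3,
) -> dict:
    """Repeatedly simulate power-law class programs and fit all models.

    Each run draws a fresh 15-species ultrametric tree (105 species
    pairs), evolves one class program under MSD = a t^b, and fits the
    power-law, linear and OU curves to the (t, MSD) cloud. Reports how
    often the power law wins on R-squared and the recovered exponent.
    """
    rng = np.random.default_rng(seed)
    wins, b_hats = 0, []
    for _ in range(n_runs):
        run_seed = int(rng.integers(2**31))
        cfg = SimulationConfig(
            seed=run_seed,
            n_species=n_species,
            n_genes=n_genes,
            classes={"PR": 30},
            divergence_model="powerlaw",
            divergence_params={"a": a, "b": b},
        )
        tree = simulate_tree(n_species, cfg.tree_depth, seed=run_seed)
        programs = simulate_class_programs(tree, cfg)
        D = tree_distance_matrix(tree)
        species = list(programs)
        t, y = [], []
        for i, s1 in enumerate(species):
            for s2 in species[i + 1 :]:
                t.append(float(D.loc[s1, s2]))
                y.append(float(np.mean((programs[s1]["PR"] - programs[s2]["PR"]) ** 2)))
        fits = fit_all_models(np.asarray(t), np.asarray(y))
        if (
            fits["powerlaw"].r_squared >= fits["linear"].r_squared
            and fits["powerlaw"].r_squared >= fits["ou"].r_squared
        ):
            wins += 1
        b_hats.append(fits["powerlaw"].b)
    return {
        "n_runs": n_runs,
        "n_pairs": n_species * (n_species - 1) // 2,
        "powerlaw_best_fraction": wins / n_runs,
        "b_true": b,
        "b_hat_mean": float(np.mean(b_hats)),
        "b_hat_sd": float(np.std(b_hats)),
    }


def orthotype_planted_recovery(
    seed: int,
    n_types: int = 14,
    n_species: int = 5,
) -> dict:
    """Recover planted orthologous types by integration + clustering.

    Simulates one cell class with ``n_types`` planted types shared by
    ``n_species`` species (plus species shifts and replicate batch
    effects), integrates, clusters at resolution 0.5, merges
    species-disjoint orthotypes, and measures the orthotype count, the
    fraction of species clusters mapping specifically, and the ARI
    against the planted labels.
    """
    from sklearn.metrics import adjusted_rand_score

    cfg = SimulationConfig(
        seed=seed,
        n_species=n_species,
        classes={"BC": 40},
        types_per_class=n_types,
        cells_per_type=60,
        n_genes=1500,
        markers_per_type=20,
        attribute_class="BC",
        species_shift_sd=0.6,
    )
    atlas = simulate_atlas(cfg)
    norm = {s: normalize_log(qc_filter(a)) for s, a in atlas.species.items()}
    integ = integrate_species(norm, n_features=500, seed=seed)
    assign = merge_species_disjoint(cluster_orthotypes(integ, resolution=0.5, seed=seed))
    truth = integ.obs["type"].to_numpy()
    _, spec = confusion_and_specificity(assign, integ.obs["type"])
    return {
        "n_planted": n_types,
        "n_orthotypes": assign.n_orthotypes(),
        "specific_fraction": float(spec["specific"].mean()),
        "ari": float(adjusted_rand_score(truth, assign.labels.to_numpy())),
        "n_cells": int(integ.n_obs),
    }


def gage_planted_recovery(seed: int, n_decoys: int = 20, noise: float = 0.1) -> dict:
    """Shape-search checks: planted recovery, exactness and invariance.

    A reference quadruple is translated by a global species shift and
    hidden among ``n_decoys`` decoy centroids with per-gene noise; the
    exhaustive ordered search must rank it first. Also measures EV of
    an exact translate (must be 1), the EV change under global
    translations of either centroid set (gauge invariance), and the
    exhaustive enumeration size for a 45-type catalogue.
    """
    rng = np.random.default_rng(seed)
    g = 40
    P = rng.normal(size=(4, g))
    shift = rng.normal(size=g) * 2.0

    exact = gage.fit_shape(P + shift, P).explained_variance

    M = P + shift + rng.normal(size=(4, g)) * noise
    names = ["a1", "a2", "a3", "a4"] + [f"d{i}" for i in range(n_decoys)]
    C = np.vstack([M, rng.normal(size=(n_decoys, g))])
    cents = gage.CentroidSet(pd.DataFrame(C, index=names))
    res = gage.search_quadruples(cents, P, highlight=[("a1", "a2", "a3", "a4")])

    ev0 = gage.fit_shape(M, P).explained_variance
    gauge = rng.normal(size=g) * 3.0
    inv_err = max(
        abs(gage.fit_shape(M + gauge, P).explained_variance - ev0),
        abs(gage.fit_shape(M, P + gauge).explained_variance - ev0),
    )

    full = gage.enumerate_assignments(45)
    return {
        "planted_rank": res.highlight_ranks[("a1", "a2", "a3", "a4")],
        "n_candidates": res.n_candidates,
        "zero_noise_ev": float(exact),
        "translation_invariance_error": float(inv_err),
        "enumeration_count_45": int(len(full)),
    }


def flda_axis_recovery(seed: int, snr: float = 5.0) -> dict:
    """Planted-direction recovery and the covariance additivity identity.

    A balanced 2x2x2 factorial design with orthogonal effect
    directions at the requested signal-to-noise ratio (effect size over
    noise s.d.); reports the weakest axis-direction cosine and the
    trace-additivity error of the covariance split.
    """
    noise_sd = 1.0 / snr
    X, attrs, dirs = simulate_attribute_design(
        n_per_combo=250, n_genes=60, effects={k: 1.0 for k in ("polarity", "kinetics", "species")},
        noise_sd=noise_sd, seed=seed,
    )
    sig = flda.decompose_covariance(X, attrs)
    axes = flda.solve_axes(sig)
    cosines = {
        a: float(abs(axes.axes[a].to_numpy() @ d) / np.linalg.norm(d))
        for a, d in dirs.items()
    }
    additivity = abs(
        np.trace(sig["total"])
        - sum(np.trace(sig[k]) for k in ("polarity", "kinetics", "species", "residual"))
    )
    return {
        "snr": snr,
        "cosine_min": min(cosines.values()),
        "cosines": cosines,
        "additivity_error": float(additivity),
        "n_cells": int(X.shape[0]),
    }


def _atlas_ranking_once(seed: int) -> tuple[int, int]:
    """One ranking run on a 20-type two-species atlas; returns
    (rank of planted quadruple, number of candidates)."""
    cfg = SimulationConfig(
        seed=seed,
        n_species=2,
        classes={"RGC": 40},
        types_per_class=20,
        quadrant_sizes=(6, 6, 2, 6),
        cells_per_type=80,
        n_genes=1500,
        markers_per_type=15,
    )
    atlas = simulate_atlas(cfg)
    norm = {s: normalize_log(a) for s, a in atlas.species.items()}
    import anndata as ad

    comb = ad.concat(norm, label="side", index_unique="-", merge="same")
    ta = atlas.truth["type_attributes"]
    side = np.where(comb.obs["side"].to_numpy() == "sp01", "m_", "p_")
    types = pd.Series(
        [p + t for p, t in zip(side, comb.obs["type"])], index=comb.obs_names
    )
    catalog = pd.DataFrame(
        [
            {"type": "m_" + t, "polarity": v["polarity"], "kinetics": v["kinetics"]}
            for t, v in ta.items()
        ]
    )
    quad_first: dict = {}
    for t, v in ta.items():
        quad_first.setdefault((v["polarity"], v["kinetics"]), t)
    reference = {q: "p_" + quad_first[q] for q in flda.QUADRANTS}
    planted = tuple("m_" + quad_first[q] for q in flda.QUADRANTS)
    X = comb.X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    ranking = flda.rank_quadruples(X, types, catalog, reference)
    rank = int(ranking.loc[ranking["types"] == planted, "rank"].iloc[0])
    return rank, len(ranking)


def flda_ranking_success(seed: int, n_runs: int = 50) -> dict:
    """Fraction of simulations in which the planted orthologous
    quadruple ranks first among all 432 candidates."""
    rng = np.random.default_rng(seed)
    n_first, n_cands = 0, None
    ranks = []
    for _ in range(n_runs):
        rank, n_cands = _atlas_ranking_once(int(rng.integers(2**31)))
        ranks.append(rank)
        if rank == 1:
            n_first += 1
    return {
        "n_runs": n_runs,
        "n_candidates": n_cands,
        "rank1_fraction": n_first / n_runs,
        "worst_rank": int(max(ranks)),
    }
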