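"""Factorized linear discriminant analysis (FLDA).

Cells carry categorical attributes — response polarity (ON/OFF),
response kinetics (sustained/transient) and species (mouse/primate).
The total expression covariance decomposes additively into
per-attribute main-effect covariances plus a residual,

    Sigma_T = Sigma_A + Sigma_B + Sigma_C + Sigma_e,

and each attribute's discriminant axis is the leading generalized
eigenvector of its covariance against the sum of all the others: the
axis captures that attribute's variation while minimally co-varying
with the remaining attributes. Projecting cells onto the three axes
yields a 3D embedding whose coordinates read out polarity, kinetics
and species.

``rank_quadruples`` scores candidate sets of four types (one per
polarity x kinetics quadrant) from one species against a fixed
four-type reference from another, by the variance FLDA captures along
the polarity and kinetics axes of the combined eight-type design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

__all__ = [
    "FLDAxes",
    "decompose_covariance",
    "solve_axes",
    "project",
    "enumerate_quadrant_candidates",
    "rank_quadruples",
    "synthetic_mouse_rgc_catalog",
]

QUADRANTS = [
    ("ON", "sustained"),
    ("ON", "transient"),
    ("OFF", "sustained"),
    ("OFF", "transient"),
]


@dataclass
class FLDAxes:
    """Per-attribute unit-norm discriminant directions in gene space."""

    axes: pd.DataFrame  # genes x attributes
    eigenvalues: dict[str, float]  # attribute-contrast ratio per axis
    variance_fractions: pd.DataFrame  # axis x (attribute components + residual)


def _as_dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)


def decompose_covariance(
    X, attributes: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Split the total covariance into attribute main effects + residual.

    ``X`` is cells x genes (normalized expression); ``attributes`` has
    one categorical column per attribute, aligned with rows of ``X``.
    Each attribute covariance is the cell-count-weighted covariance of
    that attribute's level means around the grand mean; interactions
    and within-group variance remain in the residual. The decomposition
    is additive by construction. Every attribute-level combination must
    be populated (a full factorial design).
    """
    X = _as_dense(X)
    n = X.shape[0]
    if len(attributes) != n:
        raise ValueError("attributes must have one row per cell")
    attrs = list(attributes.columns)
    for col in attrs:
        if attributes[col].nunique() < 2:
            raise ValueError(f"attribute {col!r} needs >= 2 levels")
    combos = attributes.groupby(attrs, observed=True).size()
    expected = int(np.prod([attributes[c].nunique() for c in attrs]))
    if len(combos) < expected:
        raise ValueError("design has empty attribute-level combinations")

    grand = X.mean(axis=0)
    Xc = X - grand
    sigma_t = Xc.T @ Xc / n

    out: dict[str, np.ndarray] = {"total": sigma_t}
    accounted = np.zeros_like(sigma_t)
    for col in attrs:
        sigma = np.zeros_like(sigma_t)
        for _, idx in attributes.groupby(col, observed=True).indices.items():
            d = X[idx].mean(axis=0) - grand
            sigma += (len(idx) / n) * np.outer(d, d)
        out[col] = sigma
        accounted += sigma
    out["residual"] = sigma_t - accounted
    return out


def solve_axes(
    sigmas: dict[str, np.ndarray],
    ridge: float | None = None,
) -> FLDAxes:
    """Solve each attribute's generalized eigenproblem for its axis.

    For attribute A the axis maximizes u' Sigma_A u / u' (Sigma_B +
    Sigma_C + Sigma_e + ridge I) u. The default ridge is 1e-3 times the
    mean diagonal of the denominator, which keeps the problem well
    posed when genes outnumber cells; pass ``ridge=0`` to disable.
    """
    attrs = [k for k in sigmas if k not in ("total", "residual")]
    genes = sigmas["total"].shape[0]
    axes = {}
    eigenvalues = {}
    for attr in attrs:
        denom = sigmas["residual"].copy()
        for other in attrs:
            if other != attr:
                denom = denom + sigmas[other]
        eps = ridge
        if eps is None:
            eps = 1e-3 * float(np.mean(np.diag(denom)))
        denom_r = denom + eps * np.eye(genes)
        if eps == 0:
            if np.linalg.matrix_rank(denom_r) < genes:
                raise np.linalg.LinAlgError(
                    "denominator covariance is singular; use ridge > 0"
                )
        vals, vecs = scipy.linalg.eigh(sigmas[attr], denom_r)
        u = vecs[:, -1]
        u = u / np.linalg.norm(u)
        axes[attr] = u
        eigenvalues[attr] = float(vals[-1])

    frac_rows = {}
    for attr, u in axes.items():
        row = {comp: float(u @ sigmas[comp] @ u) for comp in attrs}
        row["residual"] = float(u @ sigmas["residual"] @ u)
        row["total"] = float(u @ sigmas["total"] @ u)
        frac_rows[attr] = row
    return FLDAxes(
        axes=pd.DataFrame(axes),
        eigenvalues=eigenvalues,
        variance_fractions=pd.DataFrame(frac_rows).T,
    )


def project(X, axes: FLDAxes, gene_names=None, center: bool = True) -> pd.DataFrame:
    """Project cells onto the solved axes (inner products)."""
    X = _as_dense(X)
    A = axes.axes
    if X.shape[1] != A.shape[0]:
        raise ValueError(
            f"gene-set mismatch: data has {X.shape[1]} genes, axes have {A.shape[0]}"
        )
    if gene_names is not None and not np.array_equal(
        np.asarray(gene_names), A.index.to_numpy()
    ):
        raise ValueError("gene names do not match the axes' gene set")
    if center:
        X = X - X.mean(axis=0)
    return pd.DataFrame(X @ A.to_numpy(), columns=A.columns)


# ---------------------------------------------------------------------------
# Quadruple ranking against a fixed reference
# ---------------------------------------------------------------------------

def synthetic_mouse_rgc_catalog() -> pd.DataFrame:
    """A synthetic stand-in catalogue of 20 attribute-annotated RGC types.

    Synthetic: type names are generic placeholders, not transcriptomic
    cluster names. Quadrant sizes are 6 ON-sustained, 6 ON-transient,
    6 OFF-transient and 2 OFF-sustained types (OFF-sustained types are
    the rarest annotated group), so one-per-quadrant enumeration yields
    6 * 6 * 2 * 6 = 432 candidate quadruples from the 20 types.
    """
    rows = []
    sizes = {("ON", "sustained"): 6, ("ON", "transient"): 6,
             ("OFF", "sustained"): 2, ("OFF", "transient"): 6}
    for (pol, kin), n in sizes.items():
        for i in range(n):
            rows.append(
                {"type": f"{pol}{kin[0]}_{i + 1}", "polarity": pol, "kinetics": kin}
            )
    return pd.DataFrame(rows)


def enumerate_quadrant_candidates(catalog: pd.DataFrame) -> list[tuple[str, str, str, str]]:
    """All one-type-per-quadrant quadruples from an annotated catalogue.

    ``catalog`` needs columns type/polarity/kinetics. The count is the
    product of the four quadrant sizes. Order within each tuple follows
    the fixed quadrant order (ON-s, ON-t, OFF-s, OFF-t).
    """
    pools = []
    for pol, kin in QUADRANTS:
        pool = catalog.loc[
            (catalog["polarity"] == pol) & (catalog["kinetics"] == kin), "type"
        ].tolist()
        if not pool:
            raise ValueError(f"no types annotated {pol}/{kin}")
        pools.append(sorted(pool))
    return list(itertools.product(*pools))


def rank_quadruples(
    X,
    types: pd.Series,
    catalog: pd.DataFrame,
    reference_types: dict[tuple[str, str], str],
    candidates: list[tuple[str, str, str, str]] | None = None,
    n_features: int = 100,
    ridge_scale: float = 1e-3,
    score: str = "sum",
) -> pd.DataFrame:
    """Rank candidate quadruples against the fixed reference quadruple.

    For each candidate (one type per polarity x kinetics quadrant), an
    FLDA is fitted on the cells of the 8 combined types — the 4
    reference types plus the candidate 4 — with polarity, kinetics and
    species as attributes (species = reference vs candidate side). The
    score is the variance captured along the polarity and kinetics axes
    (sum of the two generalized eigenvalues by default; ``score='min'``
    uses the weaker of the two instead). Ties break by score, then
    lexicographic type names.

    Features are pre-selected once: genes are ranked by their variance
    across type centroids after centering within each species side, so
    type-distinguishing genes are kept rather than genes dominated by
    the global species shift, and the ``n_features`` default keeps the
    feature count well below the cell count — the generalized
    eigenvalues are whitened by an estimated covariance, whose sampling
    noise grows with the feature-to-cell ratio. The fixed feature set
    lets each candidate's covariances be assembled from per-type
    sufficient statistics. For two-level attributes each
    attribute covariance is rank one, so its leading generalized
    eigenvalue has the closed form ``w+ w- d' (D + eps I)^{-1} d`` with
    ``d`` the level-mean difference and ``D`` the summed covariance of
    everything else; this equals what :func:`solve_axes` computes.
    """
    X = _as_dense(X)
    type_arr = np.asarray(types)
    attr_of = catalog.set_index("type")[["polarity", "kinetics"]]
    for (pol, kin) in QUADRANTS:
        if (pol, kin) not in reference_types:
            raise ValueError(f"reference missing a {pol}/{kin} type")
    if candidates is None:
        candidates = enumerate_quadrant_candidates(catalog)
    for cand in candidates:
        for t, (pol, kin) in zip(cand, QUADRANTS):
            if t not in attr_of.index:
                raise ValueError(f"candidate type {t!r} not in catalogue")
            got = tuple(attr_of.loc[t])
            if got != (pol, kin):
                raise ValueError(
                    f"candidate {cand} is attribute-inconsistent: {t!r} is "
                    f"{got[0]}/{got[1]}, expected {pol}/{kin}"
                )

    ref_names = [reference_types[q] for q in QUADRANTS]
    pool = set(ref_names) | {t for cand in candidates for t in cand}
    idx_of = {t: np.flatnonzero(type_arr == t) for t in pool}
    for t in ref_names:
        if idx_of[t].size == 0:
            raise ValueError(f"reference type {t!r} has no cells")

    # feature selection: genes most variable across type centroids after
    # centering within each species side, so that type-distinguishing
    # genes are kept rather than genes dominated by the species shift
    ref_set = set(ref_names)
    cent_rows = {"reference": [], "candidate": []}
    for t in sorted(pool):
        if idx_of[t].size == 0:
            continue
        side = "reference" if t in ref_set else "candidate"
        cent_rows[side].append(X[idx_of[t]].mean(axis=0))
    centered = []
    for side_rows in cent_rows.values():
        if side_rows:
            M = np.vstack(side_rows)
            centered.append(M - M.mean(axis=0))
    cents = np.vstack(centered)
    variances = cents.var(axis=0)
    feat = np.sort(np.argsort(variances)[::-1][: min(n_features, X.shape[1])])
    Xf = X[:, feat]

    # per-type sufficient statistics on the fixed feature set
    stats = {
        t: (
            idx_of[t].size,
            Xf[idx_of[t]].sum(axis=0),
            Xf[idx_of[t]].T @ Xf[idx_of[t]],
        )
        for t in pool
    }

    def rank1_eig(n_levels: dict, m_levels: dict, grand, sigma_t, eps_eye):
        (la, lb) = sorted(n_levels)
        n = sum(n_levels.values())
        w_a, w_b = n_levels[la] / n, n_levels[lb] / n
        d = m_levels[la] - m_levels[lb]
        sigma_attr = (w_a * w_b) * np.outer(d, d)
        denom = sigma_t - sigma_attr + eps_eye
        sol = np.linalg.solve(denom, d)
        return (w_a * w_b) * float(d @ sol), sigma_attr

    rows = []
    g = len(feat)
    for cand in candidates:
        members = list(zip(ref_names, QUADRANTS, ["reference"] * 4)) + list(
            zip(cand, QUADRANTS, ["candidate"] * 4)
        )
        n_tot = sum(stats[t][0] for t, _, _ in members)
        s1 = sum(stats[t][1] for t, _, _ in members)
        s2 = sum(stats[t][2] for t, _, _ in members)
        grand = s1 / n_tot
        sigma_t = s2 / n_tot - np.outer(grand, grand)
        eigs = {}
        for attr, level_of in (
            ("polarity", {t: q[0] for t, q, _ in members}),
            ("kinetics", {t: q[1] for t, q, _ in members}),
            ("species", {t: side for t, _, side in members}),
        ):
            n_levels: dict = {}
            s_levels: dict = {}
            for t, _, _ in members:
                lev = level_of[t]
                n_levels[lev] = n_levels.get(lev, 0) + stats[t][0]
                s_levels[lev] = s_levels.get(lev, 0) + stats[t][1]
            m_levels = {lev: s_levels[lev] / n_levels[lev] for lev in n_levels}
            # ridge scaled to the mean denominator diagonal
            w = list(n_levels.values())
            d = m_levels[sorted(n_levels)[0]] - m_levels[sorted(n_levels)[1]]
            wab = (w[0] / n_tot) * (w[1] / n_tot)
            denom_diag = np.trace(sigma_t) / g - wab * float(d @ d) / g
            eps_eye = ridge_scale * denom_diag * np.eye(g)
            eigs[attr], _ = rank1_eig(n_levels, m_levels, grand, sigma_t, eps_eye)
        lp, lk = eigs["polarity"], eigs["kinetics"]
        s = lp + lk if score == "sum" else min(lp, lk)
        rows.append(
            {
                "types": tuple(cand),
                "score": s,
                "polarity_eig": lp,
                "kinetics_eig": lk,
                "species_eig": eigs["species"],
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["score", "types"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
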