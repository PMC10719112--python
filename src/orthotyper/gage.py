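"""Geometric analysis of gene expression (GAGE).

The four reference types (e.g. primate ON/OFF midget and parasol
ganglion cells) form a four-cornered shape in gene expression space —
the quadruple of their cluster centroids. GAGE asks whether four types
of another species form the *same* shape up to a pure translation (a
uniform species shift applied to every gene), with no rotation or
scaling. The fit is scored by the fraction of the reference shape's
variance explained by the translated candidate shape:

    EV = 1 - sum_i ||(m_i - delta) - p_i||^2 / sum_i ||p_i - mean(p)||^2

where delta = mean(m) - mean(p) is the least-squares translation.
EV = 1 exactly when the shapes are exact translates; EV can be
negative for badly mismatched shapes.

The search enumerates either attribute-constrained candidates (one
type per polarity x kinetics slot) or every ordered assignment of four
distinct types to the four slots — n(n-1)(n-2)(n-3) tuples, scored in
a single vectorized pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CentroidSet",
    "ShapeFit",
    "SearchResult",
    "compute_centroids",
    "fit_shape",
    "enumerate_assignments",
    "search_quadruples",
]


@dataclass
class CentroidSet:
    """Per-type mean expression vectors over a shared feature set."""

    centroids: pd.DataFrame  # types x genes
    attributes: pd.DataFrame | None = None  # type -> polarity/kinetics
    species: str | None = None

    def __post_init__(self) -> None:
        if self.centroids.index.duplicated().any():
            raise ValueError("duplicate type names")


@dataclass
class ShapeFit:
    types: tuple[str, str, str, str]
    delta: np.ndarray  # least-squares translation, mouse -> primate frame
    residuals: np.ndarray  # 4 x genes, sums to ~0 over corners
    explained_variance: float


@dataclass
class SearchResult:
    ranking: pd.DataFrame  # top candidates: types, EV, rank
    ev_all: np.ndarray  # EV of every enumerated candidate
    histogram: pd.DataFrame  # binned EV counts over all candidates
    n_candidates: int
    highlight_ranks: dict[tuple, int] = field(default_factory=dict)


def compute_centroids(
    adata: ad.AnnData,
    type_col: str = "type",
    types: list[str] | None = None,
    features: list[str] | None = None,
    attribute_cols: tuple[str, str] = ("polarity", "kinetics"),
) -> CentroidSet:
    """Mean normalized expression per type over a shared feature set."""
    if features is not None:
        missing = set(features) - set(adata.var_names)
        if missing:
            raise KeyError(f"features absent from data: {sorted(missing)[:5]} ...")
        adata = adata[:, features]
    X = adata.X
    rows, names, attr_rows = [], [], []
    for t, idx in adata.obs.groupby(type_col, observed=True).indices.items():
        if types is not None and t not in types:
            continue
        sub = X[idx]
        rows.append(np.asarray(sub.mean(axis=0)).ravel())
        names.append(str(t))
        attr_rows.append(
            {c: adata.obs[c].iloc[idx[0]] for c in attribute_cols if c in adata.obs}
        )
    centroids = pd.DataFrame(np.vstack(rows), index=names, columns=adata.var_names)
    attrs = pd.DataFrame(attr_rows, index=names) if attr_rows and attr_rows[0] else None
    return CentroidSet(centroids=centroids, attributes=attrs)


def fit_shape(mouse_quad: np.ndarray, primate_quad: np.ndarray, types=None) -> ShapeFit:
    """Fit a translation-only match of one 4-corner shape to another.

    Rows are corners (slot order defines the assignment), columns
    genes. The optimal translation is the difference of corner means;
    explained variance is relative to the reference (primate) shape's
    own scatter, so EV = 1 iff the shapes are exact translates.
    """
    m = np.asarray(mouse_quad, dtype=float)
    p = np.asarray(primate_quad, dtype=float)
    if m.shape != p.shape or m.shape[0] != 4:
        raise ValueError("both quadruples must be 4 x genes with matching genes")
    p_center = p.mean(axis=0)
    scatter = float(np.sum((p - p_center) ** 2))
    if scatter == 0:
        raise ValueError("degenerate reference shape (all corners equal): EV undefined")
    delta = m.mean(axis=0) - p_center
    residuals = (m - delta) - p
    ev = 1.0 - float(np.sum(residuals**2)) / scatter
    return ShapeFit(
        types=tuple(types) if types is not None else ("m1", "m2", "m3", "m4"),
        delta=delta,
        residuals=residuals,
        explained_variance=ev,
    )


def enumerate_assignments(n: int) -> np.ndarray:
    """All ordered assignments of 4 distinct items from n to the 4 slots.

    Returns an (n(n-1)(n-2)(n-3), 4) index array; for n = 45 that is
    3,575,880 assignments.
    """
    if n < 4:
        raise ValueError("need at least 4 types")
    idx = np.arange(n, dtype=np.int32)
    c0 = np.repeat(idx, n * n * n)
    c1 = np.tile(np.repeat(idx, n * n), n)
    c2 = np.tile(np.repeat(idx, n), n * n)
    c3 = np.tile(idx, n * n * n)
    distinct = (
        (c0 != c1)
        & (c0 != c2)
        & (c0 != c3)
        & (c1 != c2)
        & (c1 != c3)
        & (c2 != c3)
    )
    return np.stack([c0[distinct], c1[distinct], c2[distinct], c3[distinct]], axis=1)


def _ev_batch(C: np.ndarray, P: np.ndarray, tuples: np.ndarray) -> np.ndarray:
    """Vectorized EV for many slot assignments.

    ``C``: candidate centroids (n x genes); ``P``: reference corners
    (4 x genes, slot order); ``tuples``: (m, 4) candidate row indices.
    """
    p_center = P.mean(axis=0)
    Pt = P - p_center
    scatter = float(np.sum(Pt**2))
    K = C @ C.T  # n x n gram
    B = C @ Pt.T  # n x 4 cross terms with centred reference
    sq = np.einsum("ij->i", C * C)  # ||c_j||^2

    g = tuples
    # sum_i ||c_{j_i}||^2
    s_sq = sq[g].sum(axis=1)
    # ||sum_i c_{j_i}||^2 via pairwise gram sums
    s_pair = np.zeros(len(g))
    for i in range(4):
        for k in range(4):
            s_pair += K[g[:, i], g[:, k]]
    # sum_i <c_{j_i}, p~_i>
    cross = sum(B[g[:, i], i] for i in range(4))
    # residual SS = sum ||c~_i||^2 - 2 cross + scatter
    cand_scatter = s_sq - 0.25 * s_pair
    res = cand_scatter - 2.0 * cross + scatter
    return 1.0 - res / scatter


def search_quadruples(
    candidates: CentroidSet,
    reference_quad: pd.DataFrame | np.ndarray,
    mode: str = "exhaustive",
    reference_slots: list[str] | None = None,
    highlight: list[tuple[str, str, str, str]] | None = None,
    top: int = 50,
    bins: int = 50,
) -> SearchResult:
    """Score every candidate quadruple's translation fit to the reference.

    ``mode='exhaustive'`` enumerates all ordered assignments of four
    distinct candidate types to the four reference slots;
    ``mode='constrained'`` only assigns types whose polarity/kinetics
    annotations match each slot (requires ``candidates.attributes`` and
    ``reference_slots`` naming each slot's quadrant as
    'polarity/kinetics', e.g. 'ON/sustained'). Candidates are ranked by
    explained variance descending with deterministic tie-breaks (EV,
    then lexicographic type names); the full EV distribution is
    returned as a histogram, and ranks of ``highlight`` quadruples are
    reported.
    """
    C = candidates.centroids.to_numpy(dtype=float)
    names = np.asarray(candidates.centroids.index)
    P = (
        reference_quad.to_numpy(dtype=float)
        if isinstance(reference_quad, pd.DataFrame)
        else np.asarray(reference_quad, dtype=float)
    )
    if P.shape[0] != 4 or P.shape[1] != C.shape[1]:
        raise ValueError("reference must be 4 x genes on the candidate feature set")
    n = C.shape[0]

    if mode == "exhaustive":
        tuples = enumerate_assignments(n)
    elif mode == "constrained":
        if candidates.attributes is None or reference_slots is None:
            raise ValueError(
                "constrained mode needs candidate attributes and reference_slots"
            )
        pools = []
        attrs = candidates.attributes
        for slot in reference_slots:
            pol, kin = slot.split("/")
            pool = np.flatnonzero(
                (attrs["polarity"].to_numpy() == pol)
                & (attrs["kinetics"].to_numpy() == kin)
            )
            if pool.size == 0:
                raise ValueError(f"no candidate types annotated {slot}")
            pools.append(pool)
        grids = np.meshgrid(*pools, indexing="ij")
        tuples = np.stack([g.ravel() for g in grids], axis=1)
        distinct = np.ones(len(tuples), dtype=bool)
        for i in range(4):
            for k in range(i + 1, 4):
                distinct &= tuples[:, i] != tuples[:, k]
        tuples = tuples[distinct]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ev = _ev_batch(C, P, tuples)

    name_tuples = names[tuples]
    # lexsort: last key is primary -> descending EV, ties by type names
    ranked = np.lexsort(
        (name_tuples[:, 3], name_tuples[:, 2], name_tuples[:, 1], name_tuples[:, 0], -ev)
    )

    top_k = ranked[:top]
    ranking = pd.DataFrame(
        {
            "types": [tuple(r) for r in name_tuples[top_k]],
            "explained_variance": ev[top_k],
            "rank": np.arange(1, len(top_k) + 1),
        }
    )
    lo = min(float(ev.min()), 0.0)
    hi = max(float(ev.max()), 1.0)
    hist_counts, edges = np.histogram(ev, bins=bins, range=(lo, hi))
    histogram = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist_counts}
    )

    highlight_ranks: dict[tuple, int] = {}
    if highlight:
        key_of = {tuple(r): pos + 1 for pos, r in enumerate(name_tuples[ranked])}
        for h in highlight:
            highlight_ranks[tuple(h)] = key_of.get(tuple(h), -1)

    return SearchResult(
        ranking=ranking,
        ev_all=ev,
        histogram=histogram,
        n_candidates=int(len(tuples)),
        highlight_ranks=highlight_ranks,
    )
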