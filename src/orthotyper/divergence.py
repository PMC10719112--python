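"""Pseudobulk class profiles and expression divergence versus phylogeny.

Builds cell-averaged ("pseudobulk") expression vectors per
(species, class) group over the shared 1:1 orthologue space, computes
their cross-correlation structure, and fits mean squared divergence
(MSD) against evolutionary distance under three candidate models:

* power law      MSD = a * t^b
* linear         MSD = a + b * t
* Ornstein-Uhlenbeck  MSD = a * (1 - e^{-b t})

The power law (with exponent well below 1) is the signature of
divergence that decelerates with time; the OU curve saturates, as
expected under stabilizing selection; the linear form is the neutral
Brownian expectation. R-squared is computed on the original MSD scale
for all three models so they are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats
from scipy.cluster import hierarchy

__all__ = [
    "PseudobulkMatrix",
    "DivergenceFit",
    "FitConvergenceError",
    "pseudobulk",
    "msd",
    "msd_vs_distance",
    "fit_divergence",
    "fit_all_models",
    "class_cross_correlation",
    "profile_dendrogram",
]

Model = Literal["powerlaw", "linear", "ou"]


@dataclass
class PseudobulkMatrix:
    """(species, class)-indexed mean expression profiles."""

    profiles: pd.DataFrame  # MultiIndex (species, class) x genes
    zscored: bool

    def vector(self, species: str, cls: str) -> np.ndarray:
        return self.profiles.loc[(species, cls)].to_numpy()


@dataclass
class DivergenceFit:
    model: Model
    a: float
    b: float
    r_squared: float
    n_pairs: int


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed; carries the initializer fit."""

    def __init__(self, message: str, initializer: DivergenceFit):
        super().__init__(message)
        self.initializer = initializer


def pseudobulk(
    adata: ad.AnnData,
    class_col: str = "class",
    species_col: str = "species",
    zscore: bool = True,
) -> PseudobulkMatrix:
    """Cell-averaged expression per (species, class) group.

    Expects normalized log expression in ``adata.X``. Each profile is
    z-scored across genes afterwards on request; empty groups are
    omitted with a warning.
    """
    X = adata.X
    rows, index = [], []
    for (s, c), idx in adata.obs.groupby(
        [species_col, class_col], observed=True
    ).indices.items():
        if len(idx) == 0:
            warnings.warn(f"empty group ({s}, {c}) omitted")
            continue
        sub = X[idx]
        vec = np.asarray(sub.mean(axis=0)).ravel()
        rows.append(vec)
        index.append((s, c))
    profiles = pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(index, names=["species", "class"]),
        columns=adata.var_names,
    )
    if zscore:
        vals = profiles.to_numpy()
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        profiles = pd.DataFrame(
            (vals - mu) / sd, index=profiles.index, columns=profiles.columns
        )
    return PseudobulkMatrix(profiles=profiles, zscored=zscore)


def msd(a: np.ndarray, b: np.ndarray, per_gene: bool = True) -> float:
    """Squared euclidean divergence between two profiles.

    With ``per_gene`` (default) the squared distance is averaged over
    genes — the mean squared divergence; otherwise the raw sum
    ``||a - b||^2`` is returned. The two differ by a constant factor
    (the gene count), which rescales the fitted amplitude ``a`` but
    leaves exponents, rates and R-squared unchanged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    d2 = float(np.sum((a - b) ** 2))
    return d2 / a.size if per_gene else d2


def msd_vs_distance(
    pb: PseudobulkMatrix,
    distances: pd.DataFrame,
    cls: str,
    per_gene: bool = True,
) -> pd.DataFrame:
    """All species-pair (t, MSD) points for one class.

    ``distances`` is a symmetric species x species patristic distance
    matrix (see :func:`orthotyper.orthology.tree_distance_matrix`).
    """
    sub = pb.profiles.xs(cls, level="class")
    species = [s for s in sub.index if s in distances.index]
    rows = []
    for i, s1 in enumerate(species):
        for s2 in species[i + 1 :]:
            rows.append(
                {
                    "species_1": s1,
                    "species_2": s2,
                    "t": float(distances.loc[s1, s2]),
                    "msd": msd(sub.loc[s1].to_numpy(), sub.loc[s2].to_numpy(), per_gene),
                }
            )
    return pd.DataFrame(rows)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_divergence(t: np.ndarray, y: np.ndarray, model: Model) -> DivergenceFit:
    """Fit one divergence model to (t, MSD) pairs.

    The power law is fitted by nonlinear least squares initialized from
    log-log OLS; the OU curve by nonlinear least squares; the linear
    model in closed form. R-squared is evaluated on the original scale.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 (t, MSD) pairs")
    if np.any(t <= 0):
        raise ValueError("all t must be > 0")
    n = int(t.size)

    if model == "linear":
        slope, intercept = np.polyfit(t, y, 1)
        yhat = intercept + slope * t
        return DivergenceFit("linear", float(intercept), float(slope), _r_squared(y, yhat), n)

    if model == "powerlaw":
        mask = y > 0
        lb, la = np.polyfit(np.log(t[mask]), np.log(y[mask]), 1)
        init = DivergenceFit("powerlaw", float(np.exp(la)), float(lb), np.nan, n)
        try:
            (a, b), _ = optimize.curve_fit(
                lambda x, a, b: a * np.power(x, b),
                t,
                y,
                p0=[init.a, init.b],
                maxfev=10000,
            )
        except RuntimeError as err:
            init.r_squared = _r_squared(y, init.a * np.power(t, init.b))
            raise FitConvergenceError(str(err), init) from err
        yhat = a * np.power(t, b)
        return DivergenceFit("powerlaw", float(a), float(b), _r_squared(y, yhat), n)

    if model == "ou":
        a0 = float(np.max(y)) * 1.05
        b0 = 1.0 / float(np.median(t))
        init = DivergenceFit("ou", a0, b0, np.nan, n)
        try:
            (a, b), _ = optimize.curve_fit(
                lambda x, a, b: a * (1.0 - np.exp(-b * x)),
                t,
                y,
                p0=[a0, b0],
                maxfev=10000,
            )
        except RuntimeError as err:
            init.r_squared = _r_squared(y, a0 * (1 - np.exp(-b0 * t)))
            raise FitConvergenceError(str(err), init) from err
        yhat = a * (1.0 - np.exp(-b * t))
        return DivergenceFit("ou", float(a), float(b), _r_squared(y, yhat), n)

    raise ValueError(f"unknown model {model!r}")


def fit_all_models(t: np.ndarray, y: np.ndarray) -> dict[str, DivergenceFit]:
    """Fit all three models; non-converging fits fall back to initializers."""
    fits: dict[str, DivergenceFit] = {}
    for model in ("powerlaw", "linear", "ou"):
        try:
            fits[model] = fit_divergence(t, y, model)
        except FitConvergenceError as err:
            fits[model] = err.initializer
    return fits


def class_cross_correlation(
    pb: PseudobulkMatrix,
    method: str = "spearman",
    group_by: str = "class",
) -> pd.DataFrame:
    """(species, class) x (species, class) profile correlation matrix.

    Rows/columns are ordered by ``group_by`` ('class' or 'species'),
    mirroring the two report orderings. Constant profiles yield NaN
    (undefined correlation) with a warning.
    """
    profiles = pb.profiles
    order = profiles.index.sortlevel(group_by)[0]
    profiles = profiles.loc[order]
    vals = profiles.to_numpy()
    if np.any(vals.std(axis=1) == 0):
        warnings.warn("constant profile: correlations with it are undefined (NaN)")
    if method == "spearman":
        corr, _ = stats.spearmanr(vals.T)
        if np.ndim(corr) == 0:  # exactly two profiles
            corr = np.array([[1.0, float(corr)], [float(corr), 1.0]])
    elif method == "pearson":
        corr = np.corrcoef(vals)
    else:
        raise ValueError(f"unknown method {method!r}")
    labels = [f"{s}|{c}" for s, c in profiles.index]
    return pd.DataFrame(corr, index=labels, columns=labels)


def profile_dendrogram(pb: PseudobulkMatrix, method: str = "average") -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of pseudobulk profiles.

    Average linkage on correlation distance (1 - Spearman rho); returns
    the scipy linkage matrix and the leaf labels in input row order.
    """
    profiles = pb.profiles
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    corr, _ = stats.spearmanr(profiles.to_numpy().T)
    if np.ndim(corr) == 0:  # exactly two profiles
        corr = np.array([[1.0, float(corr)], [float(corr), 1.0]])
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method=method)
    labels = [f"{s}|{c}" for s, c in profiles.index]
    return Z, labels
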