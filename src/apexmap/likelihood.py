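"""Sample-associated relative likelihood via graph smoothing.

Detects cell states depleted or enriched in one sample (genotype)
relative to another. A kNN graph is built over per-cell embedding
coordinates; the one-hot sample indicator of each (sample, replicate) is
low-pass filtered on the graph by the Tikhonov filter

    density = (I + beta * L_sym)^-1 indicator,

a closed-form stand-in for graph-signal-processing density estimators:
beta controls the smoothing bandwidth (0 = no smoothing, large beta
approaches the graph's stationary signal). Densities are normalized per
sample and converted to the relative likelihood that a cell's local
neighbourhood derives from the focal sample; cells beyond 2 s.d. of the
mean likelihood are called depleted or enriched. Graph parameters (knn,
beta) can be chosen by a permutation-based mean-squared-error search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

DEPLETED = "depleted"
UNAFFECTED = "unaffected"
ENRICHED = "enriched"
CATEGORIES = (DEPLETED, UNAFFECTED, ENRICHED)

KERNELS = ("binary", "gaussian-adaptive")


@dataclass
class GraphParams:
    """kNN-graph and filter parameters."""

    knn: int = 8
    beta: float = 10.0
    kernel: str = "gaussian-adaptive"

    def __post_init__(self) -> None:
        if self.knn < 1:
            raise ValueError("knn must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")


def build_knn_graph(
    coords: np.ndarray, knn: int, kernel: str = "gaussian-adaptive"
) -> sp.csr_matrix:
    """Symmetric weighted kNN adjacency over embedding coordinates.

    Gaussian-adaptive weights are ``exp(-d_ij^2 / (sigma_i sigma_j))``
    with ``sigma_i`` the distance from cell i to its knn-th neighbour;
    the binary kernel sets every kNN edge weight to 1. The graph is
    union-symmetrized (``max(W, W.T)``); self-loops are excluded and
    distance ties are broken by index.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    n = coords.shape[0]
    if knn >= n:
        raise ValueError(f"knn={knn} must be smaller than n_cells={n}")
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}")
    nn = NearestNeighbors(n_neighbors=knn + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    # drop the self column (first neighbour at distance 0, ties by index)
    dist, idx = dist[:, 1:], idx[:, 1:]
    rows = np.repeat(np.arange(n), knn)
    cols = idx.ravel()
    if kernel == "binary":
        vals = np.ones(n * knn)
    else:
        sigma = dist[:, -1].copy()
        sigma[sigma <= 0] = np.finfo(float).eps  # duplicate points
        vals = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    w = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return w.maximum(w.T).tocsr()


def _sym_laplacian(adjacency: sp.csr_matrix) -> sp.csr_matrix:
    deg = np.asarray(adjacency.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise ValueError("graph has isolated vertices; cannot normalize")
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    n = adjacency.shape[0]
    return sp.identity(n) - d_inv_sqrt @ adjacency @ d_inv_sqrt


def smooth_sample_density(
    adjacency: sp.csr_matrix, indicator: np.ndarray, beta: float
) -> np.ndarray:
    """Tikhonov-filtered sample indicator(s): solve (I + beta L_sym) x = s.

    ``indicator`` is an (n_cells,) vector or (n_cells, k) matrix of 0/1
    sample memberships; columns are filtered independently. Results are
    clipped at zero. ``beta=0`` returns the indicator unchanged.
    """
    ind = np.asarray(indicator, dtype=float)
    single = ind.ndim == 1
    if single:
        ind = ind[:, None]
    if ind.shape[0] != adjacency.shape[0]:
        raise ValueError("indicator length does not match graph size")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if beta == 0:
        out = ind.copy()
        return out.ravel() if single else out
    lap = _sym_laplacian(adjacency)
    n = adjacency.shape[0]
    system = (sp.identity(n) + beta * lap).tocsc()
    try:
        solve = spla.splu(system).solve
    except RuntimeError as err:  # pragma: no cover - pathological graphs
        raise np.linalg.LinAlgError(
            f"Tikhonov system is singular or ill-conditioned: {err}"
        ) from err
    out = np.clip(solve(ind), 0.0, None)
    return out.ravel() if single else out


def relative_likelihood(
    density_focal: np.ndarray, density_other: np.ndarray
) -> np.ndarray:
    """Per-cell likelihood of deriving from the focal sample.

    Each sample's density vector is first normalized to sum to one
    (per-sample normalization, making the result invariant to sample
    size), then the likelihood is ``rho_f / (rho_f + rho_o)``.
    """
    f = np.asarray(density_focal, dtype=float)
    o = np.asarray(density_other, dtype=float)
    if f.sum() <= 0 or o.sum() <= 0:
        raise ValueError("sample densities must have positive mass")
    f = f / f.sum()
    o = o / o.sum()
    both = f + o
    if np.any(both <= 0):
        raise ValueError("both densities are zero for at least one cell")
    # evaluate the quotient on the larger density and complement the other,
    # so swapping focal/other maps the result to 1 - likelihood bit-exactly
    big = np.maximum(f, o) / both
    return np.where(f >= o, big, 1.0 - big)


def classify_cells(likelihoods: np.ndarray) -> np.ndarray:
    """Depleted / unaffected / enriched by a strict 2 s.d. cutoff.

    Mean and s.d. are taken over all cells; degenerate distributions
    (s.d. = 0) yield all-unaffected.
    """
    x = np.asarray(likelihoods, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 cells to classify")
    mu, sd = x.mean(), x.std()
    out = np.full(x.shape, UNAFFECTED, dtype=object)
    if sd > 0:
        out[x < mu - 2 * sd] = DEPLETED
        out[x > mu + 2 * sd] = ENRICHED
    return out


def sample_likelihood_analysis(
    meta: pd.DataFrame,
    focal: str,
    params: GraphParams | None = None,
    emb_cols: tuple[str, ...] = ("emb1", "emb2", "emb3"),
    sample_col: str = "sample",
    replicate_col: str = "replicate",
) -> pd.DataFrame:
    """Per-cell, per-replicate relative likelihood of the focal sample.

    One graph is built over all cells; for every replicate the focal and
    non-focal sample indicators of that replicate are smoothed, densities
    are normalized per sample, and every cell receives a likelihood and a
    2 s.d. category. Returns a long table (cells x replicates) plus a
    replicate-averaged likelihood column.
    """
    params = params or GraphParams()
    samples = meta[sample_col].unique()
    if focal not in samples:
        raise ValueError(f"focal sample {focal!r} not present")
    if len(samples) != 2:
        raise ValueError("exactly two samples are supported")
    other = [s for s in samples if s != focal][0]
    coords = meta[list(emb_cols)].to_numpy(dtype=float)
    adjacency = build_knn_graph(coords, params.knn, params.kernel)

    replicates = sorted(meta[replicate_col].unique())
    indicators = []
    for rep in replicates:
        for s in (focal, other):
            indicators.append(
                ((meta[sample_col] == s) & (meta[replicate_col] == rep))
                .to_numpy()
                .astype(float)
            )
    densities = smooth_sample_density(
        adjacency, np.column_stack(indicators), params.beta
    )
    frames = []
    for i, rep in enumerate(replicates):
        rho_f, rho_o = densities[:, 2 * i], densities[:, 2 * i + 1]
        lik = relative_likelihood(rho_f, rho_o)
        frames.append(
            pd.DataFrame(
                {
                    "barcode": meta["barcode"].to_numpy(),
                    "cell_sample": meta[sample_col].to_numpy(),
                    "cell_replicate": meta[replicate_col].to_numpy(),
                    "likelihood_replicate": rep,
                    "density_focal": rho_f / rho_f.sum(),
                    "density_other": rho_o / rho_o.sum(),
                    "likelihood": lik,
                    "category": classify_cells(lik),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    mean_lik = out.groupby("barcode", sort=False)["likelihood"].transform("mean")
    out["mean_likelihood"] = mean_lik
    return out


def cluster_fractions(
    result: pd.DataFrame,
    clusters: pd.Series | np.ndarray | dict,
) -> pd.DataFrame:
    """Normalized category fractions per (cluster, replicate).

    Each cell is tabulated in its own replicate (rows of ``result`` where
    the cell's replicate matches the likelihood replicate); the fraction
    divides the category count by the total number of that replicate's
    cells in the cluster. Empty cluster-replicate combinations are
    omitted. ``clusters`` maps barcode -> cluster label (dict, or Series
    indexed by barcode).
    """
    cluster_of = clusters if isinstance(clusters, dict) else pd.Series(clusters).to_dict()
    own = result[result["cell_replicate"] == result["likelihood_replicate"]].copy()
    own["cluster"] = own["barcode"].map(cluster_of)
    rows = []
    for (cluster, rep), grp in own.groupby(["cluster", "cell_replicate"]):
        total = len(grp)
        row = {"cluster": cluster, "replicate": rep, "n_cells": total}
        for cat in CATEGORIES:
            row[f"frac_{cat}"] = (grp["category"] == cat).sum() / total
        rows.append(row)
    return pd.DataFrame(rows)


def parameter_search(
    coords: np.ndarray,
    sample_labels: np.ndarray,
    focal: str,
    knn_grid,
    beta_grid,
    n_label_permutations: int = 20,
    seed: int = 0,
    kernel: str = "gaussian-adaptive",
) -> tuple[tuple[int, float], pd.DataFrame]:
    """Choose (knn, beta) by permuted-label mean squared error.

    For every grid point, sample labels are permuted uniformly (the same
    permutations across grid points); the relative likelihood computed
    from permuted labels is compared against its ground truth — the
    global focal-sample proportion, constant across cells, since permuted
    labels carry no spatial structure — and the MSE is averaged over
    permutations. Returns the argmin (ties broken toward smaller knn,
    then smaller beta) and the full MSE surface. knn values >= n_cells
    are skipped with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(sample_labels)
    n = coords.shape[0]
    knn_grid = [int(k) for k in knn_grid]
    beta_grid = [float(b) for b in beta_grid]
    if len(knn_grid) == 0 or len(beta_grid) == 0:
        raise ValueError("grids must be nonempty")
    if n_label_permutations < 1:
        raise ValueError("need at least one label permutation")
    is_focal = labels == focal
    if is_focal.sum() == 0 or is_focal.sum() == n:
        raise ValueError("both samples must be present")
    truth = is_focal.mean()
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_label_permutations)]
    indicators_f = np.column_stack([is_focal[p].astype(float) for p in perms])
    indicators_o = 1.0 - indicators_f

    usable = [k for k in knn_grid if k < n]
    for k in knn_grid:
        if k >= n:
            warnings.warn(f"skipping knn={k} >= n_cells={n}", stacklevel=2)
    if not usable:
        raise ValueError("every knn value exceeds the number of cells")

    rows = []
    for k in usable:
        adjacency = build_knn_graph(coords, k, kernel)
        for beta in beta_grid:
            dens_f = smooth_sample_density(adjacency, indicators_f, beta)
            dens_o = smooth_sample_density(adjacency, indicators_o, beta)
            mses = []
            for j in range(n_label_permutations):
                lik = relative_likelihood(dens_f[:, j], dens_o[:, j])
                mses.append(np.mean((lik - truth) ** 2))
            rows.append({"knn": k, "beta": beta, "mse": float(np.mean(mses))})
    surface = pd.DataFrame(rows)
    best = surface.sort_values(["mse", "knn", "beta"], kind="stable").iloc[0]
    return (int(best["knn"]), float(best["beta"])), surface
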