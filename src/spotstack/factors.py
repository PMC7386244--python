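"""Normalization and non-negative matrix factorization of spot counts.

Raw UMI counts are filtered, converted to analytic Pearson residuals under a
negative-binomial noise model, clipped at zero (the non-negative transform),
and factorized as ``A ~ W H`` with W (genes x k) and H (k x spots) both
non-negative. The factorization minimizes the Frobenius reconstruction error
by multiplicative updates, whose objective is provably non-increasing, and is
initialized from an independent component analysis of the input so that
factors start out spatially and transcriptionally unmixed. The top-loading
genes of each W column are that factor's *driver genes*.

The negative-binomial model uses a single global dispersion theta:
``mu[g,s] = (gene total x spot total) / grand total`` and
``r = (x - mu) / sqrt(mu + mu^2/theta)``, clipped to +/- sqrt(n_spots) by
default. A per-gene regularized dispersion fit is deliberately out of scope;
the global-theta residual is fully specified, fast, and feeds the same
downstream factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import FastICA

from .datamodel import CountMatrix

__all__ = [
    "filter_counts",
    "pearson_residuals",
    "nonneg_transform",
    "nmf_ica_init",
    "fit_nmf",
    "top_drivers",
    "run_nmf",
    "ResidualMatrix",
    "FactorModel",
]


@dataclass
class ResidualMatrix:
    """Clipped NB Pearson residuals, genes x spots (dense)."""

    values: np.ndarray
    genes: list
    spots: list
    theta: float
    clip: float


@dataclass
class FactorModel:
    """Non-negative factorization A ~ W H.

    W: genes x k loadings, columns L2-normalized; H: k x spots activities;
    ``objective_trace`` holds 0.5 * ||A - WH||_F^2 per iteration and is
    non-increasing.
    """

    W: np.ndarray
    H: np.ndarray
    k: int
    objective_trace: list
    genes: list = field(default_factory=list)
    spots: list = field(default_factory=list)
    converged: bool = True
    init_method: str = "ica"

    def __post_init__(self):
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("W and H must be non-negative")


def filter_counts(counts: CountMatrix, min_counts_gene: int = 0,
                  min_counts_spot: int = 0) -> CountMatrix:
    """Drop low-abundance genes, then low-information spots.

    One pass, gene-first: a spot whose total falls below threshold only
    after gene removal is still removed (this order dependence is
    intentional and documented).
    """
    if min_counts_gene < 0 or min_counts_spot < 0:
        raise ValueError("thresholds must be non-negative")
    values = counts.values
    gene_keep = np.flatnonzero(np.asarray(values.sum(axis=1)).ravel() >= min_counts_gene)
    values = values[gene_keep]
    spot_keep = np.flatnonzero(np.asarray(values.sum(axis=0)).ravel() >= min_counts_spot)
    if len(spot_keep) == 0:
        raise ValueError("filtering removed every spot")
    return CountMatrix(
        genes=[counts.genes[i] for i in gene_keep],
        spots=[counts.spots[j] for j in spot_keep],
        values=values[:, spot_keep],
    )


def pearson_residuals(counts, theta: float = 100.0, clip: float | None = None) -> ResidualMatrix:
    """Analytic Pearson residuals under NB(mu, theta).

    ``mu[g,s] = (gene total x spot total) / grand total``;
    ``r = (x - mu) / sqrt(mu + mu^2 / theta)``, with variance reducing to the
    Poisson ``mu`` as theta -> infinity. Residuals are clipped to
    ``+/- sqrt(n_spots)`` unless ``clip`` is given.
    """
    if isinstance(counts, CountMatrix):
        X = counts.dense()
        genes, spots = list(counts.genes), list(counts.spots)
    else:
        X = np.asarray(counts, dtype=float)
        genes = [f"gene{i}" for i in range(X.shape[0])]
        spots = list(range(X.shape[1]))
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    total = X.sum()
    if total == 0:
        raise ValueError("zero grand total: residuals undefined")
    mu = np.outer(X.sum(axis=1), X.sum(axis=0)) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X - mu) / np.sqrt(mu + mu**2 / theta)
    r[mu == 0] = 0.0  # all-zero gene or spot: no information, zero residual
    if clip is None:
        clip = float(np.sqrt(X.shape[1]))
    r = np.clip(r, -clip, clip)
    return ResidualMatrix(values=r, genes=genes, spots=spots, theta=theta, clip=clip)


def nonneg_transform(R, mode: str = "clip") -> np.ndarray:
    """Make residuals non-negative for the factorization.

    ``clip`` (default) zeroes negative entries; ``shift`` subtracts the
    global minimum instead, preserving all contrasts at the cost of a dense
    positive offset.
    """
    values = R.values if isinstance(R, ResidualMatrix) else np.asarray(R, dtype=float)
    if mode == "clip":
        return np.maximum(values, 0.0)
    if mode == "shift":
        return values - min(values.min(), 0.0)
    raise ValueError(f"mode must be 'clip' or 'shift', got {mode!r}")


def nmf_ica_init(X: np.ndarray, k: int, seed: int = 0):
    """Initial (W0, H0) from an ICA decomposition of X.

    FastICA is run with k components on the genes x spots matrix; each
    component's sign is chosen so its positive parts carry the larger mass,
    and the positive parts become the initial loadings/activities. Columns
    or rows left identically zero are lifted to 1e-6 so multiplicative
    updates can move them. On ICA failure a seeded uniform-random
    initialization is returned instead, flagged via the third element of
    the returned tuple (``"ica"`` or ``"random"``).
    """
    X = np.asarray(X, dtype=float)
    n_genes, n_spots = X.shape
    if not 1 <= k <= min(n_genes, n_spots):
        raise ValueError(f"k={k} must be in [1, {min(n_genes, n_spots)}]")
    rng = np.random.default_rng(seed)
    method = "ica"
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = FastICA(n_components=k, random_state=int(seed) % (2**31),
                          max_iter=500, whiten="unit-variance")
            S = ica.fit_transform(X)      # genes x k sources
        A = ica.mixing_                   # spots x k mixing
        W0 = np.empty((n_genes, k))
        H0 = np.empty((k, n_spots))
        for c in range(k):
            w, h = S[:, c], A[:, c]
            pos = np.linalg.norm(np.maximum(w, 0)) * np.linalg.norm(np.maximum(h, 0))
            neg = np.linalg.norm(np.maximum(-w, 0)) * np.linalg.norm(np.maximum(-h, 0))
            if neg > pos:
                w, h = -w, -h
            W0[:, c] = np.maximum(w, 0)
            H0[c] = np.maximum(h, 0)
    except Exception:  # noqa: BLE001 - ICA non-convergence falls back to random
        scale = np.sqrt(max(X.mean(), 1e-12) / k)
        W0 = rng.uniform(0, 2 * scale, size=(n_genes, k))
        H0 = rng.uniform(0, 2 * scale, size=(k, n_spots))
        method = "random"
    # Zeros are absorbing states of multiplicative updates: the clipped init
    # would freeze half the entries at 0. Lift exact zeros to a small floor
    # (relative to the matrix scale) so every entry can still move; dead
    # rows/columns get the same treatment.
    for M in (W0, H0):
        positive = M[M > 0]
        floor = 1e-2 * positive.mean() if positive.size else 1e-6
        M[M == 0] = floor
    return W0, H0, method


def fit_nmf(X: np.ndarray, k: int, init=None, max_iter: int = 200,
            tol: float = 1e-5, seed: int = 0, genes=None, spots=None) -> FactorModel:
    """Factorize a non-negative matrix by Frobenius multiplicative updates.

    Starting from ``init`` (or an ICA initialization computed here), the
    classical multiplicative update pair

    ``H <- H * (W^T X) / (W^T W H)``, ``W <- W * (X H^T) / (W H H^T)``

    is iterated; each step cannot increase ``0.5 ||X - WH||_F^2``, and the
    recorded objective trace is checked to be non-increasing. Iteration
    stops when the relative objective decrease falls below ``tol``. On
    output, W's columns are scaled to unit L2 norm with the inverse scaling
    applied to H's rows, leaving the product WH unchanged.
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("X must be non-negative")
    init_method = "user"
    if init is None:
        W, H, init_method = nmf_ica_init(X, k, seed=seed)
    else:
        W, H = init[0].copy(), init[1].copy()
    W = np.asarray(W, dtype=float).copy()
    H = np.asarray(H, dtype=float).copy()
    if W.shape != (X.shape[0], k) or H.shape != (k, X.shape[1]):
        raise ValueError("init shapes do not conform to (genes x k, k x spots)")

    eps = 1e-12
    trace = []
    converged = False
    prev = 0.5 * np.linalg.norm(X - W @ H) ** 2
    trace.append(float(prev))
    for it in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ (H @ H.T) + eps)
        obj = 0.5 * np.linalg.norm(X - W @ H) ** 2
        if not np.isfinite(obj) or not (np.isfinite(W).all() and np.isfinite(H).all()):
            raise FloatingPointError(f"non-finite values at NMF iteration {it}")
        trace.append(float(obj))
        if prev - obj < tol * max(prev, eps):
            converged = True
            break
        prev = obj

    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    H = H * norms[:, None]
    return FactorModel(W=W, H=H, k=k, objective_trace=trace,
                       genes=list(genes) if genes is not None else [],
                       spots=list(spots) if spots is not None else [],
                       converged=converged, init_method=init_method)


def top_drivers(model: FactorModel, factor_index: int, n: int = 10):
    """Top-n driver genes of one factor, by descending loading in W.

    Ties break by gene identifier; asking for more genes than exist returns
    the full sorted list.
    """
    if not 0 <= factor_index < model.k:
        raise IndexError(f"factor_index {factor_index} out of range for k={model.k}")
    if n < 1:
        raise ValueError("n must be >= 1")
    genes = model.genes or [f"gene{i}" for i in range(model.W.shape[0])]
    loading = model.W[:, factor_index]
    order = sorted(range(len(genes)), key=lambda i: (-loading[i], str(genes[i])))
    return [genes[i] for i in order[:n]]


def run_nmf(counts, k: int, theta: float = 100.0, seed: int = 0,
            min_counts_gene: int = 0, min_counts_spot: int = 0,
            max_iter: int = 200, tol: float = 1e-5) -> FactorModel:
    """Filter -> Pearson residuals -> clip at zero -> ICA-initialized NMF."""
    if isinstance(counts, CountMatrix):
        counts = filter_counts(counts, min_counts_gene, min_counts_spot)
        genes, spots = counts.genes, counts.spots
    else:
        genes = spots = None
    residuals = pearson_residuals(counts, theta=theta)
    X = nonneg_transform(residuals)
    return fit_nmf(X, k, seed=seed, max_iter=max_iter, tol=tol,
                   genes=genes, spots=spots)
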