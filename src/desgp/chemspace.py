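"""2-D chemical-space maps of DES sigma-profile descriptors via
probabilistic PCA.

Probabilistic PCA models a d-dimensional observation x as

    x = mean + W z + eps,     z ~ N(0, I_q),   eps ~ N(0, sigma2 I_d)

with a d x q loading matrix W and isotropic residual noise sigma2.  The
maximum-likelihood solution is closed-form: W spans the top-q principal
subspace scaled by (lambda_k - sigma2)^(1/2), and sigma2 is the average
discarded eigenvalue (Tipping & Bishop).  An EM route is kept as an
independent check that the likelihood climbs to the same optimum.

The 183-entry mixture descriptors (never the temperature entry) are
projected to q = 2 for map-style visualization; property predictions can
then be exported as an interpolated surface over the 2-D plane.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger("desgp")

__all__ = ["PCAModel", "Surface", "fit_ppca", "fit_ppca_em", "project",
           "inverse_map", "export_surface"]


@dataclass
class PCAModel:
    """Maximum-likelihood probabilistic PCA parameters.

    ``loadings`` columns are mutually orthogonal (closed-form solution
    with rotation R = I); ``explained_variance`` holds the top-q
    covariance eigenvalues in non-increasing order.
    """

    mean: np.ndarray               # (d,)
    loadings: np.ndarray           # (d, q)
    noise_variance: float
    explained_variance: np.ndarray  # (q,)
    log_likelihood: float = float("nan")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Flip columns so each component's largest-|loading| entry is positive."""
    W = W.copy()
    for k in range(W.shape[1]):
        j = int(np.argmax(np.abs(W[:, k])))
        if W[j, k] < 0:
            W[:, k] = -W[:, k]
    return W


def _ppca_log_likelihood(Xc: np.ndarray, W: np.ndarray, sigma2: float) -> float:
    """Gaussian log-likelihood of centered data under C = W W^T + sigma2 I."""
    n, d = Xc.shape
    q = W.shape[1]
    # Use the q x q form via Woodbury / determinant lemma.
    M = W.T @ W + sigma2 * np.eye(q)
    S_tr = float(np.sum(Xc * Xc)) / n
    XW = Xc @ W                                # (n, q)
    Minv_WtXt_sq = np.sum((XW @ np.linalg.inv(M)) * XW) / n
    sign, logdet_M = np.linalg.slogdet(M)
    logdet_C = (d - q) * np.log(sigma2) + logdet_M
    tr_CinvS = (S_tr - Minv_WtXt_sq) / sigma2
    return -0.5 * n * (d * np.log(2 * np.pi) + logdet_C + tr_CinvS)


def fit_ppca(
    X: np.ndarray, n_components: int = 2, seed: int = 0, tol: float = 1e-8
) -> PCAModel:
    """Closed-form maximum-likelihood PPCA fit.

    Eigendecomposes the sample covariance (through an SVD of the centered
    data); W = U_q (L_q - sigma2 I)^(1/2) with sigma2 the mean discarded
    eigenvalue.  Deterministic; ``seed``/``tol`` are accepted for
    interface parity with the EM route.  Rank-deficient trivial input
    (all rows identical) yields zero loadings with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    q = n_components
    if n < 3:
        raise ValueError("PPCA needs at least 3 rows")
    if q >= d:
        raise ValueError("n_components must be < n_features")
    mean = X.mean(axis=0)
    Xc = X - mean
    # Sample covariance eigenvalues via SVD (divisor n, the ML convention)
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = np.zeros(d)
    eigvals[: len(svals)] = svals**2 / n
    if eigvals[0] <= 0:
        warnings.warn("degenerate data (all rows equal): zero loadings")
        return PCAModel(mean, np.zeros((d, q)), 0.0, np.zeros(q), 0.0)
    sigma2 = float(eigvals[q:].mean())
    scale = np.sqrt(np.maximum(eigvals[:q] - sigma2, 0.0))
    W = _fix_signs(Vt[:q].T * scale)
    ll = _ppca_log_likelihood(Xc, W, max(sigma2, 1e-300)) if sigma2 > 0 else np.inf
    return PCAModel(mean, W, sigma2, eigvals[:q].copy(), float(ll))


def fit_ppca_em(
    X: np.ndarray,
    n_components: int = 2,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> tuple[PCAModel, list[float]]:
    """EM route to the same ML solution; returns the likelihood trace.

    Kept alongside the closed form as a self-check: the per-iteration
    log-likelihood must be non-decreasing and converge to the closed-form
    optimum.  Loadings are orthogonalized and sign-fixed afterwards so
    both routes agree up to the rotation ambiguity.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    q = n_components
    mean = X.mean(axis=0)
    Xc = X - mean
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((d, q))
    sigma2 = 1.0
    trace: list[float] = []
    S_tr = float(np.sum(Xc * Xc)) / n
    for _ in range(max_iter):
        # E-step sufficient statistics (q x q working space)
        M = W.T @ W + sigma2 * np.eye(q)
        Minv = np.linalg.inv(M)
        XW = Xc @ W
        Ez = XW @ Minv                                  # (n, q)
        sum_Ezz = n * sigma2 * Minv + Ez.T @ Ez
        # M-step
        W_new = (Xc.T @ Ez) @ np.linalg.inv(sum_Ezz)
        sigma2_new = (
            S_tr
            - 2.0 * float(np.sum((Xc @ W_new) * Ez)) / n
            + float(np.trace(sum_Ezz @ (W_new.T @ W_new))) / n
        ) / d
        W, sigma2 = W_new, max(sigma2_new, 1e-12)
        trace.append(_ppca_log_likelihood(Xc, W, sigma2))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
    # Orthogonalize to the canonical (rotation-free) solution
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    order = np.argsort(s)[::-1]
    U, s = U[:, order], s[order]
    W_canon = _fix_signs(U * s)
    ev = s**2 + sigma2
    model = PCAModel(mean, W_canon, float(sigma2), ev, trace[-1])
    return model, trace


def project(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Map rows to 2-D coordinates along the principal axes.

    Returns the posterior-mean latent positions re-scaled to data units
    (multiplied per-axis by the loading norms), i.e. the shrunken
    principal-component scores (lambda - sigma2)/lambda * (U^T x_c).
    As sigma2 -> 0 these converge to classical PCA scores.  The training
    mean maps to the origin.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"expected {model.mean.shape[0]} features, got {X.shape[1]}"
        )
    W = model.loadings
    q = W.shape[1]
    norms = np.linalg.norm(W, axis=0)
    if np.all(norms == 0):
        return np.zeros((X.shape[0], q))
    M = W.T @ W + model.noise_variance * np.eye(q)
    Z = (X - model.mean) @ W @ np.linalg.inv(M)        # posterior mean latents
    return Z * norms


def inverse_map(model: PCAModel, coords: np.ndarray) -> np.ndarray:
    """Reconstruct d-dimensional points from 2-D coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    W = model.loadings
    norms = np.linalg.norm(W, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    Z = coords / safe
    return model.mean + Z @ W.T


@dataclass
class Surface:
    """Scattered property values plus an interpolated regular grid."""

    points: pd.DataFrame   # columns x, y, value
    grid: pd.DataFrame     # columns x, y, value (regular lattice, tidy)
    n_grid: int


def export_surface(
    coords: np.ndarray,
    values: np.ndarray,
    n_grid: int = 50,
    power: float = 2.0,
) -> Surface:
    """Inverse-distance-weighted surface of a property over the 2-D map.

    The grid spans the bounding box of the coordinates exactly.  A grid
    node coinciding with an input point takes that point's own value
    (coincident input points are averaged).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    values = np.asarray(values, dtype=float).ravel()
    if coords.shape[0] != values.shape[0]:
        raise ValueError("coords and values length mismatch")
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 points to build a surface")
    xs = np.linspace(coords[:, 0].min(), coords[:, 0].max(), n_grid)
    ys = np.linspace(coords[:, 1].min(), coords[:, 1].max(), n_grid)
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    D = cdist(nodes, coords)
    exact = D < 1e-12
    with np.errstate(divide="ignore"):
        w = 1.0 / D**power
    interp = np.empty(len(nodes))
    hit = exact.any(axis=1)
    interp[hit] = [values[exact[i]].mean() for i in np.flatnonzero(hit)]
    wh = w[~hit]
    interp[~hit] = (wh @ values) / wh.sum(axis=1)
    points = pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1], "value": values}
    )
    grid = pd.DataFrame(
        {"x": nodes[:, 0], "y": nodes[:, 1], "value": interp}
    )
    return Surface(points=points, grid=grid, n_grid=n_grid)
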