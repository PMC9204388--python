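"""Inverse operators: eLORETA and depth-weighted minimum-norm filters.

eLORETA is the iterative weighted inverse with the exact-localization
property: with per-source 3x3 weight blocks W_i updated as the matrix square
root of L_i^T M L_i, a noiseless single point source is always localized at
its true grid position.  The depth-weighted MNE filter is the closed-form
Tikhonov solution with per-source weights ||L_i||^(-2*gamma) and no noise
model (identity noise covariance).

Both constructions include the average-reference operator, so source
estimates are invariant to adding a constant across channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import (ConvergenceError, NumericalError, StructuralError,
                         ValidationError)
from .forward import LeadField

logger = logging.getLogger("srcfc")


@dataclass
class SpatialFilter:
    """Inverse operator: (3 * n_sources) x channels, rows in source triplets."""

    matrix: np.ndarray
    method: str
    regularization: float
    depth_gamma: float | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] % 3 != 0:
            raise StructuralError("filter rows must come in source triplets")
        if not np.all(np.isfinite(self.matrix)):
            raise StructuralError("filter contains non-finite values")

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[0] // 3

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SourceEpochs:
    """Source-space epochs: epochs x n_sources x 3 x samples (real or complex)."""

    data: np.ndarray
    source_positions: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[2] != 3:
            raise StructuralError(
                "source epochs must be (epochs, sources, 3, samples)")


def _blocks(lf: LeadField) -> np.ndarray:
    """Lead field reshaped to (channels, n_sources, 3)."""
    C = lf.n_channels
    return lf.matrix.reshape(C, lf.n_sources, 3)


def _sym_sqrt_and_inv(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stacked symmetric square root and its inverse for (n, 3, 3) PSD input."""
    w, V = np.linalg.eigh(0.5 * (A + np.swapaxes(A, -1, -2)))
    w = np.clip(w, 0.0, None)
    s = np.sqrt(w)
    floor = np.maximum(s.max(axis=-1, keepdims=True) * 1e-12, 1e-300)
    sinv = np.where(s > floor, 1.0 / np.maximum(s, floor), 0.0)
    sqrtA = np.einsum("nij,nj,nkj->nik", V, s, V)
    invsqrtA = np.einsum("nij,nj,nkj->nik", V, sinv, V)
    return sqrtA, invsqrtA


def _eloreta_step(L: np.ndarray, Winv: np.ndarray, alpha: float,
                  H: np.ndarray):
    """One eLORETA weight update; returns (W_new, Winv_new, M)."""
    T = np.einsum("cnj,njk->cnk", L, Winv)
    G = np.einsum("cnk,dnk->cd", T, L)
    reg = alpha * np.mean(np.diag(G))
    M = np.linalg.pinv(G + reg * H, hermitian=True)
    A = np.einsum("cni,cd,dnj->nij", L, M, L)
    W_new, Winv_new = _sym_sqrt_and_inv(A)
    return W_new, Winv_new, M


def eloreta_filter(lf: LeadField, alpha: float = 0.05, tol: float = 1e-6,
                   max_iter: int = 100) -> SpatialFilter:
    """Iterative eLORETA spatial filter.

    ``alpha`` scales the regularization as a fraction of the mean diagonal of
    the weighted sensor Gram matrix; the regularizer is the average-reference
    operator H, and the Gram inverse is a pseudo-inverse (H is singular).
    Iterates W_i <- sqrtm(L_i^T M L_i) until the largest relative change of
    any weight block falls below ``tol``.
    """
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    L = _blocks(lf)                        # (C, N, 3)
    C_ch = L.shape[0]
    H = np.eye(C_ch) - 1.0 / C_ch
    Winv = np.tile(np.eye(3), (lf.n_sources, 1, 1))
    W = Winv.copy()
    delta = np.inf
    M = None
    for it in range(max_iter):
        W_new, Winv_new, M = _eloreta_step(L, Winv, alpha, H)
        num = np.linalg.norm(W_new - W, axis=(1, 2))
        den = np.maximum(np.linalg.norm(W, axis=(1, 2)), 1e-300)
        delta = float((num / den).max())
        W, Winv = W_new, Winv_new
        if delta < tol:
            logger.info("eLORETA converged in %d iterations (delta %.2e)",
                        it + 1, delta)
            break
    else:
        raise ConvergenceError(
            f"eLORETA did not converge in {max_iter} iterations "
            f"(last delta {delta:.3e})", last_delta=delta)
    F = np.einsum("nij,cnj,cd->nid", Winv, L, M)   # (N, 3, C)
    matrix = F.reshape(3 * lf.n_sources, C_ch)
    return SpatialFilter(matrix=matrix, method="eloreta", regularization=alpha)


def wmne_filter(lf: LeadField, lambda2: float = 1.0 / 9.0,
                depth_gamma: float = 0.5) -> SpatialFilter:
    """Depth-weighted minimum-norm filter without noise modelling.

    F = R L^T (L R L^T + lambda2 * mean(diag) * I)^(-1), with R diagonal per
    source triplet, weight ||L_i||_F^(-2*gamma).  ``lambda2`` defaults to 1/9
    (the assumed-SNR-of-3 convention); ``depth_gamma = 0`` gives plain MNE.
    """
    if lambda2 < 0:
        raise ValidationError("lambda2 must be >= 0")
    L = _blocks(lf)
    norms = np.linalg.norm(L, axis=(0, 2))         # per-source Frobenius norm
    if np.any(norms == 0):
        raise NumericalError("source with all-zero lead field")
    w = norms ** (-2.0 * depth_gamma)              # (N,)
    G = np.einsum("cnk,n,dnk->cd", L, w, L)
    reg = lambda2 * np.mean(np.diag(G))
    K = G + reg * np.eye(G.shape[0])
    if lambda2 == 0:
        rank = np.linalg.matrix_rank(K)
        if rank < K.shape[0]:
            raise NumericalError(
                "sensor Gram matrix is rank-deficient at lambda2=0; "
                "use lambda2 > 0")
    Kinv = np.linalg.inv(K) if lambda2 > 0 else np.linalg.pinv(K)
    F = np.einsum("n,cnj,cd->njd", w, L, Kinv)     # (N, 3, C)
    matrix = F.reshape(3 * lf.n_sources, lf.n_channels)
    return SpatialFilter(matrix=matrix, method="wmne", regularization=lambda2,
                         depth_gamma=depth_gamma)


def apply_inverse(filt: SpatialFilter, ep) -> SourceEpochs:
    """Project epoched sensor data into source space (per-epoch matmul).

    Accepts EpochedData (kept epochs only) or AnalyticEpochs; complex input
    yields complex source series (linearity preserves analyticity).
    """
    from .preprocess import AnalyticEpochs, EpochedData

    if isinstance(ep, EpochedData):
        data = ep.data[ep.kept_mask]
    elif isinstance(ep, AnalyticEpochs):
        data = ep.data
    else:
        data = np.asarray(ep)
        if data.ndim != 3:
            raise StructuralError("expected (epochs, channels, samples)")
    if data.shape[1] != filt.n_channels:
        raise StructuralError(
            f"filter expects {filt.n_channels} channels, data has "
            f"{data.shape[1]}")
    out = np.einsum("rc,ecs->ers", filt.matrix, data)
    E, _, S = out.shape
    out = out.reshape(E, filt.n_sources, 3, S)
    return SourceEpochs(data=out)


def orient_svd(src: SourceEpochs) -> np.ndarray:
    """Collapse each source's 3-D series onto its dominant orientation.

    The orientation is the first left singular vector of the 3 x T matrix of
    epoch-concatenated samples (real part for analytic input, so orientation
    does not depend on the Hilbert phase convention), computed once and
    applied to every epoch.  Sign convention: the largest-|.| component of
    the orientation is positive.  Returns (epochs, n_sources, samples).
    """
    data = src.data
    E, N, _, S = data.shape
    if E * S < 2:
        raise ValidationError("need at least 2 samples for orientation")
    X = np.transpose(data, (1, 2, 0, 3)).reshape(N, 3, E * S)
    Xr = X.real if np.iscomplexobj(X) else X
    cov = np.einsum("nit,njt->nij", Xr, Xr)
    w, V = np.linalg.eigh(cov)
    u = V[:, :, -1]                                   # (N, 3) top eigenvector
    zero = w[:, -1] <= 0
    if zero.any():
        logger.warning("orientation undefined for %d all-zero source(s)",
                       int(zero.sum()))
        u[zero] = 0.0
    idx = np.abs(u).argmax(axis=1)
    sign = np.sign(u[np.arange(N), idx])
    sign[sign == 0] = 1.0
    u = u * sign[:, None]
    return np.einsum("nj,enjs->ens", u, data)
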