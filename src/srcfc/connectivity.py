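"""Functional-connectivity estimators.

Phase-synchrony metrics operate on Hanning-tapered Fourier observations
(one per kept epoch): the weighted phase lag index (wPLI), the imaginary
part of coherency (iCoh), the phase-locking value (PLV), and ordinary
coherence.  With the per-observation cross-spectrum Z_k = X_k * conj(Y_k):

    wpli = |sum_k Im Z_k| / sum_k |Im Z_k|          (0/0 -> 0)
    icoh = |Im sum_k Z_k| / sqrt(sum|X|^2 sum|Y|^2)
    coh  = |sum_k Z_k|    / sqrt(sum|X|^2 sum|Y|^2)
    plv  = |mean_k exp(i (arg X_k - arg Y_k))|

and the band value is the arithmetic mean over the retained bins.  wPLI and
iCoh suppress zero-lag (volume-conducted) contributions; coherence and PLV
do not.  The trial-resampled wPLI draws 30 epochs without replacement, 50
times, and averages the matrices, stabilizing the estimator against
epoch-count bias.

Amplitude coupling (AAC) correlates natural-log power envelopes of analytic
signals, after pairwise orthogonalization: the component of y instantaneously
orthogonal to x is Im(y * conj(x) / |x|).  The pair value is the average of
the two orthogonalization directions (corr1/corr2), which makes the matrix
symmetric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .exceptions import (EstimationError, InsufficientDataError,
                         ResolutionError, StructuralError, ValidationError)
from .parcellate import LOBES, Atlas, ROITimeSeries
from .preprocess import BandSpec

logger = logging.getLogger("srcfc")

LOG_EPS = 1e-20   # inside ln of power envelopes, guards exact zeros


@dataclass
class SpectralObservations:
    """Tapered Fourier coefficients: observations x signals x frequencies."""

    coeffs: np.ndarray
    freqs: np.ndarray
    taper: str = "hanning"

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.coeffs.ndim != 3:
            raise StructuralError("coeffs must be (observations, signals, freqs)")
        if self.coeffs.shape[2] != self.freqs.shape[0]:
            raise StructuralError("frequency axis mismatch")
        if np.any(np.diff(self.freqs) <= 0):
            raise StructuralError("frequencies must strictly increase")


@dataclass
class AdjacencyMatrix:
    """Symmetric node x node connectivity matrix, diagonal fixed at 0."""

    values: np.ndarray
    metric: str
    node_labels: list[str]
    band: BandSpec | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise StructuralError("adjacency values must be square")
        if len(self.node_labels) != n:
            raise StructuralError("node label count mismatch")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise StructuralError("adjacency values must be symmetric")
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# spectral observations
# ---------------------------------------------------------------------------

def fourier_observations(roi: ROITimeSeries | np.ndarray, srate: float | None,
                         band: BandSpec) -> SpectralObservations:
    """Demean, Hanning-taper and FFT each epoch; keep in-band bins."""
    if isinstance(roi, ROITimeSeries):
        data, srate = roi.data, roi.srate
    else:
        data = np.asarray(roi)
    if srate is None:
        raise ValidationError("sampling rate required")
    if np.iscomplexobj(data):
        raise ValidationError("fourier_observations expects real series")
    if data.ndim != 3:
        raise StructuralError("expected (epochs, signals, samples)")
    if data.shape[0] < 2:
        raise InsufficientDataError("need at least 2 epochs")
    n = data.shape[-1]
    win = hann(n, sym=False)
    demeaned = data - data.mean(axis=-1, keepdims=True)
    coeffs = np.fft.rfft(demeaned * win, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / srate)
    sel = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    if not sel.any():
        raise ResolutionError(
            f"band {band.name} ({band.f_lo}-{band.f_hi} Hz) contains no FFT "
            f"bin at {freqs[1]:.3g} Hz resolution; use longer epochs")
    return SpectralObservations(coeffs=coeffs[:, :, sel], freqs=freqs[sel])


# ---------------------------------------------------------------------------
# phase metrics
# ---------------------------------------------------------------------------

def _phase_fc_values(coeffs: np.ndarray, method: str) -> np.ndarray:
    """Band-averaged metric matrix from (K, V, F) coefficients."""
    K, V, F = coeffs.shape
    if method == "wpli":
        num = np.zeros((V, V, F))
        den = np.zeros((V, V, F))
        for k in range(K):
            imz = np.einsum("if,jf->ijf", coeffs[k], np.conj(coeffs[k])).imag
            num += imz
            den += np.abs(imz)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_bin = np.abs(num) / den
        per_bin[den == 0] = 0.0
    elif method in ("coh", "icoh"):
        Sxy = np.einsum("kif,kjf->ijf", coeffs, np.conj(coeffs))
        power = np.sum(np.abs(coeffs) ** 2, axis=0)            # (V, F)
        denom = np.sqrt(np.einsum("if,jf->ijf", power, power))
        with np.errstate(invalid="ignore", divide="ignore"):
            per_bin = (np.abs(Sxy.imag) if method == "icoh"
                       else np.abs(Sxy)) / denom
        per_bin[denom == 0] = 0.0
    elif method == "plv":
        mag = np.abs(coeffs)
        unit = np.where(mag > 0, coeffs / np.where(mag > 0, mag, 1.0), 0.0)
        per_bin = np.abs(np.einsum("kif,kjf->ijf", unit, np.conj(unit))) / K
    else:
        raise ValidationError(f"unknown phase FC method {method!r}")
    values = per_bin.mean(axis=-1)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return values


def phase_fc(obs: SpectralObservations, method: str = "wpli",
             node_labels: list[str] | None = None,
             band: BandSpec | None = None) -> AdjacencyMatrix:
    """Phase-synchrony adjacency matrix (wpli | icoh | plv | coh)."""
    if obs.coeffs.shape[0] < 2:
        raise EstimationError("phase metrics need at least 2 observations")
    values = _phase_fc_values(obs.coeffs, method)
    labels = node_labels or [f"n{i}" for i in range(values.shape[0])]
    return AdjacencyMatrix(values=values, metric=method, node_labels=labels,
                           band=band)


def resampled_wpli(roi: ROITimeSeries, band: BandSpec, n_sel: int = 30,
                   n_rep: int = 50, seed: int = 0) -> AdjacencyMatrix:
    """Trial-resampled wPLI: mean over repeated 30-epoch subsets.

    Each repetition draws ``n_sel`` epochs without replacement (a draw is a
    set; indices are used in sorted order).  With exactly ``n_sel`` epochs
    available every draw is the full set and the single-draw matrix is
    returned as-is, so the degenerate case is exact.
    """
    obs = fourier_observations(roi, roi.srate, band)
    K = obs.coeffs.shape[0]
    if K < n_sel:
        raise InsufficientDataError(
            f"{K} epochs < {n_sel} required for resampled wPLI")
    rng = np.random.default_rng(seed)
    draws = [np.sort(rng.choice(K, size=n_sel, replace=False))
             for _ in range(n_rep)]
    first = _phase_fc_values(obs.coeffs[draws[0]], "wpli")
    if all(np.array_equal(d, draws[0]) for d in draws[1:]):
        values = first
    else:
        acc = first.copy()
        for d in draws[1:]:
            acc += _phase_fc_values(obs.coeffs[d], "wpli")
        values = acc / n_rep
    labels = (list(roi.roi_names) if isinstance(roi, ROITimeSeries)
              else [f"n{i}" for i in range(values.shape[0])])
    logger.info("resampled wPLI: %d epochs, %d x %d draws, seed %d",
                K, n_rep, n_sel, seed)
    return AdjacencyMatrix(values=values, metric="wpli",
                           node_labels=labels, band=band)


# ---------------------------------------------------------------------------
# amplitude coupling
# ---------------------------------------------------------------------------

def orthogonalize(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Component of y instantaneously orthogonal to x: Im(y conj(x) / |x|).

    Where |x| = 0 the projection is undefined; those samples are set to 0
    with a warning.
    """
    x = np.asarray(x, dtype=complex)
    y = np.asarray(y, dtype=complex)
    if x.shape != y.shape:
        raise StructuralError("x and y must have the same shape")
    mag = np.abs(x)
    zero = mag == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-magnitude sample(s) in x; "
                      "orthogonalized value set to 0")
    out = np.where(zero, 0.0, (y * np.conj(x)).imag / np.where(zero, 1.0, mag))
    return out


def _log_power(v: np.ndarray) -> np.ndarray:
    return np.log(np.abs(v) ** 2 + LOG_EPS)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def aac_pair(x: np.ndarray, y: np.ndarray, orthogonalized: bool = True) -> float:
    """Amplitude-to-amplitude coupling between two analytic signals.

    Epochs (leading axes) are concatenated before correlating.  With
    orthogonalization the value is (corr1 + corr2) / 2 where corr1 correlates
    ln|y orth x|^2 with ln|x|^2 and corr2 the converse; an identically-zero
    orthogonalized residual (collinear signals) contributes 0 by convention.
    A zero-variance log envelope of an original signal makes the value
    undefined (NaN).
    """
    x = np.asarray(x, dtype=complex).ravel()
    y = np.asarray(y, dtype=complex).ravel()
    if x.shape != y.shape:
        raise StructuralError("x and y must have the same length")
    if x.size < 100:
        raise InsufficientDataError("need at least 100 samples for AAC")
    lx, ly = _log_power(x), _log_power(y)
    if np.std(lx) == 0 or np.std(ly) == 0:
        return np.nan
    if not orthogonalized:
        return _pearson(lx, ly)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yox = orthogonalize(x, y)
        xoy = orthogonalize(y, x)
    corrs = []
    for resid, src in ((yox, y), (xoy, x)):
        # an (effectively) zero residual means collinear signals: value 0
        if np.max(np.abs(resid)) <= 1e-10 * max(np.max(np.abs(src)), 1e-300):
            corrs.append(0.0)
        else:
            ref = lx if resid is yox else ly
            corrs.append(_pearson(_log_power(resid), ref))
    return float(np.mean(corrs))


def aac_matrix(series, orthogonalized: bool = True,
               node_labels: list[str] | None = None,
               band: BandSpec | None = None,
               single_precision: bool = False) -> AdjacencyMatrix:
    """All-pairs AAC over analytic signals; symmetric, diagonal 0.

    ``series`` is a complex (signals, samples) array, an (epochs, signals,
    samples) array (epochs concatenated), or a complex ROITimeSeries.
    Vectorized over one axis so vertex-level matrices (V up to thousands)
    stay feasible; ``single_precision`` halves memory and time for large V
    at ~1e-6 accuracy, ample for rank/contrast use.
    """
    if isinstance(series, ROITimeSeries):
        if node_labels is None:
            node_labels = list(series.roi_names)
        data = series.data
    else:
        data = np.asarray(series)
    data = np.asarray(data, dtype=np.complex64 if single_precision else complex)
    if data.ndim == 3:
        data = np.transpose(data, (1, 0, 2)).reshape(data.shape[1], -1)
    if data.ndim != 2 or data.shape[0] < 2:
        raise StructuralError("need (signals, samples) with >= 2 signals")
    V, T = data.shape
    if T < 100:
        raise InsufficientDataError("need at least 100 samples for AAC")
    logp = _log_power(data)
    lp_c = logp - logp.mean(axis=1, keepdims=True)
    lp_n = np.linalg.norm(lp_c, axis=1)
    degenerate = lp_n == 0
    values = np.zeros((V, V))
    if not orthogonalized:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = (lp_c @ lp_c.T) / np.outer(lp_n, lp_n)
        values[degenerate, :] = np.nan
        values[:, degenerate] = np.nan
    else:
        mag = np.abs(data)
        safe = np.where(mag == 0, 1.0, mag)
        for i in range(V):
            # all signals orthogonalized to signal i at once
            resid = (data * np.conj(data[i])[None, :]).imag / safe[i][None, :]
            resid[:, mag[i] == 0] = 0.0
            zero_resid = (np.max(np.abs(resid), axis=1)
                          <= 1e-10 * np.maximum(mag.max(axis=1), 1e-300))
            lr = np.log(resid ** 2 + LOG_EPS)
            lr_c = lr - lr.mean(axis=1, keepdims=True)
            lr_n = np.linalg.norm(lr_c, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                col = (lr_c @ lp_c[i]) / (lr_n * lp_n[i])
            col[zero_resid] = 0.0                # collinear convention
            # col[j] = corr( ln|j orth i|^2 , ln|i|^2 ): one direction of (i, j)
            values[i, :] += 0.5 * col
            values[:, i] += 0.5 * col
        values[degenerate, :] = np.nan
        values[:, degenerate] = np.nan
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.info("aac_matrix: %d undefined entr%s recorded as missing",
                    n_missing, "y" if n_missing == 1 else "ies")
    labels = node_labels or [f"n{i}" for i in range(V)]
    metric = "aac_orth" if orthogonalized else "aac_plain"
    return AdjacencyMatrix(values=values, metric=metric, node_labels=labels,
                           band=band)


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def fisher_z(m: AdjacencyMatrix, clip: float = 0.9999) -> AdjacencyMatrix:
    """Fisher r-to-z transform, elementwise off-diagonal, with clipping."""
    v = np.clip(m.values, -clip, clip)
    n_clipped = int(np.sum(np.abs(m.values) > clip))
    if n_clipped:
        logger.info("fisher_z: clipped %d value(s) at +/-%g", n_clipped, clip)
    z = np.arctanh(v)
    np.fill_diagonal(z, 0.0)
    return AdjacencyMatrix(values=z, metric=m.metric + "_z",
                           node_labels=list(m.node_labels), band=m.band)


def threshold_sparsity(m: AdjacencyMatrix,
                       keep_fraction: float = 0.5) -> AdjacencyMatrix:
    """Proportional threshold: keep the strongest fraction of unique edges.

    Exactly round(keep_fraction * E) of the E = n(n-1)/2 unique off-diagonal
    edges survive; ties are broken by lexicographic (i, j) order so the count
    is exact and deterministic.
    """
    if not (0 < keep_fraction <= 1):
        raise ValidationError("keep_fraction must be in (0, 1]")
    n = m.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    vals = m.values[iu, ju]
    E = vals.size
    n_keep = int(round(keep_fraction * E))
    order = np.lexsort((ju, iu, -vals))           # value desc, then (i, j)
    keep = order[:n_keep]
    out = np.zeros_like(m.values)
    out[iu[keep], ju[keep]] = vals[keep]
    out = out + out.T
    return AdjacencyMatrix(values=out, metric=m.metric,
                           node_labels=list(m.node_labels), band=m.band)


def lobe_average(m: AdjacencyMatrix, atlas: Atlas) -> np.ndarray:
    """4 x 4 lobe-pair mean FC, computed over all ROI pairs (zeros included).

    Entry (A, B) averages m[i, j] over i in lobe A, j in lobe B, excluding
    the diagonal when A = B.  A lobe with fewer than 2 ROIs has an undefined
    within-lobe mean (NaN).
    """
    if list(m.node_labels) != list(atlas.roi_names):
        raise StructuralError("adjacency node labels do not match atlas ROIs")
    lobe_idx = atlas.lobe_index()
    out = np.full((len(LOBES), len(LOBES)), np.nan)
    for a in range(len(LOBES)):
        ia = np.flatnonzero(lobe_idx == a)
        for b in range(a, len(LOBES)):
            ib = np.flatnonzero(lobe_idx == b)
            if a == b:
                if len(ia) < 2:
                    continue
                sub = m.values[np.ix_(ia, ia)]
                val = sub.sum() / (len(ia) * (len(ia) - 1))
            else:
                if len(ia) == 0 or len(ib) == 0:
                    continue
                val = m.values[np.ix_(ia, ib)].mean()
            out[a, b] = out[b, a] = val
    return out
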