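"""Synthetic sources, sensors and recordings with known ground truth.

Oscillators are narrowband-filtered Gaussian noise (so their envelopes
fluctuate, which makes amplitude coupling meaningful), plus 1/f background
noise.  Three coupling kinds can be planted between source pairs:

``phase_lag``
    Source j shares source i's narrowband driver rotated by a fixed phase
    lag, mixed with an independent residual scaled by (1 - strength); at
    strength 1 the phase difference is exactly the lag.
``envelope_corr``
    Both sources' log power envelopes share a slow Gaussian innovation with
    weight sqrt(strength), giving Pearson correlation ~ strength between the
    log envelopes at zero phase preference (carriers stay independent).
``zero_lag_mix``
    Instantaneous leakage j <- j + strength * i, emulating volume-conducted
    common-source mixing: high coherence and plain envelope correlation, but
    no lagged interaction.

All randomness flows from a single seed expanded into fixed per-stream
substreams, so every output is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.signal import hilbert

from .core_io import Recording, SensorArray
from .exceptions import ValidationError
from .forward import LeadField, SourceGrid
from .parcellate import LOBES, Atlas
from .preprocess import BandSpec, design_bandpass, _zero_phase

logger = logging.getLogger("srcfc")

_ENVELOPE_CUTOFF_HZ = 1.0   # slow log-envelope innovations
_SIGMA_LOG_ENV = 0.4        # log-envelope SD (moderate lognormal fluctuation)


@dataclass
class Coupling:
    i: int
    j: int
    kind: str                       # phase_lag | envelope_corr | zero_lag_mix
    strength: float
    lag_radians: float = 0.0

    def __post_init__(self):
        if self.kind not in ("phase_lag", "envelope_corr", "zero_lag_mix"):
            raise ValidationError(f"unknown coupling kind {self.kind!r}")
        if not (0 <= self.strength <= 1):
            raise ValidationError(f"strength must be in [0, 1], got {self.strength}")
        if not (-np.pi < self.lag_radians <= np.pi):
            raise ValidationError("lag_radians must be in (-pi, pi]")
        if self.kind in ("phase_lag", "envelope_corr") and self.i == self.j:
            raise ValidationError(f"{self.kind} coupling needs i != j")


@dataclass
class SimulationSpec:
    """Ground-truth description of a synthetic source configuration."""

    n_sources: int
    srate: float = 500.0
    duration: float = 60.0
    band: BandSpec = dc_field(default_factory=lambda: BandSpec("alpha", 5, 11))
    couplings: list[Coupling] = dc_field(default_factory=list)
    noise_sd: float = 0.5
    pink_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self):
        cl = []
        for c in self.couplings:
            cl.append(c if isinstance(c, Coupling) else Coupling(**c))
        self.couplings = cl
        for c in self.couplings:
            for idx in (c.i, c.j):
                if not (0 <= idx < self.n_sources):
                    raise ValidationError(
                        f"coupling index {idx} out of range for "
                        f"{self.n_sources} sources")


@dataclass
class SourceTimeSeries:
    data: np.ndarray                     # (n_sources, n_samples)
    truth: SimulationSpec
    positions: np.ndarray | None = None  # optional source coordinates (m)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _narrowband_analytic(rng, n_sources, n_samples, band, srate):
    """Unit-RMS narrowband analytic signals (filtered Gaussian noise)."""
    white = rng.standard_normal((n_sources, n_samples))
    taps = design_bandpass(band.f_lo, band.f_hi, srate, n_samples)
    nb = _zero_phase(taps, white)
    z = hilbert(nb, axis=-1)
    rms = np.sqrt(np.mean(z.real ** 2, axis=-1, keepdims=True))
    return z / np.maximum(rms, 1e-30)


def _slow_gaussian(rng, shape, srate, cutoff=_ENVELOPE_CUTOFF_HZ):
    """Low-pass-filtered, standardized Gaussian processes."""
    white = rng.standard_normal(shape)
    from scipy.signal import firwin

    numtaps = min(int(3.3 * srate / cutoff) | 1, max(shape[-1] // 3 | 1, 11))
    taps = firwin(numtaps, cutoff, window="hamming", fs=srate)
    slow = _zero_phase(taps, white)
    slow = slow - slow.mean(axis=-1, keepdims=True)
    return slow / np.maximum(slow.std(axis=-1, keepdims=True), 1e-30)


def pink_noise(rng, shape, exponent=1.0):
    """1/f^exponent power-spectrum noise, unit RMS per row."""
    n = shape[-1]
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    return out / np.maximum(out.std(axis=-1, keepdims=True), 1e-30)


def simulate_sources(spec: SimulationSpec) -> SourceTimeSeries:
    """Generate coupled narrowband sources with pink background noise.

    Couplings are applied in list order, each mutating the complex carrier
    of its target; mixed carriers are rescaled to unit RMS so ``noise_sd``
    keeps a fixed signal-to-noise meaning.  Deterministic given the seed.
    """
    n_samples = int(round(spec.duration * spec.srate))
    z = _narrowband_analytic(_rng(spec.seed, 1), spec.n_sources, n_samples,
                             spec.band, spec.srate)
    env_rng = _rng(spec.seed, 2)
    for c in spec.couplings:
        if c.kind == "phase_lag":
            driver = z[c.i] * np.exp(-1j * c.lag_radians)
            mixed = c.strength * driver + (1.0 - c.strength) * z[c.j]
            rms = np.sqrt(np.mean(mixed.real ** 2))
            z[c.j] = mixed / max(rms, 1e-30)
        elif c.kind == "envelope_corr":
            slow = _slow_gaussian(env_rng, (3, n_samples), spec.srate)
            shared, own_i, own_j = slow
            a_i = np.sqrt(c.strength) * shared + np.sqrt(1 - c.strength) * own_i
            a_j = np.sqrt(c.strength) * shared + np.sqrt(1 - c.strength) * own_j
            for idx, a in ((c.i, a_i), (c.j, a_j)):
                phase = z[idx] / np.maximum(np.abs(z[idx]), 1e-30)
                z[idx] = np.exp(_SIGMA_LOG_ENV * a) * phase
        elif c.kind == "zero_lag_mix":
            mixed = z[c.j] + c.strength * z[c.i]
            rms = np.sqrt(np.mean(mixed.real ** 2))
            z[c.j] = mixed / max(rms, 1e-30)
    data = z.real.copy()
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * pink_noise(
            _rng(spec.seed, 3), data.shape, spec.pink_exponent)
    logger.info("simulated %d sources x %d samples (%d couplings), seed %d",
                spec.n_sources, n_samples, len(spec.couplings), spec.seed)
    return SourceTimeSeries(data=data, truth=spec)


def project_to_sensors(sources: SourceTimeSeries, lf: LeadField,
                       orientations: np.ndarray, noise_sd: float,
                       seed: int, source_indices=None) -> Recording:
    """Forward-project sources through the lead field, add sensor noise.

    ``orientations`` are per-source unit 3-vectors (dipole moment
    directions); ``source_indices`` picks which lead-field sources carry the
    simulated series (defaults to the first ``n_sources``).  Output is
    average-referenced, white sensor noise has SD ``noise_sd`` uV.
    """
    n_src = sources.data.shape[0]
    if lf.n_sources < n_src:
        raise ValidationError("lead field has fewer sources than the simulation")
    orientations = np.asarray(orientations, dtype=float)
    if orientations.shape != (n_src, 3):
        raise ValidationError("orientations must be (n_sources, 3)")
    norms = np.linalg.norm(orientations, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValidationError("orientations must be unit-norm")
    if source_indices is None:
        source_indices = np.arange(n_src)
    source_indices = np.asarray(source_indices, dtype=int)
    sens = np.zeros((lf.n_channels, sources.data.shape[1]))
    for k in range(n_src):
        gain = lf.source_block(source_indices[k]) @ orientations[k]   # (C,)
        sens += np.outer(gain, sources.data[k])
    if noise_sd > 0:
        sens = sens + noise_sd * _rng(seed, 4).standard_normal(sens.shape)
    sens -= sens.mean(axis=0, keepdims=True)
    return Recording(data=sens, srate=sources.truth.srate,
                     channel_labels=list(lf.channel_labels),
                     reference="average")


def make_sensor_array(n_sensors: int = 124, radius: float = 0.08,
                      coverage: float = 0.75) -> SensorArray:
    """Geodesic-net-like layout: Fibonacci points on the upper scalp.

    ``coverage`` is the fraction of the sphere's polar angle range covered
    from the vertex downward (a real 124-channel net extends below the
    equator but leaves the face/neck free).
    """
    k = np.arange(n_sensors)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    # z from near-vertex down to the coverage limit
    z = 1.0 - (1.0 - np.cos(coverage * np.pi)) * (k + 0.5) / n_sensors
    theta = golden * k
    rho = np.sqrt(np.clip(1.0 - z ** 2, 0, 1))
    pos = radius * np.column_stack([rho * np.cos(theta),
                                    rho * np.sin(theta), z])
    labels = [f"E{i + 1}" for i in range(n_sensors)]
    return SensorArray(labels=labels, positions=pos)


def make_toy_atlas(grid: SourceGrid, n_rois: int = 48, n_lobes: int = 4,
                   seed: int = 0) -> Atlas:
    """Geometric stand-in parcellation: k-means cells grouped by sector.

    Partitions the inside voxels into ``n_rois`` contiguous (convex-cell)
    ROIs and groups ROIs into ``n_lobes`` angular sectors of the axial
    plane, named after the four major lobes.
    """
    pos = grid.inside_positions
    if n_rois > pos.shape[0]:
        raise ValidationError(
            f"n_rois={n_rois} exceeds {pos.shape[0]} inside voxels")
    if n_lobes > len(LOBES):
        raise ValidationError(f"at most {len(LOBES)} lobes supported")
    labels = None
    for attempt in range(10):                 # kmeans2 may drop a cluster
        _, lab = kmeans2(pos, n_rois, minit="++", seed=seed + attempt,
                         iter=25)
        if len(np.unique(lab)) == n_rois:
            labels = lab
            break
    if labels is None:
        raise ValidationError("could not build a non-empty partition")
    roi_names = [f"roi{r:02d}" for r in range(n_rois)]
    centroids = np.array([pos[labels == r].mean(axis=0) for r in range(n_rois)])
    ang = np.arctan2(centroids[:, 1], centroids[:, 0])   # (-pi, pi]
    sector = np.minimum((ang + np.pi) / (2 * np.pi) * n_lobes,
                        n_lobes - 1).astype(int)
    roi_to_lobe = {roi_names[r]: LOBES[sector[r]] for r in range(n_rois)}
    return Atlas(voxel_labels=labels, roi_names=roi_names,
                 roi_to_lobe=roi_to_lobe)


def simulate_envelope_network(n_vertices: int, loadings: np.ndarray,
                              n_samples: int = 4000, srate: float = 250.0,
                              band: BandSpec | None = None,
                              noise_sd: float = 0.1,
                              seed: int = 0) -> np.ndarray:
    """Vertex-level analytic series with a shared envelope-coupling topology.

    Each vertex's log power envelope loads on a common slow factor with
    weight ``loadings[v]`` (in [0, 1)); the expected log-envelope correlation
    between vertices v and w is loadings[v] * loadings[w], so the loading
    vector *is* the planted hub topology.  Carriers are independent
    narrowband noise, so the coupling is purely amplitude-to-amplitude.
    Returns a complex (n_vertices, n_samples) analytic array.
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape != (n_vertices,):
        raise ValidationError("loadings must have one weight per vertex")
    if np.any((loadings < 0) | (loadings >= 1)):
        raise ValidationError("loadings must be in [0, 1)")
    band = band or BandSpec("alpha", 5, 11)
    z = _narrowband_analytic(_rng(seed, 11), n_vertices, n_samples, band, srate)
    slow = _slow_gaussian(_rng(seed, 12), (n_vertices + 1, n_samples), srate)
    shared, own = slow[0], slow[1:]
    a = loadings[:, None] * shared + np.sqrt(1 - loadings ** 2)[:, None] * own
    phase = z / np.maximum(np.abs(z), 1e-30)
    out = np.exp(_SIGMA_LOG_ENV * a) * phase
    if noise_sd > 0:
        out = out + noise_sd * _narrowband_analytic(
            _rng(seed, 13), n_vertices, n_samples, band, srate)
    return out
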