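"""Preprocessing chain for pediatric resting EEG.

Broadband FIR filtering (1-50 Hz, Hamming window, zero phase), 2-s epoching,
+/-100 uV amplitude-based artifact rejection, spherical-spline interpolation
of bad channels, a 30-clean-epoch (60 s) inclusion gate, age-specific band
definitions, and analytic-signal extraction via the Hilbert transform.

Filters are applied forward-backward (zero phase); band filtering and the
Hilbert transform operate on the continuous signal before (re-)epoching so
per-epoch edge artifacts of the analytic signal are avoided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import filtfilt, firwin, hilbert
from scipy.special import eval_legendre

from .core_io import Recording, SensorArray
from .exceptions import (ExclusionError, StructuralError, ValidationError)

logger = logging.getLogger("srcfc")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BandSpec:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not (0 < self.f_lo < self.f_hi):
            raise ValidationError(
                f"band {self.name}: need 0 < f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})")

    def validate_against(self, srate: float) -> None:
        if self.f_hi >= srate / 2:
            raise ValidationError(
                f"band {self.name} upper edge {self.f_hi} Hz >= Nyquist "
                f"({srate / 2} Hz)")


@dataclass
class EpochedData:
    """Fixed-length epochs: epochs x channels x samples, with a keep mask."""

    data: np.ndarray
    srate: float
    epoch_length: float
    channel_labels: list[str]
    kept_mask: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.data.ndim != 3:
            raise StructuralError("epoched data must be 3-D")
        if self.data.shape[2] != round(self.epoch_length * self.srate):
            raise StructuralError("samples per epoch inconsistent with length/srate")
        if self.kept_mask.shape != (self.data.shape[0],):
            raise StructuralError("kept_mask length != number of epochs")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())


@dataclass
class AnalyticEpochs:
    """Complex band-limited analytic signal: epochs x signals x samples.

    ``abs`` of the data is the amplitude envelope, ``angle`` the
    instantaneous phase.
    """

    data: np.ndarray
    band: BandSpec
    srate: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 3:
            raise StructuralError("analytic data must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise StructuralError("analytic data contains non-finite values")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def design_bandpass(f_lo: float, f_hi: float, srate: float,
                    n_samples: int | None = None) -> np.ndarray:
    """Hamming-window FIR bandpass taps.

    Order targets a transition width of 25 % of the lower edge frequency,
    floored at 2 Hz (Hamming main-lobe rule numtaps ~ 3.3 * srate / width),
    with a floor of 0.1 * srate taps.  Without the 2-Hz floor a 1-Hz lower
    edge would demand a filter longer than typical recordings, whose
    boundary transients would dominate the output.  When ``n_samples`` is
    given the order is additionally capped so the forward-backward padding
    fits the signal.
    """
    width = max(0.25 * f_lo, 2.0)
    numtaps = int(math.ceil(3.3 * srate / width))
    numtaps = max(numtaps, int(math.ceil(0.1 * srate)))
    if n_samples is not None:
        cap = max((n_samples - 2) // 3, 11)
        if numtaps > cap:
            logger.info("FIR order capped %d -> %d for %d-sample signal",
                        numtaps, cap, n_samples)
            numtaps = cap
    if numtaps % 2 == 0:
        numtaps += 1
    return firwin(numtaps, [f_lo, f_hi], pass_zero=False, window="hamming",
                  fs=srate)


def _zero_phase(taps: np.ndarray, data: np.ndarray) -> np.ndarray:
    padlen = min(3 * (len(taps) - 1), data.shape[-1] - 1)
    return filtfilt(taps, [1.0], data, axis=-1, padlen=padlen)


def broadband_filter(rec: Recording, f_lo: float = 1.0,
                     f_hi: float = 50.0) -> Recording:
    """Zero-phase Hamming-FIR bandpass of the continuous recording."""
    if f_hi >= rec.srate / 2:
        raise ValidationError(
            f"upper edge {f_hi} Hz >= Nyquist ({rec.srate / 2} Hz)")
    taps = design_bandpass(f_lo, f_hi, rec.srate, rec.n_samples)
    out = _zero_phase(taps, rec.data)
    logger.info("broadband filter %g-%g Hz, %d taps, shape %s",
                f_lo, f_hi, len(taps), rec.data.shape)
    return Recording(data=out, srate=rec.srate,
                     channel_labels=list(rec.channel_labels),
                     reference=rec.reference)


# ---------------------------------------------------------------------------
# epoching / rejection / inclusion
# ---------------------------------------------------------------------------

def epoch(rec: Recording, length_s: float = 2.0) -> EpochedData:
    """Cut consecutive non-overlapping epochs; trailing partial discarded."""
    spe = int(round(length_s * rec.srate))
    n_ep = rec.n_samples // spe
    if n_ep == 0:
        raise ExclusionError(
            f"recording shorter ({rec.duration:.3g} s) than one epoch "
            f"({length_s} s)")
    data = rec.data[:, : n_ep * spe].reshape(rec.n_channels, n_ep, spe)
    data = np.transpose(data, (1, 0, 2))
    return EpochedData(data=data, srate=rec.srate, epoch_length=length_s,
                       channel_labels=list(rec.channel_labels),
                       kept_mask=np.ones(n_ep, dtype=bool))


def reject_artifacts(ep: EpochedData, threshold_uV: float = 100.0) -> EpochedData:
    """Mark epochs containing any sample with |x| strictly above threshold.

    Sample values are never modified; only the keep mask.  A sample at
    exactly the threshold survives (strict inequality).
    """
    if threshold_uV <= 0:
        raise ValidationError("threshold must be positive")
    peaks = np.abs(ep.data).max(axis=(1, 2))
    mask = ep.kept_mask & ~(peaks > threshold_uV)
    logger.info("artifact rejection at +/-%g uV: kept %d/%d epochs",
                threshold_uV, mask.sum(), ep.n_epochs)
    return EpochedData(data=ep.data, srate=ep.srate,
                       epoch_length=ep.epoch_length,
                       channel_labels=list(ep.channel_labels), kept_mask=mask)


def inclusion_gate(ep: EpochedData, min_epochs: int = 30) -> EpochedData:
    """Keep only clean epochs; exclude the subject below the minimum count.

    The default (30 epochs of 2 s) corresponds to 60 s of clean data.
    """
    if ep.n_kept < min_epochs:
        raise ExclusionError(
            f"subject excluded: {ep.n_kept} clean epochs < required "
            f"{min_epochs} ({min_epochs * ep.epoch_length:g} s)")
    data = ep.data[ep.kept_mask]
    return EpochedData(data=data, srate=ep.srate, epoch_length=ep.epoch_length,
                       channel_labels=list(ep.channel_labels),
                       kept_mask=np.ones(data.shape[0], dtype=bool))


# ---------------------------------------------------------------------------
# spherical spline channel interpolation
# ---------------------------------------------------------------------------

def _gm(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Perrin surface spline kernel g(cos) truncated at n_terms."""
    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n ** m * (n + 1.0) ** m)
    # eval_legendre broadcasts over the trailing axis
    pl = eval_legendre(n[:, None], np.clip(cosang, -1, 1).ravel()[None, :])
    out = (coef[:, None] * pl).sum(axis=0) / (4 * np.pi)
    return out.reshape(cosang.shape)


def interpolation_matrix(sensors: SensorArray, bad: list[str],
                         m: int = 4, n_terms: int = 50,
                         reg: float = 1e-5) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spherical-spline operator mapping good-channel data to bad channels.

    Positions are projected onto the unit sphere.  Returns
    ``(A, good_idx, bad_idx)`` with ``A`` of shape (n_bad, n_good).
    """
    labels = sensors.labels
    bad_idx = np.array([labels.index(b) for b in bad], dtype=int)
    good_idx = np.array([i for i in range(len(labels)) if labels[i] not in bad],
                        dtype=int)
    pos = sensors.positions / np.linalg.norm(sensors.positions, axis=1,
                                             keepdims=True)
    pg, pb = pos[good_idx], pos[bad_idx]
    G = _gm(pg @ pg.T, m, n_terms) + reg * np.eye(len(good_idx))
    Gb = _gm(pb @ pg.T, m, n_terms)
    ng = len(good_idx)
    # solve the constrained spline system [[G, 1], [1^T, 0]]
    S = np.zeros((ng + 1, ng + 1))
    S[:ng, :ng] = G
    S[:ng, ng] = 1.0
    S[ng, :ng] = 1.0
    Sinv = np.linalg.pinv(S)
    # mapping from good data to [coefficients; constant]
    C = Sinv[:, :ng]
    A = Gb @ C[:ng, :] + np.ones((len(bad_idx), 1)) @ C[ng:ng + 1, :]
    return A, good_idx, bad_idx


def interpolate_channels(ep: EpochedData, bad: list[str],
                         sensors: SensorArray) -> EpochedData:
    """Replace bad channels by Perrin spherical-spline estimates.

    Mirrors the subject-level rule that strictly fewer than 15 % of the
    electrodes (18 of 124) may be bad; at or above the limit the subject is
    rejected.
    """
    n_ch = len(ep.channel_labels)
    limit = math.floor(0.15 * n_ch)   # 18 for 124 channels
    if len(bad) >= limit:
        raise ExclusionError(
            f"{len(bad)} bad channels >= limit {limit} (15 % of {n_ch})")
    missing = [b for b in bad if b not in ep.channel_labels]
    if missing:
        raise StructuralError(f"bad channel(s) not in recording: {missing}")
    if not bad:
        return ep
    if sensors.labels != ep.channel_labels:
        raise StructuralError("sensor layout does not match channel labels")
    A, good_idx, bad_idx = interpolation_matrix(sensors, bad)
    data = ep.data.copy()
    # (n_bad, n_good) @ (epochs, n_good, samples)
    data[:, bad_idx, :] = np.einsum("bg,egs->ebs", A, ep.data[:, good_idx, :])
    logger.info("interpolated %d bad channel(s): %s", len(bad), bad)
    return EpochedData(data=data, srate=ep.srate, epoch_length=ep.epoch_length,
                       channel_labels=list(ep.channel_labels),
                       kept_mask=ep.kept_mask.copy())


# ---------------------------------------------------------------------------
# band definitions and analytic signal
# ---------------------------------------------------------------------------

_PRESETS = {
    12: [("theta", 3, 6), ("alpha", 5, 10), ("beta", 11, 22), ("gamma", 22, 45)],
    36: [("theta", 3, 7), ("alpha", 6, 11), ("beta", 11, 22), ("gamma", 22, 45)],
}


def band_presets(age_months: int) -> list[BandSpec]:
    """Age-specific band boundaries (12 and 36 months).

    Theta and alpha deliberately overlap at 12 months (5-6 Hz shared); the
    wide, overlapping boundaries absorb the large inter-individual
    variability of peak frequencies at these ages.
    """
    if age_months not in _PRESETS:
        raise ValidationError(
            f"no band presets for age {age_months} months; supply custom bands")
    return [BandSpec(name=n, f_lo=lo, f_hi=hi) for n, lo, hi in _PRESETS[age_months]]


def band_analytic(rec_or_ep, band: BandSpec, epoch_length_s: float = 2.0,
                  length_s: float | None = None) -> AnalyticEpochs:
    """Band-limit and Hilbert-transform a recording into analytic epochs.

    Continuous input is filtered and transformed as a whole, then epoched
    (``epoch_length_s``), so the analytic signal carries no per-epoch edge
    artifacts.  Epoched input is processed epoch by epoch, restricted to kept
    epochs.
    """
    if length_s is not None:
        epoch_length_s = length_s
    if isinstance(rec_or_ep, Recording):
        rec = rec_or_ep
        band.validate_against(rec.srate)
        taps = design_bandpass(band.f_lo, band.f_hi, rec.srate, rec.n_samples)
        filtered = _zero_phase(taps, rec.data)
        analytic = hilbert(filtered, axis=-1)
        spe = int(round(epoch_length_s * rec.srate))
        n_ep = rec.n_samples // spe
        if n_ep == 0:
            raise ExclusionError("recording shorter than one epoch")
        a = analytic[:, : n_ep * spe].reshape(rec.n_channels, n_ep, spe)
        data = np.transpose(a, (1, 0, 2))
        return AnalyticEpochs(data=data, band=band, srate=rec.srate)
    ep = rec_or_ep
    band.validate_against(ep.srate)
    kept = ep.data[ep.kept_mask]
    taps = design_bandpass(band.f_lo, band.f_hi, ep.srate, kept.shape[-1])
    filtered = _zero_phase(taps, kept)
    return AnalyticEpochs(data=hilbert(filtered, axis=-1), band=band,
                          srate=ep.srate)
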