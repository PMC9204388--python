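"""On-disk formats, run configuration and logging.

All coordinates are stored internally in meters and all potentials in
microvolts; unit conversion happens only at the I/O boundary.  EEG comes in
as EDF (read through :mod:`mne`) or as a plain numeric matrix with a small
structured-text sidecar header (same stem, ``.yaml`` extension) so fixtures
can be written by hand.  Adjacency matrices, sensor layouts, lead fields and
atlas tables are all tab-separated text.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import FormatError, StructuralError, ValidationError

logger = logging.getLogger("srcfc")

_EDF_ANNOT = "EDF Annotations"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix in microvolts.
    srate : float
        Sampling rate in Hz.
    channel_labels : list of str
        Ordered channel identifiers, one per row of ``data``.
    reference : {"vertex", "average", "other"}
        Recording reference tag.
    """

    data: np.ndarray
    srate: float
    channel_labels: list[str]
    reference: str = "other"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise StructuralError("Recording data must be 2-D (channels x samples)")
        if self.srate <= 0:
            raise ValidationError(f"srate must be positive, got {self.srate}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise StructuralError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} data rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise StructuralError("Recording contains non-finite samples")
        if self.reference not in ("vertex", "average", "other"):
            raise ValidationError(f"unknown reference tag {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.srate


@dataclass
class SensorArray:
    """Electrode labels and 3-D positions in meters (head-centered)."""

    labels: list[str]
    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            raise StructuralError("sensor labels are not unique")
        if self.positions.shape != (len(self.labels), 3):
            raise StructuralError("positions must be (n_sensors, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise StructuralError("sensor positions contain non-finite values")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(norms == 0):
            raise StructuralError("sensor at the origin (zero-norm position)")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class RunConfig:
    """Pipeline configuration with the defaults of the published protocol.

    ``n_resample_trials``/``n_repeats`` control the trial-resampled wPLI
    estimator (30 trials, 50 repetitions); ``sparsity`` the proportional
    threshold (top 50 % of edges); ``grid_resolution`` the source lattice
    spacing in mm; ``n_vertices`` the vertex count of the envelope-correlation
    (aac) pipeline.
    """

    age_group: int = 12
    bands: list = field(default_factory=list)
    pipeline: str = "pps"
    fc_method: str = "wpli"
    n_resample_trials: int = 30
    n_repeats: int = 50
    sparsity: float = 0.5
    grid_resolution: float = 6.0
    n_vertices: int = 5000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.sparsity <= 1):
            raise ValidationError(f"sparsity must be in (0, 1], got {self.sparsity}")
        if self.n_resample_trials < 2:
            raise ValidationError("n_resample_trials must be >= 2")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        if self.pipeline not in ("pps", "aac"):
            raise ValidationError(f"unknown pipeline {self.pipeline!r}")
        if self.fc_method not in ("wpli", "icoh", "plv", "coh", "aac_orth", "aac_plain"):
            raise ValidationError(f"unknown fc_method {self.fc_method!r}")
        if not self.bands:
            from .preprocess import band_presets  # deferred: avoids import cycle

            self.bands = band_presets(self.age_group)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    for ext in (".yaml", ".yml", ".json"):
        cand = path.with_suffix(ext)
        if cand.exists():
            return cand
    return path.with_suffix(".yaml")


def read_recording(path, format: str | None = None) -> Recording:
    """Read a continuous EEG recording.

    ``format`` is ``"edf"`` or ``"matrix"``; when omitted it is inferred from
    the file extension (``.edf`` vs anything else).  Matrix files are plain
    numeric channels x samples tables with a YAML sidecar header (same stem)
    declaring at least ``srate``; optional keys are ``channel_labels``,
    ``unit`` (``uV`` default, or ``V``) and ``reference``.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return _read_edf(path)
    if format == "matrix":
        return _read_matrix(path)
    raise ValidationError(f"unknown recording format {format!r}")


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne returns volts
    labels = list(raw.ch_names)
    logger.info("read EDF %s: %d channels x %d samples @ %g Hz",
                path, data.shape[0], data.shape[1], raw.info["sfreq"])
    return Recording(data=data, srate=float(raw.info["sfreq"]),
                     channel_labels=labels)


def _read_matrix(path: Path) -> Recording:
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing sidecar header for {path}")
    with open(side) as fh:
        header = yaml.safe_load(fh) or {}
    if "srate" not in header:
        raise StructuralError(f"sidecar {side} missing required field 'srate'")
    try:
        data = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None,
                          ndmin=2)
    except Exception as exc:
        raise FormatError(f"cannot parse numeric matrix {path}: {exc}") from exc
    unit = header.get("unit", "uV")
    if unit == "V":
        data = data * 1e6
    elif unit != "uV":
        raise ValidationError(f"unknown unit {unit!r} in {side}")
    labels = header.get("channel_labels")
    if labels is None:
        labels = [f"ch{i + 1}" for i in range(data.shape[0])]
    if len(labels) != data.shape[0]:
        raise StructuralError(
            f"{len(labels)} channel_labels for {data.shape[0]} rows in {path}")
    return Recording(data=data, srate=float(header["srate"]),
                     channel_labels=list(labels),
                     reference=header.get("reference", "other"))


def write_recording(rec: Recording, path, format: str | None = None,
                    physical_range: tuple[float, float] | None = None) -> None:
    """Write a recording as EDF or matrix+header (inverse of read_recording)."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        _write_edf(rec, path, physical_range)
    elif format == "matrix":
        np.savetxt(path, rec.data, fmt="%.10g", delimiter="\t")
        header = {"srate": float(rec.srate), "channel_labels": list(rec.channel_labels),
                  "unit": "uV", "reference": rec.reference}
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(header, fh)
    else:
        raise ValidationError(f"unknown recording format {format!r}")


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _edf_number(v: float, width: int = 8) -> str:
    """Shortest decimal representation of v that fits the EDF field width."""
    for p in range(8, 0, -1):
        s = f"{v:.{p}g}"
        if len(s) <= width:
            return s
    return "0"


def _write_edf(rec: Recording, path: Path,
               physical_range: tuple[float, float] | None) -> None:
    """Minimal EDF writer: 16-bit samples, 1-second data records.

    Covers exactly what the toolkit needs to ship synthetic recordings in a
    standard format; requires an integer sampling rate.  The trailing partial
    record is zero-padded.
    """
    srate = rec.srate
    if abs(srate - round(srate)) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    spr = int(round(srate))
    nchan = rec.n_channels
    n_rec = math.ceil(rec.n_samples / spr)
    data = np.zeros((nchan, n_rec * spr))
    data[:, : rec.n_samples] = rec.data

    dmin, dmax = -32768, 32767
    if physical_range is None:
        lo = np.minimum(data.min(axis=1), -1.0)
        hi = np.maximum(data.max(axis=1), 1.0)
    else:
        lo = np.full(nchan, float(physical_range[0]))
        hi = np.full(nchan, float(physical_range[1]))
    # digitize against the values as they will appear in the 8-char header
    lo = np.array([float(_edf_number(v)) for v in lo])
    hi = np.array([float(_edf_number(v)) for v in hi])
    scale = (dmax - dmin) / (hi - lo)
    digital = np.rint((data - lo[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X X X X", 80))
        fh.write(_edf_field("Startdate 01-JAN-2000 X X X", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(256 * (1 + nchan), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(n_rec, 8))
        fh.write(_edf_field(1, 8))
        fh.write(_edf_field(nchan, 4))
        for lab in rec.channel_labels:
            fh.write(_edf_field(lab, 16))
        fh.write(b"".join(_edf_field("", 80) for _ in range(nchan)))
        fh.write(b"".join(_edf_field("uV", 8) for _ in range(nchan)))
        for v in lo:
            fh.write(_edf_field(_edf_number(v), 8))
        for v in hi:
            fh.write(_edf_field(_edf_number(v), 8))
        fh.write(b"".join(_edf_field(dmin, 8) for _ in range(nchan)))
        fh.write(b"".join(_edf_field(dmax, 8) for _ in range(nchan)))
        fh.write(b"".join(_edf_field("", 80) for _ in range(nchan)))
        fh.write(b"".join(_edf_field(spr, 8) for _ in range(nchan)))
        fh.write(b"".join(_edf_field("", 32) for _ in range(nchan)))
        for r in range(n_rec):
            block = digital[:, r * spr: (r + 1) * spr]
            fh.write(block.tobytes())
    logger.info("wrote EDF %s: %d channels, %d records @ %d Hz", path, nchan,
                n_rec, spr)


# ---------------------------------------------------------------------------
# sensor layouts
# ---------------------------------------------------------------------------

def read_sensor_layout(path) -> SensorArray:
    """Read a whitespace/comma-delimited ``label x y z`` table.

    ``#``-prefixed header lines may declare ``unit: mm`` (converted to
    meters) or ``unit: m`` (default).
    """
    path = Path(path)
    unit = "m"
    labels, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("unit"):
                    unit = body.split(":", 1)[1].strip().lower()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 'label x y z'")
            labels.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:4]])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinate: {exc}") from exc
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise StructuralError(f"duplicate sensor label(s): {dup}")
    pos = np.asarray(rows, dtype=float)
    if unit == "mm":
        pos = pos / 1000.0
    elif unit != "m":
        raise ValidationError(f"unknown coordinate unit {unit!r}")
    return SensorArray(labels=labels, positions=pos)


def write_sensor_layout(sensors: SensorArray, path, unit: str = "m") -> None:
    pos = sensors.positions * (1000.0 if unit == "mm" else 1.0)
    with open(path, "w") as fh:
        fh.write(f"# unit: {unit}\n")
        for lab, p in zip(sensors.labels, pos):
            fh.write(f"{lab}\t{p[0]:.8g}\t{p[1]:.8g}\t{p[2]:.8g}\n")


# ---------------------------------------------------------------------------
# adjacency matrices
# ---------------------------------------------------------------------------

def write_adjacency(matrix, path) -> None:
    """Write an AdjacencyMatrix as labeled TSV with '#' metadata lines."""
    values = np.asarray(matrix.values, dtype=float)
    if not np.allclose(values, values.T, atol=0, rtol=0, equal_nan=True):
        raise StructuralError("adjacency matrix is not symmetric")
    with open(path, "w") as fh:
        fh.write(f"# metric: {matrix.metric}\n")
        if matrix.band is not None:
            fh.write(f"# band: {matrix.band.name} {matrix.band.f_lo} "
                     f"{matrix.band.f_hi}\n")
        fh.write("node\t" + "\t".join(matrix.node_labels) + "\n")
        for lab, row in zip(matrix.node_labels, values):
            fh.write(lab + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")


def read_adjacency(path):
    """Read an adjacency TSV written by :func:`write_adjacency`."""
    from .connectivity import AdjacencyMatrix
    from .preprocess import BandSpec

    path = Path(path)
    metric, band = "unknown", None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, _, val = line.lstrip("#").strip().partition(":")
            key, val = key.strip(), val.strip()
            if key == "metric":
                metric = val
            elif key == "band":
                name, lo, hi = val.split()
                band = BandSpec(name=name, f_lo=float(lo), f_hi=float(hi))
        elif line.strip():
            body.append(line.rstrip("\n"))
    if not body:
        raise FormatError(f"{path}: no table content")
    labels = body[0].split("\t")[1:]
    rows = []
    for line in body[1:]:
        parts = line.split("\t")
        rows.append([float(v) for v in parts[1:]])
    values = np.asarray(rows)
    if values.shape != (len(labels), len(labels)):
        raise StructuralError(f"{path}: non-square adjacency table")
    values = 0.5 * (values + values.T)  # kill asymmetric rounding at 1e-6 level
    return AdjacencyMatrix(values=values, metric=metric, band=band,
                           node_labels=labels)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {"age_group", "bands", "pipeline", "fc_method",
                "n_resample_trials", "n_repeats", "sparsity",
                "grid_resolution", "n_vertices", "seed"}


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, filling protocol defaults.

    Unknown keys are rejected; ``bands`` may be given as a list of
    ``{name, f_lo, f_hi}`` mappings, otherwise the age-specific presets are
    filled in.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"config {path} is not a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    if "bands" in raw:
        from .preprocess import BandSpec

        raw["bands"] = [BandSpec(**b) for b in raw["bands"]]
    cfg = RunConfig(**raw)
    logger.info("loaded config %s: %s", path, cfg)
    return cfg
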