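"""Analytic concentric-shell head model, source grid and lead field.

The head is modelled as three concentric spherical shells (brain, skull,
scalp) with piecewise-constant conductivity.  The potential of a current
dipole inside the innermost shell is expanded in Legendre harmonics; for
each harmonic order the radial two-point boundary problem (continuity of
potential and of radial current at each interface, zero radial current at
the scalp) is solved directly, giving per-order gain factors that multiply
the infinite-medium dipole expansion.  Skull conductivity carries the
age-specific values (0.066 S/m at 12 months, 0.036 S/m at 36 months);
brain and scalp default to 0.33 S/m.

Externally computed lead fields (e.g. from FEM/BEM solvers) can be imported
from a labeled TSV container and are re-aligned to the sensor order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import SensorArray
from .exceptions import (AlignmentError, NumericalError, StructuralError,
                         ValidationError)

logger = logging.getLogger("srcfc")


@dataclass
class HeadModel:
    """Three concentric shells: radii (m) and conductivities (S/m)."""

    shell_radii: tuple[float, float, float]
    conductivities: tuple[float, float, float]
    age_months: int | None = None

    def __post_init__(self):
        r = self.shell_radii
        if not (0 < r[0] < r[1] < r[2]):
            raise ValidationError(f"shell radii must increase, got {r}")
        if any(c <= 0 for c in self.conductivities):
            raise ValidationError("conductivities must be positive")

    @property
    def brain_radius(self) -> float:
        return self.shell_radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.shell_radii[2]


@dataclass
class SourceGrid:
    """Regular lattice of candidate dipole positions inside the brain shell."""

    positions: np.ndarray      # all candidate lattice points, (n, 3) meters
    resolution: float          # lattice spacing, mm
    inside_mask: np.ndarray    # boolean per candidate

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.inside_mask = np.asarray(self.inside_mask, dtype=bool)
        if self.positions.shape[0] != self.inside_mask.shape[0]:
            raise StructuralError("inside_mask length != number of candidates")

    @property
    def inside_positions(self) -> np.ndarray:
        return self.positions[self.inside_mask]

    @property
    def n_inside(self) -> int:
        return int(self.inside_mask.sum())


@dataclass
class LeadField:
    """Forward operator: channels x (3 * n_sources), uV per unit dipole moment."""

    matrix: np.ndarray
    channel_labels: list[str]
    source_positions: np.ndarray = field(default=None)
    reference: str = "average"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] % 3 != 0:
            raise StructuralError(
                f"lead-field column count {self.matrix.shape[1]} not divisible by 3")
        if self.matrix.shape[0] != len(self.channel_labels):
            raise StructuralError("row count != number of channel labels")
        if not np.all(np.isfinite(self.matrix)):
            raise StructuralError("lead field contains non-finite values")

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1] // 3

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def source_block(self, i: int) -> np.ndarray:
        """Channels x 3 sub-matrix for source i."""
        return self.matrix[:, 3 * i: 3 * i + 3]


# ---------------------------------------------------------------------------
# presets and grid
# ---------------------------------------------------------------------------

_SKULL_SIGMA = {12: 0.066, 36: 0.036}


def head_model_preset(age_months: int) -> HeadModel:
    """Age-specific three-shell model.

    Skull conductivity 0.066 S/m (12 months) or 0.036 S/m (36 months);
    brain/scalp 0.33 S/m.  Radii 0.07/0.075/0.08 m at 12 months, scaled by
    1.07 for 36 months (head growth); radii are a package convention and
    fully configurable through :class:`HeadModel`.
    """
    if age_months not in _SKULL_SIGMA:
        raise ValidationError(f"no head-model preset for age {age_months} months")
    scale = 1.0 if age_months == 12 else 1.07
    radii = tuple(r * scale for r in (0.07, 0.075, 0.08))
    return HeadModel(shell_radii=radii,
                     conductivities=(0.33, _SKULL_SIGMA[age_months], 0.33),
                     age_months=age_months)


def build_source_grid(hm: HeadModel, resolution_mm: float = 6.0) -> SourceGrid:
    """Axis-aligned lattice; points with ||p|| < 0.95 * brain radius are inside."""
    if resolution_mm <= 0:
        raise ValidationError("resolution must be positive")
    step = resolution_mm / 1000.0
    r = hm.brain_radius
    n = int(np.floor(r / step))
    ax = np.arange(-n, n + 1) * step
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pos = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = np.linalg.norm(pos, axis=1) < 0.95 * r
    if not inside.any():
        raise ValidationError(
            f"no lattice point inside brain shell at {resolution_mm} mm")
    logger.info("source grid: %d mm, %d inside voxels", resolution_mm,
                int(inside.sum()))
    return SourceGrid(positions=pos, resolution=resolution_mm,
                      inside_mask=inside)


# ---------------------------------------------------------------------------
# concentric-shell lead field
# ---------------------------------------------------------------------------

def _shell_gains(hm: HeadModel, n_terms: int) -> np.ndarray:
    """Per-order scalp-surface gain c_n for a unit interior source coefficient.

    Radii are normalized by the scalp radius; for order n the five unknown
    expansion coefficients (one regular term in the brain, regular+singular
    in skull and scalp) solve the interface/boundary conditions.  In the
    homogeneous limit c_n = (2n+1)/n.
    """
    s1, s2, s3 = hm.conductivities
    u1, u2, u3 = (r / hm.scalp_radius for r in hm.shell_radii)
    gains = np.empty(n_terms)
    for n in range(1, n_terms + 1):
        # unknowns: A1, A2, B2, A3, B3 ; source term u^-(n+1) with coeff 1 in brain
        def reg(u):
            return u ** n

        def sing(u):
            return u ** -(n + 1)

        def dreg(u):
            return n * u ** (n - 1)

        def dsing(u):
            return -(n + 1) * u ** -(n + 2)

        A = np.array([
            [reg(u1), -reg(u1), -sing(u1), 0, 0],
            [s1 * dreg(u1), -s2 * dreg(u1), -s2 * dsing(u1), 0, 0],
            [0, reg(u2), sing(u2), -reg(u2), -sing(u2)],
            [0, s2 * dreg(u2), s2 * dsing(u2), -s3 * dreg(u2), -s3 * dsing(u2)],
            [0, 0, 0, dreg(u3), dsing(u3)],
        ])
        b = np.array([-sing(u1), -s1 * dsing(u1), 0, 0, 0])
        try:
            x = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"shell system singular at order {n}") from exc
        gains[n - 1] = x[3] * reg(u3) + x[4] * sing(u3)
    if not np.all(np.isfinite(gains)):
        raise NumericalError("non-finite shell gains (series diverged)")
    return gains


def project_sensors_to_scalp(sensors: SensorArray, hm: HeadModel) -> np.ndarray:
    """Radially project sensor positions onto the scalp sphere."""
    pos = sensors.positions
    return pos * (hm.scalp_radius / np.linalg.norm(pos, axis=1, keepdims=True))


def compute_leadfield(hm: HeadModel, grid: SourceGrid, sensors: SensorArray,
                      n_terms: int = 60) -> LeadField:
    """Three-shell analytic lead field, average-referenced.

    For each inside source and sensor the potential of the three Cartesian
    unit dipoles is the truncated Legendre series with per-order shell gains;
    the tangential part uses the derivative recurrence so no division by
    sin(gamma) occurs.  Output units are uV per unit dipole moment (A*m).
    """
    src = grid.inside_positions
    if src.shape[0] == 0:
        raise ValidationError("source grid has no inside voxels")
    b = np.linalg.norm(src, axis=1)
    if np.any(b >= hm.brain_radius):
        raise ValidationError("source outside the brain shell")
    elec = project_sensors_to_scalp(sensors, hm)
    R = hm.scalp_radius
    e_hat = elec / R
    n_src = src.shape[0]
    n_ch = elec.shape[0]

    # local radial frame; sources at the center get an arbitrary axis (their
    # t^(n-1) factor keeps only the n=1 term, which is frame-independent)
    p_hat = np.where(b[:, None] > 1e-12, src / np.maximum(b, 1e-12)[:, None],
                     np.array([0.0, 0.0, 1.0]))
    t = b / R                                # source eccentricity, in (0, 1)
    c = _shell_gains(hm, n_terms)

    x = e_hat @ p_hat.T                      # cos(gamma), (n_ch, n_src)
    x = np.clip(x, -1.0, 1.0)
    # Legendre recurrences accumulated with the per-source factor t^(n-1)
    P_prev = np.ones_like(x)                 # P_0
    P_cur = x.copy()                         # P_1
    dP_prev = np.zeros_like(x)               # P'_0
    dP_cur = np.ones_like(x)                 # P'_1
    tfac = np.ones(n_src)                    # t^(n-1)
    S_r = np.zeros_like(x)
    S_d = np.zeros_like(x)
    for n in range(1, n_terms + 1):
        w = c[n - 1] * tfac                  # (n_src,)
        S_r += (n * w)[None, :] * P_cur
        S_d += w[None, :] * dP_cur
        if n < n_terms:
            P_next = ((2 * n + 1) * x * P_cur - n * P_prev) / (n + 1)
            dP_next = dP_prev + (2 * n + 1) * P_cur
            P_prev, P_cur = P_cur, P_next
            dP_prev, dP_cur = dP_cur, dP_next
            tfac = tfac * t

    k = 1.0 / (4 * np.pi * hm.conductivities[0] * R ** 2)
    # radial part along p_hat, tangential along (e_hat - x * p_hat)
    lf = np.empty((n_ch, 3 * n_src))
    for j in range(3):
        radial = S_r * p_hat[None, :, j]
        tangential = S_d * (e_hat[:, None, j] - x * p_hat[None, :, j])
        lf[:, j::3] = k * (radial + tangential)
    lf *= 1e6  # volts -> microvolts
    lf -= lf.mean(axis=0, keepdims=True)  # average reference
    logger.info("lead field: %d channels x %d sources, %d series terms",
                n_ch, n_src, n_terms)
    return LeadField(matrix=lf, channel_labels=list(sensors.labels),
                     source_positions=src, reference="average")


# ---------------------------------------------------------------------------
# import / export
# ---------------------------------------------------------------------------

def write_leadfield(lf: LeadField, path) -> None:
    """Write a lead field as TSV with '#' header lines (channels = rows)."""
    with open(path, "w") as fh:
        fh.write("# channels: " + "\t".join(lf.channel_labels) + "\n")
        fh.write(f"# n_sources: {lf.n_sources}\n")
        fh.write(f"# reference: {lf.reference}\n")
        if lf.source_positions is not None:
            flat = " ".join(f"{v:.8g}" for v in np.ravel(lf.source_positions))
            fh.write(f"# source_positions: {flat}\n")
        np.savetxt(fh, lf.matrix, fmt="%.10g", delimiter="\t")


def import_leadfield(path, sensors: SensorArray) -> LeadField:
    """Read a lead-field TSV and align its channel rows to the sensor order."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, _, val = line.lstrip("#").strip().partition(":")
            meta[key.strip()] = val.strip()
        elif line.strip():
            body.append(line)
    if "channels" not in meta:
        raise StructuralError(f"{path}: missing '# channels:' header")
    labels = meta["channels"].split("\t")
    matrix = np.loadtxt(body, delimiter="\t", ndmin=2)
    if matrix.shape[1] % 3 != 0:
        raise StructuralError(
            f"{path}: {matrix.shape[1]} columns not divisible by 3")
    if matrix.shape[0] != len(labels):
        raise StructuralError(f"{path}: {matrix.shape[0]} rows for "
                              f"{len(labels)} channel labels")
    if set(labels) != set(sensors.labels):
        raise AlignmentError("lead-field channel labels do not match sensors")
    order = [labels.index(lab) for lab in sensors.labels]
    src = None
    if "source_positions" in meta:
        src = np.array([float(v) for v in meta["source_positions"].split()])
        src = src.reshape(-1, 3)
    return LeadField(matrix=matrix[order], channel_labels=list(sensors.labels),
                     source_positions=src,
                     reference=meta.get("reference", "average"))
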