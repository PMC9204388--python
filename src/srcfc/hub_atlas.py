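"""Data-derived hub topology from vertex-level amplitude coupling.

Per subject, an all-pairs orthogonalized power-envelope correlation matrix
over the source vertices is computed and robustly normalized using the
median and median absolute deviation of its unique off-diagonal entries
(centering makes zero the typical connectivity).  Across subjects, each
vertex pair's strength is summarized by a one-sample Student t statistic
against zero, and the per-vertex mean of the t matrix is the topology
vector: large values mark connectivity hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectivity import aac_matrix
from .exceptions import (DegenerateScaleError, InsufficientDataError,
                         StructuralError)
from .preprocess import BandSpec

logger = logging.getLogger("srcfc")


@dataclass
class SubjectMatrixSet:
    """Per-subject symmetric V x V AAC matrices."""

    matrices: np.ndarray                 # (subjects, V, V)
    subject_ids: list[str]
    band: BandSpec | None = None

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or (
                self.matrices.shape[1] != self.matrices.shape[2]):
            raise StructuralError("matrices must be (subjects, V, V)")
        if len(self.subject_ids) != self.matrices.shape[0]:
            raise StructuralError("subject id count mismatch")

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.matrices.shape[1]


@dataclass
class TopologyVector:
    """Per-vertex mean group-t connectivity strength (the hub atlas)."""

    values: np.ndarray
    band: BandSpec | None = None
    group: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise StructuralError("topology vector must be 1-D")

    def __len__(self) -> int:
        return self.values.shape[0]


def vertex_aac_matrices(subject_series: list[np.ndarray],
                        orthogonalized: bool = True,
                        subject_ids: list[str] | None = None,
                        band: BandSpec | None = None,
                        single_precision: bool = False) -> SubjectMatrixSet:
    """All-pairs AAC matrix per subject from vertex analytic series.

    Each element of ``subject_series`` is a complex (V, T) array (or
    (epochs, V, samples)); all subjects must share the same vertex count V.
    """
    Vs = set()
    mats = []
    for s in subject_series:
        arr = np.asarray(s)
        V = arr.shape[0] if arr.ndim == 2 else arr.shape[1]
        Vs.add(V)
        if len(Vs) > 1:
            raise StructuralError(f"vertex count differs across subjects: {Vs}")
        mats.append(aac_matrix(arr, orthogonalized=orthogonalized,
                               single_precision=single_precision).values)
    ids = subject_ids or [f"s{i + 1}" for i in range(len(mats))]
    logger.info("vertex AAC: %d subjects, V=%d, orthogonalized=%s",
                len(mats), Vs.pop(), orthogonalized)
    return SubjectMatrixSet(matrices=np.stack(mats), subject_ids=ids, band=band)


def robust_normalize(m: np.ndarray) -> np.ndarray:
    """Center/scale a symmetric matrix by median and MAD of unique entries.

    The MAD is unscaled (no 1.4826 normality factor): downstream use is
    rank- and contrast-based only.  The diagonal stays 0.
    """
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = m[iu, ju]
    if np.unique(vals[~np.isnan(vals)]).size < 2:
        raise DegenerateScaleError("fewer than 2 distinct off-diagonal values")
    med = np.nanmedian(vals)
    mad = np.nanmedian(np.abs(vals - med))
    if mad == 0:
        raise DegenerateScaleError("median absolute deviation is zero")
    out = (m - med) / mad
    np.fill_diagonal(out, 0.0)
    return out


def group_t_matrix(mset: SubjectMatrixSet) -> np.ndarray:
    """Per-pair one-sample Student t of subject values against zero.

    t = mean / (sd / sqrt(n)) with the (n-1)-denominator sd; pairs with zero
    across-subject variance are undefined (NaN) and counted in the log.
    """
    if mset.n_subjects < 2:
        raise InsufficientDataError("group t needs at least 2 subjects")
    X = mset.matrices
    n = mset.n_subjects
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    # zero across-subject variance (up to float rounding) is undefined
    t[sd <= np.abs(mean) * 1e-12] = np.nan
    np.fill_diagonal(t, 0.0)
    n_undef = int(np.isnan(t).sum())
    if n_undef:
        logger.info("group_t_matrix: %d undefined pair value(s)", n_undef)
    return t


def topology_vector(t: np.ndarray, band: BandSpec | None = None,
                    group: str = "") -> TopologyVector:
    """Per-vertex mean of the t matrix over the other vertices.

    Missing (NaN) entries are excluded from each mean; a vertex whose row is
    entirely missing gets NaN.
    """
    t = np.asarray(t, dtype=float)
    V = t.shape[0]
    if t.shape != (V, V):
        raise StructuralError("t matrix must be square")
    if not np.allclose(t, t.T, equal_nan=True):
        raise StructuralError("t matrix must be symmetric")
    off = t.copy()
    np.fill_diagonal(off, np.nan)
    with np.errstate(invalid="ignore"):
        counts = np.sum(~np.isnan(off), axis=1)
        sums = np.nansum(off, axis=1)
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return TopologyVector(values=values, band=band, group=group)


def write_topology(tv: TopologyVector, positions: np.ndarray | None,
                   path) -> None:
    """TSV: vertex index, x, y, z, value (coordinates optional)."""
    with open(path, "w") as fh:
        fh.write("# columns: vertex x y z value\n")
        for i, v in enumerate(tv.values):
            if positions is not None:
                x, y, z = positions[i]
            else:
                x = y = z = float("nan")
            fh.write(f"{i}\t{x:.8g}\t{y:.8g}\t{z:.8g}\t{v:.8g}\n")
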