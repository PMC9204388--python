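"""Atlas handling and ROI representative time series.

An atlas assigns every inside grid voxel to exactly one of (by default) 48
cortical ROIs, each mapped to one of the four major lobes.  A ROI's
representative series is either the mean over the voxel(s) nearest the ROI
centroid (``centroid``, the phase-synchrony pipeline default with k=1), the
mean over all member voxels (``mean``), or the first principal component of
the voxel-by-time matrix (``pca``).

For analytic (complex) input, centroid and mean act directly on the complex
series; PCA loadings are estimated on the real part and then applied to the
complex series, so the phase structure is not distorted by the component
rotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import StructuralError, ValidationError
from .forward import SourceGrid

logger = logging.getLogger("srcfc")

LOBES = ("frontal", "temporal", "parietal", "occipital")


@dataclass
class Atlas:
    """Voxel -> ROI labeling plus ROI -> lobe grouping."""

    voxel_labels: np.ndarray          # ROI index per inside voxel
    roi_names: list[str]
    roi_to_lobe: dict[str, str]

    def __post_init__(self):
        self.voxel_labels = np.asarray(self.voxel_labels, dtype=int)
        n_roi = len(self.roi_names)
        present = np.unique(self.voxel_labels)
        if present.min() < 0 or present.max() >= n_roi:
            raise StructuralError("voxel label outside ROI index range")
        if len(present) != n_roi:
            empty = sorted(set(range(n_roi)) - set(present.tolist()))
            raise StructuralError(f"empty ROI(s): {[self.roi_names[i] for i in empty]}")
        for name in self.roi_names:
            lobe = self.roi_to_lobe.get(name)
            if lobe not in LOBES:
                raise ValidationError(
                    f"ROI {name!r} mapped to unknown lobe {lobe!r}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def roi_voxels(self, roi: int) -> np.ndarray:
        return np.flatnonzero(self.voxel_labels == roi)

    def lobe_index(self) -> np.ndarray:
        """Per-ROI lobe index into LOBES."""
        return np.array([LOBES.index(self.roi_to_lobe[n]) for n in self.roi_names])


@dataclass
class ROITimeSeries:
    """Representative series per ROI: epochs x n_rois x samples."""

    data: np.ndarray
    method: str
    roi_names: list[str]
    srate: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise StructuralError("ROI series must be (epochs, rois, samples)")
        if self.data.shape[1] != len(self.roi_names):
            raise StructuralError("ROI count does not match names")

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# centroid voxels and series extraction
# ---------------------------------------------------------------------------

def roi_centroid_voxels(atlas: Atlas, grid: SourceGrid, roi: int,
                        k: int = 1) -> np.ndarray:
    """Indices of the k ROI-member voxels nearest the ROI's centroid.

    Distance ties and the ordering among equidistant voxels are broken by
    lowest voxel index.
    """
    members = atlas.roi_voxels(roi)
    if members.size == 0:
        raise ValidationError(f"ROI index {roi} has no voxels")
    if k > members.size:
        warnings.warn(f"k={k} exceeds ROI size {members.size}; clipped")
        k = members.size
    pos = grid.inside_positions[members]
    centroid = pos.mean(axis=0)
    d = np.linalg.norm(pos - centroid, axis=1)
    order = np.lexsort((members, d))      # distance first, then index
    return members[order[:k]]


def extract_roi_series(src: np.ndarray, atlas: Atlas, grid: SourceGrid,
                       method: str = "centroid", k: int = 1,
                       srate: float | None = None) -> ROITimeSeries:
    """One representative series per ROI from oriented source epochs.

    ``src`` is (epochs, n_voxels, samples), real or complex (analytic).
    """
    src = np.asarray(src)
    if src.ndim != 3:
        raise StructuralError("source series must be (epochs, voxels, samples)")
    if src.shape[1] != atlas.voxel_labels.shape[0]:
        raise StructuralError(
            f"{src.shape[1]} source series for {atlas.voxel_labels.shape[0]} "
            "atlas voxels")
    E, _, S = src.shape
    out = np.empty((E, atlas.n_rois, S), dtype=src.dtype)
    if method == "centroid":
        for roi in range(atlas.n_rois):
            sel = roi_centroid_voxels(atlas, grid, roi, k)
            out[:, roi] = src[:, sel].mean(axis=1)
    elif method == "mean":
        for roi in range(atlas.n_rois):
            out[:, roi] = src[:, atlas.roi_voxels(roi)].mean(axis=1)
    elif method == "pca":
        for roi in range(atlas.n_rois):
            sel = atlas.roi_voxels(roi)
            X = np.transpose(src[:, sel], (1, 0, 2)).reshape(len(sel), E * S)
            Xr = X.real if np.iscomplexobj(X) else X
            Xr = Xr - Xr.mean(axis=1, keepdims=True)
            cov = Xr @ Xr.T
            w, V = np.linalg.eigh(cov)
            u = V[:, -1]
            i = np.abs(u).argmax()
            if u[i] < 0:
                u = -u
            out[:, roi] = np.einsum("v,evs->es", u, src[:, sel])
    else:
        raise ValidationError(f"unknown ROI method {method!r}")
    logger.info("extracted %d ROI series (%s, k=%d)", atlas.n_rois, method, k)
    return ROITimeSeries(data=out, method=method,
                         roi_names=list(atlas.roi_names), srate=srate)


# ---------------------------------------------------------------------------
# atlas I/O
# ---------------------------------------------------------------------------

def write_atlas(atlas: Atlas, grid: SourceGrid, path) -> None:
    """TSV: voxel index, x, y, z, ROI name, lobe (one row per inside voxel)."""
    pos = grid.inside_positions
    with open(path, "w") as fh:
        fh.write("# columns: voxel x y z roi lobe\n")
        for i, lab in enumerate(atlas.voxel_labels):
            name = atlas.roi_names[lab]
            fh.write(f"{i}\t{pos[i, 0]:.8g}\t{pos[i, 1]:.8g}\t{pos[i, 2]:.8g}"
                     f"\t{name}\t{atlas.roi_to_lobe[name]}\n")


def read_atlas(path, grid: SourceGrid) -> Atlas:
    """Read a voxel->ROI label table and align it to the grid.

    Rows carry either a voxel index into the grid's inside voxels or
    coordinates matched to the nearest inside voxel (within half a lattice
    step).  Every inside voxel must be labeled exactly once; lobes must be
    one of the four major lobes.
    """
    pos = grid.inside_positions
    n_vox = pos.shape[0]
    labels = np.full(n_vox, -1, dtype=int)
    roi_names: list[str] = []
    roi_to_lobe: dict[str, str] = {}
    tol = grid.resolution / 2000.0         # half a step, meters
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 6:
                _, xs, ys, zs, roi, lobe = parts
                p = np.array([float(xs), float(ys), float(zs)])
                d = np.linalg.norm(pos - p, axis=1)
                j = int(d.argmin())
                if d[j] > tol:
                    raise StructuralError(
                        f"{path}:{lineno}: coordinates match no grid voxel "
                        f"within {tol * 1000:g} mm")
            elif len(parts) == 3:
                idx, roi, lobe = parts
                j = int(idx)
                if not (0 <= j < n_vox):
                    raise StructuralError(f"{path}:{lineno}: voxel index {j} "
                                          f"out of range (0..{n_vox - 1})")
            else:
                raise StructuralError(
                    f"{path}:{lineno}: expected 3 or 6 tab-separated fields")
            if lobe not in LOBES:
                raise ValidationError(
                    f"{path}:{lineno}: unknown lobe {lobe!r} (4-lobe scheme)")
            if roi not in roi_to_lobe:
                roi_names.append(roi)
                roi_to_lobe[roi] = lobe
            elif roi_to_lobe[roi] != lobe:
                raise StructuralError(
                    f"{path}:{lineno}: ROI {roi!r} mapped to two lobes")
            labels[j] = roi_names.index(roi)
    if np.any(labels < 0):
        raise StructuralError(
            f"{int((labels < 0).sum())} inside voxel(s) left unlabeled")
    return Atlas(voxel_labels=labels, roi_names=roi_names,
                 roi_to_lobe=roi_to_lobe)
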