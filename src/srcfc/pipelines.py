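"""End-to-end pipeline composition over synthetic inputs.

``run_pps_pipeline`` exercises the full phase-synchrony chain: simulated
coupled sources -> concentric-shell forward projection -> broadband filter,
epoching, artifact rejection, inclusion gate -> eLORETA (or wMNE) inverse ->
SVD orientation -> ROI parcellation -> trial-resampled wPLI -> Fisher z ->
proportional threshold -> lobe means.

``run_hub_pipeline`` exercises the vertex-level amplitude-coupling chain:
per-subject analytic vertex series with a planted envelope topology ->
all-pairs orthogonalized AAC -> median/MAD normalization -> per-pair group
t -> topology vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import connectivity, forward, hub_atlas, inverse, parcellate, preprocess
from .core_io import RunConfig
from .simulate import (Coupling, SimulationSpec, make_sensor_array,
                       make_toy_atlas, project_to_sensors,
                       simulate_envelope_network, simulate_sources)

logger = logging.getLogger("srcfc")


@dataclass
class PPSResult:
    adjacency: connectivity.AdjacencyMatrix       # resampled wPLI, Fisher z
    thresholded: connectivity.AdjacencyMatrix
    lobe_matrix: np.ndarray
    atlas: parcellate.Atlas
    grid: forward.SourceGrid
    truth: SimulationSpec


@dataclass
class HubResult:
    topology: hub_atlas.TopologyVector
    t_matrix: np.ndarray
    matrices: hub_atlas.SubjectMatrixSet
    loadings: np.ndarray


def run_pps_pipeline(cfg: RunConfig | None = None, seed: int = 0,
                     n_channels: int = 124, n_active: int = 8,
                     duration_s: float = 80.0, source_noise_sd: float = 0.5,
                     sensor_noise_sd: float = 0.5,
                     source_amplitude_nAm: float = 10.0,
                     band: preprocess.BandSpec | None = None,
                     method: str = "eloreta") -> PPSResult:
    """Full synthetic phase-synchrony pipeline; returns the 48x48 outputs.

    ``n_active`` coupled sources (consecutive pairs share a 90-degree phase
    lag at strength 0.8) are placed at spread-out grid voxels and projected
    through the age-specific head model with RMS dipole moments of
    ``source_amplitude_nAm`` (10 nA*m gives scalp signals of a few tens of
    uV, the physiological regime the +/-100 uV artifact rule expects).
    """
    cfg = cfg or RunConfig()
    band = band or next(b for b in cfg.bands if b.name == "alpha")
    hm = forward.head_model_preset(cfg.age_group)
    grid = forward.build_source_grid(hm, cfg.grid_resolution)
    sensors = make_sensor_array(n_channels)
    lf = forward.compute_leadfield(hm, grid, sensors)
    atlas = make_toy_atlas(grid, n_rois=48, n_lobes=4, seed=seed)

    couplings = [Coupling(i=2 * k, j=2 * k + 1, kind="phase_lag",
                          strength=0.8, lag_radians=np.pi / 2)
                 for k in range(n_active // 2)]
    spec = SimulationSpec(n_sources=n_active, srate=500.0,
                          duration=duration_s, band=band,
                          couplings=couplings, noise_sd=source_noise_sd,
                          seed=seed)
    sources = simulate_sources(spec)
    sources.data = sources.data * (source_amplitude_nAm * 1e-9)
    idx = np.linspace(0, grid.n_inside - 1, n_active).astype(int)
    rng = np.random.default_rng([seed, 21])
    ori = rng.standard_normal((n_active, 3))
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)
    rec = project_to_sensors(sources, lf, ori, sensor_noise_sd, seed,
                             source_indices=idx)

    rec = preprocess.broadband_filter(rec)
    ep = preprocess.epoch(rec, 2.0)
    ep = preprocess.reject_artifacts(ep)
    ep = preprocess.inclusion_gate(ep, min_epochs=cfg.n_resample_trials)

    if method == "eloreta":
        filt = inverse.eloreta_filter(lf)
    else:
        filt = inverse.wmne_filter(lf)
    src = inverse.apply_inverse(filt, ep)
    oriented = inverse.orient_svd(src)
    roi = parcellate.extract_roi_series(oriented, atlas, grid,
                                        method="centroid", k=1,
                                        srate=rec.srate)
    adj = connectivity.resampled_wpli(roi, band,
                                      n_sel=cfg.n_resample_trials,
                                      n_rep=cfg.n_repeats, seed=seed)
    adj_z = connectivity.fisher_z(adj)
    thr = connectivity.threshold_sparsity(adj_z, cfg.sparsity)
    lobes = connectivity.lobe_average(thr, atlas)
    return PPSResult(adjacency=adj_z, thresholded=thr, lobe_matrix=lobes,
                     atlas=atlas, grid=grid, truth=spec)


def hub_loadings(n_vertices: int, structure_seed: int = 0) -> np.ndarray:
    """A fixed hub structure: smoothly varying loadings with a few strong hubs."""
    rng = np.random.default_rng([structure_seed, 31])
    base = rng.beta(2.0, 5.0, size=n_vertices) * 0.7
    hubs = rng.choice(n_vertices, size=max(2, n_vertices // 50), replace=False)
    base[hubs] = 0.9
    return base


def run_hub_pipeline(n_vertices: int = 5000, n_subjects: int = 2,
                     seed: int = 0, loadings: np.ndarray | None = None,
                     n_samples: int = 7500, srate: float = 125.0,
                     structure_seed: int = 0, group: str = "",
                     single_precision: bool = True) -> HubResult:
    """Vertex-level AAC hub chain for one group of subjects.

    Subjects share the planted loading structure (``structure_seed``) but
    have independent noise realizations (offset by ``seed``).  Defaults give
    60 s of 125 Hz analytic data per subject — the envelope processes
    (~1 Hz) are generously oversampled at this rate, and 60 s matches the
    preprocessing chain's minimum clean-data requirement.
    """
    if loadings is None:
        loadings = hub_loadings(n_vertices, structure_seed)
    series = [simulate_envelope_network(n_vertices, loadings,
                                        n_samples=n_samples, srate=srate,
                                        seed=seed * 1000 + s)
              for s in range(n_subjects)]
    mset = hub_atlas.vertex_aac_matrices(series, orthogonalized=True,
                                         single_precision=single_precision)
    normed = np.stack([hub_atlas.robust_normalize(m) for m in mset.matrices])
    mset_n = hub_atlas.SubjectMatrixSet(matrices=normed,
                                        subject_ids=mset.subject_ids)
    t = hub_atlas.group_t_matrix(mset_n)
    tv = hub_atlas.topology_vector(t, group=group)
    return HubResult(topology=tv, t_matrix=t, matrices=mset_n,
                     loadings=loadings)
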