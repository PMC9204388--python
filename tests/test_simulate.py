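import numpy as np
import pytest
from scipy.signal import hilbert

from srcfc.connectivity import aac_pair, fourier_observations, phase_fc
from srcfc.exceptions import ValidationError
from srcfc.parcellate import ROITimeSeries
from srcfc.preprocess import BandSpec
from srcfc.simulate import (Coupling, SimulationSpec, make_sensor_array,
                            make_toy_atlas, project_to_sensors,
                            simulate_envelope_network, simulate_sources)

BAND = BandSpec("alpha", 5, 11)


def _wpli_matrix(data, srate=500.0, n_epochs=30):
    spe = data.shape[1] // n_epochs
    ep = np.stack(np.split(data[:, : n_epochs * spe], n_epochs, axis=-1))
    roi = ROITimeSeries(data=ep, method="mean",
                        roi_names=[f"s{i}" for i in range(data.shape[0])],
                        srate=srate)
    obs = fourier_observations(roi, srate, BAND)
    return phase_fc(obs, "wpli").values


class TestSimulateSources:
    def test_deterministic_given_seed(self):
        spec = SimulationSpec(n_sources=3, duration=5, seed=42)
        a = simulate_sources(spec).data
        b = simulate_sources(spec).data
        np.testing.assert_array_equal(a, b)

    def test_full_strength_phase_lag_locks_phase(self):
        spec = SimulationSpec(
            n_sources=2, duration=30, noise_sd=0.0, seed=1,
            couplings=[Coupling(0, 1, "phase_lag", 1.0, np.pi / 2)])
        st = simulate_sources(spec)
        z = hilbert(st.data, axis=-1)
        dphi = np.angle(z[0] * np.conj(z[1]))
        circ_var = 1 - abs(np.mean(np.exp(1j * dphi)))
        assert circ_var < 0.05
        assert abs(np.angle(np.mean(np.exp(1j * dphi))) - np.pi / 2) < 0.1

    def test_uncoupled_sources_match_estimator_null(self, rng):
        """Uncoupled pairs sit at the plain-wPLI finite-sample null level.

        The null mean of |sum Im Z| / sum |Im Z| over K independent
        observations is computed by Monte Carlo (iid complex Gaussian
        observations) and the simulator's uncoupled pairs must match it.
        """
        spec = SimulationSpec(n_sources=8, duration=60, seed=2, noise_sd=0.5)
        st = simulate_sources(spec)
        w = _wpli_matrix(st.data, n_epochs=30)
        iu = np.triu_indices(8, 1)
        measured = np.mean(np.abs(w[iu]))
        K = 30
        draws = []
        for _ in range(2000):
            z = ((rng.standard_normal(K) + 1j * rng.standard_normal(K))
                 * (rng.standard_normal(K)
                    - 1j * rng.standard_normal(K)))
            draws.append(abs(z.imag.sum()) / np.abs(z.imag).sum())
        null_mean = np.mean(draws)
        assert abs(measured - null_mean) < 0.05
        # and the null shrinks as observations grow
        w60 = _wpli_matrix(st.data, n_epochs=60)
        assert np.mean(np.abs(w60[iu])) < measured

    def test_planted_phase_lag_is_argmax_wpli_edge(self):
        spec = SimulationSpec(
            n_sources=6, duration=60, noise_sd=0.5, seed=3,
            couplings=[Coupling(0, 1, "phase_lag", 1.0, np.pi / 2)])
        w = _wpli_matrix(simulate_sources(spec).data)
        assert w[0, 1] > 0.8
        assert np.unravel_index(w.argmax(), w.shape) in ((0, 1), (1, 0))

    def test_planted_envelope_correlation_recovered(self):
        spec = SimulationSpec(
            n_sources=4, duration=60, noise_sd=0.05, seed=5,
            couplings=[Coupling(0, 1, "envelope_corr", 0.8)])
        z = hilbert(simulate_sources(spec).data, axis=-1)
        plain = aac_pair(z[0], z[1], orthogonalized=False)
        assert abs(plain - 0.8) < 0.1
        orth = aac_pair(z[0], z[1], orthogonalized=True)
        null = aac_pair(z[2], z[3], orthogonalized=True)
        assert orth > 0 and orth > null + 0.1

    def test_zero_lag_mix_raises_coherence_not_wpli(self):
        spec = SimulationSpec(
            n_sources=4, duration=60, noise_sd=0.5, seed=7,
            couplings=[Coupling(0, 1, "zero_lag_mix", 1.0),
                       Coupling(1, 0, "zero_lag_mix", 1.0)])
        data = simulate_sources(spec).data
        spe = 1000
        ep = np.stack(np.split(data[:, :30000], 30, axis=-1))
        roi = ROITimeSeries(data=ep, method="mean",
                            roi_names=list("abcd"), srate=500)
        obs = fourier_observations(roi, 500, BAND)
        coh = phase_fc(obs, "coh").values
        w = phase_fc(obs, "wpli").values
        assert coh[0, 1] > 0.8
        assert w[0, 1] < 0.3  # comparable to the uncoupled level

    def test_coupling_index_out_of_range(self):
        with pytest.raises(ValidationError):
            SimulationSpec(n_sources=2, couplings=[
                Coupling(0, 5, "phase_lag", 0.5)])


class TestProjectToSensors:
    def test_single_source_is_rank_one(self, leadfield_coarse):
        spec = SimulationSpec(n_sources=1, duration=2, noise_sd=0.0, seed=0)
        st = simulate_sources(spec)
        rec = project_to_sensors(st, leadfield_coarse,
                                 np.array([[0.0, 0.0, 1.0]]), 0.0, 0)
        s = np.linalg.svd(rec.data, compute_uv=False)
        assert s[1] < 1e-9 * s[0]

    def test_linearity_in_source_amplitude(self, leadfield_coarse):
        spec = SimulationSpec(n_sources=1, duration=2, noise_sd=0.0, seed=0)
        st = simulate_sources(spec)
        ori = np.array([[0.0, 0.0, 1.0]])
        rec1 = project_to_sensors(st, leadfield_coarse, ori, 0.0, 0)
        st.data = 2.0 * st.data
        rec2 = project_to_sensors(st, leadfield_coarse, ori, 0.0, 0)
        np.testing.assert_allclose(rec2.data, 2 * rec1.data, atol=1e-9)

    def test_average_referenced_output(self, leadfield_coarse):
        spec = SimulationSpec(n_sources=2, duration=2, noise_sd=0.3, seed=1)
        st = simulate_sources(spec)
        ori = np.tile([0.0, 0.0, 1.0], (2, 1))
        rec = project_to_sensors(st, leadfield_coarse, ori, 1.0, 3)
        tol = 1e-9 * np.abs(rec.data).max() * rec.n_channels
        np.testing.assert_allclose(rec.data.sum(axis=0), 0.0, atol=tol)

    def test_non_unit_orientation_rejected(self, leadfield_coarse):
        spec = SimulationSpec(n_sources=1, duration=1, seed=0)
        st = simulate_sources(spec)
        with pytest.raises(ValidationError):
            project_to_sensors(st, leadfield_coarse,
                               np.array([[0.0, 0.0, 2.0]]), 0.0, 0)


class TestToyAtlas:
    def test_48_nonempty_rois_in_8cm_sphere(self):
        from srcfc.forward import HeadModel, build_source_grid

        hm = HeadModel(shell_radii=(0.08, 0.085, 0.09),
                       conductivities=(0.33, 0.066, 0.33))
        grid = build_source_grid(hm, 6.0)
        atlas = make_toy_atlas(grid, n_rois=48, n_lobes=4, seed=0)
        sizes = [len(atlas.roi_voxels(r)) for r in range(48)]
        assert len(sizes) == 48 and all(s > 0 for s in sizes)
        assert sum(sizes) == grid.n_inside          # partition property

    def test_each_roi_has_exactly_one_lobe(self, coarse_grid):
        atlas = make_toy_atlas(coarse_grid, n_rois=12, n_lobes=4, seed=0)
        assert set(atlas.roi_to_lobe) == set(atlas.roi_names)
        from srcfc.parcellate import LOBES

        assert set(atlas.roi_to_lobe.values()) <= set(LOBES)

    def test_too_many_rois_rejected(self, coarse_grid):
        with pytest.raises(ValidationError):
            make_toy_atlas(coarse_grid, n_rois=coarse_grid.n_inside + 1)


class TestSensorArray:
    def test_124_unique_labels_on_scalp(self):
        sens = make_sensor_array(124, radius=0.08)
        assert len(set(sens.labels)) == 124
        np.testing.assert_allclose(np.linalg.norm(sens.positions, axis=1),
                                   0.08, rtol=1e-9)


class TestEnvelopeNetwork:
    def test_loading_product_sets_envelope_correlation(self):
        w = np.array([0.9, 0.9, 0.1, 0.1])
        z = simulate_envelope_network(4, w, n_samples=20000, srate=125.0,
                                      noise_sd=0.0, seed=9)
        lp = np.log(np.abs(z) ** 2)
        r_strong = np.corrcoef(lp[0], lp[1])[0, 1]
        r_weak = np.corrcoef(lp[2], lp[3])[0, 1]
        assert abs(r_strong - 0.81) < 0.1
        assert abs(r_weak - 0.01) < 0.1

    def test_deterministic(self):
        w = np.full(3, 0.5)
        a = simulate_envelope_network(3, w, n_samples=500, seed=4)
        b = simulate_envelope_network(3, w, n_samples=500, seed=4)
        np.testing.assert_array_equal(a, b)
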