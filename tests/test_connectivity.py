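import numpy as np
import pytest

from srcfc.connectivity import (AdjacencyMatrix, SpectralObservations,
                                aac_matrix, aac_pair, fisher_z,
                                fourier_observations, lobe_average,
                                orthogonalize, phase_fc, resampled_wpli,
                                threshold_sparsity)
from srcfc.exceptions import InsufficientDataError, ResolutionError
from srcfc.parcellate import Atlas, ROITimeSeries
from srcfc.preprocess import BandSpec

ALPHA12 = BandSpec("alpha", 5, 10)


def _roi(data, srate=500.0):
    return ROITimeSeries(data=data, method="mean",
                         roi_names=[f"r{i}" for i in range(data.shape[1])],
                         srate=srate)


# ---------------------------------------------------------------------------
# naive scalar reference implementations (independent oracles)
# ---------------------------------------------------------------------------

def naive_phase_fc(coeffs, method):
    K, V, F = coeffs.shape
    out = np.zeros((V, V))
    for i in range(V):
        for j in range(V):
            if i == j:
                continue
            vals = []
            for f in range(F):
                Z = np.array([coeffs[k, i, f] * np.conj(coeffs[k, j, f])
                              for k in range(K)])
                if method == "wpli":
                    den = np.sum(np.abs(Z.imag))
                    vals.append(abs(np.sum(Z.imag)) / den if den > 0 else 0.0)
                elif method == "icoh":
                    den = np.sqrt(np.sum(np.abs(coeffs[:, i, f]) ** 2)
                                  * np.sum(np.abs(coeffs[:, j, f]) ** 2))
                    vals.append(abs(np.sum(Z).imag) / den)
                elif method == "coh":
                    den = np.sqrt(np.sum(np.abs(coeffs[:, i, f]) ** 2)
                                  * np.sum(np.abs(coeffs[:, j, f]) ** 2))
                    vals.append(abs(np.sum(Z)) / den)
                elif method == "plv":
                    d = np.exp(1j * (np.angle(coeffs[:, i, f])
                                     - np.angle(coeffs[:, j, f])))
                    vals.append(abs(np.mean(d)))
            out[i, j] = np.mean(vals)
    return out


def naive_aac_pair(x, y, orthogonalized):
    eps = 1e-20
    if not orthogonalized:
        return np.corrcoef(np.log(np.abs(x) ** 2 + eps),
                           np.log(np.abs(y) ** 2 + eps))[0, 1]
    yox = (y * np.conj(x)).imag / np.abs(x)
    xoy = (x * np.conj(y)).imag / np.abs(y)
    c1 = np.corrcoef(np.log(yox ** 2 + eps), np.log(np.abs(x) ** 2 + eps))[0, 1]
    c2 = np.corrcoef(np.log(xoy ** 2 + eps), np.log(np.abs(y) ** 2 + eps))[0, 1]
    return 0.5 * (c1 + c2)


# ---------------------------------------------------------------------------
# spectral observations
# ---------------------------------------------------------------------------

class TestFourierObservations:
    def test_bin_arithmetic_2s_epochs(self, rng):
        # 2-s epochs at 500 Hz -> 0.5 Hz bins; 5-10 Hz holds 11 bins
        data = rng.standard_normal((3, 2, 1000))
        obs = fourier_observations(_roi(data), 500, ALPHA12)
        assert obs.freqs.shape == (11,)
        assert obs.freqs[0] == 5.0 and obs.freqs[-1] == 10.0

    def test_pure_sinusoid_peak_matches_windowed_closed_form(self):
        # Hann-windowed DFT of a bin-centered unit sine: |X| = N/4
        n, srate, f0 = 1000, 500.0, 8.0
        t = np.arange(n) / srate
        data = np.sin(2 * np.pi * f0 * t)[None, None, :].repeat(2, axis=0)
        obs = fourier_observations(_roi(data), srate, ALPHA12)
        peak = np.abs(obs.coeffs[0, 0, obs.freqs == f0])[0]
        assert abs(peak - n / 4) < 0.05 * (n / 4)

    def test_constant_signal_vanishes(self):
        data = np.full((2, 1, 1000), 3.0)
        obs = fourier_observations(_roi(data), 500, ALPHA12)
        assert np.abs(obs.coeffs).max() < 1e-9

    def test_band_with_no_bin_rejected(self, rng):
        data = rng.standard_normal((2, 1, 100))  # 5 Hz bins at 500 Hz
        with pytest.raises(ResolutionError):
            fourier_observations(_roi(data), 500, BandSpec("x", 6, 9))


# ---------------------------------------------------------------------------
# phase metrics
# ---------------------------------------------------------------------------

class TestPhaseFC:
    def test_wpli_hand_computed_value(self):
        # Im parts of the cross-spectrum over observations: {1, -2, 0.5}
        X = np.ones(3, dtype=complex)
        Y = np.array([0 - 1j * -1, 0 - 1j * 2, 0 - 1j * -0.5])
        # Z = X conj(Y): Im Z = {1, -2, 0.5}
        coeffs = np.stack([X, Y], axis=1)[:, :, None]
        obs = SpectralObservations(coeffs=coeffs, freqs=np.array([8.0]))
        v = phase_fc(obs, "wpli").values[0, 1]
        assert abs(v - 1.0 / 7.0) < 1e-12

    def test_perfect_quadrature_lag(self):
        X = np.ones(5, dtype=complex)
        Y = np.full(5, -1j)
        coeffs = np.stack([X, Y], axis=1)[:, :, None]
        obs = SpectralObservations(coeffs=coeffs, freqs=np.array([8.0]))
        for method in ("wpli", "plv", "coh"):
            assert abs(phase_fc(obs, method).values[0, 1] - 1.0) < 1e-12

    def test_identical_signals_zero_lag(self, rng):
        X = rng.standard_normal(6) + 1j * rng.standard_normal(6)
        coeffs = np.stack([X, X], axis=1)[:, :, None]
        obs = SpectralObservations(coeffs=coeffs, freqs=np.array([8.0]))
        assert phase_fc(obs, "wpli").values[0, 1] == 0.0   # 0/0 convention
        assert abs(phase_fc(obs, "icoh").values[0, 1]) < 1e-12
        assert abs(phase_fc(obs, "coh").values[0, 1] - 1.0) < 1e-12

    @pytest.mark.parametrize("method", ["wpli", "icoh", "plv", "coh"])
    def test_matches_naive_scalar_oracle(self, method, rng):
        coeffs = (rng.standard_normal((6, 5, 4))
                  + 1j * rng.standard_normal((6, 5, 4)))
        obs = SpectralObservations(coeffs=coeffs,
                                   freqs=np.array([5.0, 6, 7, 8]))
        got = phase_fc(obs, method).values
        want = naive_phase_fc(coeffs, method)
        np.fill_diagonal(want, 0)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_global_amplitude_rescaling_invariance(self, rng):
        coeffs = (rng.standard_normal((6, 3, 4))
                  + 1j * rng.standard_normal((6, 3, 4)))
        freqs = np.array([5.0, 6, 7, 8])
        scaled = coeffs.copy()
        scaled[:, 0] *= 13.0
        for method in ("wpli", "plv", "coh", "icoh"):
            a = phase_fc(SpectralObservations(coeffs=coeffs, freqs=freqs),
                         method).values
            b = phase_fc(SpectralObservations(coeffs=scaled, freqs=freqs),
                         method).values
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_plv_per_observation_amplitude_invariance(self, rng):
        coeffs = (rng.standard_normal((6, 3, 2))
                  + 1j * rng.standard_normal((6, 3, 2)))
        freqs = np.array([5.0, 6])
        scaled = coeffs * rng.uniform(0.1, 10, size=(6, 3, 1))
        a = phase_fc(SpectralObservations(coeffs=coeffs, freqs=freqs), "plv")
        b = phase_fc(SpectralObservations(coeffs=scaled, freqs=freqs), "plv")
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestResampledWPLI:
    def test_deterministic_given_seed(self, rng):
        data = rng.standard_normal((40, 4, 500))
        roi = _roi(data)
        a = resampled_wpli(roi, ALPHA12, n_sel=10, n_rep=5, seed=3)
        b = resampled_wpli(roi, ALPHA12, n_sel=10, n_rep=5, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_exactly_n_sel_epochs_is_bit_exact_single_pass(self, rng):
        data = rng.standard_normal((30, 4, 500))
        roi = _roi(data)
        res = resampled_wpli(roi, ALPHA12, n_sel=30, n_rep=50, seed=0)
        obs = fourier_observations(roi, 500, ALPHA12)
        single = phase_fc(obs, "wpli")
        assert np.array_equal(res.values, single.values)

    def test_too_few_epochs_rejected(self, rng):
        roi = _roi(rng.standard_normal((10, 2, 500)))
        with pytest.raises(InsufficientDataError):
            resampled_wpli(roi, ALPHA12, n_sel=30)


# ---------------------------------------------------------------------------
# orthogonalization and AAC
# ---------------------------------------------------------------------------

class TestOrthogonalize:
    def test_collinear_gives_zero(self, rng):
        x = rng.standard_normal(200) + 1j * rng.standard_normal(200)
        np.testing.assert_allclose(orthogonalize(x, 2.5 * x), 0.0, atol=1e-12)

    def test_quadrature_passes_envelope(self, rng):
        x = rng.standard_normal(200) + 1j * rng.standard_normal(200)
        np.testing.assert_allclose(orthogonalize(x, 1j * x), np.abs(x),
                                   atol=1e-12)

    def test_decomposition_identity(self, rng):
        x = rng.standard_normal(300) + 1j * rng.standard_normal(300)
        y = rng.standard_normal(300) + 1j * rng.standard_normal(300)
        parallel = (y * np.conj(x)).real / np.abs(x)
        recon = parallel + 1j * orthogonalize(x, y)
        np.testing.assert_allclose(recon, y * np.conj(x) / np.abs(x),
                                   atol=1e-12)

    def test_zero_magnitude_sample_warned(self):
        x = np.ones(5, dtype=complex)
        x[2] = 0
        y = 1j * np.ones(5)
        with pytest.warns(UserWarning):
            out = orthogonalize(x, y)
        assert out[2] == 0


class TestAACPair:
    def test_collinear_orthogonalized_is_zero(self, rng):
        x = rng.standard_normal(500) + 1j * rng.standard_normal(500)
        assert aac_pair(x, 3.0 * x, orthogonalized=True) == 0.0

    def test_collinear_plain_is_one(self, rng):
        x = rng.standard_normal(500) + 1j * rng.standard_normal(500)
        assert abs(aac_pair(x, 3.0 * x, orthogonalized=False) - 1.0) < 1e-12

    def test_matches_naive_oracle(self, rng):
        x = rng.standard_normal(400) + 1j * rng.standard_normal(400)
        y = rng.standard_normal(400) + 1j * rng.standard_normal(400)
        for orth in (True, False):
            got = aac_pair(x, y, orthogonalized=orth)
            assert abs(got - naive_aac_pair(x, y, orth)) < 1e-12

    def test_too_short_rejected(self, rng):
        z = rng.standard_normal(50) + 1j * rng.standard_normal(50)
        with pytest.raises(InsufficientDataError):
            aac_pair(z, z)


class TestAACMatrix:
    def test_identical_signals_all_zero(self, rng):
        x = rng.standard_normal(300) + 1j * rng.standard_normal(300)
        m = aac_matrix(np.stack([x, x, x]), orthogonalized=True)
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_symmetry_exact(self, rng):
        data = (rng.standard_normal((6, 300))
                + 1j * rng.standard_normal((6, 300)))
        m = aac_matrix(data, orthogonalized=True)
        np.testing.assert_array_equal(m.values, m.values.T)

    @pytest.mark.parametrize("orth", [True, False])
    def test_matches_pairwise_scalar_loop(self, orth, rng):
        data = (rng.standard_normal((5, 300))
                + 1j * rng.standard_normal((5, 300)))
        m = aac_matrix(data, orthogonalized=orth)
        for i in range(5):
            for j in range(i + 1, 5):
                want = aac_pair(data[i], data[j], orthogonalized=orth)
                assert abs(m.values[i, j] - want) < 1e-12


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def _adj(values, labels=None):
    n = values.shape[0]
    return AdjacencyMatrix(values=values, metric="wpli",
                           node_labels=labels or [f"r{i}" for i in range(n)])


class TestFisherZ:
    def test_reference_values(self):
        v = np.array([[0, 0, 0.5], [0, 0, 1.0], [0.5, 1.0, 0.0]])
        z = fisher_z(_adj(0.5 * (v + v.T))).values
        assert z[0, 1] == 0.0
        assert abs(z[0, 2] - 0.5493) < 1e-4
        assert abs(z[1, 2] - np.arctanh(0.9999)) < 1e-12


class TestSparsityThreshold:
    def test_48_nodes_keep_half_is_564_edges(self, rng):
        v = rng.standard_normal((48, 48))
        v = 0.5 * (v + v.T)
        out = threshold_sparsity(_adj(v), 0.5)
        iu = np.triu_indices(48, 1)
        assert int(np.count_nonzero(out.values[iu])) == 564

    def test_keep_all_is_identity(self, rng):
        v = rng.standard_normal((10, 10))
        v = 0.5 * (v + v.T)
        m = _adj(v)
        out = threshold_sparsity(m, 1.0)
        np.testing.assert_array_equal(out.values, m.values)

    def test_all_equal_ties_broken_deterministically(self):
        v = np.ones((48, 48))
        out1 = threshold_sparsity(_adj(v), 0.5)
        out2 = threshold_sparsity(_adj(v.copy()), 0.5)
        iu = np.triu_indices(48, 1)
        assert int(np.count_nonzero(out1.values[iu])) == 564
        np.testing.assert_array_equal(out1.values, out2.values)

    def test_kept_edges_are_the_largest(self, rng):
        v = rng.standard_normal((12, 12))
        v = 0.5 * (v + v.T)
        out = threshold_sparsity(_adj(v), 0.5)
        iu, ju = np.triu_indices(12, 1)
        kept = out.values[iu, ju] != 0
        assert kept.sum() == round(0.5 * len(iu))
        assert v[iu, ju][kept].min() >= np.sort(v[iu, ju])[::-1][kept.sum() - 1]


class TestLobeAverage:
    def _atlas48(self):
        names = [f"r{i}" for i in range(48)]
        lobes = ["frontal", "temporal", "parietal", "occipital"]
        return Atlas(voxel_labels=np.arange(48), roi_names=names,
                     roi_to_lobe={n: lobes[i % 4] for i, n in enumerate(names)})

    def test_constant_matrix(self):
        atlas = self._atlas48()
        m = _adj(np.full((48, 48), 0.3), labels=list(atlas.roi_names))
        out = lobe_average(m, atlas)
        np.testing.assert_allclose(out, 0.3, atol=1e-12)

    def test_block_structure(self):
        atlas = self._atlas48()
        lobe_idx = atlas.lobe_index()
        v = np.zeros((48, 48))
        ff = np.flatnonzero(lobe_idx == 0)
        for i in ff:
            for j in ff:
                if i != j:
                    v[i, j] = 1.0
        out = lobe_average(_adj(v, labels=list(atlas.roi_names)), atlas)
        assert out[0, 0] == 1.0
        assert np.all(out[np.triu_indices(4, 1)] == 0)

    def test_matches_double_loop_oracle(self, rng):
        atlas = self._atlas48()
        lobe_idx = atlas.lobe_index()
        v = rng.standard_normal((48, 48))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0)
        out = lobe_average(_adj(v, labels=list(atlas.roi_names)), atlas)
        for a in range(4):
            for b in range(4):
                vals = [v[i, j] for i in range(48) for j in range(48)
                        if lobe_idx[i] == a and lobe_idx[j] == b and i != j]
                assert abs(out[a, b] - np.mean(vals)) < 1e-12
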