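import numpy as np
import pytest

from priism.clockband import ClockVector
from priism.decompose import (
    BANDS,
    decompose_frame,
    decompose_gene,
    filter_clock,
    filter_noise,
    filter_treatment,
    partition_bands,
    redistribute_mean,
)
from priism.preprocess import FrameLayout, TimeCourse, make_frames, mean_shift
from priism.spectral import Spectrum, dft


def _cv(c_min, c_max, weights=None):
    n = c_max - c_min + 1
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    return ClockVector(c_min, c_max, w, np.zeros(n))


class TestPartitionBands:
    def test_enumerated_example(self):
        p = partition_bands(12, 2, 4)
        assert set(p.treatment_bins) == {0, 1, 11}
        assert set(p.clock_bins) == {2, 3, 4, 8, 9, 10}
        assert set(p.noise_bins) == {5, 6, 7}

    def test_cmin_one_leaves_only_dc_in_treatment(self):
        p = partition_bands(12, 1, 3)
        assert set(p.treatment_bins) == {0}

    @pytest.mark.parametrize("N,c_min,c_max", [(12, 2, 4), (13, 1, 6), (8, 1, 4),
                                               (16, 3, 8)])
    def test_exhaustive_and_disjoint(self, N, c_min, c_max):
        p = partition_bands(N, c_min, c_max)
        sets = [p.treatment_bins, p.clock_bins, p.noise_bins]
        assert sum(len(s) for s in sets) == N
        assert set().union(*sets) == set(range(N))
        for s in sets:
            assert all((N - n) % N in s for n in s)

    def test_band_outside_range_rejected(self):
        with pytest.raises(ValueError):
            partition_bands(12, 5, 7)  # c_max > N/2


class TestFilters:
    def _spectrum(self, rng, N=12):
        return dft(rng.normal(size=N) - rng.normal(size=N).mean(), 2.0)

    def test_treatment_filter_zeroes_clock_energy(self):
        N = 12
        G = np.zeros(N, dtype=complex)
        G[3], G[9] = 1 + 1j, 1 - 1j  # clock band
        p = partition_bands(N, 2, 4)
        out = filter_treatment(Spectrum(G, 2.0), p)
        np.testing.assert_array_equal(out.coefficients, 0.0)

    def test_treatment_filter_passes_treatment_energy_unchanged(self):
        N = 12
        G = np.zeros(N, dtype=complex)
        G[1], G[11] = 2 - 1j, 2 + 1j
        p = partition_bands(N, 2, 4)
        out = filter_treatment(Spectrum(G, 2.0), p)
        np.testing.assert_array_equal(out.coefficients, G)

    def test_noise_filter_nyquist_pass_and_treatment_kill(self):
        N = 12
        p = partition_bands(N, 2, 4)
        G = np.zeros(N, dtype=complex)
        G[6] = 3.0  # Nyquist bin, noise band
        np.testing.assert_array_equal(
            filter_noise(Spectrum(G, 2.0), p).coefficients, G)
        G2 = np.zeros(N, dtype=complex)
        G2[0] = 5.0
        np.testing.assert_array_equal(
            filter_noise(Spectrum(G2, 2.0), p).coefficients, 0.0)

    def test_mask_filters_match_elementwise_oracle(self, rng):
        sp = self._spectrum(rng)
        p = partition_bands(sp.N, 2, 4)
        for filt, band in ((filter_treatment, p.treatment_bins),
                           (filter_noise, p.noise_bins)):
            mask = np.zeros(sp.N)
            mask[list(band)] = 1.0
            np.testing.assert_allclose(filt(sp, p).coefficients,
                                       sp.coefficients * mask, atol=1e-12)

    def test_clock_filter_all_ones_passes_band(self, rng):
        sp = self._spectrum(rng)
        p = partition_bands(sp.N, 2, 4)
        out = filter_clock(sp, p, _cv(2, 4))
        mask = np.zeros(sp.N)
        mask[list(p.clock_bins)] = 1.0
        np.testing.assert_allclose(out.coefficients, sp.coefficients * mask,
                                   atol=1e-12)

    def test_clock_filter_all_zero_weights_kills_everything(self, rng):
        sp = self._spectrum(rng)
        p = partition_bands(sp.N, 2, 4)
        out = filter_clock(sp, p, _cv(2, 4, [0, 0, 0]))
        np.testing.assert_array_equal(out.coefficients, 0.0)

    def test_clock_filter_scales_bins_and_mirrors(self, rng):
        sp = self._spectrum(rng)
        p = partition_bands(sp.N, 2, 4)
        weights = [0.0, 0.5, 1.0]
        out = filter_clock(sp, p, _cv(2, 4, weights))
        expected = np.zeros(sp.N, dtype=complex)
        for c, w in zip((2, 3, 4), weights):
            expected[c] = w * sp.coefficients[c]
            expected[sp.N - c] = w * sp.coefficients[sp.N - c]
        np.testing.assert_allclose(out.coefficients, expected, atol=1e-12)

    def test_mismatched_band_rejected(self, rng):
        sp = self._spectrum(rng)
        p = partition_bands(sp.N, 2, 4)
        with pytest.raises(ValueError, match="does not match"):
            filter_clock(sp, p, _cv(2, 5))


class TestRedistributeMean:
    def _components(self, n):
        return {band: np.zeros(n) for band in BANDS}

    def test_offsets_sum_to_removed_mean(self, rng):
        x = rng.normal(size=12)
        s = mean_shift(TimeCourse("g", 2.0 * np.arange(12), x))
        sp = dft(s)
        p = partition_bands(12, 2, 4)
        cs = redistribute_mean(self._components(12), s.removed_mean, sp, p)
        assert sum(cs.restored_means.values()) == pytest.approx(
            s.removed_mean, abs=1e-9)
        assert sum(cs.band_power_fractions.values()) == pytest.approx(1.0)

    def test_fractions_match_hand_computed_band_powers(self):
        N, mean = 8, 2.0
        G = np.zeros(N, dtype=complex)
        G[1], G[7] = 3.0, 3.0        # treatment band (c_min=2)
        G[2], G[6] = 2.0, 2.0        # clock band [2,3]
        G[4] = 1.0                   # Nyquist -> noise
        sp = Spectrum(G, 2.0)
        p = partition_bands(N, 2, 3)
        cs = redistribute_mean(self._components(N), mean, sp, p)
        dc = (N * mean) ** 2
        tot = dc + 2 * 9 + 2 * 4 + 1
        assert cs.band_power_fractions["treatment"] == pytest.approx((dc + 18) / tot)
        assert cs.band_power_fractions["clock"] == pytest.approx(8 / tot)
        assert cs.band_power_fractions["noise"] == pytest.approx(1 / tot)
        assert cs.restored_means["treatment"] == pytest.approx(mean * (dc + 18) / tot)

    def test_flat_gene_mean_goes_to_treatment(self):
        sp = Spectrum(np.zeros(12, dtype=complex), 2.0)
        p = partition_bands(12, 2, 4)
        cs = redistribute_mean(self._components(12), 6.0, sp, p)
        assert cs.restored_means == {"treatment": 6.0, "clock": 0.0, "noise": 0.0}


class TestDecomposeGene:
    LAYOUT = FrameLayout()

    def _setup(self, samples):
        grid = 2.0 * np.arange(30)
        fs = make_frames(grid, self.LAYOUT)
        vectors = {}
        for f in fs.frames:
            n = fs.frame_indices(f).size
            # band at ~1 cycle/day for each frame
            c = int(round(n * 2.0 / 24.0))
            vectors[f.index] = _cv(c, c)
        return TimeCourse("g", grid, np.asarray(samples, dtype=float)), vectors, fs

    def test_constant_gene_is_all_treatment(self):
        tc, vectors, fs = self._setup(np.full(30, 6.0))
        cs = decompose_gene(tc, vectors, fs)
        np.testing.assert_allclose(cs.treatment, 6.0, atol=1e-9)
        np.testing.assert_allclose(cs.clock, 0.0, atol=1e-9)
        np.testing.assert_allclose(cs.noise, 0.0, atol=1e-9)

    def test_pure_24h_sinusoid_goes_to_clock(self):
        t = 2.0 * np.arange(30)
        x = 8.0 + np.sin(2 * np.pi * t / 24.0)
        tc, vectors, fs = self._setup(x)
        cs = decompose_gene(tc, vectors, fs)
        sine = x - 8.0
        clock_centered = cs.clock - cs.clock.mean()
        captured = np.var(clock_centered) / np.var(sine)
        assert captured > 0.8
        assert np.corrcoef(sine, cs.clock)[0, 1] > 0.99
        # treatment component stays near the baseline mean
        assert np.all(np.abs(cs.treatment - 8.0) < 0.6)

    def test_components_sum_to_original(self, rng):
        tc, vectors, fs = self._setup(rng.normal(8, 1.5, 30))
        cs = decompose_gene(tc, vectors, fs)
        np.testing.assert_allclose(cs.total(), tc.samples, atol=1e-6)

    def test_missing_frame_vector_rejected(self, rng):
        tc, vectors, fs = self._setup(rng.normal(size=30))
        del vectors[2]
        with pytest.raises(ValueError, match="frame 2"):
            decompose_gene(tc, vectors, fs)


class TestFrameOrthogonality:
    def test_zero_mean_components_orthogonal_with_unit_weights(self, rng):
        x = rng.normal(8, 1, 12)
        cs = decompose_frame(x, 2.0, _cv(2, 4))
        parts = [cs.treatment - cs.restored_means["treatment"],
                 cs.clock - cs.restored_means["clock"],
                 cs.noise - cs.restored_means["noise"]]
        scale = max(np.linalg.norm(p) for p in parts) ** 2
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(np.dot(parts[i], parts[j])) < 1e-6 * max(scale, 1.0)

    def test_components_are_real_arrays(self, rng):
        cs = decompose_frame(rng.normal(size=12), 2.0, _cv(2, 4, [0.3, 1.0, 0.0]))
        for band in BANDS:
            assert np.isrealobj(cs.component(band))
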