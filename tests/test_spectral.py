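"""Chemical-shift encoding model: phasors, encoding matrix, separation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wfsrecon import (EchoTimes, FieldParams, SpectralModel, SpeciesImages,
                      encoding_matrix, fat_phasor, forward_species,
                      lsq_separate, silicone_phasor)


class TestSpectralModel:
    def test_default_nine_peaks_amplitudes_sum_to_one(self, model):
        assert model.n_fat_peaks == 9
        assert abs(model.fat_amp.sum() - 1.0) < 1e-12

    def test_silicone_offset_matches_ppm_conversion(self, model):
        # -4.9 ppm at 127.7 MHz
        assert model.silicone_hz == pytest.approx(-625.73, abs=0.01)

    def test_yaml_round_trip(self, model, tmp_path):
        p = tmp_path / "model.yaml"
        model.to_yaml(p)
        m2 = SpectralModel.from_yaml(p)
        np.testing.assert_allclose(m2.fat_ppm, model.fat_ppm)
        np.testing.assert_allclose(m2.fat_amp, model.fat_amp)
        assert m2.larmor_hz == model.larmor_hz

    @pytest.mark.parametrize("bad", [
        dict(fat_ppm=np.array([1.0, np.nan]), fat_amp=np.array([0.5, 0.5])),
        dict(fat_ppm=np.array([1.0]), fat_amp=np.array([0.5, 0.5])),
        dict(larmor_hz=-1.0),
    ])
    def test_invalid_models_rejected(self, bad):
        with pytest.raises(ValueError):
            SpectralModel(**bad)


class TestEchoTimes:
    def test_symmetric_default(self, times):
        assert times.n_echoes == 7
        np.testing.assert_allclose(times.t, np.arange(-3, 4) * 1e-3)
        assert times.t[3] == 0.0

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            EchoTimes(t=np.array([0.0, 0.0, 1e-3]), delta_te=1e-3)


class TestPhasors:
    def test_unit_at_t_zero(self, model):
        assert fat_phasor(0.0, model) == pytest.approx(1.0 + 0j, abs=1e-12)
        assert silicone_phasor(0.0, model) == pytest.approx(1.0 + 0j, abs=1e-12)

    def test_silicone_full_period(self, model):
        t = 1.0 / abs(model.silicone_hz)
        assert silicone_phasor(t, model) == pytest.approx(1.0 + 0j, abs=1e-9)

    def test_single_peak_fat_hand_computed(self):
        # single peak at -3.4 ppm, 127.7 MHz -> -434.18 Hz
        m = SpectralModel(larmor_hz=127.7e6, fat_ppm=np.array([-3.4]),
                          fat_amp=np.array([1.0]))
        expected = np.exp(2j * np.pi * (-434.18) * 1e-3)
        assert fat_phasor(1e-3, m) == pytest.approx(expected, abs=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(t=st.floats(-0.05, 0.05, allow_nan=False))
    def test_fat_phasor_magnitude_bounded_by_one(self, t):
        assert abs(fat_phasor(t, SpectralModel())) <= 1.0 + 1e-12

    def test_nonfinite_time_rejected(self, model):
        with pytest.raises(ValueError):
            fat_phasor(np.nan, model)
        with pytest.raises(ValueError):
            silicone_phasor(np.inf, model)


class TestEncodingMatrix:
    def test_water_column_is_ones_without_field(self, times, model):
        A = encoding_matrix(0j, times, model)
        np.testing.assert_allclose(A[:, 0], 1.0)

    def test_pure_decay_monotone_in_water_column(self, times, model):
        A = encoding_matrix(-30.0 + 0j, times, model)
        mags = np.abs(A[:, 0])
        assert np.all(np.diff(mags) < 0)  # exp(-r2p t), t increasing

    def test_full_rank_default(self, times, model):
        A = encoding_matrix(0j, times, model)
        s = np.linalg.svd(A, compute_uv=False)
        assert s[-1] >= 1e-8 * s[0]

    def test_full_rank_across_field_range(self, times, model):
        for fB in np.arange(-200.0, 201.0, 25.0):
            A = encoding_matrix(2j * np.pi * fB, times, model)
            s = np.linalg.svd(A, compute_uv=False)
            assert s[-1] >= 1e-8 * s[0]


class TestForwardAndSeparation:
    def _random_problem(self, rng, shape=(12, 12)):
        rho = SpeciesImages(
            *(rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
              for _ in range(3)))
        field = FieldParams(fB=60 * rng.standard_normal(shape),
                            r2p=np.abs(15 * rng.standard_normal(shape)))
        return rho, field

    def test_linear_in_species(self, rng, times, model):
        rho1, field = self._random_problem(rng)
        rho2, _ = self._random_problem(rng)
        a, b = 1.7 - 0.3j, -0.4 + 2.1j
        combo = SpeciesImages.from_stack(a * rho1.stack() + b * rho2.stack())
        lhs = forward_species(combo, field, times, model)
        rhs = (a * forward_species(rho1, field, times, model)
               + b * forward_species(rho2, field, times, model))
        assert np.abs(lhs - rhs).max() < 1e-12 * np.abs(rhs).max()

    def test_zero_species_give_zero_echoes(self, times, model):
        rho = SpeciesImages.zeros((8, 8))
        field = FieldParams.zeros((8, 8))
        assert np.abs(forward_species(rho, field, times, model)).max() == 0

    def test_water_only_no_field_constant_across_echoes(self, times, model):
        shape = (6, 6)
        rho = SpeciesImages(w=np.full(shape, 2.0 + 1j), f=np.zeros(shape),
                            s=np.zeros(shape))
        x = forward_species(rho, FieldParams.zeros(shape), times, model)
        assert np.abs(x - x[0][None]).max() < 1e-14

    def test_matches_per_pixel_matrix_oracle(self, rng, times, model):
        rho, field = self._random_problem(rng, shape=(5, 4))
        x = forward_species(rho, field, times, model)
        stack = rho.stack()
        for iy in range(5):
            for ix in range(4):
                A = encoding_matrix(field.mu[iy, ix], times, model)
                expected = A @ stack[:, iy, ix]
                np.testing.assert_allclose(x[:, iy, ix], expected, rtol=1e-12)

    def test_round_trip_identity(self, rng, times, model):
        rho, field = self._random_problem(rng)
        x = forward_species(rho, field, times, model)
        back = lsq_separate(x, field, times, model)
        err = np.linalg.norm(back.stack() - rho.stack())
        assert err / np.linalg.norm(rho.stack()) < 1e-9

    def test_zero_echoes_zero_species(self, times, model):
        out = lsq_separate(np.zeros((7, 6, 6), complex),
                           FieldParams.zeros((6, 6)), times, model)
        assert np.abs(out.stack()).max() == 0

    def test_noise_only_echoes_finite(self, rng, times, model):
        x = rng.standard_normal((7, 6, 6)) + 1j * rng.standard_normal((7, 6, 6))
        out = lsq_separate(x, FieldParams.zeros((6, 6)), times, model)
        assert np.isfinite(out.stack()).all()

    def test_rank_deficient_pixels_zeroed_with_warning(self, times, caplog):
        # fat indistinguishable from water (0 ppm, single peak) -> rank 2
        m = SpectralModel(fat_ppm=np.array([0.0]), fat_amp=np.array([1.0]))
        x = np.ones((7, 3, 3), complex)
        with caplog.at_level("WARNING"):
            out = lsq_separate(x, FieldParams.zeros((3, 3)), times, m)
        assert np.abs(out.stack()).max() == 0
        assert any("rank-deficient" in r.message for r in caplog.records)
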