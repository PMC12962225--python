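"""Linear-operator contracts: unitarity, adjoints, simulator consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wfsrecon import make_uniform, simulate_kspace
from wfsrecon.operators import (JointOperator, PerEchoOperator, cg_normal,
                                fft2c, ifft2c, shift_operator)
from wfsrecon.phantom import ghost_sensitivities
from wfsrecon.spectral import forward_species


class TestShiftOperator:
    def test_zero_shift_is_identity(self, rng):
        img = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        np.testing.assert_array_equal(shift_operator(img, 0.0), img)

    @settings(derandomize=True, max_examples=30)
    @given(dx=st.floats(-5, 5, allow_nan=False))
    def test_inverse_and_unitary(self, dx):
        rng = np.random.default_rng(7)
        img = rng.standard_normal((6, 16)) + 1j * rng.standard_normal((6, 16))
        out = shift_operator(img, dx)
        assert np.linalg.norm(out) == pytest.approx(np.linalg.norm(img), rel=1e-12)
        back = shift_operator(out, -dx)
        assert np.abs(back - img).max() < 1e-12 * max(np.abs(img).max(), 1)

    def test_integer_shift_moves_delta(self):
        delta = np.zeros((1, 16), complex)
        delta[0, 5] = 1.0
        out = shift_operator(delta, 1.0)
        assert np.argmax(np.abs(out[0])) == 6
        assert abs(out[0, 6]) == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            shift_operator(np.zeros((2, 2)), np.nan)


@pytest.fixture(scope="module")
def joint_op(mid_phantom, times, model):
    ph = mid_phantom
    pat = make_uniform(64, 7, 2.0, 16)
    s_stack = ghost_sensitivities(ph.coils, ph.ghost_phase)
    return JointOperator(ph.field.mu, s_stack, pat.mask, times, model,
                         shifts=(0.0, -0.36, -0.63))


class TestJointOperator:
    def test_adjoint_dot_product(self, joint_op):
        assert joint_op.dot_test(rng=11) < 1e-10

    def test_reduces_to_dft_in_trivial_configuration(self, times, model, rng):
        ny = nx = 16
        mask = np.ones((2, 7, ny), np.uint8)
        s = np.ones((2, 1, ny, nx), complex) / np.sqrt(2)
        op = JointOperator(np.zeros((ny, nx), complex), s, mask, times, model)
        water = rng.standard_normal((ny, nx)) + 1j * rng.standard_normal((ny, nx))
        rho = np.stack([water, np.zeros_like(water), np.zeros_like(water)])
        y = op.forward(rho)
        expected = fft2c(water) / np.sqrt(2)
        for p in (0, 1):
            for j in range(7):
                np.testing.assert_allclose(y[p, j, 0], expected, atol=1e-12)

    def test_simulator_uses_identical_operator(self, mid_phantom, mid_cfg,
                                               times, model):
        ph = mid_phantom
        pat = make_uniform(64, 7, 2.0, 16)
        y = simulate_kspace(ph, pat, times, model, mid_cfg,
                            shifts=(0.0, -0.36, -0.63))
        s_stack = ghost_sensitivities(ph.coils, ph.ghost_phase)
        op = JointOperator(ph.field.mu, s_stack, pat.mask, times, model,
                           shifts=(0.0, -0.36, -0.63))
        np.testing.assert_allclose(y.y, op.forward(ph.truth.stack()), atol=1e-12)

    def test_coil_combined_inverse_matches_species_forward(self, times, model,
                                                           mid_cfg):
        # no ghost, no shifts, fully sampled: per-coil inverse DFT then
        # matched-filter coil combination reproduces the echo images
        from wfsrecon import PhantomConfig, make_phantom
        cfg = PhantomConfig(**{**mid_cfg.__dict__,
                               "ghost_phase_coeffs": (0.0, 0.0, 0.0)})
        ph = make_phantom(cfg)
        pat = make_uniform(64, 7, 1.0, 16)
        y = simulate_kspace(ph, pat, times, model, cfg)
        imgs = ifft2c(y.y)  # (2, Nt, nc, ny, nx)
        rss2 = (np.abs(ph.coils) ** 2).sum(0)
        comb = (ph.coils.conj()[None, None] * imgs).sum(2) / rss2[None, None]
        x_true = forward_species(ph.truth, ph.field, times, model)
        err = np.linalg.norm(comb[0] - x_true) / np.linalg.norm(x_true)
        assert err < 1e-9

    def test_masked_energy_bounded_by_full(self, mid_phantom, mid_cfg, times,
                                           model):
        ph = mid_phantom
        full = make_uniform(64, 7, 1.0, 16)
        sub = make_uniform(64, 7, 2.0, 16)
        y_full = simulate_kspace(ph, full, times, model, mid_cfg)
        y_sub = simulate_kspace(ph, sub, times, model, mid_cfg)
        assert np.linalg.norm(y_sub.y) <= np.linalg.norm(y_full.y) + 1e-12


class TestPerEchoOperator:
    def test_adjoint_dot_product(self, mid_phantom, rng):
        ph = mid_phantom
        s_stack = ghost_sensitivities(ph.coils, ph.ghost_phase)
        pat = make_uniform(64, 7, 2.0, 16)
        op = PerEchoOperator(s_stack, pat.mask[:, 0])
        x = rng.standard_normal(op.image_shape) + 1j * rng.standard_normal(op.image_shape)
        y = rng.standard_normal(op.y_shape) + 1j * rng.standard_normal(op.y_shape)
        lhs = np.vdot(y, op.forward(x))
        rhs = np.vdot(op.adjoint(y), x)
        assert abs(lhs - rhs) / (np.linalg.norm(op.forward(x)) * np.linalg.norm(y)) < 1e-10

    def test_cg_solves_fully_sampled_system(self, mid_phantom, rng):
        ph = mid_phantom
        s_stack = ghost_sensitivities(ph.coils, ph.ghost_phase)
        pat = make_uniform(64, 1, 1.0, 16)
        op = PerEchoOperator(s_stack, pat.mask[:, 0])
        x_true = (rng.standard_normal(op.image_shape)
                  + 1j * rng.standard_normal(op.image_shape)) * ph.support
        y = op.forward(x_true)
        res = cg_normal(op, y, tol=1e-12, max_iter=60)
        assert res.converged
        err = np.linalg.norm((res.x - x_true) * ph.support)
        assert err / np.linalg.norm(x_true * ph.support) < 1e-8
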