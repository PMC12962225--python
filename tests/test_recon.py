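"""Joint and two-stage reconstructions: exactness, prox behavior, shifts."""

import numpy as np
import pytest

from wfsrecon import (FieldCandidates, KSpaceData, PhantomConfig, ReconConfig,
                      ShiftSet, build_joint_operator, grid_search_lambdas,
                      joint_recon, make_phantom, make_uniform, simulate_kspace,
                      two_stage_recon)
from wfsrecon.ngc import PolaritySensitivities
from wfsrecon.operators import cg_normal
from wfsrecon.phantom import ghost_sensitivities


@pytest.fixture(scope="module")
def setup(times, model):
    cfg = PhantomConfig(shape=(48, 48), n_coils=4, seed=7)
    ph = make_phantom(cfg)
    shifts = ShiftSet.from_model(model, 1000.0)
    pat = make_uniform(48, 7, 1.0, 16)
    y = simulate_kspace(ph, pat, times, model, cfg, shifts=shifts.as_tuple)
    S = ghost_sensitivities(ph.coils, ph.ghost_phase)
    sens = PolaritySensitivities(s_pos=S[0], s_neg=S[1], method="truth")
    E = build_joint_operator(ph.field, sens, pat, times, model, shifts)
    return cfg, ph, pat, y, sens, E, shifts


class TestShiftSet:
    def test_displacements_from_model(self, model):
        s = ShiftSet.from_model(model, 1000.0)
        assert s.dx_sil == pytest.approx(model.silicone_hz / 1000.0)
        assert s.dx_fat == pytest.approx(model.mean_fat_hz / 1000.0)
        assert s.as_tuple[0] == 0.0

    def test_positive_bandwidth_required(self, model):
        with pytest.raises(ValueError):
            ShiftSet.from_model(model, 0.0)


class TestJointRecon:
    def test_exact_inversion_and_cg_agreement(self, setup):
        _, ph, _, y, _, E, _ = setup
        rho, rec = joint_recon(y, E, ReconConfig(max_iter=200, tol=0))
        truth = ph.truth.stack()
        nrmse = np.linalg.norm(rho.stack() - truth) / np.linalg.norm(truth)
        assert nrmse <= 1e-3
        oracle = cg_normal(E, y.y, tol=1e-10, max_iter=100).x
        agree = np.linalg.norm(rho.stack() - oracle) / np.linalg.norm(oracle)
        assert agree <= 1e-3

    def test_zero_data_with_regularization_gives_zero(self, setup):
        E = setup[5]
        rho, _ = joint_recon(np.zeros(E.y_shape, complex), E,
                             ReconConfig(lambda_w=1e-3, lambda_f=1e-3,
                                         lambda_s=1e-3, max_iter=5))
        assert np.abs(rho.stack()).max() == 0

    def test_objective_monotone_after_burn_in(self, setup, times, model):
        cfg, ph, _, _, sens, _, shifts = setup
        noisy_cfg = PhantomConfig(**{**cfg.__dict__, "noise_sigma": 0.03})
        pat = make_uniform(48, 7, 3.0, 12)
        y = simulate_kspace(ph, pat, times, model, noisy_cfg,
                            shifts=shifts.as_tuple)
        E = build_joint_operator(ph.field, sens, pat, times, model, shifts)
        _, rec = joint_recon(y, E, ReconConfig(lambda_w=5e-3, lambda_f=5e-3,
                                               lambda_s=5e-3, max_iter=60,
                                               tol=0))
        obj = np.array(rec.objectives[5:])
        assert np.all(np.diff(obj) <= 1e-9 * np.maximum(obj[:-1], 1e-300))

    def test_adjoint_contract(self, setup):
        E = setup[5]
        assert E.dot_test(rng=3) < 1e-10


class TestTwoStage:
    def test_exact_inversion_without_displacement(self, setup, times, model):
        cfg, ph, pat, _, sens, _, _ = setup
        y0 = simulate_kspace(ph, pat, times, model, cfg, shifts=(0, 0, 0))
        rho, _, _ = two_stage_recon(y0, sens, pat, FieldCandidates(),
                                    ReconConfig(max_iter=80, tol=1e-13),
                                    times, model)
        truth = ph.truth.stack()
        nrmse = np.linalg.norm(rho.stack() - truth) / np.linalg.norm(truth)
        assert nrmse <= 1e-3

    def test_echo_recon_touches_only_its_own_mask_rows(self, setup, times,
                                                       model):
        # modifying data of other echoes must not change the echo-j solution
        cfg, ph, _, _, sens, _, _ = setup
        pat = make_uniform(48, 7, 3.0, 12)
        y = simulate_kspace(ph, pat, times, model, cfg)
        rc = ReconConfig(lambda_echo=1e-3, max_iter=20, tol=1e-10)
        rho_a, ech_a, _ = two_stage_recon(y, sens, pat, FieldCandidates(),
                                          rc, times, model)
        y2 = KSpaceData(y=y.y.copy(), pattern=pat, times=times)
        y2.y[:, 1:] *= 0.5  # perturb every echo but the first
        _, ech_b, _ = two_stage_recon(y2, sens, pat, FieldCandidates(),
                                      rc, times, model)
        np.testing.assert_allclose(ech_b[0], ech_a[0], atol=1e-12)
        assert np.abs(ech_b[1] - ech_a[1]).max() > 1e-6

    def test_per_echo_sampling_sparser_than_aggregate(self, times):
        from wfsrecon import make_incoherent_kyte
        pat = make_incoherent_kyte(128, 7, 6.0, 12, seed=0)
        per_echo = pat.mask.sum(axis=2)  # (2, Nt)
        total_union = pat.mask.any(axis=(0, 1)).sum()
        # any single (echo, polarity) mask is far sparser than the union
        assert per_echo.max() < total_union


class TestGridSearch:
    def test_single_point_grid_returns_it(self, setup):
        _, ph, _, y, _, E, _ = setup
        cfg = ReconConfig(max_iter=10)
        best, rows = grid_search_lambdas(y, E, cfg, [1e-3], [2e-3], [3e-3],
                                         ph.truth)
        assert best == (1e-3, 2e-3, 3e-3)
        assert len(rows) == 1

    def test_table_covers_full_grid(self, setup):
        _, ph, _, y, _, E, _ = setup
        cfg = ReconConfig(max_iter=5)
        _, rows = grid_search_lambdas(y, E, cfg, [0.0, 1e-3], [0.0],
                                      [0.0, 1e-3, 1e-2], ph.truth)
        assert len(rows) == 2 * 1 * 3

    def test_noiseless_fully_sampled_prefers_smallest_lambdas(self, setup):
        _, ph, _, y, _, E, _ = setup
        cfg = ReconConfig(max_iter=60, tol=0)
        best, _ = grid_search_lambdas(y, E, cfg, [0.0, 0.05], [0.0, 0.05],
                                      [0.0, 0.05], ph.truth)
        assert best == (0.0, 0.0, 0.0)

    def test_empty_grid_rejected(self, setup):
        _, ph, _, y, _, E, _ = setup
        with pytest.raises(ValueError):
            grid_search_lambdas(y, E, ReconConfig(), [], [1e-3], [1e-3],
                                ph.truth)


class TestChemicalShiftCorrection:
    def test_ignoring_displacement_blurs_species_edges(self, times, model):
        # exaggerated displacement (low pixel bandwidth) so the effect is
        # unambiguous: reconstructing with the shift operators disabled must
        # widen the fat-silicone boundary by at least |dx|/2 pixels
        cfg = PhantomConfig(shape=(48, 48), n_coils=4, seed=7)
        ph = make_phantom(cfg)
        shifts = ShiftSet.from_model(model, 200.0)  # dx_sil ~ -3.1 px
        pat = make_uniform(48, 7, 1.0, 16)
        y = simulate_kspace(ph, pat, times, model, cfg, shifts=shifts.as_tuple)
        S = ghost_sensitivities(ph.coils, ph.ghost_phase)
        sens = PolaritySensitivities(s_pos=S[0], s_neg=S[1], method="truth")
        rc = ReconConfig(max_iter=150, tol=0)
        E_on = build_joint_operator(ph.field, sens, pat, times, model, shifts)
        E_off = build_joint_operator(ph.field, sens, pat, times, model)
        rho_on, _ = joint_recon(y, E_on, rc)
        rho_off, _ = joint_recon(y, E_off, rc)

        def edge_width(img, row):
            prof = np.abs(img[row])
            half = 0.5 * prof.max()
            above = np.where(prof >= half)[0]
            return above[-1] - above[0]

        row = int(np.argmax(np.abs(ph.truth.s).sum(axis=1)))
        w_on = edge_width(rho_on.s, row)
        w_off = edge_width(rho_off.s, row)
        assert w_off - w_on >= abs(shifts.dx_sil) / 2
        err_on = np.linalg.norm(rho_on.stack() - ph.truth.stack())
        err_off = np.linalg.norm(rho_off.stack() - ph.truth.stack())
        assert err_off > err_on
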