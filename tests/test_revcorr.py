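"""Filter bank, quadrature energies, probit classification images,
Gaussian tuning fits and bootstrap inference."""

import numpy as np
import pytest
from scipy.special import ndtr

from alphaphase import revcorr, synthdata
from alphaphase.errors import AlphaPhaseError, ResolutionError
from alphaphase.revcorr import (
    _gauss2d,
    bootstrap_compare,
    build_filter_bank,
    difference_ci,
    energy_profiles,
    fit_gauss2d,
    fit_modulation,
    fold_orientations,
    normalize_energy,
    probit_ci,
    simulate_ci_cohort,
    split_trials_by_phase,
    stimulus_energy,
)

SF = np.linspace(0.5, 4.0, 15)
OM = np.linspace(0.0, 80.0, 10)


class TestFilterBank:
    def test_cell_count_is_285(self, filter_bank):
        assert filter_bank.n_cells == 285
        assert filter_bank.g_sin.shape[:2] == (15, 19)

    def test_grid_endpoints(self, filter_bank):
        assert filter_bank.sf_values[0] == 0.5
        assert filter_bank.sf_values[-1] == 4.0
        assert filter_bank.ori_values[0] == -80.0
        assert filter_bank.ori_values[-1] == 80.0

    def test_quadrature_orthogonality(self, filter_bank):
        """Inner-product oracle over all 285 cells."""
        ip = np.abs(np.sum(filter_bank.g_sin * filter_bank.g_cos,
                           axis=(2, 3)))
        assert ip.max() < 1e-3

    def test_unit_energy_kernels(self, filter_bank):
        for g in (filter_bank.g_sin, filter_bank.g_cos):
            norms = np.sqrt(np.sum(g**2, axis=(2, 3)))
            assert np.allclose(norms, 1.0, atol=1e-12)

    def test_raster_too_small(self):
        tiny = synthdata.StimulusSpec(patch_diameter=1.0,
                                      pixels_per_degree=16.0)
        with pytest.raises(ResolutionError):
            build_filter_bank(tiny)


class TestStimulusEnergy:
    def test_zero_stimulus(self, filter_bank):
        img = np.zeros(filter_bank.g_sin.shape[-2:])
        assert not stimulus_energy(img, filter_bank).any()

    def test_matched_kernel_is_argmax(self, filter_bank):
        """Inner-product oracle: feeding a cell's own kernel back maximises
        the energy at that cell with value ||g||^2 = 1."""
        E = stimulus_energy(filter_bank.g_sin[7, 9], filter_bank)
        assert E[7, 9] == pytest.approx(1.0, abs=1e-9)
        assert np.unravel_index(E.argmax(), E.shape) == (7, 9)

    def test_energy_invariant_to_grating_phase(self, filter_bank, coarse_spec):
        """Quadrature-invariance oracle over spatial phases 0-360 deg."""
        i2 = int(np.argmin(np.abs(filter_bank.sf_values - 2.0)))
        vals = [stimulus_energy(
            synthdata.generate_gabor(coarse_spec, ph), filter_bank)[i2, 9]
            for ph in range(0, 360, 20)]
        vals = np.asarray(vals)
        assert (vals.max() - vals.min()) / vals.mean() < 0.02

    def test_batch_matches_single(self, filter_bank, coarse_spec):
        rng = np.random.default_rng(0)
        stims = np.stack([synthdata.generate_noise_patch(coarse_spec, k)
                          for k in range(3)])
        batch = energy_profiles(stims, filter_bank)
        single = stimulus_energy(stims[1], filter_bank)
        assert np.allclose(batch[1], single, atol=1e-10)


class TestNormalizeEnergy:
    def _raw(self, n=50, seed=1):
        rng = np.random.default_rng(seed)
        raw = rng.lognormal(0, 0.3, (n, 4, 5))
        present = rng.random(n) < 0.5
        return raw, present

    def test_per_condition_zscore(self):
        raw, present = self._raw()
        out = normalize_energy(raw, present)
        for cond in (present, ~present):
            assert np.abs(out[cond].mean(axis=0)).max() < 1e-9
            assert np.abs(out[cond].std(axis=0) - 1.0).max() < 1e-9

    def test_affine_invariance(self):
        raw, present = self._raw(seed=2)
        assert np.allclose(normalize_energy(raw, present),
                           normalize_energy(2.0 * raw, present))

    def test_degenerate_cell_rejected(self):
        raw, present = self._raw(seed=3)
        raw[:, 0, 0] = 1.0
        with pytest.raises(AlphaPhaseError):
            normalize_energy(raw, present)


class TestProbitCI:
    def test_recovers_known_slope(self):
        """GLM recovery oracle: responses from p(yes) = Phi(0.2 + 0.5 E) at
        one cell recover beta1 = 0.5 +/- 0.05 over 10k trials."""
        rng = np.random.default_rng(4)
        n = 10_000
        E = rng.normal(0, 1, (n, 2, 2))
        p = ndtr(0.2 + 0.5 * E[:, 1, 1])
        resp = rng.random(n) < p
        beta1, beta0 = probit_ci(E, resp)
        assert beta1[1, 1] == pytest.approx(0.5, abs=0.05)
        assert beta0[1, 1] == pytest.approx(0.2, abs=0.05)

    def test_shuffled_responses_give_null_image(self):
        rng = np.random.default_rng(5)
        E = rng.normal(0, 1, (600, 5, 4))
        resp = rng.random(600) < 0.5   # independent of energy
        beta1, _ = probit_ci(E, resp)
        # slopes scatter around 0 with SE ~ 1/sqrt(n)
        assert abs(beta1.mean()) < 0.02
        assert np.abs(beta1).max() < 5 / np.sqrt(600)

    def test_single_class_rejected(self):
        with pytest.raises(AlphaPhaseError):
            probit_ci(np.zeros((10, 1, 1)), np.ones(10))

    def test_perfect_separation_capped(self):
        E = np.linspace(-1, 1, 40).reshape(40, 1, 1)
        resp = E[:, 0, 0] > 0
        with pytest.warns(UserWarning):
            beta1, _ = probit_ci(E, resp)
        assert abs(beta1[0, 0]) <= 10.0


class TestFoldOrientations:
    def test_antisymmetric_grid_cancels(self):
        ori = np.linspace(-80, 80, 19)
        grid = np.tile(ori, (15, 1))
        folded = fold_orientations(grid, ori)
        assert folded.shape == (15, 10)
        assert np.allclose(folded[:, 1:], 0.0)
        assert np.allclose(folded[:, 0], 0.0)

    def test_symmetric_grid_equals_half(self):
        ori = np.linspace(-80, 80, 19)
        grid = np.tile(np.abs(ori), (15, 1))
        assert np.allclose(fold_orientations(grid, ori)[:, 1:],
                           grid[:, 10:])

    def test_idempotent_on_symmetric_input(self):
        rng = np.random.default_rng(6)
        ori = np.linspace(-80, 80, 19)
        grid = rng.normal(size=(15, 19))
        sym = 0.5 * (grid + grid[:, ::-1])
        assert np.allclose(fold_orientations(sym, ori),
                           fold_orientations(grid, ori))

    def test_asymmetric_grid_rejected(self):
        with pytest.raises(ValueError):
            fold_orientations(np.zeros((15, 19)), np.linspace(-80, 70, 19))


class TestGaussFit:
    def test_noise_free_self_consistency(self):
        xx, yy = np.meshgrid(SF, OM, indexing="ij")
        p = [0.5, 2.0, 0.8, 10.0, 22.0, 0.05]
        fit = fit_gauss2d(_gauss2d(p, xx, yy), SF, OM)
        assert np.allclose(fit.p, p, atol=1e-4)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_flat_grid(self):
        fit = fit_gauss2d(np.full((15, 10), 0.3), SF, OM)
        assert abs(fit.gain) < 1e-6
        assert fit.offset == pytest.approx(0.3, abs=1e-6)

    def test_noisy_recovery_of_widths(self):
        """Fit-recovery oracle: 10% noise keeps the SDs within 15%
        (median over replicates)."""
        xx, yy = np.meshgrid(SF, OM, indexing="ij")
        p = [0.5, 2.0, 0.8, 0.0, 22.0, 0.05]
        clean = _gauss2d(p, xx, yy)
        rng = np.random.default_rng(7)
        err3, err5 = [], []
        for rep in range(30):
            fit = fit_gauss2d(clean + rng.normal(0, 0.05, clean.shape),
                              SF, OM, seed=rep)
            err3.append(abs(fit.p[2] - 0.8) / 0.8)
            err5.append(abs(fit.p[4] - 22.0) / 22.0)
        assert np.median(err3) < 0.15
        assert np.median(err5) < 0.15


class TestModulationFit:
    @pytest.fixture()
    def optimal_fit(self):
        xx, yy = np.meshgrid(SF, OM, indexing="ij")
        p = [0.5, 2.0, 0.8, 0.0, 22.0, 0.05]
        return fit_gauss2d(_gauss2d(p, xx, yy), SF, OM), p, (xx, yy)

    def test_identity(self, optimal_fit):
        fit, p, (xx, yy) = optimal_fit
        mod = fit_modulation(fit, _gauss2d(p, xx, yy), SF, OM)
        for factor in (mod.gain_mod, mod.sd_mod, mod.offset_mod):
            assert factor == pytest.approx(1.0, abs=1e-3)

    def test_sd_broadening_recovered(self, optimal_fit):
        fit, p, (xx, yy) = optimal_fit
        q = [p[0], p[1], p[2] * 1.3, p[3], p[4] * 1.3, p[5]]
        mod = fit_modulation(fit, _gauss2d(q, xx, yy), SF, OM)
        assert mod.sd_mod == pytest.approx(1.3, abs=0.1)
        assert mod.gain_mod == pytest.approx(1.0, abs=0.05)
        assert mod.offset_mod == pytest.approx(1.0, abs=0.1)

    def test_gain_reduction_recovered(self, optimal_fit):
        fit, p, (xx, yy) = optimal_fit
        q = [p[0] * 0.7, p[1], p[2], p[3], p[4], p[5]]
        mod = fit_modulation(fit, _gauss2d(q, xx, yy), SF, OM)
        assert mod.gain_mod == pytest.approx(0.7, abs=0.1)
        assert mod.sd_mod == pytest.approx(1.0, abs=0.05)

    def test_zero_offset_reported_absolute(self, optimal_fit):
        xx, yy = np.meshgrid(SF, OM, indexing="ij")
        p = [0.5, 2.0, 0.8, 0.0, 22.0, 0.0]
        fit = fit_gauss2d(_gauss2d(p, xx, yy), SF, OM)
        with pytest.warns(UserWarning):
            mod = fit_modulation(fit, _gauss2d(p, xx, yy), SF, OM)
        assert mod.offset_absolute


class TestBootstrap:
    def test_identical_phases_centre_at_one(self):
        ci, _ = simulate_ci_cohort(SF, OM, sd_mod=1.0, mod_jitter=0.0,
                                   noise_sd_frac=0.0, seed=8)
        boot = bootstrap_compare(ci, ci.copy(), SF, OM, n_boot=60, seed=9)
        assert np.median(boot.sd_mod) == pytest.approx(1.0, abs=0.01)
        assert boot.p_sd > 0.5
        mean_diff, p = difference_ci(boot.diff_draws)
        assert np.allclose(mean_diff, 0.0)
        assert p.min() > 0.9

    def test_determinism(self):
        ci_o, ci_s = simulate_ci_cohort(SF, OM, seed=10)
        b1 = bootstrap_compare(ci_o, ci_s, SF, OM, n_boot=40, seed=11)
        b2 = bootstrap_compare(ci_o, ci_s, SF, OM, n_boot=40, seed=11)
        assert np.array_equal(b1.sd_mod, b2.sd_mod)
        assert np.array_equal(b1.diff_draws, b2.diff_draws)

    def test_broadened_cohort_detected(self):
        """Generative-model oracle: a 1.3x broadened cohort yields a
        significant SD modulation with non-significant gain modulation."""
        ci_o, ci_s = simulate_ci_cohort(SF, OM, sd_mod=1.3, seed=12)
        boot = bootstrap_compare(ci_o, ci_s, SF, OM, n_boot=200, seed=13)
        assert boot.p_sd < 0.05
        assert boot.p_gain > 0.05
        assert np.median(boot.sd_mod) == pytest.approx(1.3, abs=0.1)

    def test_difference_ci_ring_and_sign(self):
        ci_o, ci_s = simulate_ci_cohort(SF, OM, sd_mod=1.3, seed=14)
        boot = bootstrap_compare(ci_o, ci_s, SF, OM, n_boot=200, seed=15)
        mean_diff, p = difference_ci(boot.diff_draws)
        # sign convention: suboptimal > optimal -> positive difference
        hand = boot.diff_draws.mean(axis=0)
        assert np.allclose(mean_diff, hand)
        # broadening moves weight off-centre: significant positive cells in a
        # ring around the target more often than the 5% chance level
        xx, yy = np.meshgrid(SF, OM, indexing="ij")
        ring = (np.sqrt(((xx - 2.0) / 0.8) ** 2 + (yy / 22.0) ** 2)
                .clip(0) > 1.0) & (np.sqrt(((xx - 2.0) / 0.8) ** 2
                                           + (yy / 22.0) ** 2) < 2.5)
        frac = np.mean((mean_diff[ring] > 0) & (p[ring] < 0.05))
        assert frac > 0.3


class TestPhaseSplit:
    def _grids(self, phases_by_channel, theta_by_channel):
        n_trials = phases_by_channel.shape[0]
        n_ch = phases_by_channel.shape[1]
        phase = np.tile(phases_by_channel[:, :, None], (1, 1, 3))
        theta = np.tile(np.asarray(theta_by_channel)[:, None], (1, 3))
        times = np.array([-0.2, -0.1, 0.0])
        return phase, theta, times

    def test_unanimous_vote(self):
        phase, theta, times = self._grids(np.zeros((4, 3)), [0.0, 0.0, 0.0])
        assert split_trials_by_phase(phase, theta, times,
                                     window=(-0.2, 0)).all()

    def test_majority_two_of_three(self):
        p = np.array([[0.0, 0.0, 180.0]])
        phase, theta, times = self._grids(p, [0.0, 0.0, 0.0])
        assert split_trials_by_phase(phase, theta, times,
                                     window=(-0.2, 0)).all()

    def test_minority_is_suboptimal(self):
        p = np.array([[0.0, 180.0, 180.0]])
        phase, theta, times = self._grids(p, [0.0, 0.0, 0.0])
        assert not split_trials_by_phase(phase, theta, times,
                                         window=(-0.2, 0)).any()

    def test_optimal_split_has_higher_dprime(self):
        """Generative-model oracle: splitting by the true optimal phase
        separates high- and low-sensitivity trials."""
        import sys
        sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
        from conftest import make_phase_trials
        from alphaphase.sdt import (RateCounts, dprime_criterion,
                                    loglinear_rates)

        table, phases = make_phase_trials(30_000, "variance_reduction",
                                          m=0.3, phi_opt=45.0, seed=16)
        phase = np.tile(phases[:, None, None], (1, 3, 3))
        theta = np.full((3, 3), 45.0)
        times = np.array([-0.2, -0.1, 0.0])
        optimal = split_trials_by_phase(phase, theta, times, window=(-0.2, 0))
        tgt = table["target_present"].to_numpy()
        resp = table["response"].to_numpy()
        dps = {}
        for name, mask in (("opt", optimal), ("sub", ~optimal)):
            counts = RateCounts(int((tgt & resp & mask).sum()),
                                int((tgt & mask).sum()),
                                int((~tgt & resp & mask).sum()),
                                int((~tgt & mask).sum()))
            dps[name] = dprime_criterion(*loglinear_rates(counts)).d_prime
        assert dps["opt"] > dps["sub"] + 0.2
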