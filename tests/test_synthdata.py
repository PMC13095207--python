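"""Session design, stimuli, EEG and observer generators."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import hilbert, welch
from scipy.stats import norm

from alphaphase import synthdata
from alphaphase.errors import InvalidDesignError, ResolutionError
from alphaphase.sdt import RateCounts, dprime_criterion, loglinear_rates
from alphaphase.synthdata import (
    AlphaEEGModel,
    ObserverModel,
    SessionDesign,
    StimulusSpec,
    aperture_mask,
    analytic_rates,
    generate_gabor,
    generate_noise_patch,
    make_session_design,
    simulate_alpha_eeg,
    simulate_observer,
)

from conftest import make_phase_trials


class TestSessionDesign:
    def test_default_session_size(self, default_design_table):
        assert len(default_design_table) == 6020

    def test_unique_stimuli_per_block(self, default_design_table):
        per_block = default_design_table.groupby("block")["stimulus_id"]
        assert (per_block.nunique() == 70).all()
        assert (per_block.value_counts() == 2).all()

    def test_tiny_block_repetition_order(self):
        table = make_session_design(SessionDesign(
            n_blocks=1, trials_per_block=4, unique_stimuli_per_block=2))
        sids = table["stimulus_id"].tolist()
        assert sids == [sids[0], sids[1], sids[0], sids[1]]
        assert table["pass_index"].tolist() == [1, 1, 2, 2]

    def test_block_set_repetition_structure(self, default_design_table):
        """Trials 1-35 repeat as 36-70 and 71-105 as 106-140, in order."""
        blk = default_design_table[default_design_table.block == 1]
        sids = blk["stimulus_id"].to_numpy()
        assert (sids[0:35] == sids[35:70]).all()
        assert (sids[70:105] == sids[105:140]).all()

    def test_double_pass_integrity(self, default_design_table):
        grp = default_design_table.groupby("stimulus_id")
        assert (grp.size() == 2).all()
        for col in ("target_present", "side", "stim_seed"):
            assert (grp[col].nunique() == 1).all()
        assert (grp["pass_index"].min() == 1).all()
        assert (grp["pass_index"].max() == 2).all()

    def test_half_targets_per_block(self, default_design_table):
        uniq = default_design_table.drop_duplicates("stimulus_id")
        assert (uniq.groupby("block")["target_present"].sum() == 35).all()

    def test_odd_trials_rejected(self):
        with pytest.raises(InvalidDesignError):
            make_session_design(SessionDesign(
                n_blocks=1, trials_per_block=5, unique_stimuli_per_block=2))


class TestNoisePatch:
    def test_rms_contrast(self, coarse_spec):
        patch = generate_noise_patch(coarse_spec, 0)
        mask = aperture_mask(coarse_spec)
        assert np.sqrt(np.mean(patch[mask] ** 2)) == pytest.approx(
            0.70, abs=1e-6)

    def test_zero_contrast_gives_zero_patch(self):
        spec = StimulusSpec(pixels_per_degree=16.0, noise_rms_contrast=0.0)
        assert not generate_noise_patch(spec, 0).any()

    def test_band_limited_spectrum(self, coarse_spec):
        """FFT oracle: pre-aperture energy outside 0.25-4 cpd is negligible."""
        field = generate_noise_patch(coarse_spec, 1, apply_aperture=False)
        F = np.fft.fft2(field)
        f = np.fft.fftfreq(field.shape[0], 1.0 / coarse_spec.pixels_per_degree)
        fx, fy = np.meshgrid(f, f)
        r = np.hypot(fx, fy)
        outside = (r < 0.25) | (r > 4.0)
        frac = np.sum(np.abs(F[outside]) ** 2) / np.sum(np.abs(F) ** 2)
        assert frac < 1e-9

    def test_band_above_nyquist_rejected(self):
        spec = StimulusSpec(pixels_per_degree=6.0)  # Nyquist 3 < 4 cpd
        with pytest.raises(ResolutionError):
            generate_noise_patch(spec, 0)


class TestGabor:
    def test_vertical_grating_varies_only_horizontally(self, coarse_spec):
        g = generate_gabor(coarse_spec, 40.0)
        mask = aperture_mask(coarse_spec)
        # compare two rows on the columns both have inside the aperture
        shared = mask[20] & mask[28]
        assert np.allclose(g[20][shared], g[28][shared], atol=1e-12)

    def test_antiphase_negates(self, coarse_spec):
        assert np.allclose(generate_gabor(coarse_spec, 33.0),
                           -generate_gabor(coarse_spec, 213.0), atol=1e-12)

    def test_spectral_peak_at_target_sf(self, coarse_spec):
        """FFT oracle: dominant energy at 2 +/- 0.25 cpd."""
        g = generate_gabor(coarse_spec, 0.0)
        F = np.abs(np.fft.fft2(g))
        f = np.fft.fftfreq(g.shape[0], 1.0 / coarse_spec.pixels_per_degree)
        fx, fy = np.meshgrid(f, f)
        r = np.hypot(fx, fy)
        peak_r = r.ravel()[np.argmax(F.ravel())]
        assert abs(peak_r - 2.0) <= 0.25

    def test_nonpositive_contrast_rejected(self):
        spec = StimulusSpec(pixels_per_degree=16.0, target_contrast=0.0)
        with pytest.raises(InvalidDesignError):
            generate_gabor(spec, 0.0)


class TestAlphaEEG:
    def test_noise_free_phase_matches_truth(self, noisefree_eeg):
        _, epochs, truth = noisefree_eeg
        oz = epochs.channels.index("Oz")
        analytic = hilbert(epochs.data[:, oz, :], axis=-1)
        i0 = epochs.time_index(0.0)
        phase = np.degrees(np.angle(analytic[:, i0])) % 360.0
        err = np.abs((phase - truth + 180.0) % 360.0 - 180.0)
        assert err.max() <= 1.0

    def test_frontal_occipital_counterphase(self, noisefree_eeg):
        _, epochs, truth = noisefree_eeg
        i0 = epochs.time_index(0.0)
        afz = epochs.data[:, epochs.channels.index("AFz"), i0]
        oz = epochs.data[:, epochs.channels.index("Oz"), i0]
        # opposite topography signs -> strict sign flip of the waveform
        assert np.allclose(np.sign(afz), -np.sign(oz))

    def test_no_alpha_peak_without_alpha(self):
        """Welch oracle: alpha_amp=0 leaves no 7-14 Hz peak >3 dB above the
        1/f fit."""
        table = make_session_design(SessionDesign(
            n_blocks=1, trials_per_block=20, unique_stimuli_per_block=10,
            seed=0))
        model = AlphaEEGModel(alpha_amp=0.0, pink_noise_amp=5.0, seed=1)
        epochs, _ = simulate_alpha_eeg(table, model)
        f, pxx = welch(epochs.data[:, epochs.channels.index("Oz"), :],
                       fs=epochs.fs, nperseg=512, axis=-1)
        pxx = pxx.mean(axis=0)
        fit_band = (f >= 2) & (f <= 40) & ((f < 7) | (f > 14))
        coef = np.polyfit(np.log10(f[fit_band]), 10 * np.log10(pxx[fit_band]), 1)
        alpha_band = (f >= 7) & (f <= 14)
        excess = (10 * np.log10(pxx[alpha_band])
                  - np.polyval(coef, np.log10(f[alpha_band])))
        assert excess.max() < 3.0

    def test_fs_invariant_enforced(self):
        with pytest.raises(InvalidDesignError):
            AlphaEEGModel(iaf=13.0, fs=30.0)


class TestObserver:
    def test_baseline_dprime_matches_closed_form(self):
        """Monte-Carlo vs Phi oracle: m=0, d_prime_base=1.5 -> empirical d'
        = 1.5 +/- 0.05 over 50k trials."""
        table, _ = make_phase_trials(
            50_000, "variance_reduction", m=0.0, seed=5,
            d_prime_base=1.5, lam=1.75)
        tgt = table["target_present"].to_numpy()
        resp = table["response"].to_numpy()
        counts = RateCounts(int((tgt & resp).sum()), int(tgt.sum()),
                            int((~tgt & resp).sum()), int((~tgt).sum()))
        met = dprime_criterion(*loglinear_rates(counts))
        assert met.d_prime == pytest.approx(1.5, abs=0.05)

    @pytest.mark.parametrize("kind,far_sign", [
        ("variance_reduction", -1),   # FAR drops at the optimal phase
        ("multiplicative_gain", +1),  # FAR rises at the optimal phase
    ])
    def test_mechanism_signatures(self, kind, far_sign):
        table, phase = make_phase_trials(50_000, kind, m=0.3, phi_opt=90.0,
                                         seed=6)
        tgt = table["target_present"].to_numpy()
        resp = table["response"].to_numpy()
        near = np.abs((phase - 90.0 + 180.0) % 360.0 - 180.0) < 22.5
        anti = np.abs((phase - 270.0 + 180.0) % 360.0 - 180.0) < 22.5
        hr_opt = (tgt & resp & near).sum() / (tgt & near).sum()
        hr_anti = (tgt & resp & anti).sum() / (tgt & anti).sum()
        far_opt = (~tgt & resp & near).sum() / (~tgt & near).sum()
        far_anti = (~tgt & resp & anti).sum() / (~tgt & anti).sum()
        assert hr_opt > hr_anti
        assert np.sign(far_opt - far_anti) == far_sign

    def test_analytic_rates_counterphase(self):
        """Variance reduction: argmax HR = argmin FAR = phi_opt."""
        obs = ObserverModel(kind="variance_reduction", m=0.3, phi_opt=135.0)
        phi = np.linspace(0, 360, 721)
        hr, far = analytic_rates(obs, phi)
        assert phi[np.argmax(hr)] == pytest.approx(135.0, abs=1.0)
        assert phi[np.argmin(far)] == pytest.approx(135.0, abs=1.0)
        obs_g = ObserverModel(kind="multiplicative_gain", m=0.3, phi_opt=135.0)
        hr_g, far_g = analytic_rates(obs_g, phi)
        assert phi[np.argmax(hr_g)] == pytest.approx(135.0, abs=1.0)
        assert phi[np.argmax(far_g)] == pytest.approx(135.0, abs=1.0)

    def test_monte_carlo_converges_to_analytic(self):
        """Empirical HR(phi) tracks the closed form at large n."""
        table, phase = make_phase_trials(80_000, "variance_reduction", m=0.3,
                                         phi_opt=0.0, seed=7)
        obs = ObserverModel(kind="variance_reduction", m=0.3, phi_opt=0.0,
                            seed=8)
        tgt = table["target_present"].to_numpy()
        resp = table["response"].to_numpy()
        for center in (0.0, 90.0, 180.0):
            sel = tgt & (np.abs((phase - center + 180) % 360 - 180) < 22.5)
            emp = resp[sel].mean()
            ana = analytic_rates(obs, np.array([center]))[0][0]
            assert emp == pytest.approx(ana, abs=0.03)

    def test_template_requires_energies(self):
        table = pd.DataFrame({"target_present": [True, False]})
        obs = ObserverModel(kind="template")
        with pytest.raises(InvalidDesignError):
            simulate_observer(table, np.array([0.0, 90.0]), obs)

    def test_confidence_in_range(self):
        table, _ = make_phase_trials(500, "variance_reduction", m=0.1, seed=9)
        assert table["confidence"].between(1, 4).all()


class TestIO:
    def test_epochs_hdf5_round_trip(self, noisefree_eeg, tmp_path):
        _, epochs, truth = noisefree_eeg
        path = tmp_path / "epochs.h5"
        epochs.to_hdf5(path, truth_phase_deg=truth, iaf_true=10.4, seed=3)
        back, truth2 = synthdata.EpochedSeries.from_hdf5(path)
        assert back.channels == epochs.channels
        assert back.fs == epochs.fs
        assert np.allclose(back.times, epochs.times)
        # stored as float32
        assert np.allclose(back.data, epochs.data, atol=1e-3)
        assert np.allclose(truth2, truth)

    def test_trial_table_csv_header(self, tmp_path):
        table = make_session_design(SessionDesign(
            n_blocks=1, trials_per_block=4, unique_stimuli_per_block=2))
        table["response"] = [True, False, True, True]
        table["confidence"] = [1, 2, 3, 4]
        path = tmp_path / "trials.csv"
        synthdata.write_trial_table(table, path, participant=2)
        head = path.read_text().splitlines()[0].split(",")
        assert head == ["participant", "session", "block", "trial_in_block",
                        "stimulus_id", "pass_index", "target_present", "side",
                        "contrast", "response", "confidence"]


class TestStaircase:
    def test_one_up_two_down_steps(self):
        levels = synthdata.staircase_1up2down(
            [True, True, False, True, True], start=0.2, step=0.05)
        assert np.allclose(levels, [0.2, 0.2, 0.15, 0.2, 0.2])

    def test_block_rule_only_after_two_consecutive(self):
        assert synthdata.block_contrast_rule([1.0], 0.15) == 0.15
        assert synthdata.block_contrast_rule([1.0, 1.1], 0.15) > 0.15
        assert synthdata.block_contrast_rule([2.0, 1.9], 0.15) < 0.15
        assert synthdata.block_contrast_rule([1.0, 1.5], 0.15) == 0.15
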