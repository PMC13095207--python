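import numpy as np
import pandas as pd
import pytest

from alphaphase import revcorr, synthdata


@pytest.fixture(scope="session")
def coarse_spec():
    """Low-resolution stimulus spec used throughout the tests (16 px/deg is
    ample for the 0.25-4 cpd band and keeps rasters small)."""
    return synthdata.StimulusSpec(pixels_per_degree=16.0)


@pytest.fixture(scope="session")
def filter_bank(coarse_spec):
    return revcorr.build_filter_bank(coarse_spec)


@pytest.fixture(scope="session")
def default_design_table():
    return synthdata.make_session_design(synthdata.SessionDesign(seed=1))


@pytest.fixture(scope="session")
def noisefree_eeg():
    """100 noise-free alpha trials at 10.4 Hz with known onset phase."""
    design = synthdata.SessionDesign(
        n_blocks=1, trials_per_block=100, unique_stimuli_per_block=50, seed=3)
    table = synthdata.make_session_design(design)
    model = synthdata.AlphaEEGModel(
        iaf=10.4, pink_noise_amp=0.0, seed=4, epoch_window=(-1.5, 0.5))
    epochs, truth = synthdata.simulate_alpha_eeg(table, model)
    return table, epochs, truth


def make_phase_trials(n, kind, m, phi_opt=90.0, seed=0, **obs_kwargs):
    """Trials with uniform onset phases and a simulated observer."""
    rng = np.random.default_rng(seed)
    table = pd.DataFrame({"target_present": rng.random(n) < 0.5})
    phase = rng.uniform(0.0, 360.0, n)
    obs = synthdata.ObserverModel(kind=kind, m=m, phi_opt=phi_opt,
                                  seed=seed + 1, **obs_kwargs)
    table = synthdata.simulate_observer(table, phase, obs)
    return table, phase
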