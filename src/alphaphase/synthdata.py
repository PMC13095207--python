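"""Synthetic session designs, stimuli, observers, and alpha-band EEG.

This module generates everything the downstream analysis consumes, with known
ground truth:

* a double-pass session design (unique stimuli presented twice per block),
* band-limited noise patches with an optional vertical Gabor target,
* phase-dependent ideal observers implementing the competing signal-detection
  mechanisms (internal-noise variance reduction vs. multiplicative evidence
  gain vs. an explicit sensory template whose tuning width varies with phase),
* multichannel epoched EEG containing an alpha oscillation of known phase at
  stimulus onset riding on 1/f ("pink") background noise, with a dipole-like
  topography (posterior channels counterphase to the frontal channel).

Phase convention: cosine phase in degrees, 0 deg at the oscillation peak,
defined at t = 0 (stimulus onset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import EmptyDataError, InvalidDesignError, ResolutionError

# The 17 posterior channels used for alpha-channel selection, plus the frontal
# channel AFz used for the dipole (phase-opposition) test.
POSTERIOR_CHANNELS = (
    "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8", "P1",
    "P5", "PO7", "PO3", "POz", "PO4", "PO8", "P6", "P2",
)
IAF_CHANNELS = ("P1", "Pz", "P2", "PO3", "POz", "PO4")
DEFAULT_CHANNELS = POSTERIOR_CHANNELS + ("AFz",)

# Largest run of unique stimuli presented back to back before being repeated.
# Keeping presentation sets short controls for drowsiness/fatigue drift within
# a block; a 140-trial block therefore holds two presented-then-repeated sets
# of 35 unique stimuli each.
MAX_SET_SIZE = 35


def _default_topography(channels: Sequence[str]) -> dict[str, float]:
    """Signed alpha weights: occipital strongest/positive, frontal negative."""
    topo = {}
    for ch in channels:
        if ch.startswith("O"):
            topo[ch] = 1.0
        elif ch.startswith("PO"):
            topo[ch] = 0.8
        elif ch.startswith("P"):
            topo[ch] = 0.6
        elif ch.startswith("AF") or ch.startswith("F"):
            topo[ch] = -0.6
        else:
            topo[ch] = 0.0
    return topo


# --------------------------------------------------------------------------
# Session design
# --------------------------------------------------------------------------

@dataclass
class SessionDesign:
    """Block/trial structure of one observer's session.

    Defaults reproduce the study conditions: 43 blocks of 140 trials, each
    block built from 70 unique stimuli presented twice (double pass), half of
    them target-present, side drawn uniformly from {left, right}.
    """

    n_blocks: int = 43
    trials_per_block: int = 140
    unique_stimuli_per_block: int = 70
    p_target: float = 0.5
    sides: tuple[str, str] = ("left", "right")
    seed: int = 0

    def validate(self) -> None:
        if self.trials_per_block % 2 != 0:
            raise InvalidDesignError("trials_per_block must be even")
        if self.trials_per_block != 2 * self.unique_stimuli_per_block:
            raise InvalidDesignError(
                "trials_per_block must equal 2 x unique_stimuli_per_block"
            )
        if self.n_blocks < 1:
            raise InvalidDesignError("n_blocks must be >= 1")
        if not 0.0 <= self.p_target <= 1.0:
            raise InvalidDesignError("p_target must be a probability")


def make_session_design(design: SessionDesign) -> pd.DataFrame:
    """Expand a :class:`SessionDesign` into one row per trial.

    Each block's unique stimuli are split into consecutive presentation sets
    of at most ``MAX_SET_SIZE``; each set is presented in order and then
    repeated in the same order (pass 1 then pass 2), so every ``stimulus_id``
    appears exactly twice with identical ``target_present``, ``side`` and
    stimulus RNG key.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    u = design.unique_stimuli_per_block
    rows = []
    for block in range(1, design.n_blocks + 1):
        n_present = int(round(design.p_target * u))
        present = np.zeros(u, dtype=bool)
        present[rng.choice(u, size=n_present, replace=False)] = True
        side = rng.choice(design.sides, size=u)
        stim_seed = rng.integers(0, 2**31 - 1, size=u)
        stim_ids = [f"b{block:03d}s{k:03d}" for k in range(u)]

        n_sets = int(np.ceil(u / MAX_SET_SIZE))
        order: list[tuple[int, int]] = []  # (unique index, pass index)
        for chunk in np.array_split(np.arange(u), n_sets):
            order.extend((k, 1) for k in chunk)
            order.extend((k, 2) for k in chunk)

        for t, (k, pass_index) in enumerate(order, start=1):
            rows.append(
                {
                    "block": block,
                    "trial_in_block": t,
                    "stimulus_id": stim_ids[k],
                    "pass_index": pass_index,
                    "target_present": bool(present[k]),
                    "side": side[k],
                    "stim_seed": int(stim_seed[k]),
                }
            )
    table = pd.DataFrame(rows)
    table.index.name = "trial"
    return table


# --------------------------------------------------------------------------
# Stimuli
# --------------------------------------------------------------------------

@dataclass
class StimulusSpec:
    """Geometry and statistics of the noise patch and embedded Gabor target.

    The noise carries uniform spectral power between ``noise_band`` (cycles
    per degree) at an RMS contrast of ``noise_rms_contrast``; the target is a
    vertical grating at ``target_sf`` cpd with randomized spatial phase.
    ``pixels_per_degree`` defaults to 48, derived from the display geometry
    (74 cm viewing distance, 53.4 cm / 1920 px screen).
    """

    patch_diameter: float = 3.0           # degrees of visual angle
    noise_band: tuple[float, float] = (0.25, 4.0)   # cpd
    noise_rms_contrast: float = 0.70
    target_sf: float = 2.0                # cpd
    target_orientation: float = 0.0       # deg, 0 = vertical
    target_contrast: float = 0.15         # RMS contrast within the aperture
    pixels_per_degree: float = 48.0
    envelope_sd: Optional[float] = None   # deg; None = aperture-limited only

    @property
    def raster_size(self) -> int:
        return int(np.ceil(self.patch_diameter * self.pixels_per_degree))

    def validate(self) -> None:
        lo, hi = self.noise_band
        if not lo < hi:
            raise InvalidDesignError("noise_band lower edge must be < upper")
        if not (0.0 <= self.noise_rms_contrast <= 1.0):
            raise InvalidDesignError("noise_rms_contrast must be in [0, 1]")
        if self.pixels_per_degree < 2.0 * hi:
            raise ResolutionError(
                f"pixels_per_degree={self.pixels_per_degree} cannot sample "
                f"{hi} cpd (Nyquist)"
            )


def _pixel_grids(spec: StimulusSpec):
    n = spec.raster_size
    # pixel coordinates in degrees, centered
    axis = (np.arange(n) - (n - 1) / 2.0) / spec.pixels_per_degree
    x, y = np.meshgrid(axis, axis)
    return x, y


def aperture_mask(spec: StimulusSpec) -> np.ndarray:
    x, y = _pixel_grids(spec)
    return x**2 + y**2 <= (spec.patch_diameter / 2.0) ** 2


def generate_noise_patch(
    spec: StimulusSpec,
    rng_key,
    apply_aperture: bool = True,
) -> np.ndarray:
    """Band-limited noise patch in mean-zero contrast units.

    Uniform spectral amplitude inside ``noise_band`` with random phase,
    obtained by whitening the FFT of Gaussian noise (which preserves Hermitian
    symmetry exactly) and masking the band. A circular aperture of
    ``patch_diameter`` is applied and the in-aperture RMS contrast rescaled to
    ``noise_rms_contrast``. With ``apply_aperture=False`` the raw band-limited
    field is returned (useful for spectral checks).
    """
    spec.validate()
    rng = np.random.default_rng(rng_key)
    n = spec.raster_size
    if spec.noise_rms_contrast == 0.0:
        return np.zeros((n, n))
    z = np.fft.fft2(rng.standard_normal((n, n)))
    mag = np.abs(z)
    mag[mag == 0] = 1.0
    unit = z / mag
    f = np.fft.fftfreq(n, d=1.0 / spec.pixels_per_degree)
    fx, fy = np.meshgrid(f, f)
    radial = np.hypot(fx, fy)
    lo, hi = spec.noise_band
    band = (radial >= lo) & (radial <= hi)
    field = np.fft.ifft2(unit * band).real
    if not apply_aperture:
        rms = np.sqrt(np.mean(field**2))
        return field * (spec.noise_rms_contrast / rms)
    mask = aperture_mask(spec)
    patch = field * mask
    rms = np.sqrt(np.mean(patch[mask] ** 2))
    return patch * (spec.noise_rms_contrast / rms)


def generate_gabor(spec: StimulusSpec, phase_deg: float) -> np.ndarray:
    """Windowed sinusoid at the target SF/orientation.

    Orientation 0 deg is vertical (luminance varies only horizontally). The
    returned image is scaled so its RMS contrast within the circular aperture
    equals ``target_contrast``. If ``envelope_sd`` is set, a Gaussian envelope
    of that SD (degrees) is applied in addition to the aperture.
    """
    spec.validate()
    if spec.target_contrast <= 0:
        raise InvalidDesignError("target_contrast must be > 0")
    x, y = _pixel_grids(spec)
    theta = np.deg2rad(spec.target_orientation)
    u = x * np.cos(theta) + y * np.sin(theta)
    carrier = np.cos(2.0 * np.pi * spec.target_sf * u + np.deg2rad(phase_deg))
    if spec.envelope_sd is not None:
        carrier = carrier * np.exp(-(x**2 + y**2) / (2.0 * spec.envelope_sd**2))
    mask = aperture_mask(spec)
    patch = carrier * mask
    rms = np.sqrt(np.mean(patch[mask] ** 2))
    return patch * (spec.target_contrast / rms)


def generate_trial_stimulus(spec: StimulusSpec, row: pd.Series) -> np.ndarray:
    """Noise patch (plus target if ``target_present``) for one design row.

    The stimulus RNG key stored in the design guarantees that both members of
    a double-pass pair receive pixel-identical stimuli.
    """
    rng = np.random.default_rng(int(row["stim_seed"]))
    patch = generate_noise_patch(spec, rng)
    if row["target_present"]:
        phase = rng.uniform(0.0, 360.0)
        patch = patch + generate_gabor(spec, phase)
    return patch


# --------------------------------------------------------------------------
# Epoched EEG container
# --------------------------------------------------------------------------

@dataclass
class EpochedSeries:
    """Epoched voltages [trial x channel x sample] with time axis in seconds.

    ``times`` is relative to stimulus onset (t = 0).
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    channels: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times)
        if self.data.ndim != 3:
            raise ValueError("data must be [trial x channel x sample]")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel labels")
        if self.data.shape[2] != self.times.size:
            raise ValueError("sample axis does not match time axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.channels.index(l) for l in labels])

    def time_index(self, t: float) -> int:
        """Sample nearest to time t (seconds)."""
        return int(np.argmin(np.abs(self.times - t)))

    def to_hdf5(self, path, truth_phase_deg: Optional[np.ndarray] = None,
                **attrs) -> None:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("data", data=self.data.astype(np.float32))
            h5.create_dataset("time", data=self.times)
            h5.create_dataset(
                "channels",
                data=np.array(self.channels, dtype=h5py.string_dtype()),
            )
            h5.attrs["fs"] = self.fs
            for k, v in attrs.items():
                h5.attrs[k] = v
            if truth_phase_deg is not None:
                h5.create_dataset("truth/phase_deg", data=truth_phase_deg)

    @classmethod
    def from_hdf5(cls, path) -> tuple["EpochedSeries", Optional[np.ndarray]]:
        with h5py.File(path, "r") as h5:
            epochs = cls(
                data=h5["data"][()].astype(np.float64),
                times=h5["time"][()],
                fs=float(h5.attrs["fs"]),
                channels=[c.decode() if isinstance(c, bytes) else str(c)
                          for c in h5["channels"][()]],
            )
            truth = h5["truth/phase_deg"][()] if "truth" in h5 else None
        return epochs, truth


# --------------------------------------------------------------------------
# Alpha EEG simulation
# --------------------------------------------------------------------------

@dataclass
class AlphaEEGModel:
    """Generative model of epoched EEG around stimulus onset.

    Each trial carries an alpha oscillation at the individual alpha frequency
    ``iaf`` whose phase at t = 0 is drawn uniformly, projected onto the scalp
    with a signed dipole-like ``topography`` (posterior positive, frontal
    negative), plus independent 1/f background noise per channel.
    """

    iaf: float = 10.0                     # Hz
    alpha_amp: float = 10.0               # uV
    pink_noise_amp: float = 5.0           # uV RMS
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    topography: Optional[dict[str, float]] = None
    fs: float = 500.0
    epoch_window: tuple[float, float] = (-2.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.topography is None:
            self.topography = _default_topography(self.channel_labels)
        if not 7.0 <= self.iaf <= 14.0:
            raise InvalidDesignError("iaf must lie in [7, 14] Hz")
        if self.fs <= 2.0 * (self.iaf + 2.0):
            raise InvalidDesignError("fs must exceed 2 x (iaf + 2 Hz)")


def _pink_noise(rng: np.random.Generator, shape: tuple, fs: float) -> np.ndarray:
    """Unit-RMS 1/f-power noise along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    out = np.fft.irfft(spec * shaping, n=n, axis=-1)
    rms = np.sqrt(np.mean(out**2, axis=-1, keepdims=True))
    return out / rms


def simulate_alpha_eeg(
    table: pd.DataFrame,
    model: AlphaEEGModel,
) -> tuple[EpochedSeries, np.ndarray]:
    """Simulate epochs for every trial in ``table``.

    Returns the epoched series and the ground-truth alpha phase (degrees,
    cosine convention) of each trial at t = 0.
    """
    if len(table) == 0:
        raise EmptyDataError("trial table is empty")
    rng = np.random.default_rng(model.seed)
    n_trials = len(table)
    t0, t1 = model.epoch_window
    n_samples = int(round((t1 - t0) * model.fs))
    times = t0 + np.arange(n_samples) / model.fs
    weights = np.array([model.topography[ch] for ch in model.channel_labels])

    true_phase = rng.uniform(0.0, 360.0, size=n_trials)
    osc = np.cos(
        2.0 * np.pi * model.iaf * times[None, :]
        + np.deg2rad(true_phase)[:, None]
    )  # [trial x sample]
    data = weights[None, :, None] * model.alpha_amp * osc[:, None, :]
    if model.pink_noise_amp > 0:
        data = data + model.pink_noise_amp * _pink_noise(
            rng, (n_trials, len(model.channel_labels), n_samples), model.fs
        )
    epochs = EpochedSeries(
        data=data, times=times, fs=model.fs,
        channels=list(model.channel_labels),
    )
    return epochs, true_phase


# --------------------------------------------------------------------------
# Observers
# --------------------------------------------------------------------------

@dataclass
class ObserverModel:
    """Phase-dependent signal-detection observer.

    Three mechanisms are available (``kind``):

    ``variance_reduction``
        Evidence X ~ N(mu, sigma(phi)^2), mu = mu_n for noise trials and
        mu_n + d_prime_base * sigma0 for target trials;
        sigma(phi) = sigma0 * (1 - m * cos(phi - phi_opt)), minimal at the
        optimal phase, so hits rise *and* false alarms fall there.
    ``multiplicative_gain``
        X ~ N(g(phi) * mu, (g(phi) * sigma0)^2) with
        g(phi) = 1 + m * cos(phi - phi_opt); hits and false alarms rise
        together at the optimal phase (mu_n = 1 > 0 makes the FAR increase
        visible).
    ``template``
        Evidence is the stimulus energy profile projected onto a Gaussian
        spatial-frequency x orientation template whose tuning width broadens
        away from the optimal phase (factor ``template_sd_mod`` at the worst
        phase), plus internal noise N(0, sigma(phi)).

    Defaults reproduce the study's printed operating point: grand d' = 1.54
    and criterion 0.25 (lambda = mu_n + sigma0 * (0.25 + 1.54 / 2)), with a
    coupling depth m = 0.07 matching the printed peak-to-trough d' modulation
    of ~0.21 (~ 2 * m * d').
    """

    kind: str = "variance_reduction"
    d_prime_base: float = 1.54
    lam: float = 2.02                    # decision threshold on the evidence
    sigma0: float = 1.0
    mu_n: float = 1.0                    # noise-distribution mean
    m: float = 0.07                      # phase-modulation depth, [0, 1)
    phi_opt: float = 0.0                 # optimal phase, degrees
    template_center: tuple[float, float] = (2.0, 0.0)   # (cpd, deg)
    template_sd: tuple[float, float] = (0.9, 25.0)      # (cpd, deg)
    template_sd_mod: float = 1.3         # broadening factor at worst phase
    template_mod_profile: str = "cosine"  # or "binary"
    confidence_cutpoints: tuple[float, float, float] = (0.5, 1.0, 1.5)
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("variance_reduction", "multiplicative_gain",
                             "template"):
            raise InvalidDesignError(f"unknown observer kind {self.kind!r}")
        if not 0.0 <= self.m < 1.0:
            raise InvalidDesignError("m must be in [0, 1)")
        if self.sigma0 * (1.0 - self.m) <= 0:
            raise InvalidDesignError("sigma0 * (1 - m) must be positive")
        if np.any(np.asarray(self.template_sd) <= 0):
            raise InvalidDesignError("template_sd components must be > 0")
        if list(self.confidence_cutpoints) != sorted(self.confidence_cutpoints):
            raise InvalidDesignError("confidence_cutpoints must be increasing")

    # phase-dependent internal-noise SD (minimal at phi_opt)
    def sigma(self, phase_deg: np.ndarray) -> np.ndarray:
        dphi = np.deg2rad(np.asarray(phase_deg) - self.phi_opt)
        return self.sigma0 * (1.0 - self.m * np.cos(dphi))

    # phase-dependent evidence gain (maximal at phi_opt)
    def gain(self, phase_deg: np.ndarray) -> np.ndarray:
        dphi = np.deg2rad(np.asarray(phase_deg) - self.phi_opt)
        return 1.0 + self.m * np.cos(dphi)

    def template_width_factor(self, phase_deg: np.ndarray) -> np.ndarray:
        """Tuning-width multiplier: 1 at phi_opt, template_sd_mod at worst."""
        phase_deg = np.asarray(phase_deg, dtype=float)
        dphi = np.deg2rad(phase_deg - self.phi_opt)
        if self.template_mod_profile == "binary":
            sub = np.abs(np.angle(np.exp(1j * dphi))) >= np.pi / 2.0
            return np.where(sub, self.template_sd_mod, 1.0)
        frac = (1.0 - np.cos(dphi)) / 2.0
        return 1.0 + (self.template_sd_mod - 1.0) * frac


def analytic_rates(obs: ObserverModel, phase_deg: np.ndarray):
    """Closed-form HR(phi), FAR(phi) for the parametric observer kinds."""
    from scipy.stats import norm

    phase_deg = np.asarray(phase_deg, dtype=float)
    mu_s = obs.mu_n + obs.d_prime_base * obs.sigma0
    if obs.kind == "variance_reduction":
        sd = obs.sigma(phase_deg)
        hr = norm.sf((obs.lam - mu_s) / sd)
        far = norm.sf((obs.lam - obs.mu_n) / sd)
    elif obs.kind == "multiplicative_gain":
        g = obs.gain(phase_deg)
        hr = norm.sf((obs.lam - g * mu_s) / (g * obs.sigma0))
        far = norm.sf((obs.lam - g * obs.mu_n) / (g * obs.sigma0))
    else:
        raise InvalidDesignError("analytic rates undefined for template kind")
    return hr, far


def _template_weights(obs: ObserverModel, sf_values: np.ndarray,
                      ori_values: np.ndarray, width_factor: float) -> np.ndarray:
    """Unit-peak Gaussian template over an (sf x orientation) grid.

    Peak normalisation (rather than unit L2 norm) means broadening the
    template widens the pooling without changing the weight given to the
    best-matching feature, so broadening raises the pooled-noise variance --
    the internal-noise account of the suboptimal phase.
    """
    c_sf, c_ori = obs.template_center
    sd_sf, sd_ori = obs.template_sd
    sd_sf = sd_sf * width_factor
    sd_ori = sd_ori * width_factor
    return np.exp(
        -((sf_values[:, None] - c_sf) ** 2) / (2.0 * sd_sf**2)
        - ((ori_values[None, :] - c_ori) ** 2) / (2.0 * sd_ori**2)
    )


def simulate_observer(
    table: pd.DataFrame,
    true_phase: np.ndarray,
    obs: ObserverModel,
    energies: Optional[np.ndarray] = None,
    sf_values: Optional[np.ndarray] = None,
    ori_values: Optional[np.ndarray] = None,
    template_snr: float = 1.2,
) -> pd.DataFrame:
    """Add ``response`` (bool) and ``confidence`` (1-4) columns to ``table``.

    For the ``template`` kind, per-trial stimulus energy profiles
    (``energies`` indexed [trial x sf x ori] on the ``sf_values`` /
    ``ori_values`` grids) are required. Energies are z-scored per cell across
    trials, projected onto the phase-dependent template, and scaled by
    ``template_snr`` (template-evidence SD in units of sigma0) before internal
    noise is added; the decision threshold is placed midway between the two
    class means of the evidence ("auto" criterion).
    """
    obs.validate()
    rng = np.random.default_rng(obs.seed)
    true_phase = np.asarray(true_phase, dtype=float)
    n = len(table)
    if true_phase.shape[0] != n:
        raise InvalidDesignError("true_phase length must match table")
    target = table["target_present"].to_numpy(dtype=bool)

    if obs.kind == "template":
        if energies is None or sf_values is None or ori_values is None:
            raise InvalidDesignError(
                "template observer requires stimulus energy profiles"
            )
        ez = (energies - energies.mean(axis=0)) / energies.std(axis=0)
        widths = obs.template_width_factor(true_phase)
        # group trials by (discretised) width so template projections vectorise
        levels, inverse = np.unique(np.round(widths, 6), return_inverse=True)
        drive = np.empty(n)
        for i, wf in enumerate(levels):
            w = _template_weights(obs, np.asarray(sf_values),
                                  np.asarray(ori_values), float(wf))
            sel = inverse == i
            drive[sel] = np.tensordot(ez[sel], w, axes=([1, 2], [0, 1]))
        drive = template_snr * obs.sigma0 * drive / np.std(drive)
        evidence = drive + rng.normal(0.0, obs.sigma(true_phase))
        lam = 0.5 * (drive[target].mean() + drive[~target].mean())
    else:
        mu = np.where(target, obs.mu_n + obs.d_prime_base * obs.sigma0,
                      obs.mu_n)
        if obs.kind == "variance_reduction":
            evidence = rng.normal(mu, obs.sigma(true_phase))
        else:  # multiplicative_gain
            g = obs.gain(true_phase)
            evidence = rng.normal(g * mu, g * obs.sigma0)
        lam = obs.lam

    response = evidence > lam
    dist = np.abs(evidence - lam)
    confidence = 1 + np.searchsorted(
        np.asarray(obs.confidence_cutpoints) * obs.sigma0, dist, side="right"
    )
    out = table.copy()
    out["response"] = response
    out["confidence"] = confidence.astype(int)
    return out


# --------------------------------------------------------------------------
# Staircase (optional; default OFF in the generators above)
# --------------------------------------------------------------------------

def staircase_1up2down(
    correct: Sequence[bool],
    start: float,
    step: float,
    floor: float = 0.0,
) -> np.ndarray:
    """1-up-2-down contrast staircase trajectory (thresholding block).

    Contrast rises by ``step`` after each error, falls after two consecutive
    correct responses. Returns the contrast in force on each trial.
    """
    levels = np.empty(len(correct))
    level = start
    run = 0
    for i, ok in enumerate(correct):
        levels[i] = level
        if ok:
            run += 1
            if run == 2:
                level = max(floor, level - step)
                run = 0
        else:
            level = level + step
            run = 0
    return levels


def block_contrast_rule(
    block_dprimes: Sequence[float],
    contrast: float,
    step: float = 0.01,
    band: tuple[float, float] = (1.2, 1.8),
) -> float:
    """Between-block titration: adjust contrast when two consecutive blocks
    fall outside the target d' band."""
    if len(block_dprimes) < 2:
        return contrast
    lo, hi = band
    a, b = block_dprimes[-2], block_dprimes[-1]
    if a < lo and b < lo:
        return contrast + step
    if a > hi and b > hi:
        return max(step, contrast - step)
    return contrast


def write_trial_table(table: pd.DataFrame, path, participant: int = 1,
                      session: int = 1, contrast: float = 0.15) -> None:
    """CSV export with the documented header."""
    out = table.copy()
    out.insert(0, "participant", participant)
    out.insert(1, "session", session)
    if "contrast" not in out.columns:
        out["contrast"] = contrast
    cols = ["participant", "session", "block", "trial_in_block", "stimulus_id",
            "pass_index", "target_present", "side", "contrast"]
    for c in ("response", "confidence"):
        if c in out.columns:
            cols.append(c)
    out[cols].to_csv(path, index=False)
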