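"""Reverse correlation: classification images and phase-dependent tuning.

Each stimulus is projected onto a bank of quadrature Gabor pairs spanning
15 spatial frequencies (0.5-4 cpd) x 19 orientations (-80..80 deg, 0 =
vertical), 285 cells in all; the quadrature energy
E = sqrt((S.g_sin)^2 + (S.g_cos)^2) is phase-invariant. Energies are
z-scored per cell separately for target-present and target-absent trials and
regressed on the binary detection response with a probit link; the slope
grid (folded across orientation sign) is the classification image (CI).

Tuning differences between optimal- and suboptimal-phase trials are
quantified by fitting a 2-D Gaussian
``p1 * exp(-[(x-p2)^2/(2 p3^2) + (y-p4)^2/(2 p5^2)]) + p6`` to the optimal
CI and refitting the suboptimal CI with multiplicative modulation factors on
the gain (p1), the common tuning width (p3, p5) and the offset (p6), with a
subject-resampling bootstrap for inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import AlphaPhaseError, ResolutionError
from .coupling import circmean_deg
from .doublepass import classify_optimal
from .synthdata import StimulusSpec

N_SF, SF_RANGE = 15, (0.5, 4.0)
N_ORI, ORI_RANGE = 19, (-80.0, 80.0)
BETA_CAP = 10.0

# Gabor envelope: isotropic Gaussian with SD = this many cycles of the
# filter's own SF (~1-octave bandwidth).
ENVELOPE_CYCLES = 0.8


# --------------------------------------------------------------------------
# Filter bank and energy
# --------------------------------------------------------------------------

@dataclass
class FilterBank:
    sf_values: np.ndarray       # [15] cpd
    ori_values: np.ndarray      # [19] deg
    g_sin: np.ndarray           # [15 x 19 x h x w], unit-norm kernels
    g_cos: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.sf_values.size * self.ori_values.size

    @property
    def ori_magnitudes(self) -> np.ndarray:
        """Folded orientation axis: 0 .. max in the original step size."""
        n_half = (self.ori_values.size + 1) // 2
        return self.ori_values[self.ori_values.size // 2:]


def build_filter_bank(
    spec: StimulusSpec,
    n_sf: int = N_SF,
    sf_range: tuple[float, float] = SF_RANGE,
    n_ori: int = N_ORI,
    ori_range: tuple[float, float] = ORI_RANGE,
    envelope_cycles: float = ENVELOPE_CYCLES,
) -> FilterBank:
    """Quadrature Gabor pairs on the stimulus raster, unit energy each."""
    sf_values = np.linspace(sf_range[0], sf_range[1], n_sf)
    ori_values = np.linspace(ori_range[0], ori_range[1], n_ori)
    n = spec.raster_size
    if n / spec.pixels_per_degree < 1.0 / sf_values[0]:
        raise ResolutionError(
            "raster holds less than one full cycle of the lowest SF"
        )
    axis = (np.arange(n) - (n - 1) / 2.0) / spec.pixels_per_degree
    x, y = np.meshgrid(axis, axis)
    g_sin = np.empty((n_sf, n_ori, n, n))
    g_cos = np.empty_like(g_sin)
    for i, sf in enumerate(sf_values):
        env = np.exp(-(x**2 + y**2) / (2.0 * (envelope_cycles / sf) ** 2))
        for j, ori in enumerate(ori_values):
            th = np.deg2rad(ori)
            u = x * np.cos(th) + y * np.sin(th)
            carrier = 2.0 * np.pi * sf * u
            ks = env * np.sin(carrier)
            kc = env * np.cos(carrier)
            g_sin[i, j] = ks / np.linalg.norm(ks)
            g_cos[i, j] = kc / np.linalg.norm(kc)
    return FilterBank(sf_values=sf_values, ori_values=ori_values,
                      g_sin=g_sin, g_cos=g_cos)


def stimulus_energy(image: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Quadrature energy of one stimulus per (sf, orientation) cell."""
    if image.shape != bank.g_sin.shape[-2:]:
        raise ValueError("stimulus raster does not match the filter bank")
    s = np.tensordot(bank.g_sin, image, axes=([2, 3], [0, 1]))
    c = np.tensordot(bank.g_cos, image, axes=([2, 3], [0, 1]))
    return np.sqrt(s**2 + c**2)


def energy_profiles(stimuli: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Energies for a stack of stimuli [trial x h x w] -> [trial x sf x ori]."""
    n_sf, n_ori, h, w = bank.g_sin.shape
    flat = np.concatenate(
        [bank.g_sin.reshape(n_sf * n_ori, h * w),
         bank.g_cos.reshape(n_sf * n_ori, h * w)]
    )
    proj = stimuli.reshape(stimuli.shape[0], h * w) @ flat.T
    s, c = proj[:, : n_sf * n_ori], proj[:, n_sf * n_ori:]
    return np.sqrt(s**2 + c**2).reshape(-1, n_sf, n_ori)


def normalize_energy(raw: np.ndarray, target_present: np.ndarray) -> np.ndarray:
    """Z-score energies per (sf, ori) cell within each stimulus condition,
    so the CI reflects trial-to-trial feature fluctuations above and beyond
    the target energy itself."""
    target_present = np.asarray(target_present, dtype=bool)
    out = np.empty_like(raw, dtype=float)
    for cond in (target_present, ~target_present):
        if cond.sum() < 2:
            raise AlphaPhaseError("need >= 2 trials in each condition")
        mu = raw[cond].mean(axis=0)
        sd = raw[cond].std(axis=0)
        if np.any(sd == 0):
            raise AlphaPhaseError("degenerate stimulus set: zero-variance cell")
        out[cond] = (raw[cond] - mu) / sd
    return out


# --------------------------------------------------------------------------
# Probit classification image
# --------------------------------------------------------------------------

def probit_ci(
    energies_norm: np.ndarray,
    responses: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """285 single-regressor probit regressions p(yes) = Phi(b0 + b1 * E).

    Returns the slope grid beta1 [sf x ori] (the classification image) and
    the intercepts beta0. Cells with perfect separation or non-convergence
    get their slope capped at +/-10 with a warning.
    """
    import statsmodels.api as sm

    y = np.asarray(responses, dtype=float)
    if y.min() == y.max():
        raise AlphaPhaseError("both response classes must be present")
    n_trials, n_sf, n_ori = energies_norm.shape
    beta1 = np.empty((n_sf, n_ori))
    beta0 = np.empty((n_sf, n_ori))
    X0 = np.ones((n_trials, 2))
    n_capped = 0
    for i in range(n_sf):
        for j in range(n_ori):
            X0[:, 1] = energies_norm[:, i, j]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Probit(y, X0).fit(disp=0, tol=1e-8, maxiter=100)
                b0, b1 = res.params
            except Exception:
                b0, b1 = 0.0, np.inf
            if not np.isfinite(b1) or abs(b1) > BETA_CAP:
                b1 = np.clip(b1, -BETA_CAP, BETA_CAP)
                if not np.isfinite(b1):
                    b1 = BETA_CAP
                n_capped += 1
            beta1[i, j] = b1
            beta0[i, j] = b0 if np.isfinite(b0) else 0.0
    if n_capped:
        warnings.warn(f"{n_capped} cells showed separation; slopes capped at "
                      f"+/-{BETA_CAP}", stacklevel=2)
    return beta1, beta0


def fold_orientations(grid: np.ndarray, ori_values: Optional[np.ndarray] = None
                      ) -> np.ndarray:
    """Average columns at +theta and -theta; 0 deg column unchanged.

    Output is [sf x (n_ori + 1) / 2] with orientation magnitudes ascending.
    Folding is idempotent on an already-symmetric grid.
    """
    grid = np.asarray(grid, dtype=float)
    n_ori = grid.shape[1]
    if ori_values is None:
        ori_values = np.linspace(ORI_RANGE[0], ORI_RANGE[1], n_ori)
    if not np.allclose(ori_values + ori_values[::-1], 0.0):
        raise ValueError("orientation grid must be symmetric about 0")
    mid = n_ori // 2
    folded = np.empty((grid.shape[0], mid + 1))
    folded[:, 0] = grid[:, mid]
    for j in range(1, mid + 1):
        folded[:, j] = 0.5 * (grid[:, mid + j] + grid[:, mid - j])
    return folded


# --------------------------------------------------------------------------
# 2-D Gaussian fits
# --------------------------------------------------------------------------

@dataclass
class GaussFit:
    p: np.ndarray          # p1 gain, p2 x-center, p3 x-SD, p4 y-center,
                           # p5 y-SD, p6 offset
    r2: float

    @property
    def gain(self): return self.p[0]
    @property
    def center(self): return (self.p[1], self.p[3])
    @property
    def sds(self): return (self.p[2], self.p[4])
    @property
    def offset(self): return self.p[5]


def _gauss2d(p, x, y):
    return p[0] * np.exp(
        -((x - p[1]) ** 2 / (2.0 * p[2] ** 2)
          + (y - p[3]) ** 2 / (2.0 * p[4] ** 2))
    ) + p[5]


def _r2(data, model):
    ss_res = np.sum((data - model) ** 2)
    ss_tot = np.sum((data - data.mean()) ** 2)
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_gauss2d(
    folded: np.ndarray,
    sf_values: np.ndarray,
    ori_mag_values: np.ndarray,
    n_starts: int = 5,
    seed: int = 0,
) -> GaussFit:
    """Least-squares 2-D Gaussian fit over the folded (sf x |ori|) grid.

    Multi-start: center initialised at the grid argmax plus jittered
    restarts; the best-loss solution is returned.
    """
    folded = np.asarray(folded, dtype=float)
    x, y = np.meshgrid(sf_values, ori_mag_values, indexing="ij")
    flat = folded.ravel()

    def resid(p):
        return _gauss2d(p, x, y).ravel() - flat

    imax = np.unravel_index(np.argmax(folded), folded.shape)
    x_span = sf_values[-1] - sf_values[0]
    y_span = ori_mag_values[-1] - ori_mag_values[0]
    base = np.array([
        folded.max() - folded.min() or 1.0,
        sf_values[imax[0]], 0.25 * x_span or 1.0,
        ori_mag_values[imax[1]], 0.25 * y_span or 1.0,
        folded.min(),
    ])
    lo = [-np.inf, sf_values[0] - x_span, 1e-3, ori_mag_values[0] - y_span,
          1e-3, -np.inf]
    hi = [np.inf, sf_values[-1] + x_span, 10 * x_span,
          ori_mag_values[-1] + y_span, 10 * y_span, np.inf]
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        p0 = base.copy()
        if k > 0:
            p0[1] += rng.normal(0, 0.15 * x_span)
            p0[3] += rng.normal(0, 0.15 * y_span)
            p0[2] *= rng.uniform(0.5, 2.0)
            p0[4] *= rng.uniform(0.5, 2.0)
        p0 = np.clip(p0, lo, hi)
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise AlphaPhaseError("2-D Gaussian fit failed from every start")
    return GaussFit(p=best.x, r2=_r2(flat, _gauss2d(best.x, x, y).ravel()))


@dataclass
class ModulationFit:
    gain_mod: float
    sd_mod: float
    offset_mod: float
    center: tuple[float, float]
    r2: float
    offset_absolute: bool = False   # True when p6 = 0 made the ratio undefined


def fit_modulation(
    optimal: GaussFit,
    suboptimal_folded: np.ndarray,
    sf_values: np.ndarray,
    ori_mag_values: np.ndarray,
) -> ModulationFit:
    """Refit the suboptimal CI with the optimal-phase Gaussian scaled by
    three multiplicative modulation factors (gain, common SD, offset); the
    center stays free. Factors of 1 mean no change between phases."""
    folded = np.asarray(suboptimal_folded, dtype=float)
    x, y = np.meshgrid(sf_values, ori_mag_values, indexing="ij")
    flat = folded.ravel()
    p1, px, sx, py, sy, p6 = (optimal.p[0], optimal.p[1], optimal.p[2],
                              optimal.p[3], optimal.p[4], optimal.p[5])
    offset_absolute = abs(p6) < 1e-12

    def model(q):
        gain_mod, cx, cy, sd_mod, off = q
        offset = off if offset_absolute else off * p6
        return (gain_mod * p1) * np.exp(
            -((x - cx) ** 2 / (2.0 * (sd_mod * sx) ** 2)
              + (y - cy) ** 2 / (2.0 * (sd_mod * sy) ** 2))
        ) + offset

    def resid(q):
        return model(q).ravel() - flat

    q0 = np.array([1.0, px, py, 1.0, 0.0 if offset_absolute else 1.0])
    x_span = sf_values[-1] - sf_values[0]
    y_span = ori_mag_values[-1] - ori_mag_values[0]
    lo = [-np.inf, sf_values[0] - x_span, ori_mag_values[0] - y_span,
          1e-3, -np.inf]
    hi = [np.inf, sf_values[-1] + x_span, ori_mag_values[-1] + y_span,
          100.0, np.inf]
    sol = least_squares(resid, q0, bounds=(lo, hi), method="trf")
    gain_mod, cx, cy, sd_mod, off = sol.x
    if offset_absolute:
        warnings.warn("optimal-fit offset is 0; reporting absolute offset",
                      stacklevel=2)
    return ModulationFit(
        gain_mod=float(gain_mod), sd_mod=float(sd_mod),
        offset_mod=float(off), center=(float(cx), float(cy)),
        r2=_r2(flat, model(sol.x).ravel()),
        offset_absolute=offset_absolute,
    )


# --------------------------------------------------------------------------
# Bootstrap inference
# --------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    gain_mod: np.ndarray        # [n_boot]
    sd_mod: np.ndarray
    offset_mod: np.ndarray
    diff_draws: np.ndarray      # [n_boot x sf x |ori|], suboptimal - optimal
    p_gain: float
    p_sd: float
    p_offset: float
    n_refits: int


def _two_sided_p(draws: np.ndarray, null_value: float) -> float:
    lo = np.mean(draws <= null_value)
    hi = np.mean(draws >= null_value)
    return float(np.clip(2.0 * min(lo, hi), 0.0, 1.0))


def bootstrap_compare(
    ci_optimal: np.ndarray,
    ci_suboptimal: np.ndarray,
    sf_values: np.ndarray,
    ori_mag_values: np.ndarray,
    n_boot: int = 10000,
    seed: int = 0,
) -> BootstrapResult:
    """Subject-resampling bootstrap of the Gaussian modulation factors.

    ``ci_optimal`` / ``ci_suboptimal`` hold per-subject folded CIs
    [n_subjects x sf x |ori|]. Each iteration resamples subjects with
    replacement, averages the CIs, fits the optimal-phase Gaussian and the
    suboptimal modulation factors; failed fits are resampled (counted).
    Two-sided bootstrap p-values compare each factor's distribution to 1.
    """
    rng = np.random.default_rng(seed)
    n_subj = ci_optimal.shape[0]
    if n_subj < 2:
        raise AlphaPhaseError("bootstrap needs >= 2 subjects")
    gain = np.empty(n_boot)
    sd = np.empty(n_boot)
    off = np.empty(n_boot)
    diffs = np.empty((n_boot,) + ci_optimal.shape[1:])
    n_refits = 0
    b = 0
    while b < n_boot:
        pick = rng.integers(0, n_subj, size=n_subj)
        opt = ci_optimal[pick].mean(axis=0)
        sub = ci_suboptimal[pick].mean(axis=0)
        try:
            fit_opt = fit_gauss2d(opt, sf_values, ori_mag_values,
                                  seed=int(rng.integers(2**31 - 1)))
            fit_mod = fit_modulation(fit_opt, sub, sf_values, ori_mag_values)
        except AlphaPhaseError:
            n_refits += 1
            if n_refits > 10 * n_boot:
                raise
            continue
        gain[b] = fit_mod.gain_mod
        sd[b] = fit_mod.sd_mod
        off[b] = fit_mod.offset_mod
        diffs[b] = sub - opt
        b += 1
    return BootstrapResult(
        gain_mod=gain, sd_mod=sd, offset_mod=off, diff_draws=diffs,
        p_gain=_two_sided_p(gain, 1.0),
        p_sd=_two_sided_p(sd, 1.0),
        p_offset=_two_sided_p(off, 1.0),
        n_refits=n_refits,
    )


def difference_ci(diff_draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Model-free difference CI (suboptimal - optimal).

    Returns the mean difference grid and a per-cell two-sided bootstrap
    p-value against 0. Positive cells indicate heavier weighting of that
    feature during the suboptimal phase. No multiple-comparison correction
    is applied (flagged in the pipeline report).
    """
    draws = np.asarray(diff_draws, dtype=float)
    mean = draws.mean(axis=0)
    lo = np.mean(draws <= 0.0, axis=0)
    hi = np.mean(draws >= 0.0, axis=0)
    p = np.clip(2.0 * np.minimum(lo, hi), 0.0, 1.0)
    return mean, p


def simulate_ci_cohort(
    sf_values: np.ndarray,
    ori_mag_values: np.ndarray,
    n_subjects: int = 6,
    params: Sequence[float] = (0.5, 2.0, 0.8, 0.0, 22.0, 0.05),
    sd_mod: float = 1.3,
    gain_mod: float = 1.0,
    offset_mod: float = 1.0,
    subject_jitter: float = 0.10,
    mod_jitter: float = 0.08,
    noise_sd_frac: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic model-based cohort of folded classification images.

    Per-subject optimal-phase CIs are drawn from the 2-D Gaussian CI model
    (``params`` = p1..p6) with multiplicative subject jitter on gain/SDs and
    additive jitter on the center; the suboptimal CI applies the population
    modulation factors, each multiplied by a subject-specific lognormal
    deviation (``mod_jitter``), to the same subject's parameters -- the two
    phase splits come from disjoint trials, so their effects vary by subject.
    IID cell noise with SD ``noise_sd_frac * p1`` is added to both grids.
    Synthetic stand-in for a measured cohort; used to study the
    modulation-factor estimator itself.
    """
    rng = np.random.default_rng(seed)
    x, y = np.meshgrid(sf_values, ori_mag_values, indexing="ij")
    p1, p2, p3, p4, p5, p6 = params
    ci_opt = np.empty((n_subjects, sf_values.size, ori_mag_values.size))
    ci_sub = np.empty_like(ci_opt)
    for s in range(n_subjects):
        j = rng.normal(1.0, subject_jitter, size=3)
        ps = [p1 * j[0], p2 + rng.normal(0, 0.1), p3 * j[1],
              p4 + abs(rng.normal(0, 2.0)), p5 * j[2], p6]
        sd_s, gain_s, off_s = (
            sd_mod * rng.lognormal(0.0, mod_jitter),
            gain_mod * rng.lognormal(0.0, mod_jitter),
            offset_mod * rng.lognormal(0.0, mod_jitter),
        )
        qs = [ps[0] * gain_s, ps[1], ps[2] * sd_s, ps[3], ps[4] * sd_s,
              ps[5] * off_s]
        ci_opt[s] = _gauss2d(ps, x, y) + rng.normal(0, noise_sd_frac * p1,
                                                    x.shape)
        ci_sub[s] = _gauss2d(qs, x, y) + rng.normal(0, noise_sd_frac * p1,
                                                    x.shape)
    return ci_opt, ci_sub


# --------------------------------------------------------------------------
# Phase split
# --------------------------------------------------------------------------

def split_trials_by_phase(
    phase: np.ndarray,
    theta: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = (-0.450, 0.0),
    at_time: float = 0.0,
) -> np.ndarray:
    """Classify each trial as optimal-phase (True) or suboptimal (False).

    Per channel, the trial's phase at ``at_time`` (stimulus onset) is
    compared with the time-averaged (circular mean over ``window``)
    resultant angle of that channel; the per-channel votes are combined by
    strict majority, ties counting as suboptimal. One split per trial, so a
    single set of 285 regressions describes each phase.
    """
    phase = np.asarray(phase, dtype=float)
    theta = np.asarray(theta, dtype=float)
    sel = (times >= window[0]) & (times <= window[1])
    theta_avg = np.array([circmean_deg(theta[c, sel]) for c in
                          range(theta.shape[0])])
    s0 = int(np.argmin(np.abs(times - at_time)))
    votes = np.stack(
        [classify_optimal(phase[:, c, s0], theta_avg[c])
         for c in range(phase.shape[1])],
        axis=1,
    )
    return votes.sum(axis=1) > phase.shape[1] / 2.0
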