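"""Phase-behavior coupling: binned SDT metrics, resultant vectors, and
permutation/cluster inference.

The statistic: at each time point and channel, trials are sorted into eight
phase bins; a behavioral metric (d', c, HR or FAR) is computed per bin with
the loglinear correction; the eight values are treated as vectors (length =
metric value, angle = bin center) and summed. The resultant length rho
quantifies phase-behavior coupling, the resultant angle theta points to the
optimal phase. Under phase independence the eight vectors cancel and rho
approaches zero.

Inference: rho series are compared with the 95th percentile of a permutation
null obtained by shuffling the behavior labels against the trials and
re-running the identical chain (binning, correction, resultant, channel
average, smoothing); runs of temporally adjacent supra-threshold samples are
cluster-corrected against the per-permutation maximum cluster size. Subject
counts of significant coupling feed a one-sided binomial replication test,
and phase-opposition hypotheses (HR vs FAR, frontal vs occipital) are tested
with a circular V-test against a 180 deg mean direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import binom, norm

from .errors import DegenerateTestError
from .phaseprep import PhaseBins
from .sdt import rates_from_counts

METRICS = ("dprime", "criterion", "hr", "far")


# --------------------------------------------------------------------------
# Circular helpers
# --------------------------------------------------------------------------

def circdist_deg(a, b):
    """Signed circular difference a - b in (-180, 180] degrees."""
    return -np.degrees(np.angle(np.exp(1j * np.deg2rad(np.asarray(b) - np.asarray(a)))))


def circmean_deg(angles_deg, axis=None):
    """Circular mean in [0, 360) degrees."""
    z = np.exp(1j * np.deg2rad(np.asarray(angles_deg, dtype=float)))
    return np.mod(np.degrees(np.angle(np.mean(z, axis=axis))), 360.0)


# --------------------------------------------------------------------------
# Binned metrics and resultant vectors
# --------------------------------------------------------------------------

@dataclass
class BinnedMetric:
    """A behavioral metric evaluated in each of the 8 phase bins."""

    values: np.ndarray
    n_trials_per_bin: np.ndarray
    metric_name: str
    centers: np.ndarray = field(
        default_factory=lambda: PhaseBins().centers)
    degenerate: np.ndarray = None  # bins missing one response class

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.degenerate is None:
            self.degenerate = np.zeros(self.values.shape, dtype=bool)


def _metric_from_counts(n_hit, n_signal, n_fa, n_noise, metric: str):
    hr, far = rates_from_counts(n_hit, n_signal, n_fa, n_noise)
    if metric == "hr":
        return hr
    if metric == "far":
        return far
    zh, zf = ndtri(hr), ndtri(far)
    if metric == "dprime":
        return zh - zf
    if metric == "criterion":
        return -0.5 * (zh + zf)
    raise ValueError(f"unknown metric {metric!r}")


def binned_metric(
    trials: pd.DataFrame,
    phase_bin_index: np.ndarray,
    metric: str = "dprime",
    bins: PhaseBins | None = None,
) -> BinnedMetric:
    """Per-bin behavioral metric with loglinear-corrected rates.

    ``phase_bin_index`` holds 1-based bin indices per trial. Bins missing one
    of the two stimulus classes remain defined through the correction but are
    flagged as degenerate.
    """
    bins = bins or PhaseBins()
    b = np.asarray(phase_bin_index, dtype=int) - 1
    target = trials["target_present"].to_numpy(dtype=bool)
    response = trials["response"].to_numpy(dtype=bool)
    nb = bins.n_bins
    n_signal = np.bincount(b[target], minlength=nb)
    n_hit = np.bincount(b[target & response], minlength=nb)
    n_noise = np.bincount(b[~target], minlength=nb)
    n_fa = np.bincount(b[~target & response], minlength=nb)
    values = _metric_from_counts(n_hit, n_signal, n_fa, n_noise, metric)
    return BinnedMetric(
        values=values,
        n_trials_per_bin=n_signal + n_noise,
        metric_name=metric,
        centers=bins.centers,
        degenerate=(n_signal == 0) | (n_noise == 0),
    )


def resultant_vector(
    bm: BinnedMetric | np.ndarray,
    mode: str = "sum",
    centers: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """Resultant (rho, theta_deg) of metric-length vectors at the bin centers.

    ``mode='sum'`` sums the eight vectors; ``mode='mean'`` divides by the bin
    count. A sinusoidal profile a + A*cos(theta_b - phi) on 8 equispaced bins
    gives rho = 4A (sum mode) and theta = phi exactly; a constant profile
    gives rho = 0.
    """
    if isinstance(bm, BinnedMetric):
        values = bm.values
        centers = bm.centers
    else:
        values = np.asarray(bm, dtype=float)
        centers = PhaseBins().centers if centers is None else np.asarray(centers)
    z = np.sum(values * np.exp(1j * np.deg2rad(centers)))
    if mode == "mean":
        z = z / values.size
    elif mode != "sum":
        raise ValueError("mode must be 'sum' or 'mean'")
    rho = float(np.abs(z))
    theta = float(np.mod(np.degrees(np.angle(z)), 360.0)) if rho > 0 else np.nan
    return rho, theta


def smooth_series(series: np.ndarray, fs: float = 150.0,
                  window: float = 0.050, axis: int = -1) -> np.ndarray:
    """Centered moving mean over ``window`` seconds (odd sample count,
    shrinking at the edges); output length unchanged."""
    x = np.asarray(series, dtype=float)
    w = int(np.floor(window * fs))
    if w % 2 == 0:
        w += 1
    if w <= 1:
        return x.copy()
    x = np.moveaxis(x, axis, -1)
    kernel = np.ones(w)
    pad = np.apply_along_axis(np.convolve, -1, x, kernel, "same")
    counts = np.convolve(np.ones(x.shape[-1]), kernel, "same")
    out = pad / counts
    return np.moveaxis(out, -1, axis)


# --------------------------------------------------------------------------
# Vectorised coupling chain over [trial x channel x sample]
# --------------------------------------------------------------------------

@dataclass
class ResultantSeries:
    """Coupling statistic over the analysis grid.

    ``rho``/``theta`` are per [channel x sample]; ``rho_avg`` is the
    channel-averaged, time-smoothed length used for inference, with its
    permutation ``threshold`` and cluster labels/p-values attached by
    :func:`permutation_null` / :func:`cluster_correct`.
    """

    rho: np.ndarray
    theta: np.ndarray
    rho_avg: np.ndarray
    times: np.ndarray
    channels: list[str]
    metric: str
    mode: str
    threshold: Optional[np.ndarray] = None
    null_rho: Optional[np.ndarray] = None
    clusters: Optional[list] = None


def _encode(target: np.ndarray, response: np.ndarray) -> np.ndarray:
    """Trial outcome code 0..3: 2*target + response."""
    return (2 * target.astype(int) + response.astype(int)).astype(np.int64)


def _chain_rho(
    static_idx: np.ndarray,
    code: np.ndarray,
    shape_cs: tuple[int, int],
    n_bins: int,
    centers_z: np.ndarray,
    metric: str,
    mode: str,
    fs: float,
    smooth_window: float,
    return_complex: bool = False,
):
    """One pass of the full chain: counts -> rates -> metric -> resultant ->
    channel average -> temporal smoothing."""
    C, S = shape_cs
    idx = static_idx + code[:, None, None]
    counts = np.bincount(idx.ravel(), minlength=C * S * n_bins * 4)
    counts = counts.reshape(C, S, n_bins, 4).astype(float)
    n_noise = counts[..., 0] + counts[..., 1]
    n_fa = counts[..., 1]
    n_signal = counts[..., 2] + counts[..., 3]
    n_hit = counts[..., 3]
    values = _metric_from_counts(n_hit, n_signal, n_fa, n_noise, metric)
    z = values @ centers_z  # [C, S] complex resultant (sum mode)
    if mode == "mean":
        z = z / n_bins
    rho = np.abs(z)
    rho_avg = smooth_series(rho.mean(axis=0), fs=fs, window=smooth_window)
    if return_complex:
        return rho_avg, z
    return rho_avg


def coupling_series(
    bin_idx: np.ndarray,
    target: np.ndarray,
    response: np.ndarray,
    metric: str = "dprime",
    mode: str = "sum",
    fs: float = 150.0,
    smooth_window: float = 0.050,
    times: Optional[np.ndarray] = None,
    channels: Optional[Sequence[str]] = None,
    bins: PhaseBins | None = None,
) -> ResultantSeries:
    """Observed coupling over a [trial x channel x sample] bin-index grid."""
    bins = bins or PhaseBins()
    bin_idx = np.asarray(bin_idx, dtype=np.int64)
    T, C, S = bin_idx.shape
    static_idx = _static_index(bin_idx, bins.n_bins)
    centers_z = np.exp(1j * np.deg2rad(bins.centers))
    code = _encode(np.asarray(target, bool), np.asarray(response, bool))
    rho_avg, z = _chain_rho(
        static_idx, code, (C, S), bins.n_bins, centers_z, metric, mode,
        fs, smooth_window, return_complex=True,
    )
    return ResultantSeries(
        rho=np.abs(z),
        theta=np.mod(np.degrees(np.angle(z)), 360.0),
        rho_avg=rho_avg,
        times=np.arange(S) / fs if times is None else np.asarray(times),
        channels=list(channels) if channels is not None else
                 [f"ch{i}" for i in range(C)],
        metric=metric,
        mode=mode,
    )


def binned_values_grid(
    bin_idx: np.ndarray,
    target: np.ndarray,
    response: np.ndarray,
    metric: str = "dprime",
    bins: PhaseBins | None = None,
) -> np.ndarray:
    """Per-bin metric values over a [trial x channel x sample] grid.

    Returns [channel x sample x n_bins]; the same counts -> loglinear ->
    metric chain as :func:`coupling_series`, without the resultant step.
    """
    bins = bins or PhaseBins()
    bin_idx = np.asarray(bin_idx, dtype=np.int64)
    T, C, S = bin_idx.shape
    static_idx = _static_index(bin_idx, bins.n_bins)
    code = _encode(np.asarray(target, bool), np.asarray(response, bool))
    idx = static_idx + code[:, None, None]
    counts = np.bincount(idx.ravel(), minlength=C * S * bins.n_bins * 4)
    counts = counts.reshape(C, S, bins.n_bins, 4).astype(float)
    n_noise = counts[..., 0] + counts[..., 1]
    n_fa = counts[..., 1]
    n_signal = counts[..., 2] + counts[..., 3]
    n_hit = counts[..., 3]
    return _metric_from_counts(n_hit, n_signal, n_fa, n_noise, metric)


def _static_index(bin_idx: np.ndarray, n_bins: int) -> np.ndarray:
    """Flat count index per (trial, channel, sample), before the outcome code."""
    T, C, S = bin_idx.shape
    cell = np.arange(C * S, dtype=np.int64).reshape(1, C, S)
    return (cell * n_bins + (bin_idx - 1)) * 4


def permutation_null(
    bin_idx: np.ndarray,
    target: np.ndarray,
    response: np.ndarray,
    metric: str = "dprime",
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    mode: str = "sum",
    fs: float = 150.0,
    smooth_window: float = 0.050,
    percentile: float = 95.0,
    bins: PhaseBins | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation null of the coupling chain.

    Behavior labels (target, response) are shuffled jointly against the
    trials, breaking the EEG-behavior mapping while keeping each trial's
    phase structure; the full chain is recomputed identically for every
    permutation. Returns the per-sample ``percentile`` threshold and the full
    null rho distribution [n_perm x sample].
    """
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation quantiles are unstable",
                      stacklevel=2)
    bins = bins or PhaseBins()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    bin_idx = np.asarray(bin_idx, dtype=np.int64)
    T, C, S = bin_idx.shape
    static_idx = _static_index(bin_idx, bins.n_bins)
    centers_z = np.exp(1j * np.deg2rad(bins.centers))
    code = _encode(np.asarray(target, bool), np.asarray(response, bool))
    null = np.empty((n_perm, S))
    for p in range(n_perm):
        null[p] = _chain_rho(
            static_idx, code[rng.permutation(T)], (C, S), bins.n_bins,
            centers_z, metric, mode, fs, smooth_window,
        )
    # discrete upper order statistic (no interpolation): conservative at
    # finite permutation counts
    threshold = np.percentile(null, percentile, axis=0, method="higher")
    return threshold, null


# --------------------------------------------------------------------------
# Cluster correction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Cluster:
    start: int          # first supra-threshold sample (inclusive)
    stop: int           # last supra-threshold sample (inclusive)
    size: int           # number of temporally adjacent samples
    p: float            # fraction of permutations with max size >= this
    significant: bool   # p < 0.05


def _cluster_sizes(above: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, stop, size) of runs of True in a boolean series."""
    runs = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((i, j, j - i + 1))
            i = j + 1
        else:
            i += 1
    return runs


def cluster_correct(
    real_rho: np.ndarray,
    threshold: np.ndarray,
    null_rho: np.ndarray,
    alpha: float = 0.05,
) -> list[Cluster]:
    """Cluster correction with a max-statistic null.

    Supra-threshold runs of the observed series form clusters; each
    permutation's own supra-threshold series contributes its *maximum*
    cluster size to the null; a cluster's p-value is the fraction of
    permutations whose max size is at least as large.
    """
    real_rho = np.asarray(real_rho, dtype=float)
    threshold = np.asarray(threshold, dtype=float)
    null_rho = np.asarray(null_rho, dtype=float)
    observed = _cluster_sizes(real_rho > threshold)
    if not observed:
        return []
    null_max = np.zeros(null_rho.shape[0], dtype=int)
    for p in range(null_rho.shape[0]):
        runs = _cluster_sizes(null_rho[p] > threshold)
        if runs:
            null_max[p] = max(r[2] for r in runs)
    clusters = []
    for start, stop, size in observed:
        pval = float(np.mean(null_max >= size))
        clusters.append(Cluster(start=start, stop=stop, size=size, p=pval,
                                significant=pval < alpha))
    return clusters


def subject_significance(
    real_rho: np.ndarray,
    null_rho: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = (-0.450, 0.0),
    percentile: float = 95.0,
) -> tuple[bool, float, float]:
    """Per-subject replication criterion: time-averaged observed rho over
    ``window`` vs the same percentile of time-averaged permuted rho."""
    sel = (times >= window[0]) & (times <= window[1])
    real_avg = float(np.mean(np.asarray(real_rho)[sel]))
    null_avg = np.mean(np.asarray(null_rho)[:, sel], axis=1)
    thr = float(np.percentile(null_avg, percentile, method="higher"))
    return real_avg > thr, real_avg, thr


def binomial_replication(k_significant: int, n_subjects: int,
                         alpha: float = 0.05) -> float:
    """P(X >= k | n, alpha): chance probability of observing at least
    ``k_significant`` significant subjects out of ``n_subjects``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 <= k_significant <= n_subjects:
        raise ValueError("k must satisfy 0 <= k <= n")
    return float(binom.sf(k_significant - 1, n_subjects, alpha))


# --------------------------------------------------------------------------
# Circular tests and alignment
# --------------------------------------------------------------------------

def vtest(angles_deg: Sequence[float], mu0_deg: float) -> tuple[float, float]:
    """Circular V-test for concentration around a prespecified direction.

    V = R * cos(theta_bar - mu0) with R the unnormalised sample resultant
    length; u = V * sqrt(2 / n) is referred to the upper tail of the standard
    normal. An all-cancelling sample (R = 0) returns (0, 0.5).
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size < 2:
        raise DegenerateTestError("V-test needs at least 2 angles")
    z = np.sum(np.exp(1j * np.deg2rad(angles)))
    r = np.abs(z)
    if r < 1e-12:
        return 0.0, 0.5
    v = r * np.cos(np.angle(z) - np.deg2rad(mu0_deg))
    u = v * np.sqrt(2.0 / angles.size)
    return float(v), float(norm.sf(u))


def align_to_best_bin(
    metrics: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Align per-subject bin profiles to each subject's best-d' bin.

    ``metrics`` maps names (must include 'dprime') to [n_subjects x 8]
    arrays. Each subject's profiles are circularly shifted so the bin with
    the highest d' lands at bin 8 (argmax ties break toward the lowest bin
    index); bin 8 is then dropped. Returns shifted [n_subjects x 7] arrays
    plus '<name>_mean' group averages (visualisation only; no inference).
    """
    d = np.asarray(metrics["dprime"], dtype=float)
    if d.ndim != 2 or d.shape[1] != 8:
        raise ValueError("expect [n_subjects x 8] arrays")
    shifts = 7 - np.argmax(d, axis=1)
    out: dict[str, np.ndarray] = {}
    for name, arr in metrics.items():
        arr = np.asarray(arr, dtype=float)
        shifted = np.stack(
            [np.roll(arr[s], shifts[s]) for s in range(arr.shape[0])]
        )
        out[name] = shifted[:, :7]
        out[f"{name}_mean"] = out[name].mean(axis=0)
    return out


def phase_difference_series(angles_a_deg, angles_b_deg) -> float:
    """Circular mean (degrees, [0, 360)) of per-index circular differences
    a - b; feeds V-tests of phase opposition (mu0 = 180)."""
    a = np.asarray(angles_a_deg, dtype=float)
    b = np.asarray(angles_b_deg, dtype=float)
    if a.shape != b.shape:
        raise ValueError("angle series must have matching shapes")
    return float(circmean_deg((a - b).ravel()))
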