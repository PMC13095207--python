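"""Equal-variance signal-detection metrics with loglinear correction.

d' = z(HR) - z(FAR) and c = -(z(HR) + z(FAR)) / 2, where z is the inverse
standard-normal CDF. Rates are corrected by adding 0.5 to each count and 1 to
each trial total (the standard loglinear correction), which keeps both rates
strictly inside (0, 1) even for empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri


@dataclass(frozen=True)
class RateCounts:
    n_hit: int
    n_signal: int
    n_fa: int
    n_noise: int

    def __post_init__(self):
        if min(self.n_hit, self.n_signal, self.n_fa, self.n_noise) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_hit > self.n_signal or self.n_fa > self.n_noise:
            raise ValueError("hits/false alarms cannot exceed trial counts")


@dataclass(frozen=True)
class SdtMetrics:
    hr: float
    far: float
    d_prime: float
    criterion: float


def loglinear_rates(counts: RateCounts) -> tuple[float, float]:
    """Corrected (HR, FAR): (count + 0.5) / (total + 1), strictly in (0, 1)."""
    if counts.n_signal + counts.n_noise <= 0:
        raise ValueError("need at least one trial")
    hr = (counts.n_hit + 0.5) / (counts.n_signal + 1.0)
    far = (counts.n_fa + 0.5) / (counts.n_noise + 1.0)
    return hr, far


def dprime_criterion(hr: float, far: float) -> SdtMetrics:
    """Sensitivity and criterion from (corrected) rates in the open unit
    interval."""
    if not (0.0 < hr < 1.0 and 0.0 < far < 1.0):
        raise ValueError("rates must lie strictly in (0, 1); correct them first")
    zh, zf = ndtri(hr), ndtri(far)
    return SdtMetrics(hr=hr, far=far, d_prime=zh - zf,
                      criterion=-0.5 * (zh + zf))


def rates_from_counts(n_hit, n_signal, n_fa, n_noise):
    """Vectorised loglinear-corrected rates (arrays allowed)."""
    n_hit = np.asarray(n_hit, dtype=float)
    n_signal = np.asarray(n_signal, dtype=float)
    n_fa = np.asarray(n_fa, dtype=float)
    n_noise = np.asarray(n_noise, dtype=float)
    return (n_hit + 0.5) / (n_signal + 1.0), (n_fa + 0.5) / (n_noise + 1.0)


def dprime_criterion_arrays(hr, far):
    """Vectorised (d', c) from rate arrays."""
    zh, zf = ndtri(hr), ndtri(far)
    return zh - zf, -0.5 * (zh + zf)
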