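"""Double-pass response consistency conditioned on alpha-phase optimality.

Identical stimulus pairs (double pass) separate internal from external noise:
any disagreement between the two responses to a pixel-identical stimulus must
come from internal variability. If the optimal alpha phase reduces internal
noise, responses should be more consistent when *both* presentations occurred
during the optimal phase (within +/- 90 deg of the resultant-vector angle)
than otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .coupling import circdist_deg
from .errors import DegenerateTestError


@dataclass
class StimulusPair:
    stimulus_id: str
    trial_a: int        # positional index of the pass-1 trial
    trial_b: int        # positional index of the pass-2 trial
    response_a: bool
    response_b: bool

    @property
    def consistent(self) -> bool:
        return self.response_a == self.response_b


def find_pairs(table: pd.DataFrame) -> list[StimulusPair]:
    """Identical-stimulus pairs among surviving trials.

    ``table`` must carry ``stimulus_id``, ``pass_index`` and ``response``
    with artifact-rejected trials already removed; stimuli whose partner was
    rejected are dropped.
    """
    if "pass_index" not in table.columns:
        raise ValueError("table lacks the pass_index column")
    pairs = []
    pos = {idx: i for i, idx in enumerate(table.index)}
    for stim_id, grp in table.groupby("stimulus_id", sort=True):
        if len(grp) != 2:
            continue
        grp = grp.sort_values("pass_index")
        a, b = grp.index
        pairs.append(
            StimulusPair(
                stimulus_id=str(stim_id),
                trial_a=pos[a],
                trial_b=pos[b],
                response_a=bool(grp["response"].iloc[0]),
                response_b=bool(grp["response"].iloc[1]),
            )
        )
    return pairs


def classify_optimal(phase_deg, resultant_angle_deg) -> np.ndarray:
    """True where the phase falls strictly within +/- 90 deg of the
    resultant-vector (optimal) angle; the 90 deg boundary counts as
    suboptimal."""
    d = np.abs(circdist_deg(phase_deg, resultant_angle_deg))
    return np.asarray(d < 90.0)


def consistency(
    pairs: Sequence[StimulusPair],
    phase: np.ndarray,
    theta: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = (-0.450, 0.0),
) -> dict[str, float]:
    """Response consistency by phase-optimality condition.

    ``phase`` is the trial phase grid [trial x channel x sample] aligned with
    the pair trial indices; ``theta`` the resultant angle per [channel x
    sample]. For every time point in ``window`` and channel, pairs are split
    into *both_optimal* (both members within +/- 90 deg of that cell's
    optimal angle) and *otherwise* (one or both in the bad phase); the
    proportion of response-concordant pairs is computed per cell and averaged
    over cells (unweighted). Returns one value per condition.
    """
    if len(pairs) == 0:
        raise DegenerateTestError("no stimulus pairs available")
    sel = np.flatnonzero((times >= window[0]) & (times <= window[1]))
    ia = np.array([p.trial_a for p in pairs])
    ib = np.array([p.trial_b for p in pairs])
    same = np.array([p.consistent for p in pairs])
    C = phase.shape[1]
    props = {"both_optimal": [], "otherwise": []}
    for c in range(C):
        for s in sel:
            opt_a = classify_optimal(phase[ia, c, s], theta[c, s])
            opt_b = classify_optimal(phase[ib, c, s], theta[c, s])
            both = opt_a & opt_b
            for name, mask in (("both_optimal", both), ("otherwise", ~both)):
                if mask.sum() == 0:
                    warnings.warn(
                        f"empty {name} cell (channel {c}, sample {s}) "
                        "excluded from the average", stacklevel=2)
                    continue
                props[name].append(float(np.mean(same[mask])))
    return {k: float(np.mean(v)) for k, v in props.items()}


def compare_consistency(
    both_optimal: Sequence[float],
    otherwise: Sequence[float],
) -> dict[str, float]:
    """Two-tailed paired-samples t-test of per-subject consistency values.

    Returns t, p, the mean difference and its 95% CI. Zero variance of the
    differences raises :class:`DegenerateTestError`.
    """
    a = np.asarray(both_optimal, dtype=float)
    b = np.asarray(otherwise, dtype=float)
    if a.size < 2 or a.shape != b.shape:
        raise DegenerateTestError("need >= 2 paired subjects")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        raise DegenerateTestError("zero variance of paired differences")
    t, p = stats.ttest_rel(a, b)
    n = a.size
    se = diff.std(ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.975, n - 1) * se
    return {
        "t": float(t),
        "p": float(p),
        "df": n - 1,
        "mean_difference": float(diff.mean()),
        "ci_low": float(diff.mean() - half),
        "ci_high": float(diff.mean() + half),
    }
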