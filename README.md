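# alphaphase

Does the phase of the pre-stimulus alpha rhythm (7–14 Hz) modulate how well
people detect faint visual targets — and if so, *how*? `alphaphase` is a
simulation + analysis toolkit for that question, aimed at EEG
psychophysicists. It implements the full analysis chain for phase–behavior
coupling in a yes/no detection task, together with a synthetic-data module
that generates the task, the stimuli, the EEG and phase-dependent ideal
observers with known ground truth, so every stage of the pipeline can be
validated without any recorded data.

## The statistic at the core

Trials are assigned an instantaneous alpha phase φ at stimulus onset
(Hilbert transform of the IAF ± 2 Hz band-passed, post-stimulus-tapered
EEG). Phases are sorted into eight 45°-wide bins and, per bin, sensitivity
and bias are computed from hit and false-alarm rates with a loglinear
correction:

    d′ = z(HR) − z(FAR),    c = −½ [z(HR) + z(FAR)]

The eight bin values become vectors (length = metric, angle = bin center)
whose sum, the **resultant vector**, measures coupling: its length ρ is ~0
when behavior ignores phase and grows with phasic modulation, while its
angle θ points at the optimal phase. Significance comes from a permutation
null (behavior shuffled against trials, the identical chain re-run, 95th
percentile thresholds) with cluster correction over time via the
per-permutation maximum cluster size, plus a binomial test across subjects.

Two mechanisms can produce phase-dependent d′, and the toolkit simulates and
discriminates both: **multiplicative gain** (evidence scaled at the good
phase — hits *and* false alarms rise together) versus **variance reduction**
(internal noise shrinks at the good phase — hits rise while false alarms
fall, i.e. the HR and FAR phase profiles are counterphase). Two further
analyses probe the noise account directly: **double-pass consistency**
(identical stimulus pairs should be answered more consistently when both
fell on the optimal phase) and **reverse-correlation classification
images** (quadrature Gabor energy at 15 spatial frequencies × 19
orientations, probit-regressed on the response), whose 2-D Gaussian tuning
fit can broaden at the suboptimal phase.

## Worked example

```python
import numpy as np, pandas as pd
from alphaphase import synthdata, phaseprep, coupling

rng = np.random.default_rng(0)
n = 6020
trials = pd.DataFrame({"target_present": rng.random(n) < 0.5})
phase = rng.uniform(0, 360, n)            # alpha phase at stimulus onset
observer = synthdata.ObserverModel(kind="variance_reduction",
                                   m=0.3, phi_opt=90.0, seed=1)
trials = synthdata.simulate_observer(trials, phase, observer)

bins = phaseprep.bin_phase(phase)
bm = coupling.binned_metric(trials, bins, metric="dprime")
rho, theta = coupling.resultant_vector(bm)
print("per-bin d':", np.round(bm.values, 2))
print(f"coupling strength rho = {rho:.2f}, optimal phase = {theta:.0f} deg")
print(f"binomial replication p = {coupling.binomial_replication(3, 6):.3f}")
```

prints

```
per-bin d': [1.51 1.95 2.29 1.89 1.64 1.3  1.16 1.19]
coupling strength rho = 2.09, optimal phase = 95 deg
binomial replication p = 0.002
```

The simulated observer's internal noise is smallest at 90°: the per-bin d′
peaks in the bin centered there (2.29 vs 1.16 at the opposite phase), the
resultant angle recovers the generative optimal phase within one bin half
width, and a cohort in which 3 of 6 subjects reach individual significance
at α = 0.05 would be very unlikely under the null (p = 0.002).

A complete simulated experiment — EEG synthesis, preprocessing, IAF and
phase estimation, coupling statistics, double-pass consistency and
classification images — runs through the command line:

```
alphaphase all --profile smoke --seed 7 --out run/
alphaphase report --out run/
```

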