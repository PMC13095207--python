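# Methods

This note documents the models, the estimation chain, the numerical choices
and the known limits of `alphaphase`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Generative models (`synthdata`)

**Session design.** One session is `n_blocks` × `trials_per_block` trials
(defaults 43 × 140 = 6,020). Each block holds `trials_per_block / 2` unique
stimuli, exactly half target-present (rounded), side drawn uniformly. The
double-pass structure splits the uniques into consecutive presentation sets
of at most 35; each set is shown in order and then repeated in the same
order, so every stimulus appears exactly twice (pass 1, pass 2) with an
identical RNG key — both presentations are pixel-identical. Capping the set
length at 35 keeps the two presentations close in time (fatigue control)
and reproduces both the 140-trial block layout (35+35 / 35+35) and the
degenerate small-block case (a 4-trial block becomes s1 s2 s1 s2).

**Stimuli.** Noise patches are built in the Fourier domain: the FFT of
Gaussian white noise is normalised to unit amplitude (this preserves
Hermitian symmetry exactly, so the field is real and the in-band amplitude
is exactly flat), masked to 0.25–4 cpd, inverse-transformed, windowed by a
circular 3° aperture and rescaled to 70% RMS contrast within the aperture.
The target is a vertical 2 cpd grating of random spatial phase, aperture
limited (a Gaussian envelope SD is configurable but off by default, since
the target geometry does not force one), scaled to the nominal RMS target
contrast. `pixels_per_degree` defaults to 48 (derived from a 74 cm viewing
distance and a 53.4 cm / 1920 px display); the tests run at 16 px/°, which
still oversamples the 4 cpd band edge twofold.

**EEG.** Each trial's epoch (default −1.5 to +0.5 s at 500 Hz; the window
is configurable) is `topography(ch) · alpha_amp · cos(2π·IAF·t + φ)` plus
independent 1/f-power noise per channel. φ is drawn uniformly per trial and
returned as ground truth; the convention throughout is **cosine phase in
degrees, 0° at the oscillation peak, evaluated at t = 0** (stimulus onset).
The topography is signed — occipital channels positive, AFz negative — so
frontal and occipital phases are exactly counterphase, a minimal stand-in
for a single dipole source viewed from both ends. Defaults: IAF per subject
~ N(10.43, 0.64²) Hz, alpha 10 µV against 5 µV RMS pink noise.

**Observers.** All three observers share an equal-variance SDT backbone
(noise mean µ_n = 1, baseline SD σ0 = 1, threshold λ). Defaults are pinned
to the reference operating point: `d_prime_base = 1.54`, criterion 0.25
(λ = µ_n + σ0(0.25 + 1.54/2) = 2.02) and coupling depth `m = 0.07`,
derived from the observed peak-to-trough d′ modulation of ≈0.21 via
Δd′ ≈ 2·m·d′.

* *variance_reduction*: σ(φ) = σ0(1 − m cos(φ − φ_opt)) — internal noise is
  minimal at the optimal phase, so HR rises **and** FAR falls there
  (counterphase HR/FAR profiles).
* *multiplicative_gain*: evidence and noise both scale by
  g(φ) = 1 + m cos(φ − φ_opt). µ_n is fixed at 1 rather than 0 precisely so
  that gain raises the false-alarm rate; with µ_n = 0 a pure gain would
  leave FAR untouched and the two mechanisms would be indistinguishable in
  FAR.
* *template*: evidence is the stimulus energy profile (z-scored per filter
  cell) projected onto a Gaussian SF × orientation template centered on the
  target, plus internal noise σ(φ). The template is **peak-normalised**:
  broadening it leaves the weight of the best-matching feature unchanged
  and instead widens the pooling, which raises the pooled-noise variance —
  the internal-noise account of the suboptimal phase. Template SDs default
  to (0.9 cpd, 25°), ~1-octave SF and ~25° orientation tuning typical of a
  V1-like detection template; the drive SD is `template_snr` = 1.2 σ0, and
  the criterion is placed midway between the class means. The width
  modulation follows either the single-harmonic cosine law (default) or a
  *binary* profile (width × `template_sd_mod` whenever the phase is more
  than 90° from φ_opt). The binary profile exists because the downstream
  analysis estimates exactly the optimal-vs-suboptimal *split* contrast: a
  cosine half-cycle mixture has an effective width ratio of only ≈1.18 for
  a generative factor of 1.3, so recovery studies that want the generative
  factor to equal the estimand use the binary profile.

Single-harmonic modulation everywhere is the simplest law consistent with a
"phasic" effect analysed in eight bins. Confidence is generated from the
distance of the evidence to the threshold through three fixed cutpoints; it
exists to make trial tables schema-complete and is not analysed. The
staircase (1-up-2-down) and the between-block contrast titration rule are
provided but **off** by default so that simulations are stationary.

## Phase estimation (`phaseprep`)

* Preprocessing: zero-phase first-order Butterworth high-pass at 0.1 Hz
  (an FIR at that corner would be longer than the epoch), optional
  resampling to 500 Hz, rejection of any trial exceeding ±150 µV inside
  −0.8–0.2 s, then average reference. The recorded-data first pass
  (median reference, channel interpolation, visual inspection) is not
  simulated; threshold rejection replaces it.
* IAF: Hamming-tapered −500–0 ms window, zero-padded ×5 (0.4 Hz bins at
  500 Hz), power spectra averaged over trials and the six parieto-occipital
  channels; the IAF is the 7–14 Hz maximum. The peak must be a strict
  interior local maximum with power ≥ 1.4× the in-band minimum — an
  operational form of "a discernible alpha peak": trial-averaged flat
  spectra stay below ~1.2 even with estimation noise, while a genuine peak
  over a 1/f floor exceeds 2.
* Taper: gain 1 up to +30 ms, linear to 0 at +70 ms, exactly 0 after, so
  the non-causal filter cannot pull evoked activity backwards in time.
* Band-pass: Hamming-window sinc FIR at IAF ± 2 Hz, 2 Hz transition bands
  (≈825 taps at 500 Hz), applied forward–backward (zero phase; verified
  group delay ≤ 1 sample). The **complex analytic signal** (Hilbert) is
  computed at 500 Hz and polyphase-decimated to 150 Hz *before* taking
  angles — resampling raw angle series would smear phase across wraps.
  "Phase at time t" always means the sample nearest t on the 150 Hz grid.
* Binning: eight bins centered at 0°, 45°, …, 315°, half width 22.5°,
  lower edge inclusive (22.5° belongs to the 45° bin; 337.5° wraps to the
  0° bin).
* Channel selection: per-channel IAF ± 2 Hz pre-stimulus power over the 17
  posterior candidates, top 3, ties broken by candidate-list order.

## Coupling statistics (`coupling`)

The resultant defaults to the **sum** over the eight bin vectors (a mean
mode divides by 8; the two differ only by scale, which matters for
comparing ρ magnitudes but never for inference). Statistics are computed
per channel, averaged over the three selected channels, then smoothed with
a centered 50 ms moving mean (7 samples at 150 Hz, window shrinking at the
edges). Permutations shuffle the (target, response) pairs jointly against
trials, keeping each trial's phase time course intact, and are pushed
through the *identical* chain including smoothing. Thresholds are the
per-sample 95th percentile of the permuted ρ, taken as the discrete upper
order statistic (no interpolation — conservative at finite permutation
counts; with interpolated quantiles the empirical false-positive rate of
the full procedure ran ~1–3 points above nominal). Clusters are runs of
temporally adjacent supra-threshold samples; the null is the
per-permutation **maximum** cluster size (max-statistic FWER control — the
looser all-clusters reading of the procedure would not control family-wise
error), and a cluster is significant at p < 0.05. Per-subject significance
for the binomial replication test compares the −450–0 ms time-averaged ρ
with the 95th percentile of the time-averaged permutations. Bin alignment
shifts every metric by the subject's best-d′ bin (ties toward the lowest
index), drops bin 8 and averages across subjects — visualisation only. The
V-test uses the unnormalised resultant: V = R·cos(θ̄ − µ0),
u = V·√(2/n), upper-tail normal p; a zero resultant returns (V = 0,
p = 0.5).

## Double-pass consistency (`doublepass`)

Pairs are stimuli whose two presentations both survived rejection. At every
time point (−450–0 ms) and selected channel a trial is *optimal* if its
phase lies strictly within ±90° of that cell's resultant angle (the 90°
boundary counts as suboptimal); a pair is `both_optimal` only if both
members are, and `otherwise` pools one-bad and two-bad pairs. The
proportion of response-concordant pairs is computed per cell and averaged
over cells **unweighted** (empty cells are excluded with a warning);
subjects are compared with a two-tailed paired t-test. Consistency is
computed on the yes/no response only, not confidence.

## Classification images (`revcorr`)

The bank holds 15 × 19 = 285 quadrature Gabor pairs (0.5–4 cpd linear,
−80–80° linear, 0° vertical), each kernel unit-norm, with an isotropic
Gaussian envelope of SD = 0.8 cycles of the cell's own SF (≈1-octave
bandwidth; the envelope is a free design choice exposed as a parameter).
Energy is the printed quadrature form E = √((S·g_sin)² + (S·g_cos)²) — a
single centered inner product per kernel, not a sliding convolution, which
is the natural reading for an aperture-limited patch. The raster must hold
at least one full cycle of the lowest SF (the nominal 3° patch holds 1.5
cycles of 0.5 cpd, so a two-cycle requirement would reject the design the
bank is meant for). Energies are z-scored per cell separately within
target-present and target-absent trials; each cell is probit-regressed on
the response, p(yes) = Φ(β0 + β1E) (the standard reading of "probit link"),
with perfect-separation slopes capped at ±10. The β1 grid folded across
orientation sign (15 × 10) is the CI.

Tuning comparison: a six-parameter 2-D Gaussian is least-squares fit to the
optimal-phase CI (multi-start: argmax center plus four jittered restarts),
then the suboptimal CI is refit with three multiplicative modulation
factors (gain, common SD, offset; center free). Inference resamples
subjects with replacement (`n_boot` default 10,000), refits both stages per
draw, and reports two-sided percentile bootstrap p-values of each factor
against 1; the per-cell difference CI is suboptimal − optimal (positive =
heavier off-target weighting at the suboptimal phase) with two-sided
bootstrap p per cell and no multiple-comparison correction (flagged in the
report). Trials are split into optimal/suboptimal **once** per trial —
phase at t = 0 against each channel's time-averaged resultant angle,
majority vote over the three channels, ties suboptimal — because a single
split is what makes "285 regressions" per phase well defined.

**What the CI width ratio estimates.** A single-regressor probit CI is the
template *convolved with the filter bank's cell-to-cell correlation kernel*
and divided by the split's total evidence SD. Both operations bias the
measured optimal/suboptimal width ratio away from the generative
broadening factor (simulations in this package measured 1.06–1.46 for a
true 1.3, depending on the drive-to-noise ratio), and the bias is a
property of the method, not of this implementation. Quantitative recovery
studies therefore run on *model-based cohorts* (`simulate_ci_cohort`):
per-subject folded CIs drawn from the Gaussian CI model with subject
jitter, subject-varying modulation factors and cell noise — the same
object the bootstrap machinery consumes — while the full energy-domain
pipeline is validated qualitatively (the suboptimal CI is broader, the
optimal split has the higher d′, broadening is detected in the right
direction).

## Problem sizes

The test suite and the acceptance script scale replicate counts to desk
size as the package's own defaults for these studies: null calibration uses
200 replicate simulations of 800 trials with 500 permutations each;
mechanism discrimination 15–20 replicate six-subject cohorts of 4,000
trials; optimal-phase recovery 20 replicates at m = 0.3; tuning recovery
five cohorts × 200–300 bootstrap draws; cohort SDT quantities use the full
6 × 6,020-trial design. Replicate-rate studies generate trial phases
directly as alpha phase ramps (φ0 + 360·f·t) — what an ideal estimator
would return for the synthetic EEG — while estimator fidelity itself is
established end-to-end on noise-free EEG (phase RMSE < 2° at onset,
AFz–Oz difference within 15° of 180° through the full chain).

## What the generator does not emulate

No eye movements, blinks or muscle artifacts (rejection is exercised with
injected voltage spikes, not realistic artifact morphology); no evoked
response (the taper's purpose is demonstrated on oscillation truncation
alone); no non-stationarity in alpha amplitude or frequency; no realistic
volume conduction (the two-sign topography produces the frontal–occipital
opposition but not graded scalp maps); contrast titration is off by
default, so simulated d′ is stationary where a titrated session drifts.
Passing tests therefore demonstrate the correctness and calibration of the
*analysis* under the stated generative assumptions, not robustness to every
property of recorded EEG.

## Known limitations

* The energy-domain template observer cannot pin the CI width ratio to its
  generative broadening factor (see above); treat fitted `sd_mod` from real
  or fully simulated energy data as a qualitative, attenuated readout.
* Subject-resampling bootstrap p-values with n = 6 subjects are
  anti-conservative when between-subject variance happens to be small;
  rate claims about them hold across replicate cohorts, not for every
  single cohort.
* The double-pass consistency contrast at the default coupling depth
  (m = 0.07) is a small effect; single six-subject cohorts frequently fail
  to reach significance even though the sign is stable.
* `estimate_iaf`'s prominence rule is tuned to trial-averaged spectra; for
  single-trial spectra it will be unreliable.
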