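# Methods

`rgcdegen` implements an analysis chain for population calcium imaging of
retinal ganglion cells (RGCs) in the ganglion cell layer, aimed at the
question of how photoreceptor degeneration (the rd10 mouse, a retinitis
pigmentosa model) differentially affects functional RGC types. Because the
package must be testable without access to recordings, it ships a forward
simulator with known ground truth; every analysis stage is written against
the simulator's output format but contains no knowledge of the ground truth.

## Recording model and preprocessing

Traces are somatic fluorescence sampled at 7.8125 Hz (the line rate of a
64×64 px two-photon scan). Preprocessing follows the standard population-
imaging recipe:

1. **Detrending.** A Savitzky–Golay filter (3rd order, 60 s window = 469
   samples, mirror-padded edges) estimates the slow drift, which is
   subtracted: `r_detrend = r_raw − r_smooth`. The filter is a local cubic
   projection, so cubic trends are removed exactly in the interior; within
   about two window lengths of the trace ends the padding makes this
   approximate.
2. **Baseline and normalisation.** The mean of the first 8 samples is
   subtracted and the trace scaled so its maximum is 1. Cells whose
   post-baseline maximum is non-positive are flagged non-normalisable and
   excluded rather than sign-flipped.
3. **Snippets and quality index.** Trigger-aligned snippets form a T×R
   matrix `C` (time × repetitions). Response quality is
   `QI = Var_t[⟨C⟩_r] / ⟨Var_t[C]⟩_r` with population variances; QI = 1 for
   perfectly repeatable responses and E[QI] → 1/R for independent noise.
   A cell is *responsive* if `QI_chirp ≥ 0.35` or `QI_MB ≥ 0.6` (inclusive
   thresholds).

## Stimuli

* **Chirp** (full-field, 30 s per repetition, 5 repetitions by default):
  2 s background, 3 s bright step, 3 s dark, 2 s background, 8 s sinusoidal
  frequency sweep 0.5→8 Hz at full contrast, 2 s background, 8 s amplitude
  sweep 0→1 at 2 Hz, 2 s background. Intensity is a single achromatic
  channel in [0, 1] with 0.5 = background. Five repetitions keep the
  noise-only QI expectation (1/R = 0.2) well below the 0.35 threshold.
* **Moving bar**: 0.3 × 1 mm bar at 1 mm/s in 8 directions (45° spacing),
  one sweep per direction per repetition in shuffled order, 3 repetitions,
  1 s inter-trial background. Sweep duration is (field extent + bar width) /
  speed = 1.3 s for a 1 mm field.
* **Shifted dense noise**: 20×15 binary checks of 40 µm at 5 Hz for 5 min
  (1500 frames). Each frame is balanced (exactly half the checks bright) and
  the whole frame is jittered by a random offset on a 10 µm grid within one
  check, which carries spatial information below the check size.

## Receptive-field estimation

The response variable is the clipped temporal gradient of the detrended
trace, `ċ = max(0, d/dt r_detrend)`, with the forward difference timestamped
at the sample-interval midpoint. Stimulus (zero-order hold) and ċ (linear
interpolation) are aligned on a 50 Hz clock (10× the stimulus rate).

The RF `F(x, y, τ) = S b` lives on a (32, 20, 15) grid: 32×20 spatial pixels
at **12.5 µm/px** (a 400 × 250 µm window centred on the stimulus) and 15
lags spanning −0.20 … +1.35 s (positive lags = stimulus before response;
acausal lags are kept as a diagnostic). `S` is a tensor product of clamped
uniform cubic B-spline bases with (10, 12, 9) coefficients. The pixel
convention matters: with these knot counts the spline resolution along x is
~55 µm, so a coarser grid cannot represent the smallest RFs the simulator
produces (σ ≈ 25 µm); 12.5 µm/px keeps the representation bias of the
fitted RF size at or below ~12%.

Weights and intercept minimise `L = (1/T) Σ_t (ċ(t) − y0 − X(t) S b)² +
β |b|₁` with β = 0.01, optimised full-batch with Adam (lr 0.1, β₁ = 0.9,
β₂ = 0.999, ε = 1e−8), at least 100 and at most 2000 steps; training stops
after five consecutive steps in which the loss did not drop below the
preceding step's value, and the lowest-loss parameters are kept.
*Numerical choice:* the quadratic part is preconditioned by Cholesky-
whitening the centred Gram matrix of the projected features; Adam runs in
the whitened coordinates while the L1 penalty is still evaluated on the
original spline coefficients. The loss and its minimiser are unchanged —
without the preconditioning the raw spline features (condition number ~1e4)
leave Adam an order of magnitude short of the least-squares optimum within
the step budget. With β = 0 the fit agrees with closed-form least squares
to ~1e−8 relative error on the seeded oracle instance; because of the
early-stopping rule the worst-case gap on arbitrary instances is a ~1e−5
relative loss excess.

Each lag frame of the assembled RF is smoothed with a truncated 5×5
Gaussian (σ = 1 px, reflective borders). A rank-1 SVD of the (space × lag)
matricisation yields the temporal and spatial components, rescaled so
`max|Ft| = 1` and `max|Fs| = max|F|`, with the sign anchored so `Fs` is
positive at its absolute maximum (polarity is carried by `Ft`, and peak
detection uses |Ft|, so On and Off RFs are treated symmetrically).
`QI_SVD = 1 − Var[F − Ft⊗Fs]/Var[F]`.

The spatial component is fit with an elliptical 2D Gaussian (nonlinear
least squares; `QI_sRF = 1 − Var[Fs − F_Gauss]/Var[Fs]`). The reported RF
size is the 2-SD ellipse area `A = π(2σx)(2σy)` and the equivalent diameter
`d = 4√(σxσy)`, after correcting the fitted σ for the explicit smoothing
kernel (σ² → σ² − 1 px², floored at 0.1 px). The correction removes a known
instrumental blur; the raw fitted σ are also stored. The main temporal peak
is the supra-threshold local maximum of |Ft| (threshold 0.65 population SD)
with the smallest lag. RFs are used only if `QI_SVD > 0.5`, `QI_sRF > 0.5`
and the main peak lag lies in [0, 0.3] s; an additional temporal-fit gate
is exposed but disabled by default.

## Tuning and permutation test

Per-direction mean snippets are stacked time × direction and decomposed by
a rank-1 SVD; the tuning curve is |direction component| × singular value
with the time component's peak made positive. DSI = |Σ r_k e^{iθ_k}| / Σ r_k
and OSI uses doubled angles. Per-trial amplitudes (|projection of the trial
snippet on the SVD time component|) enter an add-one permutation test
(labels shuffled across trials, p = (1 + #{perm ≥ obs}) / (1 + n_perm));
because ties count, a perfectly selective cell's p sits just above the
1/(n_perm+1) floor.

## Functional typing

The published random-forest classifier is external prior work trained on a
reference dataset; the package substitutes a self-contained nearest-template
classifier. Reference features are noiseless simulated cells passed through
the *identical* preprocessing; cell and template chirp/bar mean snippets are
projected on fixed PCA bases (20 + 8 components) frozen with the library
seed. Similarity per template = 0.70·corr(chirp) + 0.30·corr(bar) + 0.05·
(DS-flag agreement, using p_DS < 0.05) + 0.05·log-normal soma-size affinity.
The confidence score is a squashed top-two margin, CS = tanh(s·(sim₁ −
sim₂)); s is calibrated once on the noiseless library so the smallest
template margin maps to CS = 0.8. Cells with CS ≥ 0.25 enter type-resolved
analyses. The group → super-group lookup is fixed: G1–9 Off, G10–14 On–Off,
G15–20 Fast On, G21–28 Slow On, G29–32 Uncertain.

The On–Off index is (a_On − a_Off)/(a_On + a_Off) from peak amplitudes in
windows locked to the chirp's step onset and offset, binned Off (−1, −0.2],
On–Off (−0.2, 0.2], On (0.2, 1]. α-RGCs are flagged by soma area > 136 µm²
(strict).

## Synthetic cohorts

The simulator emulates the statistical structure the analysis assumes, not
retinal circuitry:

* **Templates.** 32 groups spanning the five super-groups, generated as
  linear–nonlinear responses to the actual chirp: On/Off/sustained drive
  weights, a kinetic time constant, a frequency-sweep attenuation cutoff, a
  contrast threshold in the amplitude sweep, segment dominance weights, and
  a smooth idiosyncratic component (35% of the response SD) that represents
  type-specific dynamics the coarse parameterisation cannot express and
  keeps all pairwise chirp correlations below 0.95. Baseline abundances are
  a seeded draw normalised to 1 (the real per-type abundances are unknown).
  DS groups: G2, G12, G13, G16; OS groups: G1, G6; large-soma (α-like)
  groups G5, G8, G18 with mean soma 170 µm² (others 60–115 µm²).
* **Cells.** rate = max(0, RF ⊛ stimulus); fluorescence = rate convolved
  with a unit-area single-exponential calcium kernel (τ = 0.5 s, an OGB-1-
  like indicator at ~8 Hz); plus two slow sinusoidal drift components
  (periods 60–300 s, SD 0.30) and white noise (SD 0.12), both scaled by the
  cohort noise multiplier so a noiseless cell is exactly repeatable.
  Response gain is log-normal (σ = 0.2). The dense-noise response is scaled
  to SD 1.0 so the regression signal is on the same O(1) ΔF/F scale as the
  chirp/bar responses. Ground-truth RFs are separable Gaussians (σ per type
  22–45 µm, centre within ±3 px of the window centre) times a biphasic
  kernel with peak lag 0.08–0.18 s.
* **Fields and degeneration.** A field holds 100–120 cells; a cell is
  responsive with probability 0.6 × (super-group, age) multiplier. The
  default rd10 schedule encodes the qualitative degeneration order (Off
  declines first, then On–Off, Slow On from P45, Fast On from P90,
  'Uncertain' most resilient; all near zero by P180), shrinks RFs by 5% at
  P30/P45, speeds kinetics by 15% at P45 and raises the noise multiplier
  with age. The exact numbers are configuration, not claims about biology.

What passing tests show — and don't. The simulator reproduces trial
structure, noise, drift, type templates and a degeneration schedule, so
green tests demonstrate that the *pipeline* measures what was planted at
realistic SNR. Real recordings add motion, neuropil contamination,
oscillatory rd10 activity (unresolvable at 7.8125 Hz), non-separable RFs
with surrounds, and classifier mismatch to a taxonomy learned elsewhere;
none of these are modelled, so test results do not certify performance on
real data.

## Cohort statistics

Responsive fractions are computed per recording field and summarised as
mean ± SD across fields. Relative type abundance is log2(f_rd10 / f_wt)
over CS-included cells; a type missing in either cohort is flagged rather
than assigned a ratio. Each type's rd10 count is tested against the
wild-type proportion with an exact two-tailed binomial test ("minlike"
convention), BH-adjusted within each age, significant at adjusted p < 0.01;
abundance is computed for P30–P90 (by P180 the rd10 cohort is nearly
silent). The super-group resilience ranking is the descending order of the
mean per-type relative abundance pooled over those ages. Group comparisons
use the two-sided Mann–Whitney U test with the rank-biserial effect size
rb = 1 − 2U/(n₁n₂). Distribution similarity uses Jensen–Shannon divergence
(base 2, range [0, 1]; QI histograms on 20 equal bins of [0, 1]), and
per-type mean-response similarity uses Pearson correlation. Headline
percent differences are 100·(mean_wt − mean_rd10)/mean_wt, rounded half-up
to one decimal.

## Problem sizes and determinism

Defaults used by the shipped tests and the acceptance script: 8 fields per
(genotype, age) cohort for the end-to-end run, 200 cells for classifier
recovery, 200 permutations per cell, 8–20 cells for RF recovery with the
full 5-minute noise stimulus. All randomness flows from explicit seeds
through `numpy` seed sequences; identical seeds give identical cohorts,
fits and tables.

## Known limitations

* The classifier is a surrogate calibrated on its own template library; its
  absolute confidence values are not comparable to the published
  classifier's.
* The intercept of the penalised RF fit is weakly identified because the
  spline bases nearly sum to one; only the RF itself should be interpreted.
* RF size correction assumes the explicit smoothing kernel dominates the
  blur; the residual spline-representation bias (≤ ~12% for σ = 2 px RFs)
  is not removed.
* Per-type abundance ratios at low counts are truncation-biased (types with
  zero cells drop out); rankings should be read at the super-group level.
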