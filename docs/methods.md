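# Methods

This note documents the models, conventions and numerical choices behind
`dropload`, in the order the pipeline applies them.

## Landing waveform model

A drop-landing vertical force trace is modelled piecewise
(`dropload.waveform.make_waveform`):

1. flight: zero force for `pre_contact_s` (default 0.2 s);
2. loading ramp: linear rise from 0 to the supported weight `W` over
   `t_rise_s` (default 0.05 s);
3. impact bump, for `t ∈ [t₁, t₁ + t_abs]`:
   `F(t) = W + (peak − 1)·W·sin(π(t − t₁)/t_abs)^q`;
4. quiet stance: constant `W` for `settle_s` (default 0.5 s).

White Gaussian noise of SD `noise_sd_bw·W` (default 5 % of the weight) is
added per sample, then the total is split across the two plates by a
per-trial left share (the right channel is stored as total minus left, so
the plate sum reconstructs the total bit-exactly). The raised-sine form is
a deliberate idealisation: real landing traces show a bimodal heel/forefoot
transient, but this form makes the two target parameters *analytic* — the
noise-free trace crosses `1 W` exactly at the bump boundaries and peaks at
exactly `peak·W` at the midpoint — so extraction accuracy can be bounded a
priori (≤ one interpolation step for the peak, ≤ 2/fs for `t_abs`).
Shape exponent `q = 1` (plain half-sine) and `fs = 1000 Hz` (typical
piezoelectric-platform rate; the generator enforces ≥ 200 Hz) are the
defaults.

Consequences for interpreting tests: passing recovery bounds on these
waveforms validates the event detection, interpolation and integration
machinery, not robustness to multi-peak transients, drift, or filtering
artefacts of real hardware. Real traces with a secondary supra-weight bump
are handled by the peak-containing-interval rule (below), which is tested
on hand-built piecewise traces.

## Metric definitions and conventions

* **Contact**: first sample exceeding 5 % of the supported weight and
  staying above it for ≥ 10 ms — the conventional force-plate event
  threshold; the hardware trigger level of the original acquisition is not
  documented, so this is configurable.
* **t_abs** is the duration of the contiguous supra-weight interval that
  contains the global post-contact maximum, not the total supra-weight
  time: a landing can graze the weight level before the main impact, and
  the amortization phase is the single interval around the peak. Crossing
  times are refined by linear interpolation between the bracketing samples;
  whole-sample counting would differ by at most 2/fs.
* **Weight conventions in the gear condition.** Two distinct weights
  matter when protective clothing (+`gear_load_n`, default 75 N) is worn:
  the *supported* weight (body + gear) and the *body-only* weight. The
  supra-weight threshold always uses the supported weight — the
  post-landing plateau settles there, so a body-only threshold would never
  terminate the interval. The peak normalisation (GRF/BW) uses body-only
  weight by default (`bw_convention: body_only`), expressing overload
  relative to the person; `body_plus_gear` is available because the
  original description does not fix the convention.
* **BW source**: body mass × 9.81 m/s² from the subject table by default;
  a quiet-stance estimate (median of the settle plateau) is the documented
  alternative for recordings without a reliable mass entry.
* **Landing phase** for impulse integration: contact to the last downward
  weight crossing plus a 0.2 s settle margin, clipped to the trace end.
* **Impulse**: trapezoidal integration on the sample grid.

## Impulse-preserving trial averaging

The three trials of a condition are combined into one profile under the
constraint that averaging must not change the force impulse. The published
constraint fixes only the integral identity, not the resampling scheme;
the minimal transform satisfying it is used: each trial's landing phase is
linearly rescaled in time to the mean landing duration `t_av`, then
multiplied by (own original impulse / own rescaled impulse). Each
transformed trial then carries exactly its original impulse, and the
point-wise mean on the common grid has impulse equal to the arithmetic
mean of the trial impulses (asserted to 1e-9 relative in the tests).

Whether per-condition metrics should come from the averaged profile or
from averaging per-trial metrics is ambiguous in such protocols; the
pipeline computes both (`*_profile` and `*_mean` columns) and the
`averaging` switch (`profile_first` default, matching the "one averaged
profile per test" description) selects which feeds the statistics. The
acceptance script uses per-trial means, which are unbiased for the
generator's condition means.

## Synthetic cohort

The generator emulates the study conditions as its defaults, not as free
dials:

* group sizes 83/38/50; body mass 79.5 ± 8.36, 89.7 ± 9.39, 87.2 ± 13.25 kg;
  body height 180.6 ± 6.80, 179.9 ± 4.79, 178.0 ± 5.03 cm per age group;
* summed torque 385.2 ± 62.2, 371.1 ± 63.1, 336.4 ± 57.7 N·m and H/Q
  42.8 ± 10.0, 40.3 ± 13.8, 41.8 ± 10.9 % per group, inverted into
  extensor/flexor torques via `t_ext = ST/(2 − HQ/100)`;
* all 12 absorption-time cell means (0.29–0.50 s) from the published
  condition table;
* peak GRF/BW cell means: only two cells are published (5.6 for the
  youngest group in sportswear from 0.5 m; 8.9 in fire-protection gear
  from 1.0 m). The other ten cells are package defaults — **not published
  values** — chosen to respect the published per-group height effects
  (+39/+33/+40 % from 0.5 to 1.0 m), the gear/sport ratio implied by the
  two published cells (≈ 1.14), and the published group ordering I > II > III.

Per-subject variation is multiplicative and lognormal: a shared subject
effect (SD 0.10) scales both metrics in all conditions, and per-cell
(peak, t_abs) pairs are drawn from a Gaussian copula over lognormal
marginals (between-subject CV 0.25 each). These values make the total
between-subject CV ≈ 0.27, which reproduces the published absorption-time
SDs (0.09–0.14 at means 0.29–0.50). Trial-to-trial jitter has CV 0.03.
Lognormal marginals keep both metrics strictly positive; the copula
correlation is solved in closed form from the target Pearson correlation
of the pair (shared-effect covariance included), and an unreachable target
raises an explicit error rather than silently attenuating.

The default correlation targets are +0.02 (youngest), −0.35 (middle),
−0.45 (oldest): the older groups trade longer absorption against lower
overload, the youngest shows no such coupling. (The youngest-group target
is calibrated from the published per-condition p-values, which are
mutually consistent; one printed r in that row is not consistent with its
own p-value and was treated as a misprint.)

In the gear condition the waveform is shaped around the supported weight
while the truth table records body-only GRF/BW, so recovered values match
the calibration under the default normalisation convention.

Reproducibility: each subject draws from an independent
`SeedSequence([seed, counter])` stream, so cohorts are pure functions of
(design, seed) and invariant to generation order.

## Statistics

The split-plot ANOVA uses the classical univariate approach via
per-subject orthonormal contrast scores: every within effect (clothing,
height, clothing × height) is tested against its own effect-by-subject
error stratum, the between effect (age group) against subjects within
groups on subject means, and partial η² = SS_effect/(SS_effect + SS_error)
uses the effect's own stratum. With unequal group sizes, within main
effects test the unweighted (Type III) grand mean — the convention of the
commercial packages used for such designs; between-effect and interaction
sums of squares are the standard one-way forms on contrast scores. With
equal group sizes the strata reconstruct the total corrected sum of
squares exactly (tested to 1e-9).

Sphericity: Mauchly's W is computed from the pooled within-group
covariance of the contrast scores, with the Greenhouse–Geisser ε =
(Σλ)²/(k·Σλ²) from its eigenvalues; when Mauchly rejects at α = 0.05 the
F degrees of freedom are multiplied by ε. Both within factors of this
design have two levels, so sphericity holds trivially (ε = 1) and the
machinery is exercised on three-level fixtures in the tests, including a
500-replicate null simulation of the test's size.

Tukey post-hoc comparisons use the studentized-range distribution with
the error term of the matching stratum (Tukey–Kramer for unequal group
sizes; the factor-by-subject interaction mean square for within factors —
the error-term convention is not fixed by the original description, so
the matching-stratum choice is documented here). Pearson correlations and
OLS fits delegate to scipy (`pearsonr`, `linregress`) behind validating
wrappers; α = 0.05 throughout with no multiplicity correction beyond
Tukey. Effect-size bands: partial η² 0.01–0.06 small, 0.06–0.14 medium,
above 0.14 large.

Degenerate inputs: constant data yield F = 0 and η² = 0 (not NaN); a
singular contrast covariance (zero variance, or fewer subjects than
factor levels) raises a rank-deficiency error; a zero-variance series
raises an undefined-correlation error rather than returning NaN.

## Problem sizes

The packaged checks run cohorts of 40 subjects per group with 3 trials
per condition (1440 trials at 1 kHz) for calibration recovery over seeds
1–5, a 200-trial sweep for noise-free recovery bounds, 500-replicate null
simulations for the ANOVA's type-I error and Mauchly's size, and ten
seeds for the correlation sign pattern — sizes chosen so the standard
errors are small relative to the calibrated effects while the whole suite
completes in well under a minute per stage on one core.

## Known limitations

* The waveform is unimodal and noise is white; no heel-strike transient,
  baseline drift, or filter phase effects are modelled.
* Trial files carry no kinematics; joint angles, EMG and lumbar loading
  are out of scope.
* The ten unpublished peak-GRF cell means are package defaults (see
  above); analyses that depend on their exact values should treat them as
  plausible, not measured.
* The 5-second inter-jump interval of the protocol is metadata only; no
  fatigue or ordering effects are simulated.
* `analyze` mode expects the package's delimited trial format; C3D or
  vendor-binary ingestion is left to a format adapter.
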