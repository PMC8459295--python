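# Methods

`crnpipe` implements a complete single-trial analysis chain for response-locked
EEG components (the correct-response negativity, CRN, and the error-related
negativity, ERN) in a speeded go/no-go task, together with a synthetic-data
generator that reproduces the study conditions so every stage can be validated
against known ground truth.  This note records the models, the numerical
choices, and what the synthetic benchmarks do and do not establish.

## The trial-level amplitude model

The core statistical model regresses the z-scored single-trial component
amplitude on eleven standardized predictors, separately per feedback condition
*i* (gain-framed, loss-framed, informative control):

    Y_k ~ Student-t(nu, B_i' X_k + I_j, sigma_g)              (basic)
    Y_k ~ Student-t(nu, B_i' X_k + b_j rt_k + I_j, sigma_g)   (extended)

for trial *k* of subject *j*.  The predictors are response time (RT),
promotion strength, prevention strength, the subject's miss count (ErrN), and
every two- and three-way interaction that does not contain both promotion and
prevention — exactly eleven columns.  Base predictors are z-scored over the
analysis set; interaction columns are products of z-scores and are not
re-standardized (a config flag re-standardizes them for sensitivity
analysis).  The Student-t likelihood bounds the influence of extreme trials;
random intercepts `I_j ~ N(I0, sigma_I)` absorb stable subject differences,
and the extended variant adds mean-zero per-subject RT slopes `b_j` used by
the reliability analysis.

Sparsity is imposed by a regularized horseshoe prior on each coefficient:

    B_ip ~ N(0, tau^2 lambda_tilde_ip^2),
    lambda_tilde^2 = c^2 lambda^2 / (c^2 + tau^2 lambda^2),
    lambda_ip ~ C+(0, 1),   tau ~ C+(0, tau0),
    c^2 ~ Inv-Gamma(nu0/2, nu0 s^2/2),
    tau0 = p0 / (P C - p0) * sigma_g / sqrt(N),

with `p0 = 9` expected non-zero coefficients among `P C = 33`, slab
hyperparameters `nu0 = 20`, `s = 1`.  Remaining priors: `nu ~ Gamma(2, rate
1/10)` (mean 20; a scale parameterization is config-switchable), `sigma_g,
sigma_I ~ HalfNormal(1)`, `I0 ~ N(0, 1)`.  `tau` is global across conditions
and `c^2` is shared, matching `tau0`'s use of `P C`; the random slopes share a
single horseshoe local scale `lambda_b` (one scale for the block rather than
one per subject — with 90 subjects a per-subject scale would make each slope
its own horseshoe coefficient and the block-level shrinkage ill-determined).
The intercept scale prior is half-normal: a scale must be positive, so a
nominally normal prior on `sigma_I` is read as its positive half.

### Sampling

No gradient-based probabilistic-programming backend is part of this package's
dependency set, so the sampler is written here as a **data-augmentation Gibbs
scheme** that targets exactly the joint density implemented (and tested) in
`log_joint_density`:

* the Student-t likelihood is represented as a normal scale mixture with
  per-trial Inverse-Gamma(nu/2, nu/2) mixing weights, making `B` (per
  condition, 11-dimensional), `I`, `I0` and `b` conjugate Gaussian blocks
  solved by Cholesky factorization;
* `lambda` (33 local scales, batched), `lambda_b`, `tau`, `c^2`, `sigma_g`,
  `sigma_I` and `nu` are updated by univariate slice sampling with stepping
  out on the log scale (Jacobian included).

Each chain is an independent seeded `numpy` generator, so runs are exactly
reproducible.  Default desk-scale settings are 4 chains x (1000 warmup + 500
kept sweeps); `MCMCSettings.paper_settings()` (and `--paper-settings` on the
CLI) restores 8 chains x (8000 + 1000).  Convergence is summarized with
split-R-hat and bulk-ESS ratios (via `arviz`) at the pass thresholds R-hat
< 1.05 and ESS ratio > 0.1; a single-chain fit is flagged as undiagnosable
rather than passed.  On the desk-scale recovery benchmark (90 subjects x ~250
trials) a fit takes roughly 20 s on one CPU.

Model correctness is established two ways: the joint density matches an
independently coded scalar implementation (scipy distribution calls, looped
over trials and coefficients) to better than 1e-8, and the sampler recovers
known generating coefficients with near-nominal interval coverage in
simulation.  Shrinkage behaves as designed: with all-zero truth essentially
every 95% interval covers zero, and with nine non-null coefficients of
|beta| = 0.15 the null coefficients' posterior medians are far smaller than
the non-null ones.  Coverage for a coefficient as small as -0.05 runs below
nominal — the horseshoe deliberately biases small effects toward zero; that
trade-off is inherent to the prior, not a sampler defect.

When amplitudes are generated on an arbitrary scale, the estimand after
outcome z-scoring is `B / sd(Y)`; recovery checks therefore compare posterior
medians against the truth divided by the realized outcome SD.

## Preprocessing

The cleaning chain is fixed in this order: 0.2 Hz high-pass (2nd-order
Butterworth) -> 58-62 Hz band-stop (2nd-order) -> bad-channel interpolation ->
average reference -> (pluggable ocular cleaning; independent-components
removal is treated as an external step) -> bad-segment scoring -> 30 Hz
low-pass (6th-order, two-pass).  All stages are applied **zero-phase**
(forward-backward, half the stated order per pass).  The source procedure
specifies two-pass filtering only for the low-pass; we apply it throughout
because a causal 0.2 Hz high-pass imparts a measurable (~1 ms) forward bias
on component peak latencies, and offline ERP practice is zero-phase
filtering.  Causal per-stage filtering remains available by config.

Bad-channel interpolation replaces a channel by the unweighted mean of its
montage neighbors (neighbors = electrodes within 6 cm on the standard 10-05
layout); a channel with fewer than two good neighbors is an error rather than
a silent pass-through.  Candidate noisy channels can be flagged automatically
(robust SD > 5 x median channel robust SD), replacing manual visual
inspection.

The artifact detector divides the recording into non-overlapping 0.5 s
segments, computes each channel's amplitude spectrum (1-100 Hz band;
amplitude rather than power or log is the default, config-switchable, since
the original criterion does not specify), Pearson-correlates all channel
pairs, and averages; segments more than 1.8 SD from the mean score — in
either direction, since the criterion states no direction — are flagged, and
any epoch overlapping a flagged segment is excluded downstream.  Because the
rule is relative, it flags ~7% of perfectly clean data by construction; on
injected common-mode broadband segments its hit rate is effectively 100%.

## Single-trial extraction

Per participant, the stimulus-locked average over 0-1.5 s (all correct go
trials for the CRN; all no-go trials for the ERN, false alarms being too rare
to average) is subtracted from each trial in stimulus-locked alignment.  A
-500..+500 ms epoch is then cut around the button press and baseline-corrected
over -500..-400 ms.  The 1.5 s subtraction span covers every response up to
the 1 s deadline plus the epoch tail.  The measurement window is found once
per dataset from the grand mean at FCz: the minimum within 0-200 ms
post-response (ties to the earliest sample), refined by a least-squares
parabola over the +-10 ms neighborhood (the sample grid at 512 Hz is ~2 ms;
the refinement removes grid quantization and is far less noise-sensitive than
three-point interpolation), rounded to 1 ms, +-50 ms.  Single-trial amplitude
is the window **mean** at FCz — time averages are unbiased amplitude
estimates, peaks are not.

Retention rules: subjects with a false-alarm rate of 83% or higher on ten or
more blocks are excluded entirely; ERN analyses additionally require at least
six usable error trials per subject, and the final fixed-effects model keeps
only subjects whose internal consistency (below) reaches .8.

## Reliability (generalizability theory)

From the extended-model posterior, per draw:

    phi_j   = sigma_m^2 / (sigma_m^2 + sigma_e_j^2 / n_j)
    phi_G(S) = sigma_G^2 / (sigma_G^2 + (sigma_s^2 + sigma_e^2 / n_hat) / S)

where `sigma_m^2` is the variance of the predicted values over subject j's
own trials (between-subject terms are constant within subject and drop out),
`sigma_e_j^2` the subject's residual variance, `sigma_G^2`/`sigma_s^2`/
`sigma_e^2` the per-condition variances of the fixed-effect predictions, the
subject-specific parts, and the residuals, and `n_hat` the harmonic-mean
trial count.  The `phi_G` parenthesization divides both subject-level and
residual variance by `S`, the reading under which dependability grows with
the number of subjects, as its use requires; the flattened printed form is
ambiguous and the alternative reading is exposed by config.  Variances are
population-style (divide by n): each draw is a deterministic transform of the
posterior sample, not an estimator with its own degrees-of-freedom
correction.  Both coefficients are computed per posterior draw and summarized
by the mean and central 95% interval (plug-in evaluation at posterior medians
is available by config).  With known variance components the draw-wise
machinery reproduces the closed forms within the sampling error of the
realized variances.

## Behavioral reduced-rank regression

Four subject-level outcomes — initial log-odds correct rejection, change in
log-odds CR, change in mean correct-go RT, and the intrinsic-motivation
effort/enjoyment score — are regressed on eight standardized predictors
(promotion, prevention, gain and loss indicators, and the trait x condition
products; traits are z-scored *before* the products are formed, otherwise the
interaction columns are nearly collinear with the indicators).  "Initial" and
"change" use bins of three successive blocks: log-odds are continuity
corrected (0.5 added to both counts) per block and averaged within the bin;
change is the last full bin minus the first.  The bin windows are a design
choice — the underlying report plots three-block bins but does not define the
change score — and are set prominently here.

The model is `Y ~ (X a) w' + E` with rank 1 by default, standard-normal
priors on the projection `a` and loadings `w`, per-outcome half-normal noise
scales, and the prevention projection constrained positive for
identifiability (a joint sign flip of `(a, w)` leaves the likelihood
invariant).  Sampling uses the affine-invariant ensemble sampler (`emcee`),
initialized at the rank-r SVD of the least-squares coefficient matrix —
without that initialization the ensemble can settle on a secondary mode.
Rank comparison computes pointwise Pareto-smoothed importance-sampling
leave-one-out expected log predictive density (PSIS via `arviz`); the lower
rank is preferred unless the higher rank improves the LOO sum by more than
twice its pointwise standard error, and Pareto k-hat > 0.7 flags unstable
weights.

## The synthetic cohort: what it emulates, and what it does not

Defaults reproduce the study conditions: 91 participants split 26/35/30
across gain/loss/control; 20 blocks of 30 trials (24 go, 6 no-go); a 1 s
response deadline with the speed-points curve (full 30 speed points faster
than 452 ms, decaying linearly to 0 at the deadline — used only for feedback
realism, never by an estimator); truncated-normal RTs on (0.1, 1.0] s with
condition means 0.40/0.43/0.46 s; promotion 4.0/3.8/3.8 (SD 0.6/0.5/0.6) and
prevention 3.3/3.5/3.2 (SD 0.9/0.9/0.8) truncated to the 1-5 scale; miss rate
3% and false-alarm rate 27% (matching the reported per-group miss and
false-alarm counts).  Within- and between-subject RT spread are separate
knobs because the source reports only group-level summaries: between-subject
SD of subject mean RT is 0.05 s (the reported group SDs) and within-subject
trial-to-trial SD is 0.09 s, a typical value for speeded responding under a
1 s deadline.  Item-level questionnaire responses are the latent scale score
plus independent item noise, truncated to the response scale; the item-noise
SDs (1.03 promotion, 0.94 prevention) are calibrated so the expected
Cronbach's alpha equals the published .62 and .79.

Amplitude ground truth defaults to the published posterior medians as
generating values: RT coefficients -0.15/-0.17/-0.08 for gain/loss/control
and -0.05 for the gain RT x promotion interaction, all other coefficients
zero; random intercept SD 0.3, random RT-slope SD 0.05, residual scale 0.9
with nu = 8 (trial-level noise dominates single-trial ERP amplitudes; the
heavy-tail index is unreported and set to a moderately heavy value).  A
microvolt-scale variant centers amplitudes at -1.17 uV with between-subject
SD 0.76 uV, matching the reported grand-mean CRN.

Raw EEG is synthesized at 512 Hz on a nine-channel montage that spans the
head (Fpz, F3/F4, FCz, C3/C4, Pz, O1/O2) so that average referencing behaves
like a dense layout; the response-locked component has a focal fronto-central
topography (FCz gain 1, montage mean ~0.29).  Each trial contributes a
stimulus-locked evoked waveform (P1-N1-P3-like, posterior maximum) and, for
trials with a known amplitude, a response-locked Gaussian negativity (peak
20 ms post-response, SD 25 ms, unit peak) scaled by that amplitude, on a
background of 1/f noise plus 60 Hz line noise; common-mode broadband artifact
segments can be injected at a configurable rate with their positions logged.
The default background RMS (0.5 uV) is set so the single-trial window-mean
signal-to-noise ratio at FCz is above one, the regime in which single-trial
recovery benchmarks are informative; real resting EEG is considerably
noisier, so the extraction benchmarks certify correctness of the procedure,
not attainable single-trial precision on real data.  Other deliberate
idealizations: no ocular or muscle artifacts (ocular cleaning is a pluggable
external step), no channel drift or impedance changes, iid trait/RT
distributions, and a single fixed component topography.

The exact expected value of the extraction pipeline's output is computable
for the simulator (embedded amplitude x reference-adjusted FCz gain x template
window mean, minus the response-locked content of the subtracted evoked
average and the baseline term); the recovery benchmark compares extracted
amplitudes against this analytic oracle.  One property of the method is worth
noting: because the stimulus-locked average contains a response-time-smeared
copy of the mean response-locked component, evoked subtraction leaves a small
trial-dependent residual correlated with RT.  With the study's RT jitter this
residual is small (bias well under 0.1 uV), but it is a property of the
evoked-subtraction method itself, not of this implementation.

## Numerical conventions and edge cases

* Sample intervals are half-open `[start, stop)`; epoch time axes are in
  milliseconds relative to the button press; file-level times are seconds;
  0-based sample indices.
* Degenerate inputs fail loudly: zero-variance base predictors, missing FCz,
  subjects with fewer than two trials (flagged NaN phi), fewer than two
  scalp channels for referencing, filter cutoffs at or above Nyquist.
* Out-of-support parameter values give `log_joint_density = -inf` by
  contract.
* EDF output is 16-bit with per-channel physical scaling from the data
  extrema (quantization ~1/65535 of the range) and an integer status channel
  carrying event codes; reading is delegated to `mne`, which serves as an
  independent check on the writer.
* All randomness flows from explicit integer seeds; chain seeds are derived
  as `seed * 10000 + chain`.

## Problem sizes used by the validation suite

Benchmarks run at a desk scale chosen to keep the full validation suite in
the tens of minutes on one CPU: parameter recovery uses 90 subjects x ~250
trials over 20 replicates at 4 chains x (1000 + 500); shrinkage calibration
two fits at the same size; extraction recovery 30 subjects x 3 blocks of raw
EEG; the detector 5 x 200 segments.  The study-scale model (8 chains x
(8000 + 1000), 91 subjects x ~600 trials) is a flag away and scales linearly
in sweeps and trials.

## Known limitations

* The Gibbs sampler updates scale hyperparameters one at a time; for very
  small N the (tau, lambda) posterior is strongly coupled and mixes more
  slowly than a well-tuned Hamiltonian sampler would — convergence
  diagnostics, not assumptions, are the guard.
* Horseshoe shrinkage biases small coefficients toward zero, so interval
  coverage for effects comparable to the shrinkage scale (|beta| ~ 0.05) is
  below nominal.  This is the prior working as intended.
* ERN inference shares all machinery with the CRN but is gated by the same
  reliability criteria; with realistic false-alarm counts most simulated
  subjects fail the six-trial or phi >= .8 gates, mirroring the motivating
  study's decision not to model the ERN.
* `derive_outcomes`' first/last-bin windows and the per-block continuity
  correction are documented choices, not reproductions of an exactly
  specified procedure.
* Independent-components ocular cleaning and spherical-spline interpolation
  are out of scope; the neighbor-mean interpolator is the default and a
  spline can be slotted in behind the same interface.
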