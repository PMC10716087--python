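# Methods

## Study structure emulated by the package

Each session has 330 trials in 10 equal blocks. A central cue (1,000 ms)
indicates where a faint luminance increment/decrement target (30 ms,
followed by 300 ms of noise) is most likely to appear: on one of three
noise annuli at 1.16°, 3.47° or 10.40° eccentricity (size cueing), or at a
specific location on an annulus (location cueing). Cues are valid on exactly
80 % of trials within every cued-eccentricity cell. The target appears at a
uniformly random moment 3,000–4,000 ms after cue onset; 3,000 ms is the
earliest possible onset and hence the upper bound of the pupil analysis
window. Variants: `exp1` (size cueing, symbolic cues counterbalanced over
the 6 symbol–eccentricity permutations across consecutive participants),
`exp2` (location cueing, fixed alphanumeric code scheme: 1/2/3 = annulus,
U/D/R/L = location), `exp3` (both, blocked).

Design decisions where the structure was underdetermined:

- The noise display runs 3,000 ms before the 1-s target window, and the
  target-onset distribution is uniform on [3000, 4000) ms.
- `exp3` halves: 5 contiguous blocks (165 trials) per breadth type, each
  half opening with 15 of the 30 practice trials so that the experimental
  trials split exactly 150/150. Half order alternates with participant
  index. For `exp1`/`exp2` the 90 practice trials precede the 240
  experimental trials.
- Practice mirrors the experimental 80/20 composition.
- Invalid targets are spread evenly over the two non-cued annuli (size
  cueing) or drawn uniformly from the 11 non-cued (annulus, location) cells
  (location cueing). Target polarity is balanced 50/50 per cell. In the
  location condition 50 trials per cued annulus cannot split evenly over 4
  locations; they cycle 13/13/12/12.

## Staircases

Generic n-up-1-down with 1 % opacity steps (n = 2 for `exp1`, 3 for
`exp2`/`exp3`, matching the named procedures; the narrative description of
a 3-correct rule for all experiments is accommodated by the same `n_up`
parameter). Opacity is clamped to [1, 100] %; one independent staircase per
eccentricity; only validly cued trials update the staircase, because the
accuracy criterion the staircase enforces is defined on valid trials. The
equilibrium accuracy is `0.5 ** (1/n)`: the opacity settles where the
probability of n consecutive correct responses is 1/2 (≈ 70.7 % for n = 2,
79.4 % for n = 3). Convergence simulations discard the first 500 trials as
burn-in. Inside the generator, staircases start at 25 % opacity — an
experimenter's pilot-informed starting value — so they reach equilibrium
within a single 330-trial session; the staircase module's generic default
start is 50 %.

## Synthetic observer

Two-alternative discrimination, so chance is 0.5. With opacity $o$,
threshold $\theta$, slope $s$ and lapse rate $\lambda$:

$$p(o) = 0.5 + (0.5 - \lambda)\,F\!\big(s\,(g\,o - \theta)\big), \qquad
F(x) = \frac{\Lambda(x) - \Lambda(-s\theta)}{1 - \Lambda(-s\theta)},$$

where $\Lambda$ is the logistic CDF and the normalization pins $p(0) = 0.5$
exactly. The validity gain $g \ge 1$ (1 on invalid trials) is a *contrast
gain* on the target signal. A multiplicative gain on $(o - \theta)$ — i.e.
a pure slope change — was rejected: the staircase equilibrium (70.7 %) lies
below the psychometric midpoint, where a steeper function yields *lower*
accuracy, which would invert the cueing effect; a contrast gain produces
valid > invalid accuracy at every positive opacity. Defaults:
$\theta = 20\,\%$, $s = 0.15\,/\%$, $\lambda = 0.02$, $g = 1.4$ (valid-trial
accuracy ≈ 70 % with invalid ≈ 61–64 %, a cueing gap of the size typically
observed). Reaction times are log-normal (median 600 ms, scale 0.25) and
independent of eccentricity, mirroring the absence of RT differences across
conditions.

## Synthetic pupil traces

Per trial, in mm of diameter, as a sum of components:

- participant intercept ~ N(5.0, 0.5²) mm and per-trial tonic jitter
  ~ N(0, 0.1²) mm (the latter is what makes baseline-outlier exclusion
  meaningful);
- a slight dilation during the cue (+0.05 mm linear ramp over the 1-s cue);
- the pupillary light response to the noise display: an exponential
  constriction (amplitude ~ N(−1.0, 0.1²) mm across participants, latency
  230 ms after noise onset, time constant 400 ms); the between-participant
  amplitude variability is what gives the window-mean mixed model a
  non-degenerate random-intercept variance;
- the attentional-breadth effect: ordinal cue-eccentricity code ×
  participant slope, ramping linearly from 0 at 1,750 ms post-cue to its
  full value at 2,500 ms and held thereafter (onset and peak window are the
  empirically observed ones; the linear-ramp shape is a modelling choice).
  Slopes are ~ N(0.008, 0.015²) mm per eccentricity unit: the mean matches
  the reported fixed effect, and the SD is set so that roughly two-thirds
  of participants have a positive slope, matching the reported
  interindividual variability and giving a plausible fixed-effect SE
  (~0.0016 at n = 100 vs 0.003 reported);
- white measurement noise (SD 0.15 mm per 1000-Hz sample);
- blinks: Poisson events (0.1 /s, typical of suppressed blinking in
  psychophysics) recorded as 120-ms runs of zero samples;
- output in tracker arbitrary units via au = 500·mm + 1000 (the EyeLink au
  scale and the lab's mm calibration are free parameters; the shipped
  preprocessing config inverts this map).

Nothing in the generator depends on breadth *type* given the eccentricity
code, matching the absence of an eccentricity × type interaction.

What the generator does **not** emulate: biomechanical pupil dynamics,
luminance-coupled trace shapes, gaze-contingent artifacts beyond small
fixational jitter, eye-movement-based exclusions, and temporally correlated
(1/f) measurement noise. Passing tests therefore validate the *statistical
machinery* — estimators, selection procedure, exclusion rules — under the
assumed generative structure, not the physiological realism of any trace.

## Preprocessing

Fixed order, enforced by a state marker on the samples table:
blink interpolation → downsampling by block means (factor 10) → affine
au→mm conversion (coefficients must be supplied; the published lab formula
is not reproduced here) → per-trial baseline subtraction (mean over
[0, 50) ms after cue onset, half-open) → baseline z-flagging. Blinks are
runs of invalid samples (flagged, non-finite or ≤ 0) of at least 20 ms,
extended by a 50-ms margin on both sides, then linearly interpolated
between flanking valid samples; fully blinked trials become missing.
z-scores are computed within participant (the natural scope, since tonic
pupil size differs between people); |z| > 2 excludes the trial. On default
synthetic data total exclusions land in the 3–10 % band around the ~4.55 %
expected from the two-sided 2σ tail plus missing trials.

## Window statistics

Per-trial window means are the dependent variable throughout. The
cross-validation scheme is fixed as: participants are partitioned into 4
seed-deterministic folds; per fold, an intercepts-only mixed model per
10-ms bin on the training folds yields a |t| profile whose peak (ties break
to the earlier bin) is evaluated on the held-out fold; the selected window
is the 100-ms span centered on the mean of the 4 fold peaks, snapped to the
bin grid and clipped to 750–3000 ms; the confirmatory model is then fit on
the full data in that window with random intercepts and slopes.

Numerical choices:

- The per-bin screening fits use a dedicated profiled-likelihood
  random-intercept estimator (`_lme.py`): for a fixed variance ratio the
  GLS solution is closed-form from per-group sufficient statistics, so the
  ML fit is a 1-D search. It matches `statsmodels` MixedLM (ML) estimates
  and is ~100× faster, which matters at 900 fits per dataset. Confirmatory
  and interaction fits use `statsmodels` MixedLM (REML).
- Mixed fits at a variance boundary (a component estimated at ~0, flagged
  as non-converged by the optimizer) are retained as long as the
  fixed-effect standard errors are finite and positive — the lme4
  "singular fit" convention. Downgrading such fits to intercepts-only
  would understate the slope uncertainty. A slopes model that errors or
  returns unusable SEs is refit with intercepts only and the downgrade is
  recorded on the result.
- Two confirmatory statistics are reported: the full-data LME at the
  selected window, and a Stouffer combination of the four held-out fold
  t's. Under a null generative slope the full-data test rejects at the
  nominal 5 % rate (the averaging over fold peaks decouples the window
  from the full-data noise peak), while the Stouffer summary is slightly
  anti-conservative with small held-out folds; the full-data fit is
  therefore the primary confirmatory test and the held-out statistics are
  the leakage-free cross-check.
- Interaction model: eccentricity, breadth type (size = reference,
  dummy-coded) and their product, random intercepts only.
- Wald tests, two-sided, on all fixed effects.

## Behavioral models

Accuracy ~ validity is a binomial mixed model (logit link) with
by-participant random intercepts and validity slopes, fit by variational
Bayes (`statsmodels` `BinomialBayesMixedGLM`, deterministic start); the
reported statistic is the posterior z. RT ~ eccentricity is a linear mixed
model with random intercepts and slopes.

The staircase-efficacy Bayes factor is a one-factor repeated-measures JZS
Bayes factor computed from the default-prior ANOVA formulation: the
condition factor enters through orthonormalized centered contrasts with a
g-prior (scale 0.5), participants as a random nuisance factor (scale 1),
both g's integrated over scaled-inverse-χ² priors on a 64-point log grid.
The linear-model marginal is verified in the tests against the closed-form
Zellner g-prior Bayes factor. A BIC approximation is the fallback and the
method used is always recorded on the result. Numerical agreement with any
particular software's default BF is not claimed — only the > 3 / ≤ 3
classification on clear cases, which is what the exclusion procedure uses.

The absolute performance deviance of a participant is
|acc(near) − acc(overall)| + |acc(medium) − acc(overall)| +
|acc(far) − acc(overall)| with acc(overall) the unweighted mean of the
three (trial counts are balanced by design, making weighting moot). A
published variant of this formula counts the near term twice and omits the
far term; it is available behind `printed_formula=True` but treated as a
typo. The exclusion loop drops the largest-deviance participant (ties break
by participant id) and recomputes BF01 until it exceeds 3, reporting the
exclusion order, the BF trajectory, and an explicit failure status if the
cohort is exhausted.

## Simulation scales

The generator's defaults are the study conditions (1000-Hz traces, 330-trial
sessions, effect sizes above). The simulation studies in the test suite run
at reduced scale as the package's own choice of desk-scale problem sizes:
traces are generated directly at 100 Hz (the rate the analysis sees after
10× downsampling of a 1000-Hz recording, with noise SD interpreted at the
generated rate) and truncated at 3,100 ms; the recovery study uses 100
participants × 240 experimental trials × 20 replicates; the type-I study
uses 12 participants × 72 trials × 200 replicates. Coverage and rejection
criteria use binomial-compatible bands around the nominal rates.

## Known limitations

- The au→mm conversion is a configurable affine map; published calibration
  constants are not bundled.
- The held-out Stouffer combination assumes approximately normal per-fold
  t's; with 2–3 participants per fold it runs slightly hot and is reported
  as a cross-check only.
- The VB logistic fit gives posterior z's, not likelihood-ratio inference;
  its z statistics are larger than REML-style t's would be on the same
  data.
- Gaze is fixational jitter only; gaze-error-based participant exclusion is
  out of scope.
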