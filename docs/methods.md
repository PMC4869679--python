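# Methods

`betarousal` simulates and analyzes a risk-sensitive betting experiment in
which electrodermal activity (EDA) and heart rate (HR) are monitored while
a participant bets on roulette-style gambles. This note documents the
generative model behind the synthetic-data module, the extraction
definitions, the samplers, and the numerical and design choices, in enough
detail to judge what passing tests do — and do not — establish about real
recordings.

## Task structure

A session has 90 trials: 3 win-probability levels (40/60/80%) crossed with
2 choice conditions (active choice vs. computer-dictated "no choice"),
15 trials per cell, arranged in 3 blocks of 30 with 5 trials per cell per
block (pseudo-random order within block). Active trials offer bets of
10/50/90 points; no-choice trials dictate one amount, balanced 5/5/5
across {10, 50, 90} within each no-choice cell (the balance is a package
choice; screen positions are ignored). After the self-paced selection the
wheel spins 7–8.5 s, the outcome (win with the stated probability) is
displayed for 2 s, and a fixation intertrial interval of 8–10 s follows,
long enough for phasic responses to recover. Spin and ITI durations are
drawn uniformly from their ranges.

## Behavioral agent

Active bets follow a softmax over the three options with utility
`theta * x`, `x = (-1, 0, +1)` for bets (10, 50, 90) and

    theta = b_p * (p - 0.6)/0.2 + b_j + delta * a_t

* `b_p` (default 1.5) makes the expected bet strictly increasing in the
  win probability `p`; the default gives expected bets of roughly 20 / 50 /
  80 points at 40/60/80%, i.e. a ~60-point spread between the extreme
  levels, close to the reported behavioral effect. A symmetric
  linear-in-`p` utility cannot reproduce a mildly asymmetric step pattern;
  we accept the symmetric approximation.
* `b_j ~ N(0, 0.4)` is a stable subject-level betting tendency.
* `a_t ~ N(0, 1)` is the trial's latent arousal state (shared with the
  physiology, below) and `delta` is calibrated — see "Arousal coupling".

Response times (ms) are Gaussian around cell means with a negative
win-probability slope, steeper and slower for active trials (defaults:
intercepts 2500/1800 ms, slopes −550/−212 ms per probability step for
active/no-choice, matching the reported A80−A40 = −1100 ms and
N80−N40 = −424 ms differences), subject intercept SD 300 ms, trial noise
SD 450 ms, floored at 200 ms. Outcomes are Bernoulli(p); points change by
± the chosen bet.

## Ground-truth response structure (z scale)

Effects are specified on the within-subject z scale — the scale on which
the models operate after per-participant standardization — and mapped to
raw amplitudes by a fixed scale per channel (1 z = 0.10 µS for EDA,
1.2 bpm for HR). Per-cell mean deviations (order A40 A60 A80 N40 N60 N80,
sum zero):

* EDA: (−0.12, 0, +0.12, +0.05, 0, −0.05) — rising with odds under active
  choice, falling under no choice; interaction
  (A80−A40)−(N80−N40) = 0.34.
* HR acceleration: (−0.17, 0, +0.17, 0, 0, 0) — odds-sensitive only under
  active choice; interaction 0.34.
* HR deceleration: all zero — the null channel.

These magnitudes are the package's own choice: the study this emulates
found the EDA and HR-acceleration interactions credible at n≈63–64, which
requires a true effect of at least ~2.5–3 posterior SDs (~0.11 here), i.e.
~0.3 z; the defaults sit just above that. Subject reactivity `r_j` (the
deviation of the subject's A80−A40 z difference) modifies the active-cell
slope. For HR acceleration it is trait-linked:

    r_j = 0.047 * (BIS_j - mean) - 0.030 * (BAS_j - mean) + N(0, 0.37)

The weights are the reported regression coefficients. The residual SD
(0.37, giving a total reactivity-regression residual SD of ~0.52 once
15-trial sampling noise is included) is set to reproduce the *scale of the
reported credible intervals* (HPD95 widths imply a residual SD near 0.52
at n = 63). The reported Bayesian r² of .08 for the combined trait model
is inconsistent with those interval widths (they imply r² ≈ 0.17); we
match the interval widths because every credibility-pattern check depends
on them, and note that the generator's implied r² is therefore larger
than .08. EDA and HR-deceleration reactivities are trait-free
(SDs 0.35 / 0.30).

Trait scores are integer truncated normals inside instrument ranges
(nonplanning 13–35, BIS 10–27, BAS 22–50), with gender-specific BIS means
(19.9 male / 21.8 female) and a 25:43 male:female cohort at the default
N = 68. No gender differences are injected in behavior or physiology.

Trial-level fluctuation tops each subject's within-subject variance up to
1: the EDA trial deviation equals `s_trial * a_t` (fully coupled to the
arousal state), HR acceleration mixes `0.75 a_t` with independent noise
(so its implied bet coupling is 0.75x the EDA coupling, mirroring the
reported 0.03 vs 0.04 ratio), HR deceleration is independent, where
`s_trial = sqrt(1 - var(cell means))`. Amplitudes of the wrong sign for a
peak-minus-baseline measure (negative SCR/rebound, positive dip) are
clipped at zero — rare by construction (≲0.6% of trials) — and the
*clipped* value is recorded as the trial's truth.

## Arousal coupling calibration

`arousal_coupling` (default 0.04) is defined on the reported scale: the
regression weight of the within-subject z-scored bet on the z-scored
trial EDA response, after win-probability and subject effects. The softmax
perturbation `delta` is derived by a delta-method linearization:

    delta = coupling * s_bet * s_trial / mean_p g'(theta_p)

with `g(theta)` the softmax-expected bet, `s_bet` the within-subject bet
SD (between-cell spread plus within-cell choice variance, computed from
exact softmax moments). A direct large-sample check of the choice rule
recovers the target within ~1.5% (residual attenuation from covariate
measurement noise is ≈1% at the default noise settings).

## Signal synthesis

EDA (100 Hz default) = subject tonic level (~N(6, 1.5) µS) + two slow
sinusoidal drift components + per-trial SCR kernels + white noise
(SD 0.01 µS), clipped at 0 µS. The SCR kernel is a difference of
exponentials (rise τ 0.75 s, decay τ 2 s, 1 s onset latency, peak ≈2.2 s
post-onset, inside the 2–7 s extraction window), linearly tapered to
exactly zero by 14 s so consecutive trials cannot contaminate each other's
baselines.

HR (10 Hz default) = subject baseline (~N(70, 8) bpm) + a slow
respiratory-like oscillation (0.15 Hz, 0.3 bpm) + biphasic trial kernels +
white noise (SD 0.2 bpm). The kernel has two raised-cosine lobes with
disjoint supports: a deceleration dip over 0.2–2.6 s (minimum inside the
0–3 s window) and a rebound over 2.6–6.0 s (maximum inside the 2–6 s
window).

Each trial's kernel is normalized by its own on-grid extremum inside the
extraction window, so with noise off the extracted response equals the
injected amplitude to machine precision (the `noiseless` flag also zeroes
the drift/oscillation terms). With noise on, extremum-based extraction
carries the usual order-statistic bias (≈ +0.02 µS EDA, ≈ ±0.2 bpm HR at
defaults); it is nearly constant per subject and is absorbed by the
within-participant standardization, leaving a small (~4% for HR)
attenuation of z-scale effects — visible in the recovery suite as a bias
well inside Monte-Carlo error. The default rates (100 / 10 Hz rather than
acquisition-hardware kilohertz) resolve the seconds-scale windows while
keeping synthetic studies small; both are configurable, and rates below
4 Hz are rejected.

Excluded-subject corruption: at the default N = 68, 4 subjects' EDA and 5
disjoint subjects' HR traces receive flatline artifact spans (constant
signal over baseline + response windows) on 35% of trials, emulating
electrode failures and unusable recordings; extraction flags flat spans
invalid, the 25% invalid-fraction rule then removes those subjects from
that channel only, and the analysis ns become 64 (EDA) and 63 (HR).

## Extraction definitions

Baseline: mean over the half-open 1-s window [onset−1, onset) (a "last
sample" option exists; the mean is the default as the noise-robust
convention). Responses: EDA max over closed [onset+2, onset+7]; HR
deceleration min over [onset, onset+3]; HR acceleration max over
[onset+2, onset+6]; each minus baseline. The EDA/HR window asymmetry
(7 vs 6 s) is deliberate; the two HR windows overlap and are computed
independently. Window edges are closed with an absolute tolerance of 1e-9
on sample-time comparisons; ties at the max resolve to the earliest
sample. Truncated windows yield a missing (invalid) trial, not an
exception. Per-participant z-scores use the sample SD (n−1) over valid
trials, pooling all six cells (pooled standardization is assumed);
zero-SD participants are flagged and yield no z-scores. Invalid trials
propagate as missing values and are row-deleted per model.

## Models and sampling

All three families are Gaussian hierarchical models fit by exact
block-Gibbs sampling: cell means / coefficients get
Normal(0, (100·sd(y))²) priors (scale-free; equals SD 100 for z-scored
outcomes), SDs get Uniform(0, 10·sd(y)) priors updated by a truncated
inverse-gamma draw on the variance. The ANOVA (6 cell means + subject
random intercepts + homogeneous residual SD) and ANCOVA (win-probability
effects + subject intercepts + trial covariate) are sampled in the
unconstrained parametrization plus a translation-group "sweep" move
(a generalized-Gibbs update of the shared shift between cell means and
subject effects), which preserves the posterior exactly and removes the
slow random walk along the unidentified direction; identified cell means
are reported as `mu_cell + mean(subject effects)` — equivalent to a
sum-to-zero constraint. Because standardized outcomes make the subject
variance nearly zero, the centered Gibbs update of (subject effects,
subject SD) alone would funnel; an interweaving (ASIS) step — a
non-centered truncated-normal redraw of the SD treating the rescaled
effects as N(0,1) ancillaries — restores effective sample sizes from tens
to thousands. RT models are fit on the millisecond scale,
untransformed. The ANCOVA outcome is the within-subject z-scored bet on
active trials, matching the scale of the reported coupling weights.

The engine also provides adaptive random-walk Metropolis blocks (scale
adapted only during burn-in, target acceptance 0.44 scalar / 0.234
vector), used by the beta-binomial reference model that validates the
non-conjugate path. Chains initialize from the prior; default 4 chains ×
25,000 retained draws (100,000 total) after 5,000 burn-in per chain, no
thinning; the desk profile used by tests and the reduced pipeline is
4 × 2,500 retained after 1,000 burn-in (the `--paper-scale` CLI flag
restores the full profile). The exact burn-in/initialization of the
original analysis is not public; these are declared defaults. Convergence
gate: split-chain R-hat < 1.1 for every parameter (diagnostics via arviz,
with constant-chain conventions: R-hat 1.0, ESS 0 with a warning);
non-converged fits are flagged in reports, never silently dropped. Prior
sensitivity refits under alternative prior sets and reports the headline
contrasts side by side, including any convergence failures.

Posterior summaries: 95% HDI by exact sorted-window search over the
empirical draws (multimodal samples still yield one contiguous interval,
with a warning); "credible" = HDI excludes zero; tail probability =
min(Pr<0, Pr>0). Bayesian R² = 1 − var(residuals)/var(data), computed per
draw over a thinned subset (default 1,000 draws) and averaged; a
posterior-mean variant exists for comparison. R² change refits the named
reduced model on identical data.

## Recovery suite and problem sizes

`run_recovery_suite` replicates simulate→extract→fit cycles and reports
bias, RMSE, MC standard error, 95%-HDI coverage, and credible-flag rates
for: the EDA interaction (injected 0.34), BIS/BAS reactivity weights
(+0.047/−0.030), the EDA→bet coupling (0.04), and three structural nulls
(HR-deceleration interaction, nonplanning weight, an ANCOVA with the
uncoupled HR-deceleration covariate). The shipped validation runs 20
replicates at n = 60 subjects on the desk MCMC profile (~3–4 minutes on
one core); single-study analyses default to the full N = 68 design. At
these sizes the trait-weight credible rates sit near their theoretical
power (~50–70%): a β of −.03 with a posterior SD near .015 is
intrinsically a coin-flip effect at n = 60, which is itself a faithful
property of the emulated design.

## What the synthetic data do not capture

Linear-Gaussian amplitudes with a fixed kernel shape (no
amplitude-latency coupling, no SCR shape variability or superposition
within a trial), white measurement noise (no 1/f EDA drift structure, no
heart-rate variability spectrum beyond one oscillation, no motion
artifacts other than flatlines), stationary subject states (no fatigue or
habituation trends), and trait distributions that are independent across
scales. Passing recovery tests therefore demonstrates correctness of the
extraction arithmetic and the inference machinery at realistic effect
sizes and noise levels — not robustness to the full artifact repertoire of
real psychophysiological recordings.
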