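# Methods

## Model

A reach ends with the hand at lateral position `x_hand` (mm, positive =
rightward, relative to the displayed target center). The displayed cursor is
offset by a lateral shift drawn per trial from a discrete distribution
`p(shift_i)`, so `x_cursor = x_hand + shift` holds exactly by construction.

**Observer.** Mid-reach visual feedback gives a sensed cursor centroid
`x_sensed` with cue-dependent Gaussian uncertainty `σ_sensed`: a single dot
(small σ), a 25-dot cloud with per-axis SD 15 mm or 30 mm (larger σ), or no
feedback (σ = ∞). The belief over the current shift is the posterior

    p(shift_i | x_sensed, σ_sensed) ∝ N(x_sensed; shift_i, σ_sensed) · p(shift_i),

computed as a point-wise product over the prior's atoms and renormalized.
The product is evaluated in log space, so it cannot underflow for any finite
σ; σ = ∞ returns the prior and σ = 0 a point mass on the atom nearest
`x_sensed`. The posterior normally lives on the prior's discrete atoms; a
Gaussian-kernel-smoothed variant (`posterior(..., smoothing=bw)`) is
available for illustrating sensed positions that fall off-support, since the
discrete and smoothed readings differ only at the sub-millimeter level for
the built-in priors.

**Actor.** Given a posterior, the actor compensates by the negated minimizer
of the expected power loss

    comp* = −argmin_x Σ_i q_i |shift_i − x|^α ,

so α = 2 reproduces the posterior mean, α = 1 the weighted median, and the
0–1 limit the mode. The minimization is a two-stage vectorized grid scan
(121 coarse + 41 fine points) with parabolic refinement, followed by a
bounded scalar polish (±0.2 mm, xatol 1e−8) that resolves the kinks the
parabola misses when α ≤ 1. Agreement with a dense 0.01 mm grid argmin is
asserted at ≤ 0.02 mm over random posteriors. For α ≤ 1 the expected loss
can have a flat stretch of minimizers; a dense scan detects this, the
minimizer closest to the negated posterior mean is returned, and the
solution is flagged ambiguous.

## Built-in shift distributions

- 7-point priors (cue-uncertainty experiment): equally spaced at 5 mm, the
  modal atom carrying 9/21 of the mass and the six others 2/21 each.
  Right-skew spans 0..30 mm with mode 0 (mean 10, median 5); left-skew spans
  −10..20 mm with mode 20 (mean 10, median 15). The 5 mm spacing is the
  unique equally spaced 7-point reconstruction consistent with the range,
  moments and the (rounded) 42.8%/9.5% modal/non-modal frequencies, which
  are stored as the exact rationals 9/21 and 2/21.
- 3-point distributions (end-point experiment): support {−14, 0, 14} mm with
  modal probability 0.6 (mode −14 for right skew, +14 for left skew), giving
  mean ∓5.6 mm and median = mode = ∓14 mm. End-point schedules sample the
  500-trial multiset (300/100/100) without replacement — a seeded uniform
  permutation, identical as a multiset across seeds.

Cue conditions in the cue-uncertainty schedule are independent categorical
draws with expected ratio dot : cloud15 : cloud30 : none = 3:1:1:1 (the
protocol randomizes cues across trials without block structure).

## End-point aims

With Gaussian motor noise `σ_mv`, the cursor density is the mixture
`Σ_i p_i N(x; aim + shift_i, σ_mv)`, evaluated by default on a
[−80, 80] mm grid at 0.02 mm (covering all shifts ± 5σ of any plausible
noise; the constructor rejects grids clipping ≥ 1e−3 of the mass).

- `aim_min_sq_error` = −(mean(d) − target): the expected squared error is
  minimized when the cursor mean sits on the target, independent of σ_mv.
  A numerical variant minimizes the sampled expected loss and agrees with
  the closed form to ≤ 0.02 mm.
- `aim_max_hits_mode` aligns the density mode with the target. Since aiming
  only translates the density, the solution is `target − mode` of the
  zero-aim mixture; the mode is an argmax with parabolic refinement over the
  top three grid points, equal-height peaks are flagged and the
  smallest-|aim| alignment returned.
- `aim_max_hits_width` maximizes the closed-form probability that the cursor
  lands within a finite-width target (default 14 mm),
  `Σ_i p_i [Φ((w/2 − m_i)/σ) − Φ((−w/2 − m_i)/σ)]`; it converges to the
  mode solution as w → 0.

Both max-hits readings are reported because they bracket a genuine modeling
ambiguity: for the right-skewed 3-point distribution at σ_mv = 10.6 / 9.2 /
8.8 mm, the mode-alignment aims are 11.29 / 12.11 / 12.33 mm and the
14 mm-target aims are 10.79 / 11.56 / 11.76 mm. Either way the max-hits aim
strictly exceeds the mean-seeking +5.6 mm and grows as motor noise shrinks
— the qualitative dissociation the paradigm tests.

## Observer-model fit

`fit_bayes_model` recovers `(α, σ_dot, σ_cloud15, σ_cloud30)` from a
participant's 7 × 4 table of mean compensations (by default the last 1000
of 2000 trials, so the averaged window reflects a learned prior). The
objective is the weighted least absolute error between the table and the
model's optimal-compensation surface, with per-cue weights equal to the
prior probabilities of the shifts: each cue column sums to 1, so the four
cue conditions contribute equally while shifts weigh by how often they
occur. The withheld cue is included with σ fixed at ∞; its prediction is
shift-independent and depends only on α, anchoring the loss exponent.

Nelder–Mead runs on log-transformed parameters (positivity without bound
constraints) from 8 starts (α ∈ {1, 1.5, 2, 2.5} × two σ scalings of
(5, 15, 30) mm), fatol 1e−6, at most 5000 evaluations per start; the best
start wins. On noiseless tables the generating parameters are recovered to
well under 1%. With 2 mm execution noise and 2000 trials, the mean
recovered α over 10 simulants is within ±0.1 of the generating value for
both α = 2 and α = 1 (the test suite checks exactly this). Large sensed
SDs are the weakest-identified corner: σ ≳ 3× the prior SD compresses the
compensation slope toward zero, so its relative error grows accordingly.

## Synthetic participants

Simulants are ideal observers plus Gaussian execution noise; the sensed
centroid equals the true shift by default (optional Gaussian sensing noise
exists for robustness studies). A reach is rewarded when `|cursor| ≤ 7 mm`
(half the 14 mm target diameter) and the participant's group is reinforced;
in the cue-uncertainty experiment reward is restricted to single-dot trials,
matching the protocol. End-point simulants hold one asymptotic aim chosen
by policy (mean-seeking, mode-seeking, or fixed); a single-exponential
approach from 0 with time constant 25 trials is prepended so learning-curve
code sees realistic early data — the asymptote is reached well before trial
100 and all analyses use the final-400-trial window, so the transient's
exact shape is immaterial. The transient is a modeling convenience, not a
theory of trial-by-trial learning: no learning-rate model is implemented.

Dot clouds are generated by an explicit Box–Muller transform from seeded
uniforms, reproducing the stimulus-generation recipe rather than delegating
to a library normal sampler.

What the generator deliberately omits: online (mid-reach) corrections,
kinematics and timing, y-axis behavior, between-participant parameter
scatter, and any drift in the learned prior. Passing tests therefore show
that the pipeline's estimators and tests behave correctly on data satisfying
the model's assumptions — not that real participants satisfy them.

## Resampling statistics

Bootstrap hypothesis tests shift the data to satisfy the null (one sample:
recentered on the null value; two samples: both groups recentered on the
pooled mean) and resample with replacement, 1e6 resamples by default. The
default statistic is studentized (bootstrap-t): mean differences are
compared on the scale of their resampled standard errors, which keeps the
one-sample type-I error at ≈0.044 for n = 20 where the raw-mean statistic
inflates it to ≈0.071 (both measured over thousands of null simulations in
the test suite at reduced resample counts). The raw-mean reading remains
available as `statistic="mean"`, and a label-permutation variant of the
two-sample test as `method="permutation"`, since the literature's "no
parameter assumptions" phrasing does not pin down one recipe. Degenerate
zero-variance inputs return exact p ∈ {0, 1}.

Holm–Bonferroni adjustment is delegated to statsmodels; the
common-language effect size θ̂ (percentage of cross-group pairs with
a > b, ties half) is exact pairwise enumeration up to 1e7 pairs and seeded
Monte Carlo beyond; confidence intervals are percentile bootstrap intervals
of the mean (measured coverage ≈0.95 at n = 100).

## Problem sizes used by the test and acceptance suites

Unit tests run reduced simulation sizes (hundreds to a few thousand
resamples or trials) chosen so each stochastic assertion sits inside an
explicit binomial, chi-square or CLT envelope. The heavier end-to-end
checks use: 10 simulants per loss exponent for parameter recovery (2000
trials each), 100 random posteriors for optimizer–oracle equivalence,
10,000 null simulations × 10,000 resamples for bootstrap calibration, and
90 end-point simulants (15 per group per skew, σ_mv = 10.6/9.2/8.8 mm) for
the group-level dissociation.

## Known limitations

- The discrete-atom posterior is exact for the built-in priors but cannot
  represent beliefs between atoms; use the smoothed variant when that
  matters.
- The mode-alignment aim inherits the 0.02 mm grid resolution of the
  density (refined parabolically, in practice ~1e−3 mm).
- The fit assumes the 28-cell table is complete; sparse logs (fewer than
  ~40 trials per rare cell on average) should be averaged over longer
  windows.
- Bootstrap p-values are Monte Carlo estimates; at 1e6 resamples their SE
  is ≤ 5e−4.
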