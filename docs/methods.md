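# Methods

## The model

`ddtcycle` models the intermitotic time (IMT) of a proliferating cell — the
interval between its birth at the mother's mitosis and its own division — as
a sequence of `m >= 1` checkpoint passages.  Checkpoint `i` is a
drift–diffusion+threshold (DDT) process: a latent variable `y_i` starts at 0,
obeys the Itô SDE

    dy_i = mu_i dt + sigma_i dW_t,        y_i(0) = 0,

and the checkpoint is passed the first time `y_i = 1`.  The passage time is
therefore Wald (inverse Gaussian) distributed,

    f(t; mu, sigma) = 1 / (sigma sqrt(2 pi t^3))
                      * exp( -(mu t - 1)^2 / (2 sigma^2 t) ),    t > 0,

with mean `1/mu`, variance `sigma^2 / mu^3`, and coefficient of variation
`CV = sigma / sqrt(mu)`.  The IMT is the sum of the `m` independent passage
times, so its density is the m-fold convolution of Wald densities with
parameter vector `(mu_1, sigma_1, ..., mu_m, sigma_m)` — `2m` free
parameters.  Because convolution commutes, the checkpoint *order* is not
identifiable from IMT data; ordering comes only from external phase data
(see "Phase analysis").

The competitor model is the exponentially-modified Gaussian (EMG): a
Gaussian "transit" time plus an exponential "dwell" time (3 parameters).
Unlike the DDT threshold mechanism it has no switch-like commitment; it is
included because it is a long-standing empirical description of IMT
distributions.

Assumptions worth stating: checkpoints are independent and strictly
sequential; drift and diffusion are time-constant (no explicit growth
function); every cell completes the cycle (death and truncation are handled
by censoring the *data*, not by the likelihood).

## Numerical density machinery

DDT densities for `m >= 2` are evaluated on a uniform time grid
`{0, h, 2h, ...}`:

- **Convolution** is the left-hand Riemann sum
  `(f*g)(kh) ≈ h * sum_j f(jh) g((k-j)h)`, computed via FFT
  (`scipy.signal.fftconvolve`), which reproduces the direct sum to ~1e-15
  relative accuracy (asserted to 1e-10 in tests).  Grid mass defects are
  reported, never silently renormalized.
- **Delta substitution.**  When a component's passage-time standard deviation
  `sqrt(sigma^2/mu^3)` falls below `c * h` (default multiplier `c = 2`), or a
  self-sized trial grid mis-normalizes by more than `1e-3`, the grid cannot
  resolve it.  The component is replaced by a Dirac point mass at its mean
  `1/mu`, which turns its contribution to the convolution into an exact
  *translation* of the remaining density.  Translations are applied by linear
  interpolation at the grid nodes, so a shift falling between nodes never
  collapses into a single tall bin.  If *every* component is substitutable
  the model would degenerate to a point-mass IMT; this is an error and the
  caller must reduce `m`.
- **Error bound.**  Replacing a concentrated density `h` (std `s`) by a point
  mass at its mean inside `∫ h(u) f(t-u) du` perturbs the result by at most
  `s * sup|f'|` to first order; `sup|f'|` is estimated by finite differences
  on the convolved remainder.  The bound is conservative, cheap, and is
  validated in tests against brute-force fine-grid convolution of a
  marginally-concentrated component.
- **Defaults**: grid step `h = 0.01` h; horizon `t_max = 1.5 * max(IMT)`
  during fitting.  The left-Riemann convolution at lag `t` only consumes
  component values at arguments `<= t`, so the horizon does not corrupt the
  density below it; tail mass beyond the horizon is reported as a defect.

## Likelihood and optimization

The log-likelihood of an IMT sample is the sum of log model densities at the
observations, with off-grid evaluation by linear interpolation and exact
`-inf` (never NaN) where the density is zero.  One-checkpoint DDT and EMG
likelihoods use their closed forms directly.  The EMG is evaluated in its
standard whole-real-line form without renormalization to positive support;
for fitted IMT data (`gauss_mean >> gauss_sd`) the negative-support mass is
below 1e-10 and the effect is negligible.

Optimization is Nelder–Mead in log-parameter space (positivity by
construction; `gauss_mean` stays on its natural scale), from multi-start
method-of-moments initialization: the sample mean and variance are split
across the `m` checkpoints with Dirichlet-distributed weights per start
(first start: equal split) and inverted through `mean = 1/mu`,
`var = sigma^2/mu^3`.  Default 20 starts, at most 2000 objective evaluations
each.  The diffusion floor is `sigma >= 1e-6`; below the concentration
threshold the density layer substitutes a delta, so the likelihood remains
well defined as `sigma -> 0`.

**Refined-grid reporting.**  The likelihood reported for a grid-evaluated
fit is recomputed on a refined grid (step `min(0.005, h/2)`), and the
per-datum difference is stored as `grid_drift`.  This is not cosmetic: a
coarse optimization grid can *inflate* the likelihood of sharply-peaked
extreme-CV components (we measured a spurious +12.6 log-likelihood for a
three-checkpoint fit at `h = 0.05` that vanished below `h = 0.01`), which
would bias AICc toward spurious checkpoints.  With refined reporting, model
selection on synthetic data recovers the generating family reliably.

Fitted checkpoint blocks are stored in canonical order — descending CV, ties
broken by larger mean — so parameter vectors are comparable across fits
(bootstrap replicates, two-sample differences).  This is pure relabeling;
the likelihood is permutation invariant.

## Model selection

Candidates (default DDT1, DDT2, DDT3, EMG) are compared by

    AICc = -2 log L + 2k + 2k(k+1) / (n - k - 1),

and the evidence ratio `AICp_i = exp((min_j AICc_j - AICc_i)/2)`, which is
exactly 1 for the preferred (minimum-AICc) model.  Pairwise,
`AICp_i / AICp_j << 1` reads "model j clearly superior"; a ratio above 0.1
is reported as "cannot be entirely ruled out" (a reporting convention, not a
decision rule).  Exact AICc ties prefer fewer parameters, then earlier list
position.  Non-converged fits are excluded from the table with a warning
rather than assigned sentinel values.

Because an extra checkpoint can always be driven toward a near-delta
(adding a tiny translation), nested DDT fits satisfy
`loglik(DDT3) >= loglik(DDT2) - epsilon` in practice; AICc's penalty is what
rejects the spurious checkpoint.

## Bootstrap

*Percentile intervals*: B with-replacement resamples of the `n`
observations (each of size `n`), a refit per resample, and percentile
intervals from the ensemble.  Default `B = 1000`.  Replicate fits are
warm-started at the original optimum plus 5 fresh method-of-moments starts
(a full 20-start search per replicate would be wasteful; we verified on
synthetic data that warm-started replicate ensembles have the same spread
as fully-restarted ones).  Non-converged replicates are dropped and
counted; more than 20% failures voids the ensemble.  Replicate seeds derive
deterministically from the master seed, so any single replicate can be
reproduced in isolation.

*Two-sample test*: to compare a parameter between two conditions the
samples are pooled; each of B replicates resamples both original sizes from
the pool (the null), refits both, and records the difference `delta'`.  The
p-value is the proportion of `delta'` at least as extreme as the observed
`delta_hat`, one-sided toward the observed sign, with ties counting as
extreme (the unit step is 1 at 0).  An observed difference of exactly 0
falls between the two one-sided branches and is assigned `p = 1` by
convention, flagged.

**Calibration note.**  Because the tested tail is *chosen by the sign of the
observed difference*, this p-value is uniform on (0, 0.5) under the null,
not (0, 1): rejecting when `p < alpha` has type-I error `~2 alpha`.  The
raw one-sided values are reported exactly as defined (they are what the
resampling scheme computes), and `TwoSampleResult.p_two_sided` /
`.reject(alpha)` provide the sign-agnostic, calibrated decision (double the
observed-sign tail).  Calibration of the two-sided rule is verified by
simulation in the acceptance suite.

## Censoring pipeline

Order: death → end-of-experiment (EoE) → crowding → optional drug delay.

1. **Death**: cells with a death time are excluded outright (death is rare
   in the targeted experiments; no competing-risk likelihood is attempted).
2. **EoE** (`frac = 0.96`): the cutoff is the latest birth time such that,
   among cells born at or before it, the fraction with an observed division
   *strictly exceeds* 96%; later-born cells and any remaining non-dividers
   are removed.  If no birth time qualifies the experiment is too truncated
   and the stage raises.
3. **Crowding** (`alpha = 0.01`): Spearman rank correlation between birth
   time and IMT.  If the full sample is significant, birth-ordered prefixes
   are scanned from latest to earliest and the cutoff is the latest birth
   whose prefix is *not* significant.  The scan direction/granularity was a
   genuinely open design point; the prefix scan was chosen because it is
   deterministic, auditable, and monotone on the obvious synthetic cases.
   P-values use the large-sample approximation for `n > 30` and a seeded
   10,000-permutation test otherwise (vectorized over rank permutations).
   Fewer than 5 dividing cells, or constant IMTs, make the correlation
   unstable: the stage warns and removes nothing.
4. **Drug delay** (`t_min = 10` h, off by default): removes cells born
   strictly before `t_min`, for runs where the drug effect stabilizes
   slowly.

Every stage reports counts and cutoffs (`CensorReport`), the counts must
balance exactly, and the pipeline is idempotent on its own output.

## Synthetic data generator

`generate_dataset` emulates an asynchronous time-lapse proliferation
experiment: births uniform over a window (default 24 h), true IMTs drawn
from the configured DDT model, an independent exponential death clock
(default off), an observation horizon (default 96 h) after which divisions
are unobserved, imaging-frame quantization (default 0.1 h = 6 min frames,
detection at the first frame *after* an event, i.e. round up), and a
crowding term that adds `slope * (birth - onset)+` hours to the IMT of
late-born cells.  With `g1_offset` set, each cell carries a Fucci-style
G1→S onset at `birth + offset + first-checkpoint passage`, so
G1 = constant + H-passage and S-G2-M is the remainder; the two phase
durations sum to the IMT identically.

What it does **not** emulate: mother–daughter IMT correlation, spatial
crowding mechanics, segmentation/tracking errors, or interval censoring of
the event times beyond frame quantization.  Tests passing on this generator
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions plus the listed observation artifacts — not
robustness to lineage correlation or tracking noise.

Default conditions (births over 24 h, 6-min frames, 96 h horizon, rare
death) mirror a typical several-day imaging run of a cell line with a
~14 h mean cycle.

## Phase analysis

For a fitted DDT model the per-checkpoint CVs (`sigma/sqrt(mu)`) rank the
phases: the largest-CV checkpoint is labeled **H** (highly variable), the
rest **L** (or L1, L2 in descending CV).  Exact CV ties order by larger
mean.  With phase-resolved duration data (G1 vs S-G2-M), the H density is
translated onto the G1 durations by maximizing
`sum log f(t_i - tau; mu_H, sigma_H)` over `tau in [0, min(G1))` — a 0.05 h
grid scan plus bounded golden-section refinement (the boundary is excluded:
the smallest datum would have zero density there).  The L density is then
translated *left* by the same `tau_hat` and compared to the S-G2-M
durations; no second offset is fitted.  Reported diagnostics are KS
sup-distances (shifted and unshifted) and data-vs-model moment tables.
Whether the offset should be fitted on G1 alone or jointly on both
compartments was open; G1-only was chosen as the direct reading of the
procedure, with the S-G2-M comparison serving as an out-of-sample check.

## Problem sizes used in the test suite

The statistical studies in the acceptance tests are sized to run on a
single CPU in a few minutes each, as the package's own verification budget:

- parameter recovery: one DDT2 fit at the default grid (`h = 0.01`,
  20 starts) on `n = 2000`;
- bootstrap coverage: 20 replicate datasets (`n = 2000`, `B = 200`) with a
  coarser likelihood grid (`h = 0.05`, horizon `1.2 * max`) and
  warm-start-only replicate fits — the refined-grid report keeps the final
  likelihoods honest, and interval spread was verified to match
  fully-restarted replicates;
- selection consistency: 7 seeded replicates per generating family at
  `n = 1000` (a majority property: single samples near the decision
  boundary can legitimately tip to a neighboring model);
- two-sample calibration: 100 null trials at `n = 300`, `B = 200`,
  asserting both the nominal rate of the calibrated two-sided rule and the
  ~2 alpha rate of the raw sign-selected p-value.

## Known limitations

- The likelihood ignores interval censoring from frame quantization;
  with 6–30 min frames and ~14 h cycles the quantization noise is well
  below the biological variability.
- The EMG is not renormalized to positive support (negligible for realistic
  parameters, but a fitted EMG with `gauss_mean` close to 0 would need
  care).
- Percentile intervals are first-order; no BCa or studentization.
- The delta-substitution error bound is first-order in the component width;
  for components sitting exactly at the substitution threshold the reported
  bound can be loose in either direction (validated empirically, not
  proven sharp).
- Death is excluded from the data rather than modeled as a competing risk;
  in regimes where death is not rare this biases the IMT sample toward
  fast-cycling cells.
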