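# Methods

`conflictlab` implements the statistical machinery of a two-group
proportion-congruency experiment — a numerical Stroop task with list-wide
(LWPC) and item-specific (ISPC) congruency-proportion manipulations — and
a synthetic-data layer that emulates the study's structure, because such
participant data are typically private.  This note records the models,
the defaults and why they hold, the numerical choices, and what the
synthetic data do and do not establish.

## Experimental design generation

Each block holds 134 trials: 94 inducer items carrying the congruency
bias and 40 diagnostic items split exactly 20/20, which measure control
transfer uncontaminated by stimulus–response learning.  The inducer bias
is applied at the item level: `round(0.8 * 94) = 75` biased vs 19
unbiased trials.  (A block-level proportion of exactly 70% and an
inducer-level bias of exactly 80% cannot both be integral; the item-level
rule is honoured, making the block-level proportion ≈ 70.9% incongruent
in an MI block.)  ISPC blocks attach the bias to the digit-pair magnitude
class (small pairs < 5, large pairs > 5) with overall congruency balanced
at 67/67.

Item pools use four digit pairs per magnitude class with numerical
distances 1–2 (small from 1–4, large from 6–9); within each class two
pairs are randomly assigned the inducer role and two the diagnostic role
per participant.  These pools are synthetic stand-ins constructed to the
published constraints, not the original stimulus lists.

Trial orders are pseudo-randomized by sequential placement with
backtracking under named, pluggable constraints (defaults: no immediate
item repetition; at most 3 consecutive trials of equal congruency; at
most 4 consecutive identical response sides).  Two implementation points
matter:

* Candidates are drawn with probability proportional to their remaining
  multiplicity (a weighted shuffle).  Without this, the rarer congruency
  is consumed too fast and the sequence strands an unplaceable
  same-congruency tail almost surely.
* Each constraint can veto placements through a run-capacity lookahead:
  with a trailing run of length k of value v, at most
  `(max_run − k) + max_run · m_other` further trials of v can ever be
  placed.  The bound is necessary, not sufficient; one-step backtracking
  (up to 100 dead ends) and restarts from a random earlier position (up
  to 10 000) remain as the safety net.  An empty feasible set at an empty
  prefix is a proof of unsatisfiability and raises immediately, naming
  the violated constraint.

Counterbalancing is cyclic with period 4: bit 0 of the participant index
selects ISPC-first vs LWPC-first, bit 1 selects MI-first within the LWPC
half and doubles as the magnitude-class↔bias mapping bit.  Trial timing
(fixation, 2000 ms response deadline, 800 ms blank) is carried as
metadata only.  The source protocol states the fixation window
inconsistently (300–600 ms uniform vs 300–360 ms); both options are
recorded and neither is asserted.

## Behavioural simulation and model

Reaction times follow a shifted log-normal:

    rt = δ_g + exp(η),   η ~ Normal(μ, σ)
    μ  = μ0_g + b_participant + b_item + β_C x_C + β_P x_P + β_CP x_C x_P

with contrast codes x ∈ {−0.5, +0.5} (incongruent and MI positive), so
each β is on the scale of a cell difference in log-ms.  Errors are an
independent Bernoulli per congruency — they exist so trial filtering has
work to do, not as a choice model.  Trial filtering retains correct
trials with rt ≥ 200 ms; the accuracy rule is credited first by default
(the retained set is order-invariant, only the per-rule counts differ).

Calibration presets (`hc_like`, `pd_like`) encode the published
group-level LWPC inducer estimates as generating values — conflict effect
79.5 vs 62.1 ms, proportion effect 6.0 vs 8.3 ms, interaction −47.8 vs
−35.9 ms, grand means 673 vs 747 ms, mean error rates 1.5% vs 3.1% — by
numerically inverting the marginal-mean equations (the ms-scale cell mean
is δ + exp(μ + (σ² + τ_p² + τ_i²)/2)).  They are calibration fixtures,
not reproduction claims.  Residual and random-effect scales (σ = 0.3,
τ_participant = 0.12, τ_item = 0.04 log-ms, δ = 200 ms) are chosen as
typical of choice-RT data; they are not published values.

### Posterior sampling

No probabilistic-programming backend is assumed.  The sampler is a
blocked Gibbs scheme exploiting that, conditional on the shifts,
log(rt − δ_g) is linear-Gaussian:

* fixed effects: exact conjugate multivariate-normal update;
* random intercepts: exact conditionally-independent normal updates;
* σ, τ_participant, τ_item: univariate slice sampling on the log scale
  (half-normal priors are not conditionally conjugate);
* δ_g: slice sampling along the reparametrization that holds
  m_g = δ_g + exp(μ0_g) fixed, with the corresponding Jacobian.  The
  shift and intercept lie on a strong posterior ridge; updating δ_g
  alone mixes poorly, whereas the ridge-aligned move decorrelates in a
  few sweeps;
* interweaving translation moves between μ0_g and the means of the
  random-intercept vectors (sampled from their exact Gaussian
  conditionals), removing the additive non-identifiability that
  otherwise dominates the autocorrelation time.

Default priors: μ0 ~ Normal(6, 0.5); β ~ Normal(0, 0.3);
σ ~ HalfNormal(0.5); τ ~ HalfNormal(0.3); δ_g ~ Uniform(0, 0.95 × min
observed RT of group g).  Prior-predictive simulation under these priors
keeps the central 95% of simulated RTs inside [150, 5000] ms, the
plausibility window enforced by `prior_predictive`.

Convergence is summarized by the potential scale reduction factor
(R̂ < 1.1 for every stored parameter, computed by ArviZ); a
non-converged fit is returned flagged, never silently accepted.
Participants with fewer than 40 trials in any design cell are excluded
from fits (the threshold stated for the EEG analysis, applied
behaviourally for symmetry; it is a keyword argument, and the
reduced-scale pipeline default lowers it to 30 because two blocks yield
39-trial minority cells).  The default sampler configuration is 4 chains
× 500 warmup / 1000 kept draws; the full-scale configuration (4 × 2000 /
10 000) is available via `MCMCConfig.paper_scale()`.

Estimated marginal means are computed per draw at the four cells with
random effects at zero, on the expectation scale by default
(EMM = δ_g + exp(μ_cell + σ²/2)); a median-scale option drops the σ²/2
term.  The back-transformation convention is a genuine free choice — the
expectation scale is used because the calibration targets are mean RTs.
Conflict effects, their MI−MC difference (the adaptive-control index),
the incongruent-improvement contrast, and its between-group difference
are exact linear functions of the EMM draws and therefore bit-identical
on recomputation.

Prior transfer from inducer to diagnostic fits replaces each
fixed-effect prior by Normal(posterior mean, widen × posterior SD),
widen = 2 by default.  The widening factor is this package's decision;
the source procedure is not public beyond the fact that inducer
information was used.

## Model comparison

Evidence is estimated by bridge sampling: the iterative optimal-bridge
estimator between the second half of the posterior draws and a
moment-matched multivariate-normal proposal fitted to the first half, on
the unconstrained scale (log for σ and τ, scaled logit for δ_g, with the
corresponding Jacobians in the target density).  The estimator reports
its iteration count and an approximate relative MC error (iid formula —
an understatement for autocorrelated draws; it is used as a
self-consistency check, not a confidence interval).

Bayes inclusion factors use the matched-models rule with equal prior
weights, averaging on the evidence scale via log-sum-exp:
BIF(C) = mean{C, C+P} / mean{null, P}, BIF(P) symmetric, and
BIF(interaction) = {C+P+CP} / {C+P}.  The numerator set for a main
effect is the average of the models containing it and not the
interaction, consistent with the stated null of the source analysis.
Jeffreys evidence bands are half-open [lower, upper): anecdotal up to 3,
moderate 3–10, strong 10–30, substantial from 30, with reciprocal bands
for evidence favouring the null.  Families are fitted per group.

## EEG simulation

Epochs are fresh 1/f Gaussian noise (exponent 1, RMS 10 µV) per trial
and channel, plus a Hanning-windowed 6 Hz burst at 0.30–0.80 s
post-stimulus over fronto-central channels (Gaussian spatial profile
around FCz, SD 0.35 in normalized head coordinates).  Burst amplitude:

    base_theta + conflict_gain · 1[incongruent] · (1 − proportion_reduction · 1[MI])

with defaults base 8 µV, gain 8 µV, reduction 0.5 — i.e. incongruent
trials carry extra theta and that conflict response is halved when
conflict is expected, the adaptive-control signature whose sign the
analysis must recover.  Burst phase is randomized per trial so injected
power is non-phase-locked (total power, not an evoked response).
Response-locked simulation shifts the burst back by each trial's RT.

The montage is a schematic 31-channel 10-20 layout (not the 128-channel
original): spatial adjacency and cluster behaviour are identical in kind
and the tests stay fast.  Adjacency connects channels within a 0.45
radius in normalized layout units (on this montage: 4–8 neighbours per
channel, FCz's neighbours being Fz, FC1, FC2 and Cz).  No artefacts are
simulated; the preprocessing chain of real recordings is out of scope.

## Time-frequency analysis

Morlet wavelet power: 20 centre frequencies log-spaced 2–30 Hz
(f_k = 2·15^(k/19)), cycles log-spaced 3–10, kernels unit-energy
normalized, half-width 3.5 time-SDs.  Convolution is by FFT with mirror
padding of one maximal kernel half-width, which both eliminates
wrap-around and lets the circular FFT length cover only the padded
signal.  The inverse transform is evaluated directly on the 125 Hz
output grid by folding the product spectrum (a standard FFT decimation
identity), which is exact and cuts the dominant cost by the decimation
factor.  An epoch shorter than the longest kernel triggers an explicit
edge-effect warning.

Decibel baselining divides by the mean power of a reference window —
[0, 1] s stimulus-locked, [−1, 0] s response-locked — computed per
channel × frequency over the condition-agnostic trial average (the
default; a per-trial divisor is available).  The stored divisor makes
the conversion invertible.  Note that the *mean of per-trial dB* of
stationary noise is biased (≈ −2.5 dB for exponential-distributed
single-trial power); the self-normalization property (0 ± 0.1 dB) holds
for the dB of the trial-averaged spectrum, and tests check exactly that.

The theta band 4–8 Hz contains five grid frequencies (4.079, 4.704,
5.424, 6.255, 7.213 Hz); theta averaging is an unweighted mean over
them.

## Mass-univariate regression and cluster inference

Per participant, ordinary least squares with effect-coded regressors
(intercept, congruency, proportion, product; codes ±0.5) at every
(channel, frequency, time) point of the dB-scaled TFR, inducer and
diagnostic trials pooled.  Marginal means and conflict maps are linear
in the betas; with ±0.5 coding the adaptive map conflict(MI) −
conflict(MC) equals the interaction beta exactly.  On balanced designs
beta-derived cell means equal brute-force cell averages to numerical
precision (oracle-tested); the beta-based route is used because it also
handles the mildly unbalanced cells the proportion manipulation
produces.

Group inference: one-sample (dependent-samples) t of the participant
maps against zero; supra-threshold clustering at the two-sided critical
t at cluster-alpha 0.05 with N−1 df; connectivity is spatial adjacency
at the same sample or temporal adjacency (consecutive 125 Hz samples) on
the same channel; cluster mass is the summed t (max-sum convention).
The null permutes by sign-flipping whole participant maps and records
the maximum |cluster mass| over both signs — a single two-sided null.
Sampled p-values use the add-one rule (1 + exceedances)/(1 + n_perm),
which can never be zero; for N ≤ 12 all 2^N sign assignments are
enumerated instead and p-values are exact (the identity assignment keeps
p ≥ 2^−N).  Zero-variance points yield t = 0 for 0/0 and ±∞ (with a
warning) for a nonzero mean.  Cluster reports carry (start s, end s, p,
channels), the format in which such results are conventionally printed.

## Pipeline and problem sizes

`run_experiment` derives all stage seeds from one master seed via
`SeedSequence.spawn`, writes every table next to a MANIFEST with a
config hash, and skips recomputation when re-run with an unchanged
config against complete outputs.  Reduced-scale defaults: 8 participants
per group, two LWPC blocks, 4 × 500/1000 MCMC, 1000 permutations (or
exhaustive below N = 13); `--paper-scale` restores the published
dimensions.  The acceptance-style validation suites use deliberately
reduced problem sizes chosen once: parameter recovery at 8 participants
× 160 trials with 2 × 250/400 draws; family-wise-error calibration on
5-channel × 30-sample maps at N = 8 over 500 simulations; end-to-end
theta-cluster detection at 10 participants × 160 trials on a 6-channel
fronto-central montage over 50 replicates per condition.

## What the synthetic data do not show

The generators match the study's *structure* (design counts, effect
magnitudes, error rates, theta-burst direction), not its realism: no
artefacts, volume conduction, between-participant montage variation,
RT–theta coupling, sequential (trial-history) effects, or item-specific
learning dynamics.  Green tests certify that the estimators recover what
the generators inject at the stated sizes — parameter recovery,
calibrated error rates, exactness of enumerated nulls — not that the
published findings would replicate on new participants.  Bridge-sampling
accuracy is verified against a closed-form conjugate evidence; its MC
error on hierarchical fits is approximate.  The JZS Bayes factor
recomputed from the printed t statistic (1.647) differs from the printed
1.66 in the second decimal because the printed t is itself rounded.
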