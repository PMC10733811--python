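# conflictlab

Simulation and analysis of **proportion-congruency conflict-adaptation
experiments**: the class of two-group studies (e.g. patients vs matched
controls) that measure proactive and reactive cognitive control with a
conflict task whose congruency proportions are manipulated list-wide
(LWPC) or item-specific (ISPC), while EEG midline-frontal theta tracks
conflict monitoring.

The package is aimed at researchers who want to prototype, validate, or
power such an analysis end to end without access to participant data: it
ships generators that emulate the structure of a published study design
(pseudo-randomized 134-trial blocks with 94 biased inducer and 40
unbiased diagnostic items, two groups of ~30), and the full analysis
stack those data feed.

## What it computes

**Behaviour.** Correct-trial RTs (rt ≥ 200 ms) are modelled with a
hierarchical shifted log-normal:

    rt = δ_g + exp(η),   η ~ N(μ0_g + b_subj + b_item
                               + β_C x_C + β_P x_P + β_CP x_C x_P,  σ)

with contrast codes x ∈ {−½, +½}, participant/item random intercepts,
and a group-specific non-decision shift δ_g.  Posterior sampling is a
blocked Gibbs/slice scheme (conjugate updates for all location
parameters, ridge-aligned updates for the shift), with R̂ convergence
reporting.  From the posterior: millisecond-scale estimated marginal
means per cell, conflict effects (incongruent − congruent), their MI−MC
difference (the adaptive-control index), and Bayes inclusion factors
from bridge-sampling marginal likelihoods over the matched model family
{null, C, P, C+P, C+P+CP}, labelled with Jeffreys evidence bands.

**EEG.** Morlet wavelet power (20 log-spaced frequencies 2–30 Hz, cycles
3–10) via FFT convolution, decibel baselining, per-participant OLS over
every (electrode, frequency, time) point with effect-coded contrasts,
theta-band (4–8 Hz) conflict-effect maps, and group-level cluster-based
sign-flip permutation tests (max-sum cluster mass, exact enumeration for
N ≤ 12, add-one p-values).

**Descriptives.** Pooled/Welch t tests and Yates-corrected chi-square
from printed summary statistics, and the default two-sample JZS Bayes
factor (Cauchy scale √2/2) from a t statistic.

## Worked example

```python
import pandas as pd
from conflictlab.behavior import preset, simulate_behavior, filter_trials
from conflictlab.rtmodel import (ModelSpec, MCMCConfig, fit_shifted_lognormal,
                                 marginal_means, adaptive_control_contrasts)

# 8 participants x 160 trials, fully crossed congruency x proportion
design = pd.DataFrame(
    {"participant_id": f"s{p}", "group": "HC", "item_id": f"i{t % 4}",
     "congruency": c, "proportion_condition": b}
    for p in range(8)
    for c in ("congruent", "incongruent")
    for b in ("MC", "MI")
    for t in range(40)
)
table = simulate_behavior(design, preset("hc_like"), seed=1)
table, report = filter_trials(table)                 # accuracy + 200 ms rules
fit = fit_shifted_lognormal(table, ModelSpec(),
                            MCMCConfig(chains=2, warmup=300, draws=500, seed=0),
                            min_trials_per_cell=30)
print(fit.converged, round(max(fit.rhat.values()), 3))
print(adaptive_control_contrasts(marginal_means(fit)).summary().round(1))
```

prints

```
True 1.087
  group                 contrast  mean_ms  ci_low  ci_high
0    HC              conflict_MC    103.3    80.9    126.5
1    HC              conflict_MI     65.1    43.3     90.7
2    HC              interaction    -38.1   -68.5     -6.8
3    HC  incongruent_improvement     -5.5   -29.4     18.2
```

The `hc_like` preset generates a 79.5 ms average conflict effect that
shrinks by 47.8 ms in the mostly-incongruent context.  At this small
sample (8 participants, one quarter of the published trial count) the
fitted interaction of −38 ms [−69, −7] recovers the adaptive-control
signature: the conflict effect is credibly smaller where conflict is
expected.  `converged True` with max R̂ = 1.087 reports the sampler's
convergence check (threshold 1.1).

The same experiment end to end, including the EEG theta cluster test:

```bash
conflictlab run-all --out runs/demo --seed 7
```

which writes `emm.tsv`, `contrasts.tsv`, `bif.tsv`, `clusters.json` and a
`MANIFEST.json`.  At seed 7 the cluster summary for the control-like
group contains one significant *negative* MI−MC theta cluster over
fronto-central channels (`start_s 0.272, end_s 0.8, p = 0.0078`,
members including FCz) — less conflict theta when conflict is expected —
while the patient-like group (weaker generating modulation at this
reduced scale) shows none.

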