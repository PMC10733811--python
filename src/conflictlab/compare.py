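"""Marginal likelihoods by bridge sampling and Bayes inclusion factors.

The evidence of each fitted model is estimated with the iterative
optimal-bridge estimator between the posterior draws and a moment-matched
multivariate-normal proposal on the unconstrained parameter scale.  Bayes
inclusion factors (BIFs) compare matched model families: the evidence for
models containing a factor, averaged on the evidence scale with equal
model prior weights, against the matched models lacking it.  For the
2 x 2 design the family is {null, C, P, C+P, C+P+CP}:

    BIF(Congruency)  = mean{C, C+P}   / mean{null, P}
    BIF(Proportion)  = mean{P, C+P}   / mean{null, C}
    BIF(Interaction) = {C+P+CP}       / {C+P}

Evidence strength is labelled with Jeffreys bands (anecdotal < 3,
moderate 3-10, strong 10-30, substantial > 30, and reciprocals), using a
half-open [lower, upper) convention on each band boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .rtmodel import (
    FACTORS,
    MCMCConfig,
    ModelSpec,
    PosteriorFit,
    fit_shifted_lognormal,
)

__all__ = [
    "BridgeResult",
    "ModelFamily",
    "BIFReport",
    "bridge_sampling",
    "log_marginal_likelihood",
    "fit_model_family",
    "inclusion_bf",
    "jeffreys_label",
    "FAMILY_MASKS",
]

FAMILY_MASKS = {
    "null": frozenset(),
    "C": frozenset({"congruency"}),
    "P": frozenset({"proportion"}),
    "C+P": frozenset({"congruency", "proportion"}),
    "C+P+CP": frozenset({"congruency", "proportion", "interaction"}),
}


class BridgeConvergenceError(RuntimeError):
    pass


@dataclass
class BridgeResult:
    log_evidence: float
    re2: float  # squared relative MC error (approximate, iid assumption)
    n_iterations: int
    n_posterior: int
    n_proposal: int

    @property
    def mc_error(self) -> float:
        """Approximate standard error of the log evidence."""
        return float(np.sqrt(self.re2))


def bridge_sampling(
    draws: np.ndarray,
    log_q,
    n_proposal: int | None = None,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> BridgeResult:
    """Iterative optimal-bridge estimate of the normalizing constant.

    ``draws`` are posterior samples (rows) on the unconstrained scale and
    ``log_q`` evaluates the *unnormalized* log posterior there.  The first
    half of the draws fits a moment-matched Gaussian proposal; the second
    half enters the bridge.  Returns the log normalizing constant (log
    marginal likelihood when ``log_q`` = log likelihood + log prior +
    transform Jacobians).
    """
    draws = np.asarray(draws, dtype=float)
    n, d = draws.shape
    half = n // 2
    fit_half, bridge_half = draws[:half], draws[half:]
    n1 = len(bridge_half)
    n2 = n_proposal or n1
    rng = np.random.default_rng(seed)

    mean = fit_half.mean(axis=0)
    cov = np.cov(fit_half.T)
    cov = np.atleast_2d(cov) + 1e-10 * np.eye(d)
    proposal = multivariate_normal(mean=mean, cov=cov, allow_singular=False)
    prop_draws = proposal.rvs(size=n2, random_state=rng).reshape(n2, d)

    # log(q/g) at posterior draws (l1) and proposal draws (l2)
    l1 = np.array([log_q(x) for x in bridge_half]) - proposal.logpdf(bridge_half)
    l2 = np.array([log_q(x) for x in prop_draws]) - proposal.logpdf(prop_draws)
    if not np.all(np.isfinite(l1)):
        raise ValueError("non-finite log posterior at posterior draws")
    finite2 = np.isfinite(l2)
    l2 = np.where(finite2, l2, -np.inf)

    lstar = np.median(l1)
    s1 = n1 / (n1 + n2)
    s2 = n2 / (n1 + n2)
    log_r = 0.0
    for it in range(1, max_iter + 1):
        # numerator: mean over proposal draws of l2' / (s1 l2' + s2 r)
        log_num = logsumexp(
            (l2 - lstar)
            - np.logaddexp(np.log(s1) + l2 - lstar, np.log(s2) + log_r)
        ) - np.log(n2)
        log_den = logsumexp(
            -np.logaddexp(np.log(s1) + l1 - lstar, np.log(s2) + log_r)
        ) - np.log(n1)
        log_r_new = log_num - log_den
        if abs(log_r_new - log_r) < tol:
            log_r = log_r_new
            break
        log_r = log_r_new
    else:
        raise BridgeConvergenceError(
            f"bridge estimator did not converge within {max_iter} iterations"
        )
    log_evidence = float(log_r + lstar)

    # approximate relative MC error (iid formula)
    f1 = np.exp(l2 - lstar - np.logaddexp(np.log(s1) + l2 - lstar,
                                          np.log(s2) + log_r))
    f2 = np.exp(-np.logaddexp(np.log(s1) + l1 - lstar, np.log(s2) + log_r))
    with np.errstate(invalid="ignore"):
        re2 = (
            np.var(f1) / (n2 * np.mean(f1) ** 2)
            + np.var(f2) / (n1 * np.mean(f2) ** 2)
        )
    return BridgeResult(
        log_evidence=log_evidence,
        re2=float(re2),
        n_iterations=it,
        n_posterior=n1,
        n_proposal=n2,
    )


def log_marginal_likelihood(
    fit: PosteriorFit, seed: int = 0, min_draws: int = 2000
) -> BridgeResult:
    """Bridge-sampling log evidence of a fitted RT model."""
    if not fit.converged:
        warnings.warn(
            "estimating evidence from a non-converged fit", stacklevel=2
        )
    if fit.n_draws_total < min_draws:
        raise ValueError(
            f"need at least {min_draws} post-warmup draws for a stable "
            f"bridge estimate; have {fit.n_draws_total}"
        )
    model = fit.model
    chains, ndraws = fit.draws["sigma"].shape
    mats = []
    for c in range(chains):
        for d in range(ndraws):
            state = {
                "beta": np.array(
                    [fit.draws[nm][c, d] for nm in fit.coef_names]
                ),
                "b_p": fit.draws["b_participant"][c, d],
                "b_i": fit.draws["b_item"][c, d],
                "sigma": fit.draws["sigma"][c, d],
                "tau_p": fit.draws["tau_participant"][c, d],
                "tau_i": fit.draws["tau_item"][c, d],
                "delta": np.array(
                    [fit.draws[f"delta[{g}]"][c, d] for g in fit.groups]
                ),
            }
            mats.append(model.pack(state))
    return bridge_sampling(np.asarray(mats), model.log_unnorm_posterior, seed=seed)


@dataclass
class ModelFamily:
    """The five nested fixed-effect models sharing one data set."""

    fits: dict  # name -> PosteriorFit
    log_evidence: dict  # name -> float
    bridge: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(FAMILY_MASKS) - set(self.log_evidence)
        if missing:
            raise ValueError(f"family incomplete; missing members {missing}")


def fit_model_family(
    table: pd.DataFrame,
    base_spec: ModelSpec | None = None,
    mcmc: MCMCConfig | None = None,
    min_trials_per_cell: int = 40,
    seed: int = 0,
) -> ModelFamily:
    """Fit all five members on one data set and estimate their evidence.

    All members share the likelihood, data, and random-effect structure;
    only the fixed-effect mask differs.
    """
    base_spec = base_spec or ModelSpec()
    mcmc = mcmc or MCMCConfig()
    fits, logml, bridge = {}, {}, {}
    for k, (name, mask) in enumerate(FAMILY_MASKS.items()):
        spec = ModelSpec(
            include=mask,
            priors=base_spec.priors,
            coding=base_spec.coding,
            random_participant=base_spec.random_participant,
            random_item=base_spec.random_item,
        )
        fit = fit_shifted_lognormal(
            table, spec,
            MCMCConfig(mcmc.chains, mcmc.warmup, mcmc.draws, mcmc.seed + k),
            min_trials_per_cell=min_trials_per_cell,
        )
        res = log_marginal_likelihood(fit, seed=seed + k)
        fits[name] = fit
        logml[name] = res.log_evidence
        bridge[name] = res
    return ModelFamily(fits=fits, log_evidence=logml, bridge=bridge)


JEFFREYS_BANDS = [
    (30.0, np.inf, "substantial"),
    (10.0, 30.0, "strong"),
    (3.0, 10.0, "moderate"),
    (1 / 3, 3.0, "anecdotal"),
    (1 / 10, 1 / 3, "moderate (null)"),
    (1 / 30, 1 / 10, "strong (null)"),
    (0.0, 1 / 30, "substantial (null)"),
]


def jeffreys_label(bf: float) -> str:
    """Evidence-strength label; bands are half-open [lower, upper)."""
    if not bf > 0:
        raise ValueError("Bayes factor must be positive")
    for lo, hi, label in JEFFREYS_BANDS:
        if lo <= bf < hi:
            return label
    return "substantial"  # bf == inf


@dataclass
class BIFReport:
    factor: str
    bif: float
    label: str
    numerator_models: tuple
    denominator_models: tuple


_MATCHED = {
    "congruency": (("C", "C+P"), ("null", "P")),
    "proportion": (("P", "C+P"), ("null", "C")),
    "interaction": (("C+P+CP",), ("C+P",)),
}


def inclusion_bf(family: ModelFamily, factor: str) -> BIFReport:
    """Matched-models Bayes inclusion factor for one factor.

    Averaging is on the evidence scale (equal model prior weights),
    computed with log-sum-exp for stability.
    """
    if factor not in _MATCHED:
        raise KeyError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    num, den = _MATCHED[factor]
    missing = [m for m in num + den if m not in family.log_evidence]
    if missing:
        raise KeyError(f"family lacks members {missing}")
    log_num = logsumexp([family.log_evidence[m] for m in num]) - np.log(len(num))
    log_den = logsumexp([family.log_evidence[m] for m in den]) - np.log(len(den))
    bif = float(np.exp(log_num - log_den))
    return BIFReport(
        factor=factor,
        bif=bif,
        label=jeffreys_label(bif),
        numerator_models=num,
        denominator_models=den,
    )


def bif_table(family: ModelFamily) -> pd.DataFrame:
    rows = []
    for factor in FACTORS:
        rep = inclusion_bf(family, factor)
        rows.append(
            {"factor": factor, "BIF": rep.bif, "evidence": rep.label}
        )
    return pd.DataFrame(rows)
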