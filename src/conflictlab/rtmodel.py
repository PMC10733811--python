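"""Hierarchical shifted-lognormal reaction-time model.

The likelihood is rt = delta_g + exp(eta) with eta Gaussian around a
linear predictor of contrast-coded Congruency, Proportion and their
interaction (codes +-0.5, per experimental group), plus participant and
item random intercepts; the non-decision shift delta_g is group-specific.
Posterior sampling uses a blocked Gibbs scheme: conditional on the shift,
log(rt - delta_g) is a linear-Gaussian model, so fixed and random effects
have exact conjugate updates; the scale parameters (sigma, taus) and the
shifts are updated by univariate slice sampling.  Convergence is reported
through the potential scale reduction factor (R-hat, required < 1.1) for
every parameter.

Millisecond-scale estimated marginal means (EMMs) are computed per
posterior draw at the four design cells with random effects at zero; by
default on the expectation scale, EMM = delta_g + exp(mu_cell + sigma^2/2)
(median scale, delta_g + exp(mu_cell), is available).  Adaptive-control
contrasts are exact linear functions of the EMM draws.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import X_CODE

logger = logging.getLogger(__name__)

__all__ = [
    "NormalPrior",
    "HalfNormalPrior",
    "UniformPrior",
    "PointPrior",
    "PriorSpec",
    "ModelSpec",
    "MCMCConfig",
    "PosteriorFit",
    "EMMTable",
    "ContrastTable",
    "SpecificationError",
    "prior_predictive",
    "fit_shifted_lognormal",
    "marginal_means",
    "adaptive_control_contrasts",
    "transfer_priors",
    "posterior_predictive_quantiles",
]

FACTORS = ("congruency", "proportion", "interaction")


class SpecificationError(ValueError):
    """An improper or degenerate model specification."""


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class NormalPrior:
    loc: float
    scale: float

    def __post_init__(self):
        if self.scale < 0:
            raise SpecificationError("normal prior scale must be >= 0")

    def sample(self, rng, size=None):
        return rng.normal(self.loc, self.scale, size)

    def logpdf(self, x):
        if self.scale == 0:
            raise SpecificationError("point-mass prior has no density")
        return -0.5 * ((x - self.loc) / self.scale) ** 2 - np.log(
            self.scale * np.sqrt(2 * np.pi)
        )


@dataclass(frozen=True)
class HalfNormalPrior:
    scale: float

    def __post_init__(self):
        if self.scale <= 0:
            raise SpecificationError(
                "half-normal prior scale must be positive (a zero-variance "
                "scale prior is degenerate)"
            )

    def sample(self, rng, size=None):
        return np.abs(rng.normal(0.0, self.scale, size))

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(
            x >= 0,
            -0.5 * (x / self.scale) ** 2
            + np.log(2.0)
            - np.log(self.scale * np.sqrt(2 * np.pi)),
            -np.inf,
        )
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class UniformPrior:
    low: float
    high: float

    def __post_init__(self):
        if not self.high > self.low:
            raise SpecificationError("uniform prior needs high > low")

    def sample(self, rng, size=None):
        return rng.uniform(self.low, self.high, size)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(
            (x >= self.low) & (x <= self.high),
            -np.log(self.high - self.low),
            -np.inf,
        )
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class PointPrior:
    """Degenerate prior fixing a parameter (prior-predictive checks only)."""

    value: float

    def sample(self, rng, size=None):
        return np.full(size, self.value) if size else self.value

    def logpdf(self, x):
        raise SpecificationError("point-mass prior has no density")


@dataclass(frozen=True)
class PriorSpec:
    """Default weakly-informative priors of the RT model.

    Fixed effects may carry per-name overrides (used by prior transfer).
    The shift prior is Uniform(0, shift_upper_frac * min observed RT per
    group), resolved against the data at fit time.
    """

    intercept: object = NormalPrior(6.0, 0.5)
    effect: object = NormalPrior(0.0, 0.3)
    sigma: object = HalfNormalPrior(0.5)
    tau_participant: object = HalfNormalPrior(0.3)
    tau_item: object = HalfNormalPrior(0.3)
    shift_upper_frac: float = 0.95
    # explicit shift prior for prior-predictive simulation, where no data
    # minimum exists yet; None means Uniform(0, 1000 ms)
    shift: object = None
    effect_overrides: dict = field(default_factory=dict)

    def effect_prior(self, name: str):
        return self.effect_overrides.get(name, self.effect)


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one fitted model.

    ``include`` masks the fixed-effect factors (besides per-group
    intercepts, which are always present); the nested family used for
    Bayes inclusion factors varies only this mask.
    """

    include: frozenset = frozenset(FACTORS)
    priors: PriorSpec = PriorSpec()
    coding: float = 0.5
    random_participant: bool = True
    random_item: bool = True

    def __post_init__(self):
        unknown = set(self.include) - set(FACTORS)
        if unknown:
            raise SpecificationError(f"unknown factors {unknown}")
        if "interaction" in self.include and not {
            "congruency",
            "proportion",
        } <= set(self.include):
            raise SpecificationError(
                "interaction requires both main effects in the model"
            )


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    warmup: int = 500
    draws: int = 1000
    seed: int = 0

    @staticmethod
    def paper_scale(seed: int = 0) -> "MCMCConfig":
        return MCMCConfig(chains=4, warmup=2000, draws=10_000, seed=seed)


# ---------------------------------------------------------------------------
# model internals


def _slice_sample(x0, logp, width, lower, upper, rng, max_steps=50):
    """Univariate slice sampler with stepping-out on a bounded domain."""
    ll0 = logp(x0)
    ll_threshold = ll0 + np.log(rng.random())
    u = rng.random() * width
    left = max(x0 - u, lower)
    right = min(left + width, upper)
    for _ in range(max_steps):
        if left <= lower or logp(left) < ll_threshold:
            break
        left = max(left - width, lower)
    for _ in range(max_steps):
        if right >= upper or logp(right) < ll_threshold:
            break
        right = min(right + width, upper)
    for _ in range(max_steps):
        x1 = rng.uniform(left, right)
        if logp(x1) >= ll_threshold:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # extremely narrow slice; keep the current state


class ShiftedLognormalModel:
    """Data-bound model: design matrices, Gibbs sweeps, and the joint
    unnormalized log posterior on the unconstrained scale (for bridge
    sampling)."""

    def __init__(self, table: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.groups = sorted(table["group"].unique())
        self.participants = sorted(table["participant_id"].unique())
        self.items = sorted(table["item_id"].unique())
        g_index = {g: k for k, g in enumerate(self.groups)}
        p_index = {p: k for k, p in enumerate(self.participants)}
        i_index = {i: k for k, i in enumerate(self.items)}
        self.g_idx = table["group"].map(g_index).to_numpy()
        self.p_idx = table["participant_id"].map(p_index).to_numpy()
        self.i_idx = table["item_id"].map(i_index).to_numpy()
        self.rt = table["rt_ms"].to_numpy(float)
        self.n = len(table)
        self.n_groups = len(self.groups)
        self.n_p = len(self.participants)
        self.n_i = len(self.items)

        xc = table["congruency"].map(X_CODE).to_numpy(float)
        xp = table["proportion_condition"].map(X_CODE).to_numpy(float)
        scale = spec.coding / 0.5
        xc, xp = xc * scale, xp * scale

        cols, names, prior_list = [], [], []
        for k, g in enumerate(self.groups):
            gmask = (self.g_idx == k).astype(float)
            cols.append(gmask)
            names.append(f"mu0[{g}]")
            prior_list.append(spec.priors.intercept)
            factor_cols = {
                "congruency": xc,
                "proportion": xp,
                "interaction": xc * xp,
            }
            for factor in FACTORS:
                if factor in spec.include:
                    cols.append(gmask * factor_cols[factor])
                    name = f"beta_{factor}[{g}]"
                    names.append(name)
                    prior_list.append(spec.priors.effect_prior(name))
        self.X = np.column_stack(cols)
        self.coef_names = names
        self.coef_priors = prior_list
        self.prior_loc = np.array([p.loc for p in prior_list])
        self.prior_scale = np.array([p.scale for p in prior_list])
        if np.any(self.prior_scale <= 0):
            raise SpecificationError("fixed-effect priors must be proper")
        self.XtX = self.X.T @ self.X
        self.mu0_pos = np.array([names.index(f"mu0[{g}]") for g in self.groups])
        # participant -> group membership (first row wins; design is nested)
        p_group = np.zeros(self.n_p, dtype=int)
        p_group[self.p_idx] = self.g_idx
        self.group_participants = [
            np.nonzero(p_group == k)[0] for k in range(self.n_groups)
        ]

        # group-wise shift upper bounds: 0.95 * min rt of the group
        self.shift_upper = np.array(
            [
                spec.priors.shift_upper_frac * self.rt[self.g_idx == k].min()
                for k in range(self.n_groups)
            ]
        )
        self.group_rows = [
            np.nonzero(self.g_idx == k)[0] for k in range(self.n_groups)
        ]

    # -- Gibbs machinery ---------------------------------------------------

    def initial_state(self, rng) -> dict:
        delta = 0.6 * self.shift_upper
        y = np.log(self.rt - delta[self.g_idx])
        beta = np.zeros(self.X.shape[1])
        # start intercepts at the group means of y
        for k in range(self.n_groups):
            beta[self.mu0_pos[k]] = y[self.g_idx == k].mean()
        return {
            "beta": beta,
            "b_p": np.zeros(self.n_p),
            "b_i": np.zeros(self.n_i),
            "sigma": max(float(y.std()), 0.05),
            "tau_p": 0.1,
            "tau_i": 0.1,
            "delta": delta,
        }

    def sweep(self, state: dict, rng) -> dict:
        spec = self.spec
        delta = state["delta"]
        y = np.log(self.rt - delta[self.g_idx])
        b_p = state["b_p"] if spec.random_participant else np.zeros(self.n_p)
        b_i = state["b_i"] if spec.random_item else np.zeros(self.n_i)
        sigma = state["sigma"]

        # fixed effects: conjugate Gaussian update
        r = y - b_p[self.p_idx] - b_i[self.i_idx]
        prec = self.XtX / sigma**2 + np.diag(1.0 / self.prior_scale**2)
        rhs = self.X.T @ r / sigma**2 + self.prior_loc / self.prior_scale**2
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        beta = mean + np.linalg.solve(chol.T, rng.standard_normal(len(mean)))
        xb = self.X @ beta

        # random intercepts: conditionally independent Gaussian updates
        if spec.random_participant:
            res = y - xb - b_i[self.i_idx]
            sums = np.bincount(self.p_idx, weights=res, minlength=self.n_p)
            counts = np.bincount(self.p_idx, minlength=self.n_p)
            var = 1.0 / (counts / sigma**2 + 1.0 / state["tau_p"] ** 2)
            b_p = rng.normal(var * sums / sigma**2, np.sqrt(var))
        if spec.random_item:
            res = y - xb - b_p[self.p_idx]
            sums = np.bincount(self.i_idx, weights=res, minlength=self.n_i)
            counts = np.bincount(self.i_idx, minlength=self.n_i)
            var = 1.0 / (counts / sigma**2 + 1.0 / state["tau_i"] ** 2)
            b_i = rng.normal(var * sums / sigma**2, np.sqrt(var))

        # translation moves: the likelihood only identifies mu0_g plus the
        # mean of the random intercepts, so shift mass between them by
        # sampling the translation from its exact Gaussian conditional
        # (an interweaving move that removes the slow ridge).
        loc = self.prior_loc
        sc = self.prior_scale
        if spec.random_participant:
            tau2 = state["tau_p"] ** 2
            for k in range(self.n_groups):
                j = self.mu0_pos[k]
                members = self.group_participants[k]
                prec = 1.0 / sc[j] ** 2 + len(members) / tau2
                mean_a = (
                    (loc[j] - beta[j]) / sc[j] ** 2 + b_p[members].sum() / tau2
                ) / prec
                a = rng.normal(mean_a, 1.0 / np.sqrt(prec))
                beta[j] += a
                b_p[members] -= a
        if spec.random_item:
            tau2 = state["tau_i"] ** 2
            jj = self.mu0_pos
            prec = float(np.sum(1.0 / sc[jj] ** 2)) + self.n_i / tau2
            mean_a = (
                float(np.sum((loc[jj] - beta[jj]) / sc[jj] ** 2))
                + b_i.sum() / tau2
            ) / prec
            a = rng.normal(mean_a, 1.0 / np.sqrt(prec))
            beta[jj] += a
            b_i -= a
        xb = self.X @ beta

        resid = y - xb - b_p[self.p_idx] - b_i[self.i_idx]
        ss = float(resid @ resid)

        # sigma: slice sample on log scale (half-normal prior + Jacobian)
        sig_prior = spec.priors.sigma

        def logp_lsig(ls):
            s = np.exp(ls)
            return (
                -self.n * ls - ss / (2 * s**2) + sig_prior.logpdf(s) + ls
            )

        sigma = float(
            np.exp(
                _slice_sample(
                    np.log(sigma), logp_lsig, 0.5, -10.0, 3.0, rng
                )
            )
        )

        def tau_update(b, tau_prior, tau0):
            m = len(b)
            sb = float(b @ b)

            def logp_ltau(lt):
                t = np.exp(lt)
                return -m * lt - sb / (2 * t**2) + tau_prior.logpdf(t) + lt

            return float(
                np.exp(_slice_sample(np.log(tau0), logp_ltau, 0.5, -10.0, 3.0, rng))
            )

        tau_p = (
            tau_update(b_p, spec.priors.tau_participant, state["tau_p"])
            if spec.random_participant
            else state["tau_p"]
        )
        tau_i = (
            tau_update(b_i, spec.priors.tau_item, state["tau_i"])
            if spec.random_item
            else state["tau_i"]
        )

        # group shifts: the shift and the group intercept lie on a ridge
        # (their effects on the mean RT trade off), so the conditional
        # update is taken along the reparametrization (delta, m) with
        # m = delta + exp(mu0) held fixed: mu0 = log(m - delta), with the
        # change-of-variables term -log(m - delta).
        mu_full = xb + b_p[self.p_idx] + b_i[self.i_idx]
        delta = delta.copy()
        mu0_prior = self.spec.priors.intercept
        for k in range(self.n_groups):
            rows = self.group_rows[k]
            rt_g = self.rt[rows]
            j = self.mu0_pos[k]
            mu0_old = beta[j]
            mu_rest = mu_full[rows] - mu0_old
            m_const = delta[k] + np.exp(mu0_old)
            upper = min(self.shift_upper[k], m_const * (1 - 1e-9))

            def logp_delta(d):
                if not (0.0 < d < upper):
                    return -np.inf
                mu0 = np.log(m_const - d)
                yg = np.log(rt_g - d)
                resid = yg - mu_rest - mu0
                return float(
                    -yg.sum()
                    - (resid @ resid) / (2 * sigma**2)
                    + mu0_prior.logpdf(mu0)
                    - np.log(m_const - d)
                )

            delta[k] = _slice_sample(
                min(delta[k], upper - 1e-9),
                logp_delta,
                0.1 * self.shift_upper[k],
                1e-9,
                upper - 1e-9,
                rng,
            )
            beta[j] = np.log(m_const - delta[k])
        xb = self.X @ beta

        return {
            "beta": beta,
            "b_p": b_p,
            "b_i": b_i,
            "sigma": sigma,
            "tau_p": tau_p,
            "tau_i": tau_i,
            "delta": delta,
        }

    # -- joint density on the unconstrained scale (bridge sampling) --------

    @property
    def n_params(self) -> int:
        p = self.X.shape[1] + 3 + self.n_groups
        if self.spec.random_participant:
            p += self.n_p
        if self.spec.random_item:
            p += self.n_i
        return p

    def pack(self, state: dict) -> np.ndarray:
        from scipy.special import logit

        parts = [state["beta"]]
        if self.spec.random_participant:
            parts.append(state["b_p"])
        if self.spec.random_item:
            parts.append(state["b_i"])
        parts.append(
            [
                np.log(state["sigma"]),
                np.log(state["tau_p"]),
                np.log(state["tau_i"]),
            ]
        )
        parts.append(logit(state["delta"] / self.shift_upper))
        return np.concatenate([np.atleast_1d(np.asarray(p)) for p in parts])

    def log_unnorm_posterior(self, z: np.ndarray) -> float:
        """Unnormalized log posterior on the unconstrained scale, including
        the log-Jacobians of the transforms (log for scales, scaled logit
        for shifts)."""
        from scipy.special import expit

        spec = self.spec
        k = self.X.shape[1]
        beta = z[:k]
        pos = k
        if spec.random_participant:
            b_p = z[pos : pos + self.n_p]
            pos += self.n_p
        else:
            b_p = np.zeros(self.n_p)
        if spec.random_item:
            b_i = z[pos : pos + self.n_i]
            pos += self.n_i
        else:
            b_i = np.zeros(self.n_i)
        lsig, ltau_p, ltau_i = z[pos : pos + 3]
        pos += 3
        zd = z[pos : pos + self.n_groups]
        sigma = np.exp(lsig)
        tau_p, tau_i = np.exp(ltau_p), np.exp(ltau_i)
        sd = expit(zd)
        delta = self.shift_upper * sd

        lp = 0.0
        # priors + Jacobians
        lp += float(
            np.sum(
                -0.5 * ((beta - self.prior_loc) / self.prior_scale) ** 2
                - np.log(self.prior_scale * np.sqrt(2 * np.pi))
            )
        )
        lp += spec.priors.sigma.logpdf(sigma) + lsig
        if spec.random_participant:
            lp += spec.priors.tau_participant.logpdf(tau_p) + ltau_p
            lp += float(
                np.sum(-0.5 * (b_p / tau_p) ** 2)
                - self.n_p * np.log(tau_p * np.sqrt(2 * np.pi))
            )
        if spec.random_item:
            lp += spec.priors.tau_item.logpdf(tau_i) + ltau_i
            lp += float(
                np.sum(-0.5 * (b_i / tau_i) ** 2)
                - self.n_i * np.log(tau_i * np.sqrt(2 * np.pi))
            )
        # shift: uniform prior density + logit Jacobian
        lp += float(
            np.sum(-np.log(self.shift_upper) + np.log(self.shift_upper)
                   + np.log(sd) + np.log1p(-sd))
        )
        # likelihood
        arg = self.rt - delta[self.g_idx]
        if np.any(arg <= 0):
            return -np.inf
        y = np.log(arg)
        mu = self.X @ beta + b_p[self.p_idx] + b_i[self.i_idx]
        lp += float(
            np.sum(
                -y
                - 0.5 * ((y - mu) / sigma) ** 2
                - np.log(sigma * np.sqrt(2 * np.pi))
            )
        )
        return lp


# ---------------------------------------------------------------------------
# fit container


@dataclass
class PosteriorFit:
    """Posterior draws (chains x draws [x dim]) plus diagnostics."""

    draws: dict
    coef_names: list
    groups: list
    spec: ModelSpec
    config: MCMCConfig
    rhat: dict
    converged: bool
    model: ShiftedLognormalModel
    excluded_participants: list = field(default_factory=list)

    def flat(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled over chains."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def n_draws_total(self) -> int:
        return self.draws["sigma"].size


def _rhat(draws: dict) -> dict:
    import arviz as az

    data = {}
    for name, arr in draws.items():
        data[name] = arr
    idata = az.from_dict(posterior=data)
    rh = az.rhat(idata)
    out = {}
    for name in draws:
        vals = np.asarray(rh[name].values)
        out[name] = float(np.nanmax(vals))
    return out


def fit_shifted_lognormal(
    table: pd.DataFrame,
    spec: ModelSpec | None = None,
    mcmc: MCMCConfig | None = None,
    min_trials_per_cell: int = 40,
) -> PosteriorFit:
    """Fit the hierarchical shifted-lognormal model by blocked Gibbs MCMC.

    Participants with fewer than ``min_trials_per_cell`` trials in any
    congruency x proportion cell are excluded with a logged warning.  The
    fit is returned regardless of convergence; ``converged`` reflects
    whether every parameter's R-hat stayed below 1.1.
    """
    spec = spec or ModelSpec()
    mcmc = mcmc or MCMCConfig()

    counts = table.groupby(
        ["participant_id", "congruency", "proportion_condition"]
    ).size().unstack([1, 2], fill_value=0)
    bad = counts.index[(counts < min_trials_per_cell).any(axis=1)].tolist()
    if bad:
        logger.warning(
            "excluding %d participant(s) with <%d trials in a cell: %s",
            len(bad), min_trials_per_cell, bad,
        )
        table = table[~table["participant_id"].isin(bad)]
    if table.empty:
        raise ValueError("no participants left after the trial-count exclusion")
    cells = table.groupby(["group", "congruency", "proportion_condition"]).size()
    for g in table["group"].unique():
        if len(cells.loc[g]) < 4:
            raise ValueError(f"group {g} has an empty design cell")

    model = ShiftedLognormalModel(table, spec)
    ss = np.random.SeedSequence(mcmc.seed)
    chain_rngs = [np.random.default_rng(s) for s in ss.spawn(mcmc.chains)]

    names = model.coef_names
    store = {
        name: np.empty((mcmc.chains, mcmc.draws)) for name in names
    }
    store["sigma"] = np.empty((mcmc.chains, mcmc.draws))
    store["tau_participant"] = np.empty((mcmc.chains, mcmc.draws))
    store["tau_item"] = np.empty((mcmc.chains, mcmc.draws))
    for g in model.groups:
        store[f"delta[{g}]"] = np.empty((mcmc.chains, mcmc.draws))
    store["b_participant"] = np.empty((mcmc.chains, mcmc.draws, model.n_p))
    store["b_item"] = np.empty((mcmc.chains, mcmc.draws, model.n_i))

    for c, rng in enumerate(chain_rngs):
        state = model.initial_state(rng)
        for _ in range(mcmc.warmup):
            state = model.sweep(state, rng)
        for d in range(mcmc.draws):
            state = model.sweep(state, rng)
            for j, name in enumerate(names):
                store[name][c, d] = state["beta"][j]
            store["sigma"][c, d] = state["sigma"]
            store["tau_participant"][c, d] = state["tau_p"]
            store["tau_item"][c, d] = state["tau_i"]
            for k, g in enumerate(model.groups):
                store[f"delta[{g}]"][c, d] = state["delta"][k]
            store["b_participant"][c, d] = state["b_p"]
            store["b_item"][c, d] = state["b_i"]

    rhat = _rhat(store)
    converged = all(v < 1.1 for v in rhat.values() if np.isfinite(v))
    if not converged:
        warnings.warn(
            "MCMC not converged (max R-hat %.3f); fit flagged, not discarded"
            % max(rhat.values()),
            stacklevel=2,
        )
    return PosteriorFit(
        draws=store,
        coef_names=names,
        groups=model.groups,
        spec=spec,
        config=mcmc,
        rhat=rhat,
        converged=converged,
        model=model,
        excluded_participants=bad,
    )


# ---------------------------------------------------------------------------
# marginal means and contrasts


CELLS = [
    ("congruent", "MC"),
    ("incongruent", "MC"),
    ("congruent", "MI"),
    ("incongruent", "MI"),
]


@dataclass
class EMMTable:
    """Posterior draws of millisecond-scale marginal means per cell."""

    draws: dict  # (group, congruency, proportion) -> 1-D array
    groups: list
    mode: str

    def summary(self) -> pd.DataFrame:
        rows = []
        for (g, c, p), arr in self.draws.items():
            lo, hi = np.percentile(arr, [2.5, 97.5])
            rows.append(
                {
                    "group": g,
                    "congruency": c,
                    "proportion": p,
                    "mean_ms": float(arr.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
        return pd.DataFrame(rows)


def marginal_means(fit: PosteriorFit, mode: str = "mean") -> EMMTable:
    """EMM draws per (group x proportion x congruency) cell.

    Random effects at zero.  ``mode='mean'`` uses the expectation scale
    (adds sigma^2/2 inside the exponent); ``mode='median'`` omits it.
    """
    if mode not in ("mean", "median"):
        raise ValueError("mode must be 'mean' or 'median'")
    sigma2 = fit.flat("sigma") ** 2
    out = {}
    for g in fit.groups:
        mu0 = fit.flat(f"mu0[{g}]")
        delta = fit.flat(f"delta[{g}]")
        betas = {}
        for factor in FACTORS:
            name = f"beta_{factor}[{g}]"
            betas[factor] = (
                fit.flat(name) if name in fit.draws else np.zeros_like(mu0)
            )
        for c, p in CELLS:
            xc, xp = X_CODE[c], X_CODE[p]
            mu = (
                mu0
                + betas["congruency"] * xc
                + betas["proportion"] * xp
                + betas["interaction"] * xc * xp
            )
            if mode == "mean":
                mu = mu + sigma2 / 2
            out[(g, c, p)] = delta + np.exp(mu)
    return EMMTable(draws=out, groups=list(fit.groups), mode=mode)


@dataclass
class ContrastTable:
    """Adaptive-control contrasts as posterior draws and summaries."""

    draws: dict  # (group or 'between', name) -> 1-D array

    def summary(self) -> pd.DataFrame:
        rows = []
        for (g, name), arr in self.draws.items():
            lo, hi = np.percentile(arr, [2.5, 97.5])
            rows.append(
                {
                    "group": g,
                    "contrast": name,
                    "mean_ms": float(arr.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
        return pd.DataFrame(rows)


def adaptive_control_contrasts(
    emm: EMMTable, pairing: tuple[str, str] | None = None
) -> ContrastTable:
    """Conflict effects, their MI-MC difference, and the incongruent-
    improvement contrast, draw-wise from the EMM table.

    ``pairing=(a, b)`` adds the between-group difference of the
    incongruent-improvement contrast, improvement_a - improvement_b.
    """
    out = {}
    for g in emm.groups:
        need = [(g, c, p) for c, p in CELLS]
        missing = [k for k in need if k not in emm.draws]
        if missing:
            raise KeyError(f"missing EMM cells: {missing}")
        cong_mc = emm.draws[(g, "congruent", "MC")]
        incg_mc = emm.draws[(g, "incongruent", "MC")]
        cong_mi = emm.draws[(g, "congruent", "MI")]
        incg_mi = emm.draws[(g, "incongruent", "MI")]
        out[(g, "conflict_MC")] = incg_mc - cong_mc
        out[(g, "conflict_MI")] = incg_mi - cong_mi
        out[(g, "interaction")] = out[(g, "conflict_MI")] - out[(g, "conflict_MC")]
        out[(g, "incongruent_improvement")] = incg_mi - incg_mc
    if pairing is not None:
        a, b = pairing
        out[("between", "improvement_difference")] = (
            out[(a, "incongruent_improvement")]
            - out[(b, "incongruent_improvement")]
        )
    return ContrastTable(draws=out)


def transfer_priors(inducer_fit: PosteriorFit, widen: float = 2.0) -> PriorSpec:
    """Inducer-informed priors for the diagnostic-item model.

    Each fixed-effect prior becomes Normal(posterior mean, widen x
    posterior SD); variance-component and shift priors are unchanged.
    Refuses a non-converged inducer fit.
    """
    if not inducer_fit.converged:
        raise ValueError("refusing prior transfer from a non-converged fit")
    overrides = {}
    base = inducer_fit.spec.priors
    intercept_priors = {}
    for name in inducer_fit.coef_names:
        arr = inducer_fit.flat(name)
        prior = NormalPrior(float(arr.mean()), widen * float(arr.std(ddof=1)))
        if name.startswith("mu0"):
            intercept_priors[name] = prior
        else:
            overrides[name] = prior
    # intercept priors are transferred through the override table as well
    overrides.update(intercept_priors)
    return replace(base, effect_overrides=overrides)


# ---------------------------------------------------------------------------
# prior and posterior predictive


def prior_predictive(
    spec: ModelSpec,
    design: pd.DataFrame,
    n_draws: int = 1000,
    seed: int = 0,
    plausible_ms: tuple[float, float] = (150.0, 5000.0),
) -> dict:
    """Simulate RTs from the priors alone and summarize their quantiles.

    Uses a representative shift upper bound of 1000 ms for the uniform
    shift prior (no data minimum exists before data are seen).  Flags
    implausibility when the central 95% mass leaves ``plausible_ms``.
    """
    rng = np.random.default_rng(seed)
    priors = spec.priors
    if isinstance(priors.sigma, PointPrior) and priors.sigma.value <= 0:
        raise SpecificationError("sigma fixed at zero is degenerate")
    xc = design["congruency"].map(X_CODE).to_numpy(float)
    xp = design["proportion_condition"].map(X_CODE).to_numpy(float)
    n = len(design)
    rts = np.empty((n_draws, n))
    for d in range(n_draws):
        mu0 = priors.intercept.sample(rng)
        betas = {
            f: (
                priors.effect_prior(f"beta_{f}").sample(rng)
                if f in spec.include
                else 0.0
            )
            for f in FACTORS
        }
        sigma = priors.sigma.sample(rng)
        if sigma <= 0:
            raise SpecificationError("sigma draw must be positive")
        delta = (
            priors.shift.sample(rng)
            if priors.shift is not None
            else rng.uniform(0, 1000.0)
        )
        tau_p = priors.tau_participant.sample(rng)
        tau_i = priors.tau_item.sample(rng)
        b_p = {
            p: rng.normal(0, tau_p) for p in design["participant_id"].unique()
        }
        b_i = {i: rng.normal(0, tau_i) for i in design["item_id"].unique()}
        mu = (
            mu0
            + design["participant_id"].map(b_p).to_numpy()
            + design["item_id"].map(b_i).to_numpy()
            + betas["congruency"] * xc
            + betas["proportion"] * xp
            + betas["interaction"] * xc * xp
        )
        rts[d] = delta + np.exp(rng.normal(mu, sigma))
    q = {
        "q2.5": float(np.percentile(rts, 2.5)),
        "median": float(np.percentile(rts, 50)),
        "q97.5": float(np.percentile(rts, 97.5)),
    }
    q["plausible"] = (
        plausible_ms[0] <= q["q2.5"] and q["q97.5"] <= plausible_ms[1]
    )
    # condition-wise medians for inspection
    for c, p in CELLS:
        sel = (design["congruency"] == c) & (design["proportion_condition"] == p)
        if sel.any():
            q[f"median_{c}_{p}"] = float(np.median(rts[:, sel.to_numpy()]))
    return q


def posterior_predictive_quantiles(
    fit: PosteriorFit, n_rep: int = 200, seed: int = 0,
    quantiles=(0.1, 0.25, 0.5, 0.75, 0.9),
) -> dict:
    """Quantiles of RTs simulated from the posterior predictive.

    Returns per-quantile arrays over ``n_rep`` posterior draws, for
    comparison against the observed data quantiles.
    """
    rng = np.random.default_rng(seed)
    model = fit.model
    total = fit.n_draws_total
    idx = rng.choice(total, size=min(n_rep, total), replace=False)
    chains, draws = fit.draws["sigma"].shape
    sim_q = {q: [] for q in quantiles}
    for flat_i in idx:
        c, d = divmod(flat_i, draws)
        beta = np.array([fit.draws[n][c, d] for n in fit.coef_names])
        b_p = fit.draws["b_participant"][c, d]
        b_i = fit.draws["b_item"][c, d]
        sigma = fit.draws["sigma"][c, d]
        delta = np.array(
            [fit.draws[f"delta[{g}]"][c, d] for g in fit.groups]
        )
        mu = model.X @ beta + b_p[model.p_idx] + b_i[model.i_idx]
        rt = delta[model.g_idx] + np.exp(rng.normal(mu, sigma))
        for q in quantiles:
            sim_q[q].append(float(np.quantile(rt, q)))
    return {q: np.asarray(v) for q, v in sim_q.items()}
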