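"""Cluster-based sign-flip permutation statistics on channel x time maps.

Second-level inference over participants: a dependent-samples (one-sample)
t-map of per-participant effect maps against zero, supra-threshold cluster
formation over a channel-adjacency graph with temporal contiguity, and a
permutation null built by randomly negating whole participant maps
(exchangeable under the null of a symmetric effect distribution).  The
cluster statistic is the summed t (max-sum convention); the null records
the maximum |cluster mass| over both signs per permutation, giving a
two-sided family-wise-corrected p-value with the add-one convention.
For small samples (N <= 12) all 2^N sign assignments are enumerated and
p-values are exact.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Cluster",
    "ClusterResult",
    "dependent_t_map",
    "find_clusters",
    "permutation_test",
]

EXHAUSTIVE_MAX_N = 12


@dataclass
class Cluster:
    """A connected set of supra-threshold (channel, time) points."""

    members: list  # list of (channel_index, time_index)
    mass: float
    sign: int
    p_value: float | None = None

    def channels(self, ch_names) -> set:
        return {ch_names[c] for c, _ in self.members}

    def time_window(self, times) -> tuple[float, float]:
        idx = [t for _, t in self.members]
        return float(times[min(idx)]), float(times[max(idx)])


@dataclass
class ClusterResult:
    clusters: list
    t_map: np.ndarray
    null_max_mass: np.ndarray
    config: dict
    ch_names: list
    times: np.ndarray

    def significant(self, alpha: float | None = None) -> list:
        a = self.config["alpha"] if alpha is None else alpha
        return [c for c in self.clusters if c.p_value is not None and c.p_value <= a]

    def summary(self) -> list[dict]:
        """Cluster windows in report form: (start s, end s, p, channels)."""
        out = []
        for c in sorted(self.clusters, key=lambda c: c.p_value or 1.0):
            lo, hi = c.time_window(self.times)
            out.append(
                {
                    "start_s": lo,
                    "end_s": hi,
                    "p": c.p_value,
                    "sign": c.sign,
                    "mass": c.mass,
                    "n_points": len(c.members),
                    "channels": sorted(c.channels(self.ch_names)),
                }
            )
        return out


def dependent_t_map(stack: np.ndarray) -> np.ndarray:
    """One-sample t of participant difference maps against zero.

    ``stack`` is participants x channels x time; t = mean / (sd / sqrt(N))
    with df = N - 1.  Zero-variance points: 0/0 is defined as t = 0; a
    nonzero mean over zero variance yields +-inf with a warning.
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    if n < 2:
        raise ValueError("need at least two participants")
    if not np.all(np.isfinite(stack)):
        raise ValueError("stack contains non-finite values")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    if degenerate.any():
        if np.any(degenerate & (mean != 0)):
            warnings.warn(
                "zero variance with nonzero mean; t set to +-inf", stacklevel=2
            )
        t[degenerate & (mean == 0)] = 0.0
    return t


def _adjacency_indices(adjacency: dict, ch_names: list) -> list[list[int]]:
    index = {c: i for i, c in enumerate(ch_names)}
    neigh: list[list[int]] = [[] for _ in ch_names]
    for c, nbrs in adjacency.items():
        if c not in index:
            continue
        for b in nbrs:
            if b in index:
                neigh[index[c]].append(index[b])
    # validate symmetry and absence of self-loops
    for i, nbrs in enumerate(neigh):
        if i in nbrs:
            raise ValueError("adjacency contains a self-loop")
        for j in nbrs:
            if i not in neigh[j]:
                raise ValueError("adjacency is not symmetric")
    return neigh


def find_clusters(
    t_map: np.ndarray,
    adjacency: dict,
    ch_names: list,
    threshold: float,
) -> list[Cluster]:
    """Group equal-sign supra-threshold points into connected clusters.

    Connectivity: spatial neighbours at the same time sample, or the same
    channel at adjacent time samples.  Cluster mass is the sum of member
    t-values.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    neigh = _adjacency_indices(adjacency, ch_names)
    n_ch, n_t = t_map.shape
    clusters: list[Cluster] = []
    visited = np.zeros((n_ch, n_t), dtype=bool)
    for sign in (1, -1):
        supra = (sign * t_map) > threshold
        for c0 in range(n_ch):
            for t0 in range(n_t):
                if not supra[c0, t0] or visited[c0, t0]:
                    continue
                # breadth-first flood over the supra-threshold mask
                members = []
                queue = [(c0, t0)]
                visited[c0, t0] = True
                while queue:
                    c, t = queue.pop()
                    members.append((c, t))
                    for nc in neigh[c]:
                        if supra[nc, t] and not visited[nc, t]:
                            visited[nc, t] = True
                            queue.append((nc, t))
                    for nt in (t - 1, t + 1):
                        if 0 <= nt < n_t and supra[c, nt] and not visited[c, nt]:
                            visited[c, nt] = True
                            queue.append((c, nt))
                clusters.append(
                    Cluster(
                        members=members,
                        mass=float(sum(t_map[c, t] for c, t in members)),
                        sign=sign,
                    )
                )
    return clusters


def _max_cluster_mass(
    t_map: np.ndarray, adjacency_idx: list[list[int]], threshold: float
) -> float:
    """Maximum |cluster mass| of a t-map (0 when no cluster forms)."""
    n_ch, n_t = t_map.shape
    best = 0.0
    visited = np.zeros((n_ch, n_t), dtype=bool)
    for sign in (1, -1):
        supra = (sign * t_map) > threshold
        if not supra.any():
            continue
        for c0, t0 in zip(*np.nonzero(supra)):
            if visited[c0, t0]:
                continue
            mass = 0.0
            queue = [(c0, t0)]
            visited[c0, t0] = True
            while queue:
                c, t = queue.pop()
                mass += t_map[c, t]
                for nc in adjacency_idx[c]:
                    if supra[nc, t] and not visited[nc, t]:
                        visited[nc, t] = True
                        queue.append((nc, t))
                for nt in (t - 1, t + 1):
                    if 0 <= nt < n_t and supra[c, nt] and not visited[c, nt]:
                        visited[c, nt] = True
                        queue.append((c, nt))
            best = max(best, abs(mass))
    return best


def _t_from_signed(stack: np.ndarray, signs: np.ndarray) -> np.ndarray:
    flipped = stack * signs[:, None, None]
    n = stack.shape[0]
    mean = flipped.mean(axis=0)
    sd = flipped.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[np.isnan(t)] = 0.0
    return t


def permutation_test(
    stack: np.ndarray,
    adjacency: dict,
    ch_names: list,
    times: np.ndarray,
    n_perm: int = 10_000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    method: str = "auto",
) -> ClusterResult:
    """Sign-flip cluster permutation test of participant effect maps.

    The cluster-forming threshold is the two-sided critical t at
    ``cluster_alpha`` with N-1 df.  ``method='auto'`` enumerates all 2^N
    sign assignments when N <= 12 (exact p-values; the identity assignment
    is part of the null, so p >= 1/2^N), otherwise draws ``n_perm`` random
    assignments and applies the add-one rule
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    if n_perm < 100:
        raise ValueError("n_perm below 100 is refused")
    if n < 5:
        warnings.warn("fewer than 5 participants; permutation null is coarse",
                      stacklevel=2)
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    threshold = float(stats.t.ppf(1 - cluster_alpha / 2, df=n - 1))
    neigh = _adjacency_indices(adjacency, ch_names)

    t_obs = dependent_t_map(stack)
    clusters = find_clusters(t_obs, adjacency, ch_names, threshold)

    exhaustive = method == "exhaustive" or (
        method == "auto" and n <= EXHAUSTIVE_MAX_N
    )
    if exhaustive:
        sign_sets = (
            np.array(s) for s in itertools.product((1.0, -1.0), repeat=n)
        )
        null = np.array(
            [
                _max_cluster_mass(_t_from_signed(stack, s), neigh, threshold)
                for s in sign_sets
            ]
        )
        for c in clusters:
            c.p_value = float(np.mean(null >= abs(c.mass)))
    else:
        null = np.empty(n_perm)
        for k in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n)
            null[k] = _max_cluster_mass(
                _t_from_signed(stack, signs), neigh, threshold
            )
        for c in clusters:
            c.p_value = float((1 + np.sum(null >= abs(c.mass))) / (1 + n_perm))

    return ClusterResult(
        clusters=clusters,
        t_map=t_obs,
        null_max_mass=null,
        config={
            "n_perm": int(null.size),
            "cluster_alpha": cluster_alpha,
            "alpha": alpha,
            "threshold": threshold,
            "method": "exhaustive" if exhaustive else "sampling",
            "n_participants": n,
        },
        ch_names=list(ch_names),
        times=np.asarray(times),
    )
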