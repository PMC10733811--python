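"""First-level mass-univariate regression of time–frequency power.

Per participant, an ordinary least-squares model with effect-coded
regressors (intercept, congruency, proportion condition, their product;
codes +-0.5) is fitted at every (electrode, frequency, time) point of the
decibel-scaled TFR.  Inducer and diagnostic trials are pooled.  From the
betas, condition marginal means and the conflict-effect maps follow
linearly: conflict(level) = incongruent - congruent within a proportion
level, and the adaptive-control map is conflict(MI) - conflict(MC) —
negative where conflict theta shrinks when conflict is expected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import X_CODE
from .tfr import TFRArray

__all__ = [
    "FirstLevelDesign",
    "EffectMap",
    "build_design",
    "check_min_trials",
    "first_level_ols",
    "conflict_effect_maps",
    "theta_band_average",
]

REGRESSORS = ["intercept", "congruency", "proportion", "interaction"]


@dataclass(frozen=True)
class FirstLevelDesign:
    """Effect-coded per-trial design matrix (columns: REGRESSORS)."""

    matrix: np.ndarray
    trial_index: np.ndarray

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            # name the offending columns for the error message
            bad = []
            for j, name in enumerate(REGRESSORS):
                others = np.delete(self.matrix, j, axis=1)
                proj = others @ np.linalg.lstsq(others, self.matrix[:, j], rcond=None)[0]
                if np.allclose(proj, self.matrix[:, j]):
                    bad.append(name)
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")


@dataclass
class EffectMap:
    """Channels x time map of a named contrast (dB), theta-averaged."""

    values: np.ndarray
    ch_names: list
    times: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.ch_names), len(self.times)):
            raise ValueError("axis metadata inconsistent with value array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("effect map must be finite")


def build_design(trials: pd.DataFrame) -> FirstLevelDesign:
    """Effect-coded design from a behaviour table slice (one participant)."""
    xc = trials["congruency"].map(X_CODE).to_numpy(float)
    xp = trials["proportion_condition"].map(X_CODE).to_numpy(float)
    X = np.column_stack([np.ones(len(trials)), xc, xp, xc * xp])
    return FirstLevelDesign(matrix=X, trial_index=trials.index.to_numpy())


def check_min_trials(trials: pd.DataFrame, min_per_cell: int = 40) -> bool:
    """True when every congruency x proportion cell holds enough trials.

    Participants failing the threshold are excluded from first-level
    fitting, mirroring the too-few-trials exclusion rule of the EEG
    analysis.
    """
    cells = trials.groupby(["congruency", "proportion_condition"]).size()
    return len(cells) == 4 and bool((cells >= min_per_cell).all())


def first_level_ols(
    tfr: TFRArray, design: FirstLevelDesign
) -> dict[str, np.ndarray]:
    """OLS beta maps per regressor over every (channel, frequency, time).

    Returns ``{regressor: channels x frequencies x time array}``.
    """
    X = design.matrix
    n_trials = tfr.power.shape[0]
    if X.shape[0] != n_trials:
        raise ValueError("design rows do not align with TFR trials")
    Y = tfr.power.reshape(n_trials, -1)
    betas, *_ = np.linalg.lstsq(X, Y, rcond=None)
    out_shape = tfr.power.shape[1:]
    return {
        name: betas[j].reshape(out_shape) for j, name in enumerate(REGRESSORS)
    }


def conflict_effect_maps(betas: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Marginal means and conflict contrasts from effect-coded betas.

    With +-0.5 coding, cell(c, p) = b0 + bC xc + bP xp + bCP xc xp;
    conflict(p) = cell(incongruent, p) - cell(congruent, p) = bC + bCP xp,
    and the adaptive map conflict(MI) - conflict(MC) equals bCP.
    """
    missing = [r for r in REGRESSORS if r not in betas]
    if missing:
        raise KeyError(f"missing regressors: {missing}")
    b0, bc, bp, bcp = (betas[r] for r in REGRESSORS)
    cells = {}
    for c in ("congruent", "incongruent"):
        for p in ("MC", "MI"):
            xc, xp = X_CODE[c], X_CODE[p]
            cells[f"mean_{c}_{p}"] = b0 + bc * xc + bp * xp + bcp * xc * xp
    maps = dict(cells)
    maps["conflict_MC"] = cells["mean_incongruent_MC"] - cells["mean_congruent_MC"]
    maps["conflict_MI"] = cells["mean_incongruent_MI"] - cells["mean_congruent_MI"]
    maps["adaptive"] = maps["conflict_MI"] - maps["conflict_MC"]
    return maps


def theta_band_average(
    map_3d: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float] = (4.0, 8.0),
) -> np.ndarray:
    """Unweighted mean over grid frequencies inside ``band`` (inclusive).

    ``map_3d`` is channels x frequencies x time; returns channels x time.
    """
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError("no frequency bins inside the requested band")
    return map_3d[:, sel, :].mean(axis=1)
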