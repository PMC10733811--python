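"""Experimental design generation for a proportion-congruency numerical Stroop task.

The task crosses two adaptive-control manipulations:

* **LWPC** (list-wide proportion congruency): whole blocks are mostly
  incongruent (MI) or mostly congruent (MC); the congruency bias is carried
  by *inducer* items while unbiased *diagnostic* items (50/50) measure the
  transfer of control free of stimulus–response learning.
* **ISPC** (item-specific proportion congruency): blocks are balanced
  overall, but the congruency bias is attached to an item feature — the
  magnitude class of the digit pair (small pairs < 5 vs large pairs > 5).

This module builds the item pools, composes block trial multisets with the
exact printed composition (134 trials: 94 inducer, 40 diagnostic), assigns
counterbalancing plans, and pseudo-randomizes trial orders under named,
pluggable constraints using random shuffling with backtracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Item",
    "DesignConfig",
    "AssignmentPlan",
    "Trial",
    "Constraint",
    "NoImmediateItemRepeat",
    "MaxRunLength",
    "DEFAULT_CONSTRAINTS",
    "ConfigurationError",
    "RandomizationError",
    "make_item_pool",
    "compose_block",
    "pseudo_randomize",
    "counterbalance_assign",
    "validate_sequence",
    "generate_participant_events",
    "generate_experiment",
    "write_events",
    "read_events",
]

EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "participant_id",
    "group",
    "block",
    "manipulation",
    "proportion_condition",
    "role",
    "congruency",
    "item_id",
    "correct_side",
]


class ConfigurationError(ValueError):
    """A design configuration that cannot be satisfied."""


class RandomizationError(RuntimeError):
    """Pseudo-randomization exhausted its retry budget."""

    def __init__(self, constraint_name: str):
        self.constraint_name = constraint_name
        super().__init__(
            f"no constraint-satisfying order found; last violated "
            f"constraint: {constraint_name}"
        )


@dataclass(frozen=True)
class Item:
    """A digit-pair stimulus.

    ``magnitude_class`` is 'small' (both digits < 5) or 'large' (both > 5);
    ``role`` (inducer vs diagnostic) is fixed per item within a participant.
    """

    item_id: str
    pair: tuple[int, int]
    magnitude_class: str
    role: str
    correct_side: str

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ValueError("digits of a pair must be distinct")
        if self.magnitude_class == "small" and not (a < 5 and b < 5):
            raise ValueError("small-class digits must all be < 5")
        if self.magnitude_class == "large" and not (a > 5 and b > 5):
            raise ValueError("large-class digits must all be > 5")


@dataclass(frozen=True)
class Trial:
    """One planned trial: an item shown congruently or incongruently."""

    item_id: str
    congruency: str  # congruent | incongruent
    proportion_condition: str  # MC | MI
    role: str  # inducer | diagnostic
    block_index: int = 0
    magnitude_class: str = ""
    correct_side: str = ""


@dataclass(frozen=True)
class DesignConfig:
    n_blocks: int = 8
    trials_per_block: int = 134
    n_inducer: int = 94
    n_diagnostic: int = 40
    inducer_bias: float = 0.8
    manipulation: str = "LWPC"
    counterbalance_index: int = 0
    constraint_set: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inducer + self.n_diagnostic != self.trials_per_block:
            raise ConfigurationError(
                "n_inducer + n_diagnostic must equal trials_per_block"
            )
        if not (0.5 < self.inducer_bias <= 1.0):
            raise ConfigurationError("inducer_bias must lie in (0.5, 1]")
        if self.n_diagnostic % 2:
            raise ConfigurationError(
                "diagnostic trials cannot be split evenly between congruencies"
            )


@dataclass(frozen=True)
class AssignmentPlan:
    """Counterbalancing plan for one participant.

    ``block_types`` lists the per-block manipulation/condition labels;
    ``large_class_mc`` records the magnitude-class <-> bias mapping for the
    ISPC blocks (True: large pairs carry the MC bias, small pairs MI).
    """

    participant_index: int
    group: str
    ispc_first: bool
    mi_first: bool
    large_class_mc: bool
    block_types: tuple[str, ...]


# ---------------------------------------------------------------------------
# constraints


class Constraint:
    """Prefix-decidable ordering constraint.

    ``ok(prefix, candidate)`` decides whether ``candidate`` may be appended
    to ``prefix``.  ``admissible(prefix, candidate, pool)`` may additionally
    veto a placement when the *remaining* multiset ``pool`` (a mapping
    trial -> count, candidate not yet removed) provably cannot complete the
    sequence — a forward-checking bound that keeps the backtracking search
    away from doomed branches.  The default is no lookahead.
    """

    name = "constraint"

    def ok(self, prefix: list[Trial], candidate: Trial) -> bool:  # pragma: no cover
        raise NotImplementedError

    def admissible(self, prefix, candidate, pool) -> bool:
        return self.ok(prefix, candidate)


class MaxRunLength(Constraint):
    """No more than ``max_run`` consecutive trials sharing one attribute value.

    The lookahead uses a run-capacity bound: with a trailing run of length
    k of value v, at most ``(max_run - k) + max_run * m_other`` further
    trials of v can ever be placed, where ``m_other`` counts remaining
    trials of any other value.  The bound is necessary, not sufficient, so
    backtracking remains the safety net.
    """

    def __init__(self, attribute: str, max_run: int):
        self.attribute = attribute
        self.max_run = max_run
        self.name = f"max_run_{attribute}_{max_run}"

    def _tail_run(self, prefix, value) -> int:
        run = 0
        for trial in reversed(prefix):
            if getattr(trial, self.attribute) != value:
                break
            run += 1
        return run

    def ok(self, prefix, candidate):
        value = getattr(candidate, self.attribute)
        return self._tail_run(prefix, value) + 1 <= self.max_run

    def admissible(self, prefix, candidate, pool):
        if not self.ok(prefix, candidate):
            return False
        r = self.max_run
        cand_value = getattr(candidate, self.attribute)
        # remaining counts by attribute value once the candidate is placed
        counts: dict = {}
        for trial, count in pool.items():
            if count > 0:
                v = getattr(trial, self.attribute)
                counts[v] = counts.get(v, 0) + count
        counts[cand_value] -= 1
        total = sum(counts.values())
        for v, m_v in counts.items():
            m_other = total - m_v
            k = (
                self._tail_run(prefix, cand_value) + 1
                if v == cand_value
                else 0
            )
            if m_v > (r - k) + r * m_other:
                return False
        return True


class NoImmediateItemRepeat(MaxRunLength):
    """The same item never appears on two consecutive trials."""

    def __init__(self):
        super().__init__("item_id", 1)
        self.name = "no_immediate_item_repeat"


def DEFAULT_CONSTRAINTS() -> list[Constraint]:
    return [
        NoImmediateItemRepeat(),
        MaxRunLength("congruency", 3),
        MaxRunLength("correct_side", 4),
    ]


# ---------------------------------------------------------------------------
# item pools


_SMALL_PAIRS = [(1, 2), (3, 4), (2, 4), (1, 3)]
_LARGE_PAIRS = [(6, 7), (8, 9), (7, 9), (6, 8)]


def make_item_pool(rng: np.random.Generator) -> list[Item]:
    """Build the per-participant item pool.

    Four digit pairs per magnitude class (numerical distances 1–2, small
    pairs from 1–4, large from 6–9); within each class two pairs are
    randomly assigned the inducer role and two the diagnostic role.
    Correct sides alternate within each class x role cell so left/right
    responses stay balanced.
    """
    items: list[Item] = []
    for cls, pairs in (("small", _SMALL_PAIRS), ("large", _LARGE_PAIRS)):
        roles = ["inducer", "inducer", "diagnostic", "diagnostic"]
        order = rng.permutation(4)
        side_counter = {"inducer": 0, "diagnostic": 0}
        for k, idx in enumerate(order):
            role = roles[k]
            side = "left" if side_counter[role] % 2 == 0 else "right"
            side_counter[role] += 1
            pair = pairs[idx]
            items.append(
                Item(
                    item_id=f"{cls}_{pair[0]}{pair[1]}",
                    pair=pair,
                    magnitude_class=cls,
                    role=role,
                    correct_side=side,
                )
            )
    return items


# ---------------------------------------------------------------------------
# block composition


def _allocate(total: int, k: int) -> list[int]:
    """Split ``total`` into k near-equal integer parts."""
    base = total // k
    counts = [base] * k
    for i in range(total - base * k):
        counts[i] += 1
    return counts


def _trials_for_items(
    items: list[Item],
    n_trials: int,
    n_incongruent: int,
    proportion_condition: str,
    block_index: int,
) -> list[Trial]:
    """Distribute ``n_trials`` over ``items`` with an exact congruency split.

    Trials and the incongruent quota are spread over items as evenly as
    integer counts permit; totals are exact by construction.
    """
    per_item = _allocate(n_trials, len(items))
    inc_per_item = _allocate(n_incongruent, len(items))
    # an item cannot take more incongruent trials than trials
    for i in range(len(items)):
        while inc_per_item[i] > per_item[i]:
            j = min(
                (j for j in range(len(items)) if inc_per_item[j] < per_item[j]),
                key=lambda j: inc_per_item[j],
            )
            inc_per_item[i] -= 1
            inc_per_item[j] += 1
    trials = []
    for item, n_it, n_inc in zip(items, per_item, inc_per_item):
        for t in range(n_it):
            congruency = "incongruent" if t < n_inc else "congruent"
            trials.append(
                Trial(
                    item_id=item.item_id,
                    congruency=congruency,
                    proportion_condition=proportion_condition,
                    role=item.role,
                    block_index=block_index,
                    magnitude_class=item.magnitude_class,
                    correct_side=item.correct_side,
                )
            )
    return trials


def compose_block(
    config: DesignConfig,
    block_type: str,
    items: list[Item] | None = None,
    large_class_mc: bool = True,
    block_index: int = 0,
) -> list[Trial]:
    """Compose the unordered trial multiset of one block.

    ``block_type`` is 'MC' or 'MI' for LWPC blocks, or 'ISPC'.  Inducer
    trials receive round(inducer_bias * n_inducer) trials of the biased
    congruency (incongruent in MI, congruent in MC); diagnostic trials are
    always split evenly.  ISPC blocks attach the bias per magnitude class
    (mapping given by ``large_class_mc``) with overall block congruency
    balanced.
    """
    if items is None:
        items = make_item_pool(np.random.default_rng(config.seed))
    inducers = [i for i in items if i.role == "inducer"]
    diagnostics = [i for i in items if i.role == "diagnostic"]

    n_diag_inc = config.n_diagnostic // 2

    if block_type in ("MC", "MI"):
        n_biased = round(config.inducer_bias * config.n_inducer)
        n_ind_inc = n_biased if block_type == "MI" else config.n_inducer - n_biased
        trials = _trials_for_items(
            inducers, config.n_inducer, n_ind_inc, block_type, block_index
        )
        trials += _trials_for_items(
            diagnostics, config.n_diagnostic, n_diag_inc, block_type, block_index
        )
    elif block_type == "ISPC":
        if config.n_inducer % 2 or config.n_diagnostic % 4:
            raise ConfigurationError(
                "ISPC blocks need inducer counts even and diagnostic counts "
                "divisible by 4 to balance the magnitude classes"
            )
        mapping = {
            "large": "MC" if large_class_mc else "MI",
            "small": "MI" if large_class_mc else "MC",
        }
        trials = []
        n_ind_cls = config.n_inducer // 2
        n_biased = round(config.inducer_bias * n_ind_cls)
        n_diag_cls = config.n_diagnostic // 2
        for cls in ("small", "large"):
            cond = mapping[cls]
            cls_inducers = [i for i in inducers if i.magnitude_class == cls]
            cls_diag = [i for i in diagnostics if i.magnitude_class == cls]
            n_inc = n_biased if cond == "MI" else n_ind_cls - n_biased
            trials += _trials_for_items(
                cls_inducers, n_ind_cls, n_inc, cond, block_index
            )
            trials += _trials_for_items(
                cls_diag, n_diag_cls, n_diag_cls // 2, cond, block_index
            )
    else:
        raise ConfigurationError(f"unknown block type {block_type!r}")

    assert len(trials) == config.trials_per_block
    return trials


# ---------------------------------------------------------------------------
# pseudo-randomization


def pseudo_randomize(
    trials: list[Trial],
    constraints: list[Constraint] | None = None,
    seed: int | np.random.Generator = 0,
    max_dead_ends: int = 100,
    max_restarts: int = 10_000,
) -> list[Trial]:
    """Order a trial multiset under constraints by shuffling + backtracking.

    Trials are placed left-to-right, drawing uniformly among the remaining
    trials that all constraints accept given the prefix.  A position with
    no acceptable trial is a dead end and triggers a one-step backtrack;
    after ``max_dead_ends`` dead ends the search restarts from a random
    earlier position, up to ``max_restarts`` restarts.  Identical seeds
    yield identical orders.
    """
    if not trials:
        raise ValueError("trial multiset is empty")
    if constraints is None:
        constraints = DEFAULT_CONSTRAINTS()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    from collections import Counter

    last_violated = constraints[0].name if constraints else "none"
    n = len(trials)
    counts: Counter = Counter(trials)

    def feasible(pool: Counter, prefix: list[Trial]) -> list[Trial]:
        """Constraint-passing distinct trials, in count-weighted random order.

        Weighting by remaining multiplicity reproduces a uniform shuffle of
        the multiset; without it the rarer congruency would deplete early
        and strand an unplaceable run at the end of the list.
        """
        nonlocal last_violated
        ok: list[Trial] = []
        weights: list[int] = []
        for trial, count in pool.items():
            if count <= 0:
                continue
            rejected = None
            for c in constraints:
                if not c.admissible(prefix, trial, pool):
                    rejected = c.name
                    break
            if rejected is None:
                ok.append(trial)
                weights.append(count)
            else:
                last_violated = rejected
        if not ok:
            return []
        # Efraimidis–Spirakis weighted shuffle; list stored so that .pop()
        # yields the weighted order
        keys = rng.random(len(ok)) ** (1.0 / np.asarray(weights))
        order = np.argsort(keys)  # ascending; pop() takes the largest key
        return [ok[i] for i in order]

    pool = counts.copy()
    prefix: list[Trial] = []
    dead_ends = 0
    restarts = 0
    while len(prefix) < n:
        cands = feasible(pool, prefix)
        if cands:
            trial = cands.pop()
            prefix.append(trial)
            pool[trial] -= 1
            continue
        if not prefix:
            # no candidate is placeable even on an empty prefix: unsatisfiable
            raise RandomizationError(last_violated)
        dead_ends += 1
        if dead_ends <= max_dead_ends:
            # backtrack one step and redraw
            returned = prefix.pop()
            pool[returned] += 1
        else:
            # persistent dead end: restart from a random earlier position
            restarts += 1
            if restarts > max_restarts:
                raise RandomizationError(last_violated)
            keep = int(rng.integers(len(prefix)))
            while len(prefix) > keep:
                returned = prefix.pop()
                pool[returned] += 1
            dead_ends = 0
    return prefix


def validate_sequence(
    sequence: list[Trial], constraints: list[Constraint] | None = None
) -> list[str]:
    """Re-check every constraint on an emitted sequence; return violations."""
    if constraints is None:
        constraints = DEFAULT_CONSTRAINTS()
    violations = []
    for pos in range(len(sequence)):
        for c in constraints:
            if not c.ok(list(sequence[:pos]), sequence[pos]):
                violations.append(f"{c.name}@{pos}")
    return violations


# ---------------------------------------------------------------------------
# counterbalancing


def counterbalance_assign(participant_index: int, group: str) -> AssignmentPlan:
    """Cyclic 2x2 counterbalance with period 4.

    Bit 0 of the index selects whether the ISPC half comes first; bit 1
    selects MI-first vs MC-first within the LWPC half and doubles as the
    magnitude-class <-> bias mapping bit (large pairs carry MC when set).
    """
    if participant_index < 0:
        raise ValueError("participant_index must be >= 0")
    idx = participant_index % 4
    ispc_first = bool(idx & 1)
    mi_first = bool((idx >> 1) & 1)
    large_class_mc = mi_first
    lwpc = ("MI", "MC", "MI", "MC") if mi_first else ("MC", "MI", "MC", "MI")
    ispc = ("ISPC",) * 4
    block_types = ispc + lwpc if ispc_first else lwpc + ispc
    return AssignmentPlan(
        participant_index=participant_index,
        group=group,
        ispc_first=ispc_first,
        mi_first=mi_first,
        large_class_mc=large_class_mc,
        block_types=block_types,
    )


# ---------------------------------------------------------------------------
# event tables

# Nominal trial timing, recorded as metadata only (no presentation).  The
# fixation duration is specified inconsistently at the source protocol
# level (300-600 ms uniform vs 300-360 ms); both options are carried.
FIXATION_WINDOWS = {"uniform_300_600": (0.300, 0.600), "short_300_360": (0.300, 0.360)}
STIMULUS_DEADLINE_S = 2.0
BLANK_S = 0.8


def generate_participant_events(
    config: DesignConfig,
    participant_index: int,
    group: str,
    seed: int,
    constraints: list[Constraint] | None = None,
) -> pd.DataFrame:
    """Generate the full ordered event table for one participant."""
    rng = np.random.default_rng(seed)
    plan = counterbalance_assign(participant_index, group)
    items = make_item_pool(rng)
    rows = []
    onset = 0.0
    for b, btype in enumerate(plan.block_types):
        manipulation = "ISPC" if btype == "ISPC" else "LWPC"
        trials = compose_block(
            config, btype, items=items, large_class_mc=plan.large_class_mc,
            block_index=b,
        )
        ordered = pseudo_randomize(trials, constraints, rng)
        for t in ordered:
            rows.append(
                {
                    "onset": round(onset, 3),
                    "duration": STIMULUS_DEADLINE_S,
                    "trial_type": f"{manipulation}_{t.proportion_condition}_{t.congruency}",
                    "participant_id": f"sub-{participant_index:03d}",
                    "group": group,
                    "block": b,
                    "manipulation": manipulation,
                    "proportion_condition": t.proportion_condition,
                    "role": t.role,
                    "congruency": t.congruency,
                    "item_id": t.item_id,
                    "correct_side": t.correct_side,
                }
            )
            onset += 0.45 + STIMULUS_DEADLINE_S + BLANK_S
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def generate_experiment(
    config: DesignConfig,
    n_per_group: int = 30,
    groups: tuple[str, str] = ("HC", "PD"),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate event tables for a two-group experiment."""
    ss = np.random.SeedSequence(seed)
    tables = []
    child_seeds = ss.spawn(len(groups) * n_per_group)
    k = 0
    for group in groups:
        for p in range(n_per_group):
            pidx = p if group == groups[0] else n_per_group + p
            tables.append(
                generate_participant_events(
                    config, pidx, group, seed=child_seeds[k].generate_state(1)[0] % (2**31)
                )
            )
            k += 1
    return pd.concat(tables, ignore_index=True)


def write_events(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
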