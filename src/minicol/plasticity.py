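"""The reward-gated cluster learning rule and the training loop.

A cluster is *eligible* in an episode when enough of its sources are active
(all of them, under the default threshold) while its cell is fired by the
apical "guess" input.  Eligible clusters are strengthened when the episode's
reward is positive or insignificant and weakened when it is negative; the
default weakening removes the accumulated enhancement outright
(reset-to-zero), with a graded decrement mode available.  The behavioural
eligibility window collapses to same-episode coincidence because patterns
are static within an episode.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .core import (
    DETECTOR_XXXXX,
    DETECTOR_XXOXX,
    BasalTree,
    LearnerCell,
    Minicolumn,
    Network,
)
from .patterns import InputPattern, PatternAssignment, detect_object


@dataclass(frozen=True)
class RewardSignal:
    """A reward outcome: its sign and non-negative magnitude."""

    sign: Literal["positive", "insignificant", "negative"]
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("reward magnitude must be non-negative")
        if self.sign == "insignificant" and self.magnitude != 0:
            object.__setattr__(self, "magnitude", 0.0)


POSITIVE = RewardSignal("positive", 1.0)
NEGATIVE = RewardSignal("negative", 1.0)
INSIGNIFICANT = RewardSignal("insignificant")


@dataclass(frozen=True)
class PlasticityRule:
    """How eligible clusters change weight under each reward sign.

    Strengthening adds ``potentiation_increment`` scaled by the reward
    magnitude; an insignificant (zero-magnitude) reward strengthens by one
    full increment, since the rule treats positive and insignificant
    rewards identically.  Weakening either resets the weight to zero
    (default — enhancement is removed if present) or decrements it by
    ``decrement_step`` per unit magnitude, floored at zero.
    """

    potentiation_increment: float = 1.0
    weakening_mode: Literal["reset_to_zero", "decrement"] = "reset_to_zero"
    decrement_step: float = 1.0

    def __post_init__(self) -> None:
        if self.potentiation_increment <= 0 or self.decrement_step <= 0:
            raise ValueError("increments must be positive")


DEFAULT_RULE = PlasticityRule()


def cluster_active(
    cluster_sources: Iterable[int] | np.ndarray,
    extended_activity: np.ndarray,
    G: int,
) -> bool:
    """Is the cluster excited: are >= G of its sources active?

    With G equal to the cluster size this is "all synapses active", the
    rule the minicolumn experiments use.
    """
    sources = np.fromiter(cluster_sources, dtype=np.int64) if not isinstance(
        cluster_sources, np.ndarray
    ) else cluster_sources
    activity = np.asarray(extended_activity, dtype=bool)
    if sources.size and (sources.min() < 0 or sources.max() >= activity.size):
        raise KeyError("cluster source outside the activity map")
    return int(activity[sources].sum()) >= G


def active_cluster_mask(
    tree: BasalTree, extended_activity: np.ndarray, G: int
) -> np.ndarray:
    """Vectorised eligibility over a whole tree: one boolean per cluster."""
    activity = np.asarray(extended_activity, dtype=bool)
    if activity.size != tree.I + tree.n_detectors:
        raise KeyError(
            f"activity map of size {activity.size} does not cover the tree's "
            f"{tree.I + tree.n_detectors} source codes"
        )
    hits = activity[tree.sources]
    if G >= tree.cluster_size:
        return hits.all(axis=1)
    return hits.sum(axis=1) >= G


def extend_activity(pattern: InputPattern, minicolumn: Minicolumn) -> np.ndarray:
    """Activity over all of a minicolumn's source codes.

    External codes carry the pattern's activity; detector codes (present
    only in the hierarchical configuration) carry the detectors' responses
    to the raw pattern.
    """
    activity = pattern.activity
    if minicolumn.detectors is None:
        return activity.copy()
    ext = np.zeros(activity.size + 2, dtype=bool)
    ext[: activity.size] = activity
    for det in minicolumn.detectors:
        idx = DETECTOR_XXXXX if det.object_type == "XXXXX" else DETECTOR_XXOXX
        ext[activity.size + idx] = detect_object(activity, det.object_type)
    return ext


def apply_reward_rule(
    weight: float,
    eligible: bool,
    reward: RewardSignal,
    rule: PlasticityRule = DEFAULT_RULE,
) -> float:
    """Update a single cluster weight; the scalar reference for the rule."""
    if weight < 0:
        raise ValueError("weights are non-negative by invariant")
    if not eligible:
        return weight
    if reward.sign in ("positive", "insignificant"):
        scale = reward.magnitude if reward.sign == "positive" and reward.magnitude > 0 else 1.0
        return weight + rule.potentiation_increment * scale
    if rule.weakening_mode == "reset_to_zero":
        return 0.0
    return max(0.0, weight - rule.decrement_step * reward.magnitude)


def _update_tree(
    tree: BasalTree,
    eligible: np.ndarray,
    reward: RewardSignal,
    rule: PlasticityRule,
) -> None:
    if reward.sign in ("positive", "insignificant"):
        scale = reward.magnitude if reward.sign == "positive" and reward.magnitude > 0 else 1.0
        tree.weights[eligible] += rule.potentiation_increment * scale
    elif rule.weakening_mode == "reset_to_zero":
        tree.weights[eligible] = 0.0
    else:
        tree.weights[eligible] = np.maximum(
            tree.weights[eligible] - rule.decrement_step * reward.magnitude, 0.0
        )


@dataclass
class TrainingEpisode:
    """One presentation: a pattern, the apically fired cells, the reward."""

    pattern: InputPattern
    fired_cells: set[tuple[int, str]]
    reward: RewardSignal = POSITIVE


def training_episode(
    network: Network, episode: TrainingEpisode, rule: PlasticityRule = DEFAULT_RULE
) -> Network:
    """Apply one episode in place: update every eligible cluster of every
    fired learner; every other cell is untouched."""
    G = network.config.g_threshold
    cells = {(mc.id, cell.layer): cell for mc in network.minicolumns for cell in mc.learners()}
    columns = {mc.id: mc for mc in network.minicolumns}
    for mc_id, layer in sorted(episode.fired_cells):
        cell = cells.get((mc_id, layer))
        if cell is None:
            raise KeyError(f"no learner ({mc_id}, {layer}) in this network")
        ext = extend_activity(episode.pattern, columns[mc_id])
        eligible = active_cluster_mask(cell.tree, ext, G)
        _update_tree(cell.tree, eligible, episode.reward, rule)
    return network


def fired_cells_for(network: Network, mc_id: int) -> set[tuple[int, str]]:
    """The cells that fire when minicolumn ``mc_id`` is apically selected:
    its L5 and, through dendritic-bundle cross-induction, its co-bundled
    L2/3 learner (the prewired detectors hold no plastic weights)."""
    mc = network.minicolumns[mc_id]
    fired = {(mc_id, "L5")}
    if mc.l23_learner is not None:
        fired.add((mc_id, "L23"))
    return fired


def train(
    network: Network,
    assignment: PatternAssignment,
    rule: PlasticityRule = DEFAULT_RULE,
    reward_schedule: Optional[Sequence[RewardSignal]] = None,
) -> Network:
    """One training epoch: each pattern presented once, in order, firing its
    assigned minicolumn.  Default schedule: positive unit reward every
    episode (under which final weights are order-independent)."""
    if reward_schedule is None:
        reward_schedule = [POSITIVE] * len(assignment)
    if len(reward_schedule) != len(assignment):
        raise ValueError("reward schedule length must match the pattern count")
    for pattern, mc_id, reward in zip(
        assignment.patterns, assignment.assigned_mc, reward_schedule
    ):
        episode = TrainingEpisode(pattern, fired_cells_for(network, mc_id), reward)
        training_episode(network, episode, rule)
    return network


# ---------------------------------------------------------------------------
# Worked example: abstract-concept extraction with 2-synapse clusters
# ---------------------------------------------------------------------------

ConceptStep = tuple[frozenset[int], str]


def run_concept_extraction(
    sequence: Sequence[tuple[Iterable[int], str]],
    n_inputs: int = 4,
    return_history: bool = False,
):
    """Replay a trial-and-error sequence on a cell whose basal tree is all
    2-synapse clusters over ``n_inputs`` inputs (numbered from 1).

    Each step is ``(active_inputs, reward_sign)`` with sign ``"+"`` or
    ``"-"``; the cell trial-fires on every step, so every fully active pair
    is strengthened (binary enhancement) on ``"+"`` and has its enhancement
    removed on ``"-"``.  A pair that survives the sequence is an extracted
    abstract concept: a combination the rewards singled out.

    Returns the set of enhanced pairs (as sorted tuples), plus the per-step
    history of enhanced sets when ``return_history`` is true.
    """
    pairs = list(combinations(range(1, n_inputs + 1), 2))
    weights = {p: 0 for p in pairs}
    history = []
    for active, sign in sequence:
        active = frozenset(int(a) for a in active)
        if not active <= set(range(1, n_inputs + 1)):
            raise ValueError(f"active inputs {sorted(active)} outside 1..{n_inputs}")
        if sign not in ("+", "-"):
            raise ValueError(f"reward sign must be '+' or '-', got {sign!r}")
        reward = POSITIVE if sign == "+" else NEGATIVE
        for pair in pairs:
            eligible = set(pair) <= active
            w = apply_reward_rule(weights[pair], eligible, reward)
            weights[pair] = 1 if w > 0 else 0  # binary enhancement
        history.append({p for p, w in weights.items() if w > 0})
    enhanced = {p for p, w in weights.items() if w > 0}
    if return_history:
        return enhanced, history
    return enhanced
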