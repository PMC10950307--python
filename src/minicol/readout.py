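"""Memory readout: response scores, winner-take-all, and accuracy metrics.

Testing is read-only.  For each pattern, every minicolumn's L5 sums the
weights of its fully active clusters and the minicolumn with the largest
sum fires (ties broken uniformly at random).  In the internal-representation
configuration the L2/3 learners run an independent competition of their
own, and a pattern is *simultaneously* correct when both layer winners are
the assigned minicolumn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import LearnerCell, Network
from .patterns import PatternAssignment
from .plasticity import active_cluster_mask, extend_activity


@dataclass(frozen=True)
class ClassificationOutcome:
    """The readout of one test pattern."""

    pattern_id: int
    assigned_mc: int
    winner_l5: int
    winner_l23: Optional[int]
    correct_l5: bool
    correct_simultaneous: Optional[bool]
    margin_l5: float
    margin_l23: Optional[float]


def pc_response(
    cell: LearnerCell, extended_activity: np.ndarray, G: int
) -> float:
    """Summed weight of the cell's excited clusters under this activity."""
    mask = active_cluster_mask(cell.tree, extended_activity, G)
    return float(cell.tree.weights[mask].sum())


def winner_take_all(scores, rng: np.random.Generator) -> int:
    """Index of the maximum score; ties broken uniformly at random.

    The generator is consulted only when there is an actual tie, so
    tie-free competitions leave the stream untouched.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("winner_take_all needs at least one score")
    top = scores.max()
    winners = np.flatnonzero(scores == top)
    if winners.size == 1:
        return int(winners[0])
    return int(winners[rng.integers(winners.size)])


def _margin(scores: np.ndarray) -> float:
    if scores.size < 2:
        return float(scores[0])
    top2 = np.partition(scores, -2)[-2:]
    return float(top2[1] - top2[0])


def evaluate(
    network: Network,
    assignment: PatternAssignment,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Present every training pattern once for testing.

    Returns the per-pattern outcome table and the summary accuracies
    (``accuracy_l5`` always; ``accuracy_l23`` and ``accuracy_simultaneous``
    in the internal-representation configuration).  Tie-break draws consume
    the generator in a fixed order: pattern order, L5 before L2/3.
    """
    config = network.config
    G = config.g_threshold
    internal_rep = all(mc.l23_learner is not None for mc in network.minicolumns)

    # score matrix per layer: (n_patterns, n_mc), computed tree by tree so
    # the per-tree eligibility test is a single vectorised gather
    n_pat = len(assignment)
    scores_l5 = np.zeros((n_pat, config.n_mc))
    scores_l23 = np.zeros((n_pat, config.n_mc)) if internal_rep else None
    for mc in network.minicolumns:
        ext = np.stack([extend_activity(p, mc) for p in assignment.patterns])
        for cell in mc.learners():
            hits = ext[:, cell.tree.sources]  # (n_pat, n_clusters, C)
            active = hits.all(axis=2) if G >= cell.tree.cluster_size else hits.sum(axis=2) >= G
            col = active @ cell.tree.weights
            if cell.layer == "L5":
                scores_l5[:, mc.id] = col
            else:
                scores_l23[:, mc.id] = col

    outcomes = []
    for pid, target in enumerate(assignment.assigned_mc):
        w5 = winner_take_all(scores_l5[pid], rng)
        correct_l5 = w5 == target
        if internal_rep:
            w23 = winner_take_all(scores_l23[pid], rng)
            simultaneous = correct_l5 and w23 == target
            outcomes.append(
                ClassificationOutcome(
                    pid, target, w5, w23, correct_l5, simultaneous,
                    _margin(scores_l5[pid]), _margin(scores_l23[pid]),
                )
            )
        else:
            outcomes.append(
                ClassificationOutcome(
                    pid, target, w5, None, correct_l5, None,
                    _margin(scores_l5[pid]), None,
                )
            )

    df = pd.DataFrame(outcomes)
    accuracies = {"accuracy_l5": float(df["correct_l5"].mean())}
    if internal_rep:
        accuracies["accuracy_l23"] = float(
            (df["winner_l23"] == df["assigned_mc"]).mean()
        )
        accuracies["accuracy_simultaneous"] = float(df["correct_simultaneous"].mean())
    return df, accuracies
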