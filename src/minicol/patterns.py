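"""Synthetic input patterns: randomly placed objects on a 1-D input line.

Two object types, each 5 inputs wide: ``XXXXX`` (five adjacent active
inputs) and ``XXOXX`` (two active pairs separated by one inactive input).
Objects within a pattern neither overlap nor touch — at least one inactive
input separates consecutive footprints — and there is no wrap-around at the
line's ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .config import ExperimentConfig

OBJECT_WIDTH = 5
#: Active offsets within the 5-wide footprint, per object type.
_FOOTPRINT = {
    "XXXXX": (0, 1, 2, 3, 4),
    "XXOXX": (0, 1, 3, 4),
}
_MAX_REDRAWS = 1_000
_MAX_ASSIGNMENT_REDRAWS = 10_000


@dataclass(frozen=True)
class ObjectPlacement:
    """One object: its type and the leftmost input of its 5-wide footprint."""

    object_type: Literal["XXXXX", "XXOXX"]
    start: int


@dataclass(frozen=True)
class InputPattern:
    """A binary activity vector together with the placements that made it."""

    activity: np.ndarray
    placements: tuple[ObjectPlacement, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "activity", np.asarray(self.activity, dtype=bool))

    @property
    def I(self) -> int:
        return self.activity.size

    def key(self) -> bytes:
        return self.activity.tobytes()


@dataclass
class PatternAssignment:
    """A pattern set plus the minicolumn each pattern is assigned to."""

    patterns: list[InputPattern]
    assigned_mc: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patterns)


def _activity_from_placements(
    I: int, placements: Sequence[ObjectPlacement]
) -> np.ndarray:
    activity = np.zeros(I, dtype=bool)
    for p in placements:
        if not 0 <= p.start <= I - OBJECT_WIDTH:
            raise ValueError(f"placement start {p.start} out of range for I={I}")
        for off in _FOOTPRINT[p.object_type]:
            activity[p.start + off] = True
    return activity


def place_objects(
    I: int,
    object_type: Literal["XXXXX", "XXOXX"],
    n_objects: int,
    rng: np.random.Generator,
) -> InputPattern:
    """Place ``n_objects`` objects uniformly over all valid placement sets.

    Valid means: non-overlapping, non-touching (gap >= 1 inactive input
    between footprints), fully inside the line.  Sampling is exact — the
    sorted start positions are drawn through the stars-and-bars bijection
    with combinations, not by rejection.

    Raises
    ------
    ValueError
        If the packing is infeasible (``5 n + (n-1) > I``) or the object
        type is unknown.
    """
    if object_type not in _FOOTPRINT:
        raise ValueError(f"unknown object type {object_type!r}")
    if n_objects < 0:
        raise ValueError("n_objects must be non-negative")
    if n_objects == 0:
        return InputPattern(np.zeros(I, dtype=bool), ())
    min_span = n_objects * OBJECT_WIDTH + (n_objects - 1)
    if min_span > I:
        raise ValueError(
            f"cannot place {n_objects} objects of width {OBJECT_WIDTH} with "
            f"unit gaps on {I} inputs (needs {min_span})"
        )
    # Stars-and-bars bijection: sorted starts s_k with s_{k+1} >= s_k + 6
    # (footprint 5 + gap 1) map via t_k = s_k - 6k to non-decreasing
    # sequences in [0, M], and via v_k = t_k + k to plain combinations from
    # {0, ..., M + n - 1}; drawing v uniformly is exactly uniform over
    # valid placement sets.
    M = I - OBJECT_WIDTH - 6 * (n_objects - 1)
    v = np.sort(rng.choice(M + n_objects, size=n_objects, replace=False))
    k = np.arange(n_objects)
    starts = (v - k) + 6 * k
    placements = tuple(ObjectPlacement(object_type, int(s)) for s in starts)
    return InputPattern(_activity_from_placements(I, placements), placements)


def detect_object(
    pattern: InputPattern | np.ndarray, object_type: Literal["XXXXX", "XXOXX"]
) -> bool:
    """Detector response: does the raw activity contain the object's motif?

    ``XXXXX`` fires on any 5 adjacent active inputs; ``XXOXX`` on any two
    active adjacent pairs separated by one *inactive* input.  Detectors are
    sensory cells: they see activity, not the placements that generated it.
    """
    activity = pattern.activity if isinstance(pattern, InputPattern) else pattern
    activity = np.asarray(activity, dtype=bool)
    if activity.size < OBJECT_WIDTH:
        return False
    w = np.lib.stride_tricks.sliding_window_view(activity, OBJECT_WIDTH)
    if object_type == "XXXXX":
        return bool(w.all(axis=1).any())
    if object_type == "XXOXX":
        template_on = w[:, [0, 1, 3, 4]].all(axis=1)
        return bool((template_on & ~w[:, 2]).any())
    raise ValueError(f"unknown object type {object_type!r}")


def _distinct_patterns(
    n: int,
    I: int,
    object_type: str,
    n_objects: int,
    rng: np.random.Generator,
) -> list[InputPattern]:
    """Draw n patterns with pairwise-distinct activity vectors (bounded redraw)."""
    seen: set[bytes] = set()
    out: list[InputPattern] = []
    redraws = 0
    while len(out) < n:
        p = place_objects(I, object_type, n_objects, rng)
        if p.key() in seen:
            redraws += 1
            if redraws > _MAX_REDRAWS:
                raise RuntimeError(
                    f"could not draw {n} distinct patterns in {_MAX_REDRAWS} redraws"
                )
            continue
        seen.add(p.key())
        out.append(p)
    return out


def _balanced_assignment(
    n_patterns: int, n_mc: int, rng: np.random.Generator
) -> np.ndarray:
    per_mc = n_patterns // n_mc
    slots = np.repeat(np.arange(n_mc), per_mc)
    return rng.permutation(slots)


def make_pattern_set(
    config: ExperimentConfig, rng: np.random.Generator
) -> PatternAssignment:
    """Build the experiment's pattern set and its minicolumn assignment.

    Internal-representation mode: ``n_patterns`` distinct XXXXX patterns,
    ``n_patterns / n_mc`` assigned to each minicolumn.

    Hierarchical mode: ``n_patterns / 2`` distinct random XXXXX patterns
    plus one XXOXX twin per XXXXX pattern copying its exact object start
    positions; each twin pair is assigned to two *different* minicolumns
    (balanced assignment, redrawn until the constraint holds).
    """
    if config.n_patterns % config.n_mc:
        raise ValueError("n_patterns must be divisible by n_mc")
    if config.mode == "internal_rep":
        patterns = _distinct_patterns(
            config.n_patterns, config.I, "XXXXX", config.n_objects, rng
        )
        assigned = _balanced_assignment(config.n_patterns, config.n_mc, rng)
        return PatternAssignment(patterns, [int(a) for a in assigned])

    # hierarchical: location-matched twins
    if config.n_patterns % 2:
        raise ValueError("hierarchical mode needs an even n_patterns")
    half = config.n_patterns // 2
    x_patterns = _distinct_patterns(half, config.I, "XXXXX", config.n_objects, rng)
    twins = []
    for p in x_patterns:
        placements = tuple(ObjectPlacement("XXOXX", pl.start) for pl in p.placements)
        twins.append(
            InputPattern(_activity_from_placements(config.I, placements), placements)
        )
    patterns = x_patterns + twins
    for attempt in range(_MAX_ASSIGNMENT_REDRAWS):
        assigned = _balanced_assignment(config.n_patterns, config.n_mc, rng)
        if (assigned[:half] != assigned[half:]).all():
            return PatternAssignment(patterns, [int(a) for a in assigned])
    raise RuntimeError("could not split every twin pair across minicolumns")


def write_patterns(assignment: PatternAssignment, path: str | Path) -> None:
    """Plain-text export: pattern_id, assigned_mc, 0/1 activity, placements."""
    lines = []
    for pid, (pattern, mc) in enumerate(zip(assignment.patterns, assignment.assigned_mc)):
        activity = "".join("1" if a else "0" for a in pattern.activity)
        placements = ";".join(f"{p.object_type}:{p.start}" for p in pattern.placements)
        lines.append(f"{pid}\t{mc}\t{activity}\t{placements}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_patterns(path: str | Path) -> PatternAssignment:
    """Inverse of :func:`write_patterns`; the round trip is lossless."""
    patterns: list[InputPattern] = []
    assigned: list[int] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        _pid, mc, activity, placements_field = line.split("\t")
        placements = tuple(
            ObjectPlacement(t, int(s))
            for t, s in (item.split(":") for item in placements_field.split(";") if item)
        )
        activity_arr = np.frombuffer(activity.encode(), dtype=np.uint8) == ord("1")
        expected = _activity_from_placements(activity_arr.size, placements)
        if not np.array_equal(expected, activity_arr):
            raise ValueError(f"{path}: activity inconsistent with placements")
        patterns.append(InputPattern(activity_arr, placements))
        assigned.append(int(mc))
    return PatternAssignment(patterns, assigned)
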