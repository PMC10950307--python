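"""Domain types and basal-tree construction.

Sources (presynaptic identities) are encoded as integer codes: external
input ``i`` is code ``i`` (``0 <= i < I``) and detector ``d`` is code
``I + d``.  A basal tree stores its clusters as a dense ``(n_clusters, C)``
integer array of source codes plus a weight vector, which is what makes the
training and readout loops vectorisable; the :class:`SynapticCluster` /
:class:`SourceId` objects are the ergonomic per-cluster view of the same
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

import numpy as np
import pandas as pd

from .config import ExperimentConfig

#: Detector indices within a minicolumn (code = I + index).
DETECTOR_XXXXX = 0
DETECTOR_XXOXX = 1
OBJECT_TYPES = ("XXXXX", "XXOXX")


@dataclass(frozen=True)
class SourceId:
    """A presynaptic source: an external input or an L2/3 detector."""

    kind: Literal["external", "l23_detector"]
    index: int

    def code(self, I: int) -> int:
        if self.kind == "external":
            if not 0 <= self.index < I:
                raise ValueError(f"external index {self.index} out of range [0, {I})")
            return self.index
        if self.index not in (DETECTOR_XXXXX, DETECTOR_XXOXX):
            raise ValueError(f"detector index {self.index} must be 0 or 1")
        return I + self.index

    @classmethod
    def from_code(cls, code: int, I: int) -> "SourceId":
        if code < I:
            return cls("external", code)
        return cls("l23_detector", code - I)


@dataclass(frozen=True)
class SynapticCluster:
    """A set of C distinct sources sharing one excitation weight."""

    sources: frozenset[int]
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("cluster weight must be non-negative")


@dataclass
class SourcePool:
    """The weighted sampling space for cluster construction.

    Each external input owns one sampling slot; each detector owns F slots,
    so a single draw hits a detector with probability 2F / (I + 2F).
    """

    I: int
    F: float = 0.0
    include_detectors: bool = False

    @property
    def n_sources(self) -> int:
        return self.I + (2 if self.include_detectors else 0)

    def weights(self) -> np.ndarray:
        w = np.ones(self.n_sources, dtype=float)
        if self.include_detectors:
            w[self.I :] = self.F
        return w


class BasalTree:
    """The basal dendritic tree of one learner cell.

    Clusters own disjoint physical synapses (total synapses = C x
    n_clusters, capped at S_max) but repeated source compositions across
    clusters are allowed.
    """

    def __init__(self, sources: np.ndarray, I: int, n_detectors: int = 0) -> None:
        sources = np.asarray(sources, dtype=np.int32)
        if sources.ndim != 2:
            raise ValueError("sources must be a (n_clusters, C) array")
        n_codes = I + n_detectors
        if sources.size and (sources.min() < 0 or sources.max() >= n_codes):
            raise ValueError("source code out of range for this tree")
        # within-cluster distinctness: no two synapses from the same input
        row_sorted = np.sort(sources, axis=1)
        if sources.shape[1] > 1 and (row_sorted[:, 1:] == row_sorted[:, :-1]).any():
            raise ValueError("clusters may not contain duplicate sources")
        self.sources = sources
        self.I = I
        self.n_detectors = n_detectors
        self.weights = np.zeros(sources.shape[0], dtype=float)

    @property
    def cluster_size(self) -> int:
        return self.sources.shape[1]

    @property
    def n_clusters(self) -> int:
        return self.sources.shape[0]

    @property
    def n_synapses(self) -> int:
        return self.sources.size

    def clusters(self) -> Iterator[SynapticCluster]:
        for row, w in zip(self.sources, self.weights):
            yield SynapticCluster(frozenset(int(s) for s in row), float(w))

    def copy(self) -> "BasalTree":
        tree = BasalTree(self.sources.copy(), self.I, self.n_detectors)
        tree.weights = self.weights.copy()
        return tree

    def to_frame(self) -> pd.DataFrame:
        """Tabular dump: one row per cluster, sources sorted, for debugging."""
        srt = np.sort(self.sources, axis=1)
        return pd.DataFrame(
            {
                "cluster_index": np.arange(self.n_clusters),
                "sources": [",".join(map(str, row)) for row in srt],
                "weight": self.weights,
            }
        )


@dataclass(frozen=True)
class DetectorCell:
    """A prewired L2/3 cell whose output is a pure function of the pattern."""

    object_type: Literal["XXXXX", "XXOXX"]

    def __post_init__(self) -> None:
        if self.object_type not in OBJECT_TYPES:
            raise ValueError(f"object_type must be one of {OBJECT_TYPES}")


@dataclass
class LearnerCell:
    """A pyramidal cell with a plastic basal tree (L5 or L2/3)."""

    layer: Literal["L5", "L23"]
    tree: BasalTree


@dataclass
class Minicolumn:
    """One L5 learner plus configuration-dependent L2/3 cells."""

    id: int
    l5: LearnerCell
    l23_learner: Optional[LearnerCell] = None
    detectors: Optional[tuple[DetectorCell, DetectorCell]] = None

    def __post_init__(self) -> None:
        if self.l23_learner is not None and self.detectors is not None:
            raise ValueError("a minicolumn has either an L2/3 learner or detectors")

    def learners(self) -> list[LearnerCell]:
        cells = [self.l5]
        if self.l23_learner is not None:
            cells.append(self.l23_learner)
        return cells


@dataclass
class Network:
    """All minicolumns of one experiment run."""

    config: ExperimentConfig
    minicolumns: list[Minicolumn] = field(default_factory=list)

    def tree_dump(self) -> pd.DataFrame:
        frames = []
        for mc in self.minicolumns:
            for cell in mc.learners():
                df = cell.tree.to_frame()
                df.insert(0, "layer", cell.layer)
                df.insert(0, "minicolumn", mc.id)
                frames.append(df)
        return pd.concat(frames, ignore_index=True)


def selection_capacity(I: int, G: int) -> int:
    """Number of pyramidal cells individually addressable through tuft clusters.

    If every cell's tuft cluster is a distinct G-subset of I selection
    inputs, and G coincidently active synapses fire the cluster's NMDA
    spike, then exactly C(I, G) cells can be singled out.  Returned as an
    exact arbitrary-precision integer.
    """
    if I < 0 or G < 0:
        raise ValueError("I and G must be non-negative")
    if G > I:
        raise ValueError(f"G={G} exceeds I={I}")
    return math.comb(I, G)


def _sample_source_rows(
    n_rows: int, C: int, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw n_rows clusters of C distinct sources, probability per draw
    proportional to the source's slot weight, duplicates rejected.

    Uses exponential sorting keys (key = Exp(1)/w; take the C smallest),
    which reproduces successive weighted draws with rejection of
    already-chosen sources.  Rows are returned in selection order, so
    column 0 is an exact single categorical draw from the pool.
    """
    n_sources = weights.size
    if np.count_nonzero(weights > 0) < C:
        raise ValueError(
            f"cluster size {C} exceeds the {np.count_nonzero(weights > 0)} "
            "distinct sources with positive weight"
        )
    keys = rng.exponential(size=(n_rows, n_sources))
    with np.errstate(divide="ignore"):
        keys /= weights
    idx = np.argpartition(keys, C - 1, axis=1)[:, :C]
    order = np.argsort(np.take_along_axis(keys, idx, axis=1), axis=1)
    return np.take_along_axis(idx, order, axis=1).astype(np.int32)


def sample_cluster(pool: SourcePool, C: int, rng: np.random.Generator) -> SynapticCluster:
    """Sample one cluster of C distinct sources from the weighted pool."""
    row = _sample_source_rows(1, C, pool.weights(), rng)[0]
    return SynapticCluster(frozenset(int(s) for s in row), 0.0)


def build_basal_tree(
    config: ExperimentConfig, include_detectors: bool, rng: np.random.Generator
) -> BasalTree:
    """Build a fresh tree of floor(S_max / C) independently sampled clusters.

    Detector sources enter the sampling pool (at slot weight F each) only
    for hierarchical-configuration L5 trees.
    """
    pool = SourcePool(config.I, config.F, include_detectors)
    n_clusters = config.S_max // config.C
    sources = _sample_source_rows(n_clusters, config.C, pool.weights(), rng)
    n_det = 2 if include_detectors else 0
    return BasalTree(sources, config.I, n_detectors=n_det)


def build_network(config: ExperimentConfig, rng: np.random.Generator) -> Network:
    """Build all minicolumns for one run.

    Draw order is fixed for reproducibility: minicolumn 0's L5 tree, then
    its L2/3 tree (internal-representation mode), then minicolumn 1, ...
    """
    hierarchical = config.mode == "hierarchical"
    minicolumns = []
    for mc_id in range(config.n_mc):
        l5 = LearnerCell("L5", build_basal_tree(config, hierarchical, rng))
        if hierarchical:
            detectors = (DetectorCell("XXXXX"), DetectorCell("XXOXX"))
            minicolumns.append(Minicolumn(mc_id, l5, detectors=detectors))
        else:
            l23 = LearnerCell("L23", build_basal_tree(config, False, rng))
            minicolumns.append(Minicolumn(mc_id, l5, l23_learner=l23))
    return Network(config, minicolumns)
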