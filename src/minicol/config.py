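"""Experiment configuration: every free parameter of the simulations."""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Any

import yaml

VALID_MODES = ("hierarchical", "internal_rep")


@dataclass(frozen=True)
class ExperimentConfig:
    """All free parameters of a minicolumn learning experiment.

    Parameters
    ----------
    I : int
        Number of external inputs on the 1-D input line.
    n_mc : int
        Number of minicolumns (= number of classes in the readout).
    C : int
        Synaptic cluster size (synapses per basal cluster).
    G : int or None
        Active synapses required for a cluster to be excited.  ``None``
        means G = C ("all synapses active"), which is what the minicolumn
        experiments use.
    S_max : int
        Maximum basal synapses per learner cell; a tree holds
        ``floor(S_max / C)`` clusters.
    F : float
        Layer-2/3 sampling factor: each detector source occupies F slots in
        the cluster sampling space where each external input occupies 1.
        F = 0 means no L2/3-to-L5 connectivity.
    n_objects : int
        Objects placed per input pattern.
    mode : str
        ``"hierarchical"`` (two prewired object detectors per minicolumn) or
        ``"internal_rep"`` (one plastic L2/3 learner per minicolumn).
    n_patterns : int
        Patterns in the training/testing set.
    n_runs : int
        Independent repetitions to average.
    seed : int
        Master seed; every stream in a run derives from it.
    """

    I: int = 100
    n_mc: int = 10
    C: int = 4
    G: int | None = None
    S_max: int = 20_000
    F: float = 0.0
    n_objects: int = 5
    mode: str = "internal_rep"
    n_patterns: int = 100
    n_runs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        for name in ("I", "n_mc", "C", "S_max", "n_objects", "n_patterns", "n_runs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.F < 0:
            raise ValueError("F must be >= 0")
        if self.G is not None and not (0 < self.G <= self.C):
            raise ValueError("G must satisfy 0 < G <= C")

    @property
    def g_threshold(self) -> int:
        """Effective excitation threshold (defaults to the cluster size)."""
        return self.C if self.G is None else self.G

    @property
    def n_detectors(self) -> int:
        """Detector cells per minicolumn (2 in hierarchical mode)."""
        return 2 if self.mode == "hierarchical" else 0

    @property
    def n_clusters(self) -> int:
        return self.S_max // self.C

    def replace(self, **changes: Any) -> "ExperimentConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "ExperimentConfig":
        """Load a YAML mapping of config keys; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of config keys")
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        """Echo the resolved configuration to a YAML file."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
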