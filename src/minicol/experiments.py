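"""Experiment orchestration: seeded sweeps, run tables, and summaries.

Two experiments, mirroring the two minicolumn connectivity configurations:

* a *hierarchical* sweep over the L2/3-to-L5 connectivity factor F, in which
  prewired object detectors feed the L5 trees and classification accuracy
  is measured as a function of F (pattern sets are paired across F values at
  fixed run index so the sweep supports paired comparisons);
* an *internal-representation* sweep over the number of objects per
  pattern, in which each minicolumn's plastic L2/3 learner is trained in
  parallel with its L5 through cross-induction, and the headline metric is
  the rate of simultaneous correct classification in both layers.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .core import build_network
from .patterns import make_pattern_set
from .plasticity import DEFAULT_RULE, PlasticityRule, train
from .readout import evaluate

logger = logging.getLogger(__name__)

RUN_COLUMNS = [
    "mode", "C", "F", "n_objects", "run", "seed",
    "accuracy_l5", "accuracy_l23", "accuracy_simultaneous",
]
SUMMARY_STATS = ("mean", "std", "sem")


def seed_ladder(master_seed: int, *labels) -> np.random.Generator:
    """Derive an independent generator for one (purpose, cell, run) slot.

    The stream is seeded by a ``SeedSequence`` whose entropy is the master
    seed followed by the CRC-32 of each label's string form, so any run of
    any sweep cell is independently reproducible from the master seed and
    its labels alone.
    """
    entropy = [int(master_seed)] + [zlib.crc32(str(l).encode()) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def run_once(
    config: ExperimentConfig,
    run: int,
    rule: PlasticityRule = DEFAULT_RULE,
    pattern_labels: Optional[tuple] = None,
) -> dict:
    """One independent run: fresh trees, fresh patterns, one training
    epoch, then testing.

    ``pattern_labels`` overrides the seed labels of the pattern stream —
    the hierarchical F sweep passes labels that omit F, so all F cells of a
    run share one pattern set.
    """
    tree_rng = seed_ladder(config.seed, "trees", config.mode, config.C, config.F, run)
    if pattern_labels is None:
        pattern_labels = ("patterns", config.mode, config.C, config.F, run)
    pattern_rng = seed_ladder(config.seed, *pattern_labels)
    tie_rng = seed_ladder(config.seed, "ties", config.mode, config.C, config.F, run)

    network = build_network(config, tree_rng)
    assignment = make_pattern_set(config, pattern_rng)
    train(network, assignment, rule)
    _, acc = evaluate(network, assignment, tie_rng)
    return {
        "mode": config.mode,
        "C": config.C,
        "F": config.F,
        "n_objects": config.n_objects,
        "run": run,
        "seed": config.seed,
        "accuracy_l5": acc["accuracy_l5"],
        "accuracy_l23": acc.get("accuracy_l23", np.nan),
        "accuracy_simultaneous": acc.get("accuracy_simultaneous", np.nan),
    }


def summarize_runs(runs: pd.DataFrame, group_keys: Sequence[str]) -> pd.DataFrame:
    """Mean / sd / sem of each accuracy over runs, grouped by sweep cell."""
    acc_cols = [c for c in runs.columns if c.startswith("accuracy_")]
    grouped = runs.groupby(list(group_keys), sort=True)
    summary = grouped[acc_cols].agg(["mean", "std", "sem"])
    summary.columns = [f"{c}_{stat}" for c, stat in summary.columns]
    summary["n_runs"] = grouped.size()
    return summary.reset_index()


@dataclass
class SweepResult:
    """Per-run records and their per-cell summaries for one sweep."""

    runs: pd.DataFrame
    summary: pd.DataFrame
    config: ExperimentConfig

    def to_csv(self, runs_path: str | Path, summary_path: Optional[str | Path] = None) -> None:
        self.runs.to_csv(runs_path, index=False, columns=RUN_COLUMNS)
        if summary_path is not None:
            self.summary.to_csv(summary_path, index=False)


def _append_row(row: dict, out_path: Optional[Path]) -> None:
    # incremental CSV so long sweeps stay inspectable while running
    if out_path is None:
        return
    header = not out_path.exists()
    pd.DataFrame([row]).to_csv(out_path, mode="a", header=header, index=False,
                               columns=RUN_COLUMNS)


def run_hierarchical_experiment(
    config: ExperimentConfig,
    f_grid: Sequence[float] = (0, 1, 2, 5, 10, 20, 50, 100),
    n_runs: Optional[int] = None,
    out_path: Optional[str | Path] = None,
) -> SweepResult:
    """Sweep the L2/3 connectivity factor F in the hierarchical
    configuration (default 50 runs per cell, averaged).

    Run ``r`` of every F cell reuses the same pattern-set stream, so
    comparisons across F are paired.
    """
    config = config.replace(mode="hierarchical")
    n_runs = config.n_runs if n_runs is None else n_runs
    out_path = Path(out_path) if out_path is not None else None
    rows = []
    for F in f_grid:
        cell_config = config.replace(F=float(F))
        for run in range(n_runs):
            t0 = time.perf_counter()
            row = run_once(
                cell_config, run,
                pattern_labels=("patterns", "hierarchical", config.C, run),
            )
            rows.append(row)
            _append_row(row, out_path)
            logger.info(
                "hierarchical C=%d F=%g run=%d acc_l5=%.3f (%.2fs)",
                config.C, F, run, row["accuracy_l5"], time.perf_counter() - t0,
            )
    runs = pd.DataFrame(rows)
    return SweepResult(runs, summarize_runs(runs, ["mode", "C", "F"]), config)


def run_internal_rep_experiment(
    config: ExperimentConfig,
    objects_grid: Sequence[int] = tuple(range(1, 9)),
    n_runs: Optional[int] = None,
    out_path: Optional[str | Path] = None,
) -> SweepResult:
    """Sweep the number of objects per pattern in the
    internal-representation configuration (default 10 runs per cell).

    Every cell is validated for packing feasibility before any run starts.
    """
    config = config.replace(mode="internal_rep", F=0.0)
    n_runs = config.n_runs if n_runs is None else n_runs
    for n_obj in objects_grid:
        if n_obj * 5 + (n_obj - 1) > config.I:
            raise ValueError(f"{n_obj} objects cannot be packed on {config.I} inputs")
    out_path = Path(out_path) if out_path is not None else None
    rows = []
    for n_obj in objects_grid:
        cell_config = config.replace(n_objects=int(n_obj))
        for run in range(n_runs):
            t0 = time.perf_counter()
            row = run_once(cell_config, run)
            rows.append(row)
            _append_row(row, out_path)
            logger.info(
                "internal_rep C=%d n_objects=%d run=%d acc_l5=%.3f acc_l23=%.3f "
                "acc_sim=%.3f (%.2fs)",
                config.C, n_obj, run, row["accuracy_l5"], row["accuracy_l23"],
                row["accuracy_simultaneous"], time.perf_counter() - t0,
            )
    runs = pd.DataFrame(rows)
    return SweepResult(runs, summarize_runs(runs, ["mode", "C", "n_objects"]), config)
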