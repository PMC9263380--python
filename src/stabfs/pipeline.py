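"""End-to-end orchestration: grid evaluation -> exclusion screen -> decision."""

from __future__ import annotations

import logging

import numpy as np

from .config import RunConfig
from .decision import (DecisionTable, apply_exclusions, build_grid, select_best)
from .evaluate import CombinationResult, run_combination
from .io import FeatureTable

__all__ = ["evaluate_grid", "decide"]

log = logging.getLogger("stabfs")


def evaluate_grid(features: FeatureTable | np.ndarray, labels: np.ndarray,
                  cfg: RunConfig) -> list[CombinationResult]:
    """Run the bootstrap evaluation for every combination in the config's grid."""
    grid = build_grid([cfg.spec_with_overrides(s) for s in cfg.supervised],
                      [cfg.spec_with_overrides(u) for u in cfg.unsupervised])
    results: list[CombinationResult] = []
    for sup, unsup in grid:
        name = f"{sup.id}{unsup.id}"
        log.info("evaluating combination %s (%s + %s)", name, sup.name, unsup.name)
        try:
            res = run_combination(features, labels, sup, unsup, cfg.eval)
        except RuntimeError as exc:
            log.error("combination %s failed: %s", name, exc)
            raise
        log.info("%s: mean AUC %.3f, stability %s, mean runtime %.3fs",
                 name, res.mean_auc,
                 "degenerate" if res.stability is None
                 else f"{res.stability.value:.3f}",
                 res.mean_runtime)
        results.append(res)
    return results


def decide(features: FeatureTable | np.ndarray, labels: np.ndarray,
           cfg: RunConfig) -> tuple[DecisionTable, list[CombinationResult]]:
    """Evaluate the full grid and return the ranked decision table."""
    results = evaluate_grid(features, labels, cfg)
    apply_exclusions(results, auc_floor=cfg.auc_floor,
                     time_ceiling=cfg.time_ceiling)
    table = select_best(results)
    log.info("winner(s): %s", ", ".join(table.winners))
    return table, results
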