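"""The combination grid, exclusion screen and AUC x Stability decision graph.

Every supervised scorer is paired with every unsupervised scorer (with the
default pools: 4 x 6 = 24 combinations named S1U1 ... S4U6, supervised-major
order).  After the bootstrap evaluation, combinations whose mean AUC falls
below the floor (default 0.5, strict: exactly 0.5 is retained) or whose
slowest try exceeds the time ceiling (default 30 min, strict) are excluded,
as are combinations whose stability is degenerate.  The remaining rows are
ranked by the product mean AUC x stability; all rows within 1e-12 of the
maximum are reported as co-winners.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StabfsError
from .evaluate import CombinationResult
from .selectors import SelectorSpec

__all__ = [
    "CombinationGrid",
    "DecisionTable",
    "build_grid",
    "apply_exclusions",
    "decision_score",
    "select_best",
    "export_decision_graph",
    "read_decision_table",
    "plot_decision_graph",
]

#: rows within this distance of the maximal decision score are co-winners
TIE_TOLERANCE = 1e-12

AUC_FLOOR_DEFAULT = 0.5
TIME_CEILING_DEFAULT = 1800.0  # 30 minutes per try


@dataclass
class CombinationGrid:
    """Ordered list of (supervised, unsupervised) selector pairs."""

    combinations: list[tuple[SelectorSpec, SelectorSpec]] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return [f"{s.id}{u.id}" for s, u in self.combinations]

    def __len__(self) -> int:
        return len(self.combinations)

    def __iter__(self):
        return iter(self.combinations)


def build_grid(supervised: list[SelectorSpec],
               unsupervised: list[SelectorSpec]) -> CombinationGrid:
    """Full Cartesian product in supervised-major order."""
    if not supervised or not unsupervised:
        raise ConfigurationError("both selector pools must be non-empty")
    for pool, kind in ((supervised, "supervised"), (unsupervised, "unsupervised")):
        ids = [s.id for s in pool]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate ids in the {kind} pool: {ids}")
    return CombinationGrid(combinations=list(product(supervised, unsupervised)))


def decision_score(mean_auc: float, stab: float) -> float:
    """The product criterion AUC x Stability."""
    return float(mean_auc) * float(stab)


def apply_exclusions(results: list[CombinationResult],
                     auc_floor: float = AUC_FLOOR_DEFAULT,
                     time_ceiling: float = TIME_CEILING_DEFAULT,
                     ) -> list[CombinationResult]:
    """Flag excluded combinations in place (strict inequalities) and return them."""
    for res in results:
        reasons = []
        if res.failed or res.n_failed * 2 > len(res.tries) + res.n_failed:
            reasons.append("majority of tries failed")
        if res.mean_auc < auc_floor:
            reasons.append(f"AUC below floor ({res.mean_auc:.3f} < {auc_floor})")
        if res.max_runtime > time_ceiling:
            reasons.append(f"time budget exceeded ({res.max_runtime:.1f}s "
                           f"> {time_ceiling:.0f}s)")
        if res.stability is None:
            reasons.append("degenerate stability: "
                           + (res.stability_degenerate_reason or "undefined"))
        res.excluded = bool(reasons)
        res.exclusion_reason = "; ".join(reasons) if reasons else None
    return results


@dataclass
class DecisionTable:
    """Ranked per-combination summary plus the winning combination name(s)."""

    rows: pd.DataFrame
    winners: list[str]


def select_best(results: list[CombinationResult]) -> DecisionTable:
    """Rank non-excluded combinations by decision score and pick the winner(s).

    Ties within :data:`TIE_TOLERANCE` of the maximum are reported as
    co-winners; ordering ties break lexicographically on the combination name.
    """
    records = []
    for res in results:
        stab = res.stability_value
        score = (decision_score(res.mean_auc, stab)
                 if (stab is not None and not res.excluded) else np.nan)
        records.append({
            "name": res.name,
            "mean_auc": res.mean_auc,
            "stability": np.nan if stab is None else stab,
            "decision_score": score,
            "mean_runtime": res.mean_runtime,
            "max_runtime": res.max_runtime,
            "excluded": res.excluded,
            "reason": res.exclusion_reason or "",
        })
    df = pd.DataFrame.from_records(records)
    kept = df[~df["excluded"]]
    if kept.empty:
        raise StabfsError(
            "all combinations were excluded; relax the exclusion thresholds "
            "or revisit the evaluation config"
        )
    df = df.sort_values(["excluded", "decision_score", "name"],
                        ascending=[True, False, True],
                        na_position="last").reset_index(drop=True)
    best = kept["decision_score"].max()
    winners = sorted(kept.loc[kept["decision_score"] >= best - TIE_TOLERANCE,
                              "name"].tolist())
    return DecisionTable(rows=df, winners=winners)


def export_decision_graph(table: DecisionTable, path: str | os.PathLike,
                          plot_path: str | os.PathLike | None = None) -> None:
    """Write the decision table as TSV (and optionally the scatter rendering)."""
    if table.rows.empty:
        raise StabfsError("cannot export an empty decision table")
    table.rows.to_csv(path, sep="\t", index=False)
    if plot_path is not None:
        plot_decision_graph(table, plot_path)


def read_decision_table(path: str | os.PathLike) -> DecisionTable:
    """Re-read an exported decision table (round-trip of the ranking)."""
    df = pd.read_csv(path, sep="\t")
    df["reason"] = df["reason"].fillna("")
    kept = df[~df["excluded"]]
    best = kept["decision_score"].max()
    winners = sorted(kept.loc[kept["decision_score"] >= best - TIE_TOLERANCE,
                              "name"].tolist())
    return DecisionTable(rows=df, winners=winners)


def plot_decision_graph(table: DecisionTable,
                        path: str | os.PathLike) -> None:
    """Stability-vs-AUC scatter with iso-product contours, winners highlighted."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.rows
    fig, ax = plt.subplots(figsize=(6, 5))
    kept = df[~df["excluded"]]
    drop = df[df["excluded"]]
    ax.scatter(kept["stability"], kept["mean_auc"], c="tab:blue", label="evaluated")
    if not drop.empty:
        ax.scatter(drop["stability"], drop["mean_auc"], c="lightgray",
                   marker="x", label="excluded")
    win = kept[kept["name"].isin(table.winners)]
    ax.scatter(win["stability"], win["mean_auc"], facecolors="none",
               edgecolors="tab:red", s=160, linewidths=2, label="winner")
    for _, row in kept.iterrows():
        ax.annotate(row["name"], (row["stability"], row["mean_auc"]),
                    fontsize=7, xytext=(3, 3), textcoords="offset points")

    s_lo = float(np.nanmin(df["stability"])) if np.isfinite(df["stability"]).any() else 0.0
    s = np.linspace(max(0.01, min(0.01, s_lo)), 1.0, 200)
    for level in np.linspace(0.2, 0.9, 5):
        ax.plot(s, np.clip(level / s, 0, 1.05), lw=0.5, ls="--", c="gray")
    ax.set_xlabel("Stability")
    ax.set_ylabel("Mean AUC")
    ax.set_title("Decision graph (iso AUC x Stability contours)")
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
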