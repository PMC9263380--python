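"""The selection matrix Z and the frequency-based stability estimator.

Across M repeated feature-selection tries, row i of the binary matrix Z marks
which of the d original features try i selected.  Stability is one minus the
ratio of the average unbiased per-feature selection-frequency variance to the
variance of a Bernoulli variable at the observed overall selection rate:

    Stability(Z) = 1 - [ (1/d) * sum_f (M/(M-1)) * p_f * (1 - p_f) ]
                       / [ qbar * (1 - qbar) ]

with p_f the column mean of Z and qbar its grand mean.  The value is 1 exactly
when all tries select the same set and has expectation ~0 under random
fixed-size selection.  Although often described as ranging from 0 to 1, the
estimator as defined can be negative for anti-correlated selections (e.g.
Z = [[1,0],[0,1]] gives -1); negative values are returned as-is.

The estimator is undefined when qbar is 0 or 1 (no feature ever selected, or
every feature always selected); that raises :class:`DegenerateStabilityError`
rather than silently returning a boundary value.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateStabilityError, ParameterError

__all__ = ["SelectionMatrix", "StabilityValue", "row_from_indices", "stability"]


def row_from_indices(selected: Iterable[int], d: int) -> np.ndarray:
    """Length-d 0/1 row with ones exactly at the selected feature indices."""
    row = np.zeros(d, dtype=np.int8)
    idx = np.asarray(sorted(set(int(i) for i in selected)), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= d):
        raise ParameterError(f"selected indices must lie in [0, {d}), got {idx}")
    row[idx] = 1
    return row


@dataclass
class SelectionMatrix:
    """M tries x d features binary selection matrix."""

    Z: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z)
        if self.Z.ndim != 2:
            raise ParameterError("Z must be a 2-D matrix")
        if not np.isin(self.Z, (0, 1)).all():
            raise ParameterError("Z entries must be 0 or 1")
        self.Z = self.Z.astype(np.int8)
        if self.feature_names is not None and len(self.feature_names) != self.d:
            raise ParameterError("feature_names length must equal d")

    @property
    def M(self) -> int:
        return self.Z.shape[0]

    @property
    def d(self) -> int:
        return self.Z.shape[1]

    @classmethod
    def from_index_sets(cls, sets: Sequence[Iterable[int]], d: int,
                        feature_names: list[str] | None = None) -> "SelectionMatrix":
        rows = [row_from_indices(s, d) for s in sets]
        return cls(Z=np.vstack(rows), feature_names=feature_names)

    def to_csv(self, path: str | os.PathLike) -> None:
        names = self.feature_names or [f"feat_{j + 1:03d}" for j in range(self.d)]
        pd.DataFrame(self.Z, columns=names).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "SelectionMatrix":
        df = pd.read_csv(path)
        return cls(Z=df.to_numpy(), feature_names=[str(c) for c in df.columns])


@dataclass(frozen=True)
class StabilityValue:
    """A stability estimate with its diagnostics."""

    value: float
    M: int
    d: int
    mean_selected_fraction: float


def stability(Z: SelectionMatrix | np.ndarray) -> StabilityValue:
    """Frequency-based stability of a selection matrix (see module docstring)."""
    if not isinstance(Z, SelectionMatrix):
        Z = SelectionMatrix(Z=np.asarray(Z))
    M, d = Z.M, Z.d
    if M < 2:
        raise ParameterError(f"stability needs M >= 2 tries, got {M}")
    A = Z.Z.astype(float)
    p = A.mean(axis=0)  # per-feature selection frequency
    qbar = float(p.mean())  # overall selection rate = kbar/d
    if qbar <= 0.0 or qbar >= 1.0:
        raise DegenerateStabilityError(
            "stability undefined: overall selection rate is "
            f"{qbar:g} (no feature ever selected)" if qbar <= 0.0 else
            "stability undefined: overall selection rate is 1 "
            "(every feature selected in every try)"
        )
    sample_var = (M / (M - 1)) * p * (1.0 - p)  # unbiased column variance
    value = 1.0 - sample_var.mean() / (qbar * (1.0 - qbar))
    return StabilityValue(value=float(value), M=M, d=d,
                          mean_selected_fraction=qbar)
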