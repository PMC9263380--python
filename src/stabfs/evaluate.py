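"""Bootstrap evaluation of one supervised x unsupervised selector combination.

Each of M tries draws a stratified 70/30 train/test partition, runs the
supervised scorer on the training data (keeping the top k1 features), runs the
unsupervised scorer on the training table restricted to those k1 columns
(keeping k2), fits a ridge regression on the +/-1-coded labels over the
selected features, and records the test-set AUC of its continuous decision
values.  The M selected sets form the selection matrix Z over the ORIGINAL
feature space, from which the frequency-based stability is computed.

Design notes:

* "bootstrap sampling" is realised as repeated stratified subsampling WITHOUT
  replacement: each try is a disjoint train/test partition, so no subject can
  appear on both sides of the split;
* standardisation uses training-set statistics only, applied to the test set
  (no leakage);
* split seeds depend on (base_seed, try_index) only, so every combination
  evaluated under the same config sees identical splits (paired comparison);
  scorer seeds additionally mix in the combination name.
"""

from __future__ import annotations

import time
import warnings
import zlib
from dataclasses import dataclass
from typing import Any

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.metrics import roc_auc_score

from .errors import ConfigurationError, DegenerateStabilityError, SplitError
from .io import FeatureTable
from .selectors import SelectorSpec
from .stability import SelectionMatrix, StabilityValue, stability

__all__ = [
    "EvalConfig",
    "TryResult",
    "CombinationResult",
    "bootstrap_split",
    "select_features_one_try",
    "ridge_auc",
    "run_combination",
]


@dataclass(frozen=True)
class EvalConfig:
    """Parameters of the bootstrap evaluation workflow."""

    M: int = 100
    train_fraction: float = 0.70
    k1: int = 20
    k2: int = 10
    ridge_alpha: float = 1.0
    stratified: bool = True
    base_seed: int = 0
    time_budget: float = 1800.0  # seconds per try; breaches recorded, not raised

    def validate(self, d: int | None = None) -> None:
        if self.M < 2:
            raise ConfigurationError("M must be >= 2")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if not 1 <= self.k2 <= self.k1:
            raise ConfigurationError("need 1 <= k2 <= k1")
        if d is not None and self.k1 > d:
            raise ConfigurationError(f"k1 = {self.k1} exceeds d = {d}")
        if self.ridge_alpha < 0:
            raise ConfigurationError("ridge_alpha must be >= 0")


@dataclass
class TryResult:
    try_index: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    selected: np.ndarray
    auc: float
    runtime: float


@dataclass
class CombinationResult:
    """Everything measured for one selector combination over M tries."""

    supervised: SelectorSpec
    unsupervised: SelectorSpec
    tries: list[TryResult]
    Z: SelectionMatrix
    mean_auc: float
    stability: StabilityValue | None
    stability_degenerate_reason: str | None
    mean_runtime: float
    max_runtime: float
    n_failed: int = 0
    excluded: bool = False
    exclusion_reason: str | None = None
    failed: bool = False

    @property
    def name(self) -> str:
        return f"{self.supervised.id}{self.unsupervised.id}"

    @property
    def stability_value(self) -> float | None:
        return None if self.stability is None else self.stability.value

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "supervised": {"id": self.supervised.id, "name": self.supervised.name},
            "unsupervised": {"id": self.unsupervised.id,
                             "name": self.unsupervised.name},
            "mean_auc": self.mean_auc,
            "stability": self.stability_value,
            "stability_degenerate_reason": self.stability_degenerate_reason,
            "mean_runtime": self.mean_runtime,
            "max_runtime": self.max_runtime,
            "n_failed": self.n_failed,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
            "tries": [
                {"try_index": t.try_index, "auc": t.auc, "runtime": t.runtime,
                 "selected": t.selected.tolist()}
                for t in self.tries
            ],
            "Z": self.Z.Z.tolist(),
        }


def _split_seed(base_seed: int, try_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(base_seed),
                                                         int(try_index)]))


def _scorer_seed(base_seed: int, try_index: int, combination: str) -> int:
    tag = zlib.crc32(combination.encode())
    ss = np.random.SeedSequence([int(base_seed), int(try_index), int(tag)])
    return int(ss.generate_state(1)[0] % (2**31))


def bootstrap_split(n: int, labels: np.ndarray, config: EvalConfig,
                    try_index: int) -> tuple[np.ndarray, np.ndarray]:
    """One stratified train/test partition without replacement.

    Per class, round(train_fraction * n_c) subjects go to training and the
    remainder to test; both classes are guaranteed on both sides.
    """
    labels = np.asarray(labels).ravel()
    if n < 4:
        raise SplitError("need at least 4 subjects to split")
    if labels.shape[0] != n:
        raise SplitError("labels length must equal n")
    rng = _split_seed(config.base_seed, try_index)

    if not config.stratified:
        perm = rng.permutation(n)
        n_train = int(round(config.train_fraction * n))
        train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        for part, side in ((train, "training"), (test, "test")):
            if np.unique(labels[part]).shape[0] < 2:
                raise SplitError(f"unstratified split left one class out of "
                                 f"the {side} set; use stratified=True")
        return train, test

    train_parts, test_parts = [], []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        n_c = members.shape[0]
        n_train_c = int(round(config.train_fraction * n_c))
        if n_train_c < 1 or n_c - n_train_c < 1:
            raise SplitError(
                f"class {c} has {n_c} subjects; cannot place it on both sides "
                f"of a {config.train_fraction:.0%} split"
            )
        perm = rng.permutation(members)
        train_parts.append(perm[:n_train_c])
        test_parts.append(perm[n_train_c:])
    return (np.sort(np.concatenate(train_parts)),
            np.sort(np.concatenate(test_parts)))


def select_features_one_try(X_train: np.ndarray, y_train: np.ndarray,
                            supervised: SelectorSpec,
                            unsupervised: SelectorSpec,
                            k1: int, k2: int,
                            seed: int | None = None) -> np.ndarray:
    """Sequential supervised (top k1) then unsupervised (top k2) selection.

    The unsupervised scorer sees only the k1 surviving columns; the returned
    indices refer to the original feature space.
    """
    d = X_train.shape[1]
    if not 1 <= k2 <= k1 <= d:
        raise ConfigurationError(f"need 1 <= k2 <= k1 <= d, got k1={k1}, "
                                 f"k2={k2}, d={d}")
    sup = supervised.build(k=k1, seed=seed)
    sup.fit(X_train, y_train)
    idx1 = sup.top_k_indices()

    unsup = unsupervised.build(k=k2, seed=seed)
    unsup.fit(X_train[:, idx1])
    idx2 = unsup.top_k_indices()
    return np.sort(idx1[idx2])


def ridge_auc(X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray,
              y_test: np.ndarray, ridge_alpha: float = 1.0) -> float:
    """Test-set AUC of a ridge regression on +/-1-coded labels.

    Features are standardised by training-set mean/sd (test transformed with
    the training parameters); training-constant features are dropped.  The
    AUC is the Mann-Whitney statistic of the continuous decision values, with
    midrank handling of ties.
    """
    y_train = np.asarray(y_train).ravel()
    y_test = np.asarray(y_test).ravel()
    if np.unique(y_train).shape[0] < 2 or np.unique(y_test).shape[0] < 2:
        raise SplitError("both classes required in the training and test sets")

    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} training-constant "
                      "feature(s) from the ridge model", RuntimeWarning)
    if not keep.any():
        return 0.5  # no usable feature: constant decision values
    Xtr = (X_train[:, keep] - mu[keep]) / sd[keep]
    Xte = (X_test[:, keep] - mu[keep]) / sd[keep]

    model = Ridge(alpha=ridge_alpha)
    model.fit(Xtr, 2.0 * y_train - 1.0)
    decision = model.predict(Xte)
    return float(roc_auc_score(y_test, decision))


def run_combination(features: FeatureTable | np.ndarray, labels: np.ndarray,
                    supervised: SelectorSpec, unsupervised: SelectorSpec,
                    config: EvalConfig) -> CombinationResult:
    """Evaluate one combination: M tries, Z, mean AUC, stability, runtimes."""
    X = features.values if isinstance(features, FeatureTable) else np.asarray(features, dtype=float)
    feature_names = (features.feature_names
                     if isinstance(features, FeatureTable) else None)
    labels = np.asarray(labels).ravel()
    n, d = X.shape
    config.validate(d=d)
    name = f"{supervised.id}{unsupervised.id}"

    tries: list[TryResult] = []
    rows: list[np.ndarray] = []
    errors: list[str] = []
    for i in range(config.M):
        t0 = time.perf_counter()
        try:
            train, test = bootstrap_split(n, labels, config, i)
            seed = _scorer_seed(config.base_seed, i, name)
            selected = select_features_one_try(
                X[train], labels[train], supervised, unsupervised,
                config.k1, config.k2, seed=seed,
            )
            auc = ridge_auc(X[train][:, selected], labels[train],
                            X[test][:, selected], labels[test],
                            config.ridge_alpha)
        except Exception as exc:  # noqa: BLE001 - per-try isolation
            errors.append(f"{name} try {i}: {type(exc).__name__}: {exc}")
            continue
        runtime = time.perf_counter() - t0
        tries.append(TryResult(try_index=i, train_idx=train, test_idx=test,
                               selected=selected, auc=auc, runtime=runtime))
        rows.append(selected)

    n_failed = config.M - len(tries)
    if n_failed > config.M // 2:
        raise RuntimeError(
            f"combination {name}: {n_failed}/{config.M} tries failed; "
            "first errors: " + "; ".join(errors[:3])
        )
    if n_failed:
        warnings.warn(f"combination {name}: {n_failed} of {config.M} tries "
                      "failed; first error: " + errors[0], RuntimeWarning)

    Z = SelectionMatrix.from_index_sets(rows, d, feature_names=feature_names)
    stab: StabilityValue | None
    degenerate_reason: str | None = None
    try:
        stab = stability(Z)
    except DegenerateStabilityError as exc:
        stab = None
        degenerate_reason = str(exc)

    aucs = np.array([t.auc for t in tries])
    runtimes = np.array([t.runtime for t in tries])
    result = CombinationResult(
        supervised=supervised, unsupervised=unsupervised, tries=tries, Z=Z,
        mean_auc=float(aucs.mean()), stability=stab,
        stability_degenerate_reason=degenerate_reason,
        mean_runtime=float(runtimes.mean()), max_runtime=float(runtimes.max()),
        n_failed=n_failed,
    )
    if result.max_runtime > config.time_budget:
        warnings.warn(f"combination {name}: slowest try took "
                      f"{result.max_runtime:.1f}s (budget "
                      f"{config.time_budget:.0f}s)", RuntimeWarning)
    return result
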