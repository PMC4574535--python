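"""Accuracy evaluation of somatic call sets against ground truth.

A truth set partitions interrogated sites into three pairwise-disjoint
classes: known somatic mutations, confirmed reference (non-somatic) sites,
and ambiguous sites excluded from scoring. Calls are compared by exact
candidate key; ambiguous calls never enter any count. Accuracy is summarized
by sensitivity (recall), precision (positive predictive value), their
harmonic mean F1, and the negative predictive value. Undefined ratios (e.g.
precision of an empty call set) are reported as missing, never coerced to 0.

The module also provides the repeated twofold cross-validation protocol used
for benchmarking: the rows are split 50/50 at random, a model is trained on
each half and evaluated on the other, and metrics are averaged over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .boosting import PASS_THRESHOLD, StochasticAdaBoostClassifier, TrainingConfig

__all__ = [
    "TruthSet",
    "EvaluationResult",
    "f1_score",
    "evaluate",
    "sensitivity_only",
    "cross_validate",
    "CrossValidationResult",
    "cutoff_sweep",
]


@dataclass
class TruthSet:
    """Disjoint partition of site keys into somatic / reference / ambiguous."""

    somatic: set
    reference: set = field(default_factory=set)
    ambiguous: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.somatic = set(self.somatic)
        self.reference = set(self.reference)
        self.ambiguous = set(self.ambiguous)
        if (self.somatic & self.reference or self.somatic & self.ambiguous
                or self.reference & self.ambiguous):
            raise ValueError("truth partitions must be pairwise disjoint")

    def __len__(self) -> int:
        return len(self.somatic) + len(self.reference) + len(self.ambiguous)


def f1_score(sensitivity: float, precision: float) -> Optional[float]:
    """Harmonic mean of sensitivity and precision; None when both are zero."""
    for name, v in (("sensitivity", sensitivity), ("precision", precision)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if sensitivity == 0.0 and precision == 0.0:
        return None
    return 2.0 * sensitivity * precision / (sensitivity + precision)


@dataclass
class EvaluationResult:
    """Confusion counts and derived accuracy metrics for one call set."""

    tp: int
    fp: int
    fn: int
    tn: int
    call_set_size: int

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def f1(self) -> Optional[float]:
        s, p = self.sensitivity, self.precision
        if s is None or p is None:
            return None
        return f1_score(s, p)

    @property
    def npv(self) -> Optional[float]:
        d = self.tn + self.fn
        return self.tn / d if d else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "call_set_size": self.call_set_size,
            "sensitivity": self.sensitivity, "precision": self.precision,
            "f1": self.f1, "npv": self.npv,
        }


def evaluate(calls: Iterable, truth: TruthSet) -> EvaluationResult:
    """Score a call set against a truth partition.

    Calls at ambiguous sites — and at sites outside the truth partition
    entirely (outside the interrogated region) — are ignored.
    """
    calls = set(calls)
    tp = len(calls & truth.somatic)
    fp = len(calls & truth.reference)
    fn = len(truth.somatic - calls)
    tn = len(truth.reference - calls)
    return EvaluationResult(tp=tp, fp=fp, fn=fn, tn=tn, call_set_size=len(calls))


def sensitivity_only(calls: Iterable, validated: Iterable) -> float:
    """Recall against a published list of validated mutations.

    Used for real tumor-normal pairs where confirmed true negatives are not
    available, so precision cannot be computed.
    """
    validated = set(validated)
    if not validated:
        raise ValueError("validated mutation list is empty")
    return len(set(calls) & validated) / len(validated)


def _counts_from_predictions(
    P: np.ndarray, labels: np.ndarray, cutoff: float
) -> EvaluationResult:
    called = P >= cutoff
    pos = labels.astype(bool)
    tp = int((called & pos).sum())
    fp = int((called & ~pos).sum())
    fn = int((~called & pos).sum())
    tn = int((~called & ~pos).sum())
    return EvaluationResult(tp, fp, fn, tn, call_set_size=int(called.sum()))


@dataclass
class CrossValidationResult:
    """Per-repeat and aggregate metrics from repeated twofold CV."""

    repeats: pd.DataFrame          # one row per (repeat, direction)
    probabilities: list            # per (repeat, direction): (P, labels) arrays

    @property
    def mean_f1(self) -> float:
        return float(self.repeats["f1"].mean())

    @property
    def std_f1(self) -> float:
        return float(self.repeats["f1"].std(ddof=1))

    def summary(self) -> dict:
        metrics = ["sensitivity", "precision", "f1", "npv"]
        out = {}
        for m in metrics:
            out[f"mean_{m}"] = float(self.repeats[m].mean())
            out[f"std_{m}"] = float(self.repeats[m].std(ddof=1))
        return out


def cross_validate(
    features: pd.DataFrame,
    labels: Sequence[int],
    config: Optional[TrainingConfig] = None,
    n_repeats: int = 10,
    seed: int = 0,
    pass_threshold: float = PASS_THRESHOLD,
    max_redraws: int = 100,
) -> CrossValidationResult:
    """Repeated twofold cross-validation of the boosted classifier.

    Each repeat splits the rows 50/50 with the seeded RNG, trains on one half
    and predicts the other, in both directions. A split leaving either half
    single-class is redrawn. Metrics treat a prediction of P >= pass_threshold
    as a call. Deterministic given the seed.
    """
    if config is None:
        config = TrainingConfig()
    labels = np.asarray(labels)
    n = len(features)
    if n < 4:
        raise ValueError("too few rows for a twofold split")
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)

    rows = []
    probabilities = []
    for rep in range(n_repeats):
        for _ in range(max_redraws):
            perm = rng.permutation(n)
            half = n // 2
            a_idx, b_idx = perm[:half], perm[half:]
            if (len(np.unique(labels[a_idx])) == 2
                    and len(np.unique(labels[b_idx])) == 2):
                break
        else:
            raise RuntimeError("could not draw a split with both classes in "
                               "both halves")
        for direction, (tr, te) in enumerate([(a_idx, b_idx), (b_idx, a_idx)]):
            model = StochasticAdaBoostClassifier(
                n_iterations=config.n_iterations,
                max_depth=config.max_depth,
                subsample_fraction=config.subsample_fraction,
                learning_rate=config.learning_rate,
                random_state=int(rng.integers(2**31)),
            )
            model.fit(features.iloc[tr], labels[tr])
            P = model.somatic_probability(features.iloc[te])
            res = _counts_from_predictions(P, labels[te], pass_threshold)
            rows.append({"repeat": rep, "direction": direction, **res.as_dict()})
            probabilities.append((P, labels[te]))

    return CrossValidationResult(pd.DataFrame(rows), probabilities)


def cutoff_sweep(
    P_values: Sequence[float],
    labels: Sequence[int],
    cutoffs: Sequence[float],
) -> pd.DataFrame:
    """Sensitivity/precision/F1 at each probability cutoff.

    A cutoff of 0 calls every candidate; sensitivity is non-increasing in the
    cutoff by construction.
    """
    P = np.asarray(P_values, dtype=float)
    if ((P < 0) | (P > 1)).any():
        raise ValueError("P values outside [0, 1]")
    labels = np.asarray(labels)
    rows = []
    for cutoff in cutoffs:
        res = _counts_from_predictions(P, labels, cutoff)
        rows.append({
            "cutoff": cutoff,
            "calls": res.call_set_size,
            "sensitivity": res.sensitivity,
            "precision": res.precision,
            "f1": res.f1,
        })
    return pd.DataFrame(rows)
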