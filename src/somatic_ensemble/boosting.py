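"""Stochastic adaptive boosting over depth-limited decision trees.

The classifier that turns a candidate's feature vector into a probability P
of being a true somatic mutation is a natively implemented discrete AdaBoost
ensemble. At each iteration a small CART-style tree (weighted Gini split
criterion, exhaustive threshold search over midpoints of sorted unique
feature values) is fitted to a random subsample of the training rows under
the current example weights; the weighted training error eps_m of that tree
on the full set gives its stage weight

    alpha_m = learning_rate * 0.5 * ln((1 - eps_m) / eps_m),

examples are reweighted by exp(-alpha_m * y * h_m(x)) and renormalized. The
ensemble margin F(x) = sum_m alpha_m * h_m(x) is mapped to a probability by
the logistic calibration P = 1 / (1 + exp(-2 F(x))), which is the population
minimizer correspondence for the exponential loss.

Candidates are then tiered by P: PASS (P >= 0.7), REJECT (P <= 0.1), and
LowQual in between; thresholds are configurable.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import MISSING

__all__ = [
    "TrainingConfig",
    "StochasticAdaBoostClassifier",
    "ClassifiedCall",
    "stage_weight_from_error",
    "assign_tier",
    "tier_calls",
    "feature_importance",
    "export_tree",
    "parse_tree_text",
    "save_model",
    "load_model",
    "PASS_THRESHOLD",
    "REJECT_THRESHOLD",
]

PASS_THRESHOLD = 0.7
REJECT_THRESHOLD = 0.1

_EPS_FLOOR = 1e-10


@dataclass
class TrainingConfig:
    """Hyperparameters of the boosting learner.

    Defaults follow the conventional stochastic-boosting setup: 500 rounds of
    depth-3 trees fitted to 50% subsamples with unit learning rate.
    """

    n_iterations: int = 500
    max_depth: int = 3
    subsample_fraction: float = 0.5
    learning_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if self.max_depth < 1:
            raise ValueError("max_depth must be positive")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in (0, 1]")


@dataclass
class ClassifiedCall:
    """A candidate with its somatic-truth probability and confidence tier."""

    candidate: object
    P: float
    tier: str


def stage_weight_from_error(eps: float, learning_rate: float = 1.0) -> float:
    """AdaBoost stage weight 0.5*ln((1-eps)/eps), scaled by the learning rate.

    eps is clamped to [1e-10, 0.5 - 1e-10]: a perfect tree gets a large but
    finite weight, and a worse-than-chance subsample tree gets ~0 weight
    instead of halting training.
    """
    eps = min(max(eps, _EPS_FLOOR), 0.5 - _EPS_FLOOR)
    return learning_rate * 0.5 * math.log((1.0 - eps) / eps)


def assign_tier(
    P: float,
    pass_threshold: float = PASS_THRESHOLD,
    reject_threshold: float = REJECT_THRESHOLD,
) -> str:
    """Confidence tier for a probability: PASS / LowQual / REJECT."""
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"P={P} outside [0, 1]")
    if P >= pass_threshold:
        return "PASS"
    if P <= reject_threshold:
        return "REJECT"
    return "LowQual"


def tier_calls(
    P: np.ndarray,
    pass_threshold: float = PASS_THRESHOLD,
    reject_threshold: float = REJECT_THRESHOLD,
) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if ((P < 0) | (P > 1)).any():
        raise ValueError("probabilities outside [0, 1]")
    tiers = np.full(P.shape, "LowQual", dtype=object)
    tiers[P >= pass_threshold] = "PASS"
    tiers[P <= reject_threshold] = "REJECT"
    return tiers


# ---------------------------------------------------------------------------
# weighted CART trees


def _leaf_value(y: np.ndarray, w: np.ndarray) -> int:
    # weighted majority vote; exact tie breaks toward +1 for determinism
    return 1 if w[y > 0].sum() >= w[y < 0].sum() else -1


def _best_split(X: np.ndarray, y01: np.ndarray, w: np.ndarray):
    """Exhaustive weighted-Gini split search.

    Returns (feature, threshold, gain) or None. Candidate thresholds are
    midpoints between consecutive distinct sorted values; ties in gain break
    toward the lowest feature index, then the lowest threshold.
    """
    W = w.sum()
    P = (w * y01).sum()
    if W <= 0 or P <= 0 or P >= W:
        return None
    parent = 2.0 * P * (W - P) / W
    best = None  # (neg_gain tolerance handled by strict comparison order)
    best_score = parent
    for j in range(X.shape[1]):
        xj = X[:, j]
        order = np.argsort(xj, kind="stable")
        xs = xj[order]
        ws = w[order]
        ps = ws * y01[order]
        cw = np.cumsum(ws)[:-1]
        cp = np.cumsum(ps)[:-1]
        valid = xs[:-1] < xs[1:]
        if not valid.any():
            continue
        wl, pl = cw, cp
        wr, pr = W - cw, P - cp
        with np.errstate(divide="ignore", invalid="ignore"):
            score = 2.0 * pl * (wl - pl) / wl + 2.0 * pr * (wr - pr) / wr
        score = np.where(valid & (wl > 0) & (wr > 0), score, np.inf)
        i = int(np.argmin(score))
        if score[i] < best_score - 1e-15:
            best_score = float(score[i])
            best = (j, float((xs[i] + xs[i + 1]) / 2.0), parent - best_score)
    return best


def _build_tree(X, y, y01, w, depth: int):
    value = _leaf_value(y, w)
    if depth == 0 or len(y) < 2:
        return {"leaf": value}
    split = _best_split(X, y01, w)
    if split is None or split[2] <= 0:
        return {"leaf": value}
    j, threshold, gain = split
    mask = X[:, j] < threshold
    return {
        "feature": j,
        "threshold": threshold,
        "gain": gain,
        "left": _build_tree(X[mask], y[mask], y01[mask], w[mask], depth - 1),
        "right": _build_tree(X[~mask], y[~mask], y01[~mask], w[~mask], depth - 1),
    }


def _apply_tree(node, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0], dtype=float)
    stack = [(node, np.arange(X.shape[0]))]
    while stack:
        nd, idx = stack.pop()
        if "leaf" in nd:
            out[idx] = nd["leaf"]
            continue
        mask = X[idx, nd["feature"]] < nd["threshold"]
        stack.append((nd["left"], idx[mask]))
        stack.append((nd["right"], idx[~mask]))
    return out


def _tree_leaf_count(node) -> int:
    if "leaf" in node:
        return 1
    return _tree_leaf_count(node["left"]) + _tree_leaf_count(node["right"])


# ---------------------------------------------------------------------------
# the estimator


class StochasticAdaBoostClassifier(BaseEstimator, ClassifierMixin):
    """Discrete AdaBoost with stochastic subsampling over shallow CART trees.

    Parameters
    ----------
    n_iterations : int, default=500
        Number of boosting rounds (trees).
    max_depth : int, default=3
        Depth limit of each tree.
    subsample_fraction : float, default=0.5
        Fraction of rows drawn (without replacement) to fit each tree; the
        weighted error and the reweighting always use the full training set.
    learning_rate : float, default=1.0
        Shrinkage applied to every stage weight.
    random_state : int or None, default=None
        Seed for the subsampling RNG; fitting is deterministic given it.

    Attributes
    ----------
    trees_ : list of nested-dict tree nodes
    stage_weights_ : ndarray of per-tree weights alpha_m
    stage_errors_ : ndarray of weighted errors eps_m
    feature_names_in_ : ndarray of column names (DataFrame input only)
    feature_importances_ : stage-weighted Gini importance, normalized to 1
    classes_ : ndarray of the two class labels (negative first)
    """

    def __init__(
        self,
        n_iterations: int = 500,
        max_depth: int = 3,
        subsample_fraction: float = 0.5,
        learning_rate: float = 1.0,
        random_state: Optional[int] = None,
    ):
        self.n_iterations = n_iterations
        self.max_depth = max_depth
        self.subsample_fraction = subsample_fraction
        self.learning_rate = learning_rate
        self.random_state = random_state

    @classmethod
    def from_config(cls, config: TrainingConfig) -> "StochasticAdaBoostClassifier":
        return cls(
            n_iterations=config.n_iterations,
            max_depth=config.max_depth,
            subsample_fraction=config.subsample_fraction,
            learning_rate=config.learning_rate,
            random_state=config.seed,
        )

    # -- input handling ----------------------------------------------------

    def _coerce_X(self, X, fitting: bool) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if fitting:
                self.feature_names_in_ = np.asarray(X.columns, dtype=object)
                return X.to_numpy(dtype=float)
            names = getattr(self, "feature_names_in_", None)
            if names is not None:
                missing = [n for n in names if n not in X.columns]
                if missing:
                    warnings.warn(
                        f"features absent at prediction time, using sentinel: "
                        f"{missing}"
                    )
                X = X.reindex(columns=list(names), fill_value=MISSING)
            return X.to_numpy(dtype=float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        return arr

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        TrainingConfig(
            n_iterations=self.n_iterations,
            max_depth=self.max_depth,
            subsample_fraction=self.subsample_fraction,
            learning_rate=self.learning_rate,
            seed=self.random_state or 0,
        )  # reuse its range validation
        Xa = self._coerce_X(X, fitting=True)
        y = np.asarray(y)
        if Xa.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        if Xa.shape[0] < 2:
            raise ValueError("need at least two training rows")
        if not np.isfinite(Xa).all():
            raise ValueError("feature matrix contains non-finite values; "
                             "encode missing data with sentinels")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(
                f"exactly two classes required, got {len(classes)}"
            )
        self.classes_ = classes
        self.n_features_in_ = Xa.shape[1]
        ypm = np.where(y == classes[1], 1, -1).astype(float)
        y01 = (ypm > 0).astype(float)

        n = Xa.shape[0]
        rng = np.random.default_rng(self.random_state)
        w = np.full(n, 1.0 / n)
        sub_n = max(2, int(round(self.subsample_fraction * n)))

        trees: list[dict] = []
        alphas: list[float] = []
        errors: list[float] = []
        for _ in range(self.n_iterations):
            if self.subsample_fraction < 1.0 and sub_n < n:
                idx = rng.choice(n, size=sub_n, replace=False)
            else:
                idx = np.arange(n)
            tree = _build_tree(
                Xa[idx], ypm[idx], y01[idx], w[idx], self.max_depth
            )
            h = _apply_tree(tree, Xa)
            eps = float(w[h != ypm].sum())
            if eps >= 0.5:
                warnings.warn(
                    f"boosting round {len(trees) + 1}: weighted error "
                    f"{eps:.3f} >= 0.5; stage weight clamped to ~0"
                )
            alpha = stage_weight_from_error(eps, self.learning_rate)
            trees.append(tree)
            alphas.append(alpha)
            errors.append(eps)
            if eps == 0.0:
                break  # perfect separation: further rounds are redundant
            w = w * np.exp(-alpha * ypm * h)
            w /= w.sum()

        self.trees_ = trees
        self.stage_weights_ = np.asarray(alphas)
        self.stage_errors_ = np.asarray(errors)
        self.feature_importances_ = self._importances()
        return self

    def _importances(self) -> np.ndarray:
        imp = np.zeros(self.n_features_in_)

        def walk(node, alpha):
            if "leaf" in node:
                return
            imp[node["feature"]] += alpha * node.get("gain", 0.0)
            walk(node["left"], alpha)
            walk(node["right"], alpha)

        for tree, alpha in zip(self.trees_, self.stage_weights_):
            walk(tree, alpha)
        total = imp.sum()
        return imp / total if total > 0 else imp

    # -- prediction --------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        """Ensemble margin F(x) = sum_m alpha_m h_m(x)."""
        Xa = self._coerce_X(X, fitting=False)
        F = np.zeros(Xa.shape[0])
        for tree, alpha in zip(self.trees_, self.stage_weights_):
            F += alpha * _apply_tree(tree, Xa)
        return F

    def staged_margins(self, X) -> Iterator[np.ndarray]:
        """Yield the cumulative margin after each boosting round."""
        Xa = self._coerce_X(X, fitting=False)
        F = np.zeros(Xa.shape[0])
        for tree, alpha in zip(self.trees_, self.stage_weights_):
            F = F + alpha * _apply_tree(tree, Xa)
            yield F.copy()

    def somatic_probability(self, X) -> np.ndarray:
        """P(true somatic) = 1 / (1 + exp(-2 F(x))), strictly monotone in F."""
        F = self.decision_function(X)
        return 1.0 / (1.0 + np.exp(-2.0 * np.clip(F, -350, 350)))

    def predict_proba(self, X) -> np.ndarray:
        p = self.somatic_probability(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        p = self.somatic_probability(X)
        return self.classes_[(p >= 0.5).astype(int)]


# ---------------------------------------------------------------------------
# model inspection, text export, serialization


def feature_importance(model: StochasticAdaBoostClassifier) -> list[tuple[str, float]]:
    """Features ranked by normalized importance; ties break by name."""
    names = getattr(model, "feature_names_in_", None)
    if names is None:
        names = [f"f{i}" for i in range(model.n_features_in_)]
    pairs = list(zip(list(names), model.feature_importances_.tolist()))
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def _feature_label(model, index: int) -> str:
    names = getattr(model, "feature_names_in_", None)
    return str(names[index]) if names is not None else f"f{index}"


def export_tree(model: StochasticAdaBoostClassifier, index: int) -> str:
    """Indented text rendering of one tree.

    Internal nodes print ``feature < threshold``; the left block is the
    branch where the condition holds. Terminal nodes print the class score
    marked with an asterisk.
    """
    if not 0 <= index < len(model.trees_):
        raise IndexError(f"tree index {index} out of range")

    lines: list[str] = []

    def walk(node, depth):
        pad = "  " * depth
        if "leaf" in node:
            lines.append(f"{pad}{node['leaf']:+d} *")
            return
        lines.append(f"{pad}{_feature_label(model, node['feature'])} < {node['threshold']!r}")
        walk(node["left"], depth + 1)
        walk(node["right"], depth + 1)

    walk(model.trees_[index], 0)
    return "\n".join(lines) + "\n"


def parse_tree_text(text: str, feature_names: Sequence[str]) -> dict:
    """Inverse of :func:`export_tree` (round-trips predictions exactly)."""
    name_index = {str(n): i for i, n in enumerate(feature_names)}
    entries = []
    for raw in text.splitlines():
        if not raw.strip():
            continue
        depth = (len(raw) - len(raw.lstrip())) // 2
        entries.append((depth, raw.strip()))

    pos = 0

    def parse(depth):
        nonlocal pos
        d, content = entries[pos]
        if d != depth:
            raise ValueError("malformed tree text: bad indentation")
        pos += 1
        if content.endswith("*"):
            return {"leaf": int(content[:-1].strip())}
        name, _, threshold = content.partition(" < ")
        node = {
            "feature": name_index[name],
            "threshold": float(threshold),
            "left": parse(depth + 1),
        }
        node["right"] = parse(depth + 1)
        return node

    tree = parse(0)
    if pos != len(entries):
        raise ValueError("malformed tree text: trailing lines")
    return tree


def tree_leaf_count(tree: dict) -> int:
    return _tree_leaf_count(tree)


MODEL_FORMAT_VERSION = 1


def _strip_gain(node):
    if "leaf" in node:
        return {"leaf": node["leaf"]}
    return {
        "feature": node["feature"],
        "threshold": node["threshold"],
        "gain": node.get("gain", 0.0),
        "left": _strip_gain(node["left"]),
        "right": _strip_gain(node["right"]),
    }


def save_model(model: StochasticAdaBoostClassifier, path: str | Path) -> None:
    """Serialize a fitted model to versioned JSON (reloads bit-identically)."""
    names = getattr(model, "feature_names_in_", None)
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": {
            "n_iterations": model.n_iterations,
            "max_depth": model.max_depth,
            "subsample_fraction": model.subsample_fraction,
            "learning_rate": model.learning_rate,
            "random_state": model.random_state,
        },
        "classes": [int(c) if isinstance(c, (int, np.integer)) else c
                    for c in model.classes_.tolist()],
        "n_features": int(model.n_features_in_),
        "feature_names": None if names is None else [str(n) for n in names],
        "stage_weights": model.stage_weights_.tolist(),
        "stage_errors": model.stage_errors_.tolist(),
        "trees": [_strip_gain(t) for t in model.trees_],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path: str | Path) -> StochasticAdaBoostClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {payload.get('format_version')}"
        )
    cfg = payload["config"]
    model = StochasticAdaBoostClassifier(**cfg)
    model.classes_ = np.asarray(payload["classes"])
    model.n_features_in_ = payload["n_features"]
    if payload["feature_names"] is not None:
        model.feature_names_in_ = np.asarray(payload["feature_names"], dtype=object)
    model.stage_weights_ = np.asarray(payload["stage_weights"])
    model.stage_errors_ = np.asarray(payload["stage_errors"])
    model.trees_ = payload["trees"]
    model.feature_importances_ = model._importances()
    return model
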