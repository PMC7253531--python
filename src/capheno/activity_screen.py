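"""Active / inactive screening of ΔF/F0 traces with boosted decision stumps.

A handful of trace-shape features — built from the trace's intervals of high
activity (time spent above a threshold) plus simple amplitude statistics —
feed a discrete AdaBoost ensemble of depth-1 stumps trained on a small
labeled subset, mirroring the workflow where ~100 representative traces per
class are curated by hand and the rest are assigned automatically.  The
default activity threshold is twice the trace's robust noise SD
(1.4826 · MAD), so a flat noisy trace sits almost entirely below it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

from .errors import InputError, TrainingError

__all__ = [
    "ScreenFeatures",
    "ScreenModel",
    "SCREEN_FEATURE_NAMES",
    "default_threshold",
    "high_activity_intervals",
    "screen_features",
    "train_screen",
    "classify_screen",
]

SCREEN_FEATURE_NAMES = (
    "fraction_active",
    "n_intervals",
    "mean_interval_s",
    "max_dff_pct",
    "sd_dff_pct",
)

ACTIVE, INACTIVE = "active", "inactive"


@dataclass(frozen=True)
class ScreenFeatures:
    """Trace-shape features for screening one neuron.

    ``fraction_active``: fraction of frames above the threshold;
    ``n_intervals``: number of maximal supra-threshold runs;
    ``mean_interval_s``: their mean duration (0 when there are none);
    ``max_dff_pct`` / ``sd_dff_pct``: trace maximum and SD in % ΔF/F0.
    """

    fraction_active: float
    n_intervals: float
    mean_interval_s: float
    max_dff_pct: float
    sd_dff_pct: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SCREEN_FEATURE_NAMES], dtype=float)


def default_threshold(trace) -> float:
    """High-activity threshold: 2 × robust noise SD (1.4826 · MAD) of the trace."""
    v = np.asarray(trace.values, dtype=float)
    mad = np.median(np.abs(v - np.median(v)))
    return 2.0 * 1.4826 * mad


def high_activity_intervals(trace, threshold: float) -> list[tuple[float, float]]:
    """Maximal runs of the trace strictly above ``threshold``.

    Runs are half-open in frames and reported in seconds: a run spanning
    frames [a, b) at ``fps`` becomes ``(a/fps, b/fps)``.
    """
    v = np.asarray(trace.values, dtype=float)
    above = v > threshold
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    fps = float(trace.fps)
    return [(s / fps, e / fps) for s, e in zip(edges[0::2], edges[1::2])]


def screen_features(trace, threshold: float | None = None) -> ScreenFeatures:
    """Deterministic screening feature vector for one normalized trace."""
    if threshold is None:
        threshold = default_threshold(trace)
    v = np.asarray(trace.values, dtype=float)
    intervals = high_activity_intervals(trace, threshold)
    durations = [e - s for s, e in intervals]
    return ScreenFeatures(
        fraction_active=float(np.mean(v > threshold)),
        n_intervals=float(len(intervals)),
        mean_interval_s=float(np.mean(durations)) if durations else 0.0,
        max_dff_pct=float(v.max()),
        sd_dff_pct=float(v.std()),
    )


@dataclass
class ScreenModel:
    """Weighted depth-1 stump ensemble, fully serializable to JSON.

    Each stump is ``(feature_index, threshold, left_label, right_label)``:
    samples with ``x[feature] <= threshold`` vote ``left_label``.  The
    classifier output is the sign of the weighted vote with ties resolved
    as active (favoring sensitivity).
    """

    stumps: list[tuple[int, float, str, str]]
    weights: list[float]
    feature_names: tuple[str, ...] = SCREEN_FEATURE_NAMES
    n_labeled: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stumps:
            raise TrainingError("model must contain at least one stump")
        if not np.all(np.isfinite(self.weights)):
            raise TrainingError("stump weights must be finite")

    def to_json(self, path=None) -> str:
        payload = {
            "stumps": [list(s) for s in self.stumps],
            "weights": list(map(float, self.weights)),
            "feature_names": list(self.feature_names),
            "n_labeled": self.n_labeled,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ScreenModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if "\n" not in text and text.strip().endswith(".json"):
                with open(text) as fh:
                    payload = json.load(fh)
            else:
                payload = json.loads(text)
        return cls(
            stumps=[(int(f), float(t), l, r) for f, t, l, r in payload["stumps"]],
            weights=[float(w) for w in payload["weights"]],
            feature_names=tuple(payload["feature_names"]),
            n_labeled={k: int(v) for k, v in payload.get("n_labeled", {}).items()},
            seed=int(payload.get("seed", 0)),
        )


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        x = features
    else:
        x = np.array([f.as_array() if isinstance(f, ScreenFeatures) else np.asarray(f, float)
                      for f in features])
    return np.atleast_2d(x).astype(float)


def train_screen(features, labels, n_rounds: int = 50, seed: int = 0) -> ScreenModel:
    """Fit a discrete-AdaBoost stump ensemble on labeled screening features.

    Labels must contain both classes ("active"/"inactive").  Training is
    deterministic for a fixed seed; on separable data the ensemble reaches
    zero training error.
    """
    x = _as_matrix(features)
    y = np.asarray(labels)
    classes = set(y.tolist())
    if classes - {ACTIVE, INACTIVE}:
        raise TrainingError(f"unknown labels: {sorted(classes - {ACTIVE, INACTIVE})}")
    if len(classes) < 2:
        raise TrainingError("training requires both active and inactive examples")

    booster = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=1, random_state=seed),
        n_estimators=n_rounds,
        random_state=seed,
    )
    booster.fit(x, y)

    stumps: list[tuple[int, float, str, str]] = []
    weights: list[float] = []
    for est, w in zip(booster.estimators_, booster.estimator_weights_):
        if w <= 0:
            continue
        tree = est.tree_
        if tree.node_count == 1:  # degenerate single-leaf stump
            label = str(est.classes_[int(np.argmax(tree.value[0]))])
            stumps.append((0, np.inf, label, label))
        else:
            feat = int(tree.feature[0])
            thr = float(tree.threshold[0])
            left = str(est.classes_[int(np.argmax(tree.value[tree.children_left[0]]))])
            right = str(est.classes_[int(np.argmax(tree.value[tree.children_right[0]]))])
            stumps.append((feat, thr, left, right))
        weights.append(float(w))
    if not stumps:  # all rounds rejected: fall back to a single majority stump
        majority = ACTIVE if np.mean(y == ACTIVE) >= 0.5 else INACTIVE
        stumps, weights = [(0, np.inf, majority, majority)], [1.0]
    n_labeled = {c: int(np.sum(y == c)) for c in (ACTIVE, INACTIVE)}
    return ScreenModel(stumps=stumps, weights=weights, n_labeled=n_labeled, seed=seed)


def classify_screen(model: ScreenModel, features) -> tuple[str, float] | list[tuple[str, float]]:
    """Classify feature vector(s); returns (label, margin) per sample.

    The margin is the weight-normalized vote in [-1, 1] (positive = active);
    a zero margin classifies as active.
    """
    single = isinstance(features, ScreenFeatures) or (
        isinstance(features, np.ndarray) and features.ndim == 1
    )
    x = _as_matrix(features)
    if x.shape[1] != len(model.feature_names):
        raise InputError(
            f"expected {len(model.feature_names)} features, got {x.shape[1]}"
        )
    total = float(np.sum(model.weights))
    score = np.zeros(x.shape[0])
    for (feat, thr, left, right), w in zip(model.stumps, model.weights):
        votes = np.where(x[:, feat] <= thr, 1.0 if left == ACTIVE else -1.0,
                         1.0 if right == ACTIVE else -1.0)
        score += w * votes
    margins = score / total
    results = [(ACTIVE if m >= 0 else INACTIVE, float(m)) for m in margins]
    return results[0] if single else results
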