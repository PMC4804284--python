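"""Nucleus classification: labels, logistic regression, leave-image-out CV.

Ground truth comes as dot annotations: an expert clicks near the center of
each nucleus of the target cell type.  A segmented nucleus is labeled
``target`` when a dot lies within a matching radius of its centroid (15 px
by default, roughly the largest target-nucleus radius at the working
magnification).  An L2-regularized logistic regression (liblinear solver)
is trained on the standardized per-nucleus descriptors; performance is
estimated by leave-image-out cross-validation — all nuclei of one image
form the held-out fold, so no within-image information leaks — and an
operating threshold is chosen on the pooled precision/recall curve as the
largest threshold whose recall still meets a required floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .features import NucleusFeatureVector
from .preprocess import NucleusRecord

TARGET = "target"
NON_TARGET = "non_target"


@dataclass
class LabelSet:
    """Per-nucleus class labels with annotation provenance."""

    labels: dict[tuple[str, int], str]
    provenance: dict[tuple[str, int], int | None] = field(default_factory=dict)
    unmatched_dots: list[tuple[str, int]] = field(default_factory=list)

    def label(self, image_id: str, nucleus_id: int) -> str:
        return self.labels[(image_id, nucleus_id)]

    def y(self, keys: Sequence[tuple[str, int]]) -> np.ndarray:
        return np.array([self.labels[k] == TARGET for k in keys], dtype=int)


@dataclass
class TrainedModel:
    """Logistic-regression weights plus the chosen operating threshold."""

    weights: np.ndarray
    intercept: float
    feature_names: list[str]
    regularization_c: float
    threshold: float
    training_image_ids: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != len(self.feature_names):
            raise ValueError("weights and feature_names misaligned")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")

    def score(self, vectors: Sequence[NucleusFeatureVector]) -> np.ndarray:
        """Posterior probability of the target class for each nucleus."""
        x = np.array(
            [[v.values[n] for n in self.feature_names] for v in vectors], dtype=float
        )
        logit = x @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-logit))

    def to_json(self, path: str | Path, config_hash: str = "") -> None:
        payload = {
            "feature_names": self.feature_names,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "C": self.regularization_c,
            "threshold": self.threshold,
            "training_image_ids": self.training_image_ids,
            "config_hash": config_hash,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            feature_names=list(d["feature_names"]),
            regularization_c=float(d["C"]),
            threshold=float(d["threshold"]),
            training_image_ids=list(d["training_image_ids"]),
        )


@dataclass
class PRCurve:
    """Precision/recall at every distinct score threshold (descending)."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray


def match_annotations(
    nuclei: Sequence[NucleusRecord],
    dots: Sequence[tuple[float, float]],
    radius: float = 15.0,
) -> LabelSet:
    """Label nuclei from dot annotations by radius matching.

    A nucleus is ``target`` iff some dot lies within Euclidean distance
    ``radius`` (inclusive) of its centroid.  Each dot is assigned to its
    nearest in-radius centroid, ties broken by smaller nucleus_id; dots with
    no centroid in radius are reported as unmatched.
    """
    labels: dict[tuple[str, int], str] = {
        (n.image_id, n.nucleus_id): NON_TARGET for n in nuclei
    }
    provenance: dict[tuple[str, int], int | None] = {
        (n.image_id, n.nucleus_id): None for n in nuclei
    }
    unmatched: list[tuple[str, int]] = []
    if nuclei:
        centroids = np.array([n.centroid for n in nuclei], dtype=float)
        ids = np.array([n.nucleus_id for n in nuclei])
        order = np.argsort(ids, kind="stable")
        for di, (r, c) in enumerate(dots):
            d = np.hypot(centroids[:, 0] - r, centroids[:, 1] - c)
            in_radius = d <= radius
            if not in_radius.any():
                img = nuclei[0].image_id
                unmatched.append((img, di))
                continue
            # nearest centroid; among exact-distance ties the smaller id wins
            dmin = d[in_radius].min()
            tied = np.nonzero(np.isclose(d, dmin) & in_radius)[0]
            best = tied[np.argmin(ids[tied])]
            key = (nuclei[best].image_id, nuclei[best].nucleus_id)
            labels[key] = TARGET
            if provenance[key] is None:
                provenance[key] = di
    else:
        unmatched = [("", di) for di in range(len(dots))]
    return LabelSet(labels=labels, provenance=provenance, unmatched_dots=unmatched)


def _design_matrix(
    vectors: Sequence[NucleusFeatureVector],
) -> tuple[np.ndarray, list[str], list[tuple[str, int]]]:
    names = list(vectors[0].values.keys())
    x = np.array([[v.values[n] for n in names] for v in vectors], dtype=float)
    keys = [(v.image_id, v.nucleus_id) for v in vectors]
    return x, names, keys


def train_logreg(
    vectors: Sequence[NucleusFeatureVector],
    labels: LabelSet,
    c: float = 1.0,
    class_weight: str | None = None,
    threshold: float = 0.5,
) -> TrainedModel:
    """Fit an L2 logistic regression with the liblinear solver.

    ``class_weight`` may be ``None`` or ``"balanced"``.  The fit is
    deterministic given the data and ``C``.
    """
    if c <= 0:
        raise ValueError("C must be positive")
    x, names, keys = _design_matrix(vectors)
    y = labels.y(keys)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    clf = LogisticRegression(
        C=c, solver="liblinear", class_weight=class_weight, tol=1e-8
    )
    clf.fit(x, y)
    return TrainedModel(
        weights=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        feature_names=names,
        regularization_c=c,
        threshold=threshold,
        training_image_ids=sorted({v.image_id for v in vectors}),
    )


def loio_cv(
    vectors: Sequence[NucleusFeatureVector],
    labels: LabelSet,
    c: float = 1.0,
    class_weight: str | None = None,
) -> pd.DataFrame:
    """Leave-image-out cross-validated scores for every nucleus.

    For each image a model is trained on all other images' nuclei and
    applied to that image's nuclei.  Returns a frame with columns
    image_id, nucleus_id, score, label, training_image_ids.
    """
    image_ids = sorted({v.image_id for v in vectors})
    if len(image_ids) < 2:
        raise ValueError("leave-image-out needs at least 2 images")
    rows = []
    for held_out in image_ids:
        train = [v for v in vectors if v.image_id != held_out]
        test = [v for v in vectors if v.image_id == held_out]
        _, _, train_keys = _design_matrix(train)
        if len(np.unique(labels.y(train_keys))) < 2:
            raise ValueError(
                f"training complement of image '{held_out}' is single-class"
            )
        model = train_logreg(train, labels, c=c, class_weight=class_weight)
        assert held_out not in model.training_image_ids
        scores = model.score(test)
        for v, s in zip(test, scores):
            rows.append(
                {
                    "image_id": v.image_id,
                    "nucleus_id": v.nucleus_id,
                    "score": float(s),
                    "label": labels.label(v.image_id, v.nucleus_id),
                    "training_image_ids": ",".join(model.training_image_ids),
                }
            )
    return pd.DataFrame(rows)


def pr_curve(scores: np.ndarray, is_target: np.ndarray) -> PRCurve:
    """Exact precision/recall counts at every distinct score threshold.

    A nucleus is predicted target iff its score >= threshold.  With a
    threshold above all scores nothing is predicted and precision is 1 by
    convention.
    """
    scores = np.asarray(scores, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    if scores.shape != is_target.shape:
        raise ValueError("scores and labels misaligned")
    n_pos = int(is_target.sum())
    if n_pos == 0:
        raise ValueError("no target nuclei: recall undefined")
    thresholds = np.unique(scores)[::-1]
    tp = np.empty(thresholds.size, dtype=int)
    fp = np.empty(thresholds.size, dtype=int)
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    cum_tp = np.cumsum(is_target[order])
    cum_fp = np.cumsum(~is_target[order])
    for i, t in enumerate(thresholds):
        k = int(np.searchsorted(-sorted_scores, -t, side="right"))
        tp[i] = cum_tp[k - 1] if k else 0
        fp[i] = cum_fp[k - 1] if k else 0
    fn = n_pos - tp
    denom = tp + fp
    precision = np.where(denom > 0, tp / np.maximum(denom, 1), 1.0)
    recall = tp / n_pos
    return PRCurve(
        thresholds=thresholds, precision=precision, recall=recall, tp=tp, fp=fp, fn=fn
    )


def select_threshold(curve: PRCurve, target_recall: float) -> tuple[float, float, float]:
    """Operating point maximizing precision subject to a recall floor.

    Returns ``(threshold, precision, recall)``: among thresholds whose
    recall is at least ``target_recall``, the one with maximal precision is
    chosen; among precision ties the higher-recall (smaller-threshold) point
    wins, since it Pareto-dominates, and exact recall ties resolve to the
    larger threshold.  Relaxing the floor can therefore never lower the
    selected precision.
    """
    if curve.thresholds.size == 0:
        raise ValueError("empty curve")
    ok = curve.recall >= target_recall
    if not ok.any():
        raise ValueError(
            f"target recall {target_recall} exceeds the maximum achievable "
            f"{curve.recall.max():.3f}"
        )
    feasible = np.nonzero(ok)[0]
    best = curve.precision[feasible].max()
    tied = feasible[curve.precision[feasible] >= best - 1e-12]
    # thresholds descend, so the first argmax picks the largest threshold
    # among the highest-recall points of the precision tie
    idx = int(tied[np.argmax(curve.recall[tied])])
    return (
        float(curve.thresholds[idx]),
        float(curve.precision[idx]),
        float(curve.recall[idx]),
    )


def read_annotation_csv(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Dot annotations grouped by image: CSV with header image_id,row,col."""
    frame = pd.read_csv(path)
    out: dict[str, list[tuple[float, float]]] = {}
    for _, row in frame.iterrows():
        out.setdefault(str(row["image_id"]), []).append(
            (float(row["row"]), float(row["col"]))
        )
    return out
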