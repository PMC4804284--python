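"""Prediction, user correction and marker-colocalization reporting.

A trained model applied to a new image yields per-nucleus target
probabilities; nuclei at or above the model threshold are predicted
targets.  A file-based correction step lets the user accept or reject
individual nuclei (the marker channel plays no role in this step, so the
quantified readout cannot bias the correction).  Marker positivity
(e.g. EdU or TUNEL) is called per nucleus as the fraction of nuclear pixels
above the marker channel's Otsu threshold, and the report counts nuclei of
each subgroup with the derived percentages: targets among all nuclei,
marker-positive among all nuclei, marker-positive among targets, and
targets among marker-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .classify import TrainedModel
from .features import NucleusFeatureVector
from .preprocess import ChannelStack, NucleusRecord

ACCEPT = "accept"
REJECT = "reject"
UNTOUCHED = "untouched"


@dataclass(frozen=True)
class PredictionRecord:
    nucleus_id: int
    image_id: str
    score: float
    predicted: str  # "target" | "non_target"
    user_decision: str = UNTOUCHED

    @property
    def final_target(self) -> bool:
        """Prediction after the user decision, which overrides the score."""
        if self.user_decision == ACCEPT:
            return True
        if self.user_decision == REJECT:
            return False
        return self.predicted == "target"


def predict(
    model: TrainedModel, vectors: Sequence[NucleusFeatureVector]
) -> list[PredictionRecord]:
    """Score nuclei and threshold at the model's operating point."""
    scores = model.score(vectors)
    return [
        PredictionRecord(
            nucleus_id=v.nucleus_id,
            image_id=v.image_id,
            score=float(s),
            predicted="target" if s >= model.threshold else "non_target",
        )
        for v, s in zip(vectors, scores)
    ]


def marker_positive(
    stack: ChannelStack,
    nuclei: Sequence[NucleusRecord],
    min_fraction: float = 0.25,
) -> dict[int, bool]:
    """Call each nucleus marker-positive from the corrected marker channel.

    The marker channel is binarized by Otsu; a nucleus is positive iff the
    fraction of its pixels above threshold is at least ``min_fraction``.
    """
    if stack.marker is None:
        raise ValueError("stack has no marker channel")
    if not stack.corrected:
        raise ValueError("stack must be illumination-corrected")
    marker = stack.marker
    if np.ptp(marker) == 0:
        return {n.nucleus_id: False for n in nuclei}
    mask = marker >= threshold_otsu(marker)
    out: dict[int, bool] = {}
    for n in nuclei:
        rr, cc = n.coords()
        frac = mask[rr, cc].mean()
        out[n.nucleus_id] = bool(frac >= min_fraction)
    return out


def apply_corrections(
    predictions: Sequence[PredictionRecord],
    corrections: pd.DataFrame | str | Path,
) -> list[PredictionRecord]:
    """Apply a user-correction table to predictions.

    ``corrections`` has columns image_id,nucleus_id,decision with decision
    in {accept, reject}.  Accept forces target; reject forces non_target;
    absent nuclei are untouched.  Idempotent and independent of row order
    (the last decision for a nucleus wins, matching a user re-editing the
    file).  Unknown nucleus references raise, listing the offenders.
    """
    if not isinstance(corrections, pd.DataFrame):
        corrections = pd.read_csv(corrections)
    known = {(p.image_id, p.nucleus_id) for p in predictions}
    decisions: dict[tuple[str, int], str] = {}
    offenders = []
    for _, row in corrections.iterrows():
        key = (str(row["image_id"]), int(row["nucleus_id"]))
        decision = str(row["decision"]).strip()
        if decision not in (ACCEPT, REJECT):
            raise ValueError(f"unknown decision '{decision}' for {key}")
        if key not in known:
            offenders.append(key)
        decisions[key] = decision
    if offenders:
        raise KeyError(f"corrections reference unknown nuclei: {sorted(offenders)}")
    return [
        replace(p, user_decision=decisions.get((p.image_id, p.nucleus_id), p.user_decision))
        for p in predictions
    ]


@dataclass
class QuantReport:
    """Counts and percentages per image plus a pooled row.

    Percentages are exact ratios of the integer counts; pooled values use
    summed counts, not averages of per-image percentages.
    """

    per_image: pd.DataFrame
    pooled: dict[str, float | int | None]

    def to_json(self, path: str | Path) -> None:
        import json

        payload = {
            "pooled": self.pooled,
            "per_image": self.per_image.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _percentages(n_total: int, n_target: int, n_marker: int, n_both: int) -> dict:
    def pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    return {
        "n_total_nuclei": n_total,
        "n_target": n_target,
        "n_marker_pos": n_marker,
        "n_marker_pos_target": n_both,
        "pct_target_of_total": pct(n_target, n_total),
        "pct_marker_of_total": pct(n_marker, n_total),
        "pct_marker_target_of_target": pct(n_both, n_target),
        "pct_marker_target_of_marker": pct(n_both, n_marker),
    }


def quantify(
    nuclei: Sequence[NucleusRecord],
    target_flags: Mapping[tuple[str, int], bool],
    marker_flags: Mapping[tuple[str, int], bool],
) -> QuantReport:
    """Count nucleus subgroups per image and pooled.

    ``target_flags`` and ``marker_flags`` map (image_id, nucleus_id) to the
    final target call and the marker-positivity call.  Conservation
    (n_target + n_non_target = n_total, and the co-labeled count bounded by
    both margins) holds by construction and is asserted on every call.
    """
    rows = []
    by_image: dict[str, list[NucleusRecord]] = {}
    for n in nuclei:
        by_image.setdefault(n.image_id, []).append(n)
    totals = np.zeros(4, dtype=int)
    for image_id in sorted(by_image):
        group = by_image[image_id]
        n_total = len(group)
        n_target = sum(target_flags[(image_id, n.nucleus_id)] for n in group)
        n_marker = sum(marker_flags[(image_id, n.nucleus_id)] for n in group)
        n_both = sum(
            target_flags[(image_id, n.nucleus_id)]
            and marker_flags[(image_id, n.nucleus_id)]
            for n in group
        )
        assert n_both <= min(n_target, n_marker) <= n_total
        totals += (n_total, n_target, n_marker, n_both)
        rows.append({"image_id": image_id, **_percentages(n_total, n_target, n_marker, n_both)})
    pooled = _percentages(*totals.tolist())
    return QuantReport(per_image=pd.DataFrame(rows), pooled=pooled)


def predictions_to_frame(
    predictions: Sequence[PredictionRecord],
    nuclei: Sequence[NucleusRecord] | None = None,
) -> pd.DataFrame:
    """predictions.csv layout: nucleus_id,image_id,row,col,score,predicted."""
    centroid = {}
    if nuclei:
        centroid = {(n.image_id, n.nucleus_id): n.centroid for n in nuclei}
    rows = []
    for p in predictions:
        r, c = centroid.get((p.image_id, p.nucleus_id), (np.nan, np.nan))
        rows.append(
            {
                "nucleus_id": p.nucleus_id,
                "image_id": p.image_id,
                "row": round(float(r), 3),
                "col": round(float(c), 3),
                "score": p.score,
                "predicted": p.predicted,
                "user_decision": p.user_decision,
            }
        )
    return pd.DataFrame(rows)
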