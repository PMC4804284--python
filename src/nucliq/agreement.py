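"""Multi-rater agreement over radius-matched nucleus selections.

Several raters independently dot the nuclei they consider to belong to the
target cell type.  Dots are matched to segmented nuclei within a Euclidean
radius (15 px by default), turning every nucleus into an item rated
selected / not-selected by each rater.  Agreement is Fleiss' kappa

    kappa = (P_bar - P_bar_e) / (1 - P_bar_e)

where P_bar is the mean per-item pairwise agreement and P_bar_e the chance
agreement from the pooled category proportions.  The large-sample standard
error uses the Fleiss-Nee-Landis form, and two independent agreement
conditions are compared with a normal z-test on the kappa difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .classify import match_annotations
from .preprocess import NucleusRecord

BANDS = (
    # (lower, upper, name) on the 2-decimal-rounded kappa
    (0.01, 0.20, "slight"),
    (0.21, 0.40, "fair"),
    (0.41, 0.60, "moderate"),
    (0.61, 0.80, "substantial"),
)


@dataclass
class RaterMatrix:
    """Per-item counts of raters assigning each of the two categories."""

    items: list[tuple[str, int]]
    raters: list[str]
    counts: np.ndarray  # shape (n_items, 2): [selected, not_selected]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.raters)
        if k < 2:
            raise ValueError("need at least 2 raters")
        if not np.all(self.counts.sum(axis=1) == k):
            raise ValueError("per-item counts must sum to the number of raters")


@dataclass
class AgreementResult:
    kappa: float
    se: float
    n_items: int
    n_raters: int
    band: str

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "se": self.se,
            "n_items": self.n_items,
            "n_raters": self.n_raters,
            "band": self.band,
        }


def build_rater_matrix(
    nuclei: Sequence[NucleusRecord],
    rater_dots: Mapping[str, Sequence[tuple[float, float]]],
    radius: float = 15.0,
) -> RaterMatrix:
    """Radius-match each rater's dots to the nuclei and tally selections.

    A nucleus counts as selected by a rater when at least one of that
    rater's dots lies within ``radius`` of its centroid (multiple dots by
    one rater on one nucleus count once: selection is binary per rater).
    """
    if len(rater_dots) < 2:
        raise ValueError("need at least 2 raters")
    raters = sorted(rater_dots)
    items = [(n.image_id, n.nucleus_id) for n in nuclei]
    selected = np.zeros((len(items), len(raters)), dtype=bool)
    for j, rater in enumerate(raters):
        labels = match_annotations(nuclei, rater_dots[rater], radius=radius)
        for i, key in enumerate(items):
            selected[i, j] = labels.labels[key] == "target"
    n_sel = selected.sum(axis=1)
    counts = np.stack([n_sel, len(raters) - n_sel], axis=1)
    return RaterMatrix(items=items, raters=raters, counts=counts)


def fleiss_kappa(matrix: RaterMatrix) -> AgreementResult:
    """Fleiss' kappa with its Fleiss-Nee-Landis large-sample standard error."""
    counts = matrix.counts
    n, k = counts.shape[0], int(counts.sum(axis=1)[0])
    if n < 1:
        raise ValueError("need at least 1 item")
    p_j = counts.sum(axis=0) / (n * k)  # pooled category proportions
    p_bar_e = float(np.sum(p_j**2))
    if p_bar_e >= 1.0:
        raise ValueError(
            "all raters used a single category for every item: kappa undefined"
        )
    p_i = (np.sum(counts**2, axis=1) - k) / (k * (k - 1))
    p_bar = float(np.mean(p_i))
    kappa = (p_bar - p_bar_e) / (1.0 - p_bar_e)
    q_j = 1.0 - p_j
    s = float(np.sum(p_j * q_j))
    var = (2.0 / (n * k * (k - 1))) * (s**2 - float(np.sum(p_j * q_j * (q_j - p_j)))) / s**2
    se = float(np.sqrt(var))
    return AgreementResult(
        kappa=float(kappa), se=se, n_items=n, n_raters=k, band=interpret_kappa(kappa)
    )


def interpret_kappa(kappa: float) -> str:
    """Map kappa to its verbal agreement band.

    Bands follow the conventional 2-decimal cutpoints (slight 0.01-0.2,
    fair 0.21-0.4, moderate 0.41-0.6, substantial 0.61-0.8, almost perfect
    above 0.8); kappa is rounded half-up to 2 decimals first so values in
    the printed gaps (e.g. 0.205) land in a band, and values at or below 0
    mean no agreement beyond chance.
    """
    if not np.isfinite(kappa):
        raise ValueError("kappa must be finite")
    k2 = np.floor(kappa * 100 + 0.5) / 100  # round half-up at 2 decimals
    if k2 < 0.01:
        return "poor"
    for lo, hi, name in BANDS:
        if lo <= k2 <= hi:
            return name
    return "almost_perfect"


def kappa_z_test(a: AgreementResult, b: AgreementResult) -> tuple[float, float]:
    """Normal z-test comparing two independent kappas.

    z = (kappa_a - kappa_b) / sqrt(se_a^2 + se_b^2); returns (z, two-sided p).
    """
    var = a.se**2 + b.se**2
    if var <= 0:
        raise ValueError("nonpositive pooled variance")
    z = (a.kappa - b.kappa) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)
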