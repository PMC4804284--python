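"""Per-pixel texture features and per-nucleus descriptor vectors.

The classifier separates target-cell nuclei (e.g. cardiomyocyte nuclei,
which sit inside striated alpha-actin-positive cytoplasm) from other nuclei
using texture computed on the nuclear and structural channels.  Five
per-pixel feature families are computed:

(i)   rotation-invariant gradient-orientation histograms (Fourier HOG):
      magnitudes of angular Fourier moments of the local gradient
      distribution, pooled with isotropic Gaussian radial profiles;
(ii)  Haralick statistics of a sliding-window gray-level co-occurrence
      matrix (contrast, correlation, energy, homogeneity, entropy);
(iii) local Shannon entropy of the intensity histogram;
(iv)  a curvilinear-structure (membrane) saliency map: steerable
      second-derivative-of-Gaussian ridge filtering followed by stick
      tensor voting;
(v)   the area of the extracellular connected component containing each
      pixel (ECS), from an Otsu tissue mask of the structural channel.

Each map is summarized over two regions per nucleus — the nucleus pixel set
and a surrounding ring — by four statistics (mean, median, sample standard
deviation, median absolute deviation), and the resulting descriptor columns
are standardized to zero mean and unit variance within each image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .preprocess import ChannelStack, NucleusRecord, _label_binary

CHANNEL_ROLES = ("nuclear", "structural")
REGIONS = ("nucleus", "ring")
STATISTICS = ("mean", "median", "std", "mad")
HARALICK_STATS = ("contrast", "correlation", "energy", "homogeneity", "entropy")


@dataclass
class FeatureConfig:
    """Free parameters of the five feature families.

    Defaults are sized for nuclei of roughly 5-15 px radius imaged at 40x.
    """

    hog_max_order: int = 4
    hog_radial_sigmas: tuple[float, ...] = (2.0, 4.0, 8.0)
    haralick_window: int = 15
    haralick_levels: int = 8
    haralick_offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
    entropy_window: int = 9
    entropy_bins: int = 32
    ridge_sigma: float = 2.0
    voting_sigma: float = 10.0
    n_voting_orientations: int = 16
    ring_radius: int = 15

    def __post_init__(self) -> None:
        for w in (self.haralick_window, self.entropy_window):
            if w < 3 or w % 2 == 0:
                raise ValueError("windows must be odd and >= 3")
        if self.hog_max_order < 1:
            raise ValueError("hog_max_order must be >= 1")
        for s in (*self.hog_radial_sigmas, self.ridge_sigma, self.voting_sigma):
            if s <= 0:
                raise ValueError("all sigmas must be > 0")
        if self.n_voting_orientations % 4 != 0:
            raise ValueError("n_voting_orientations must be a multiple of 4")


@dataclass
class PixelFeatureMaps:
    """Per-channel named feature maps for one image."""

    image_id: str
    per_channel: dict[str, dict[str, np.ndarray]]


@dataclass
class NucleusFeatureVector:
    """Named per-nucleus descriptor; insertion order is the canonical order."""

    nucleus_id: int
    image_id: str
    values: dict[str, float]


# ---------------------------------------------------------------------------
# (i) Fourier HOG


def fourier_hog(channel: np.ndarray, cfg: FeatureConfig | None = None) -> dict[str, np.ndarray]:
    """Rotation-invariant gradient-orientation moment magnitudes.

    The image gradient is treated, per pixel, as a one-point orientation
    distribution with mass ``|g|`` at angle ``theta``.  Its angular Fourier
    coefficient of order ``m`` is ``|g| * exp(i*m*theta)``; pooling this
    complex field with an isotropic Gaussian and taking the magnitude gives
    a map that rotates with the image but whose values are unchanged by
    rotation (the phase picked up by a global rotation cancels).
    """
    cfg = cfg or FeatureConfig()
    channel = np.asarray(channel, dtype=float)
    grow, gcol = np.gradient(channel)
    g = gcol + 1j * grow
    mag = np.abs(g)
    ang = np.angle(g)
    out: dict[str, np.ndarray] = {}
    for m in range(cfg.hog_max_order + 1):
        moment = mag * np.exp(1j * m * ang)
        for s in cfg.hog_radial_sigmas:
            resp = ndimage.gaussian_filter(moment.real, s, mode="reflect") + 1j * (
                ndimage.gaussian_filter(moment.imag, s, mode="reflect")
            )
            out[f"fhog_m{m}_s{s:g}"] = np.abs(resp)
    return out


# ---------------------------------------------------------------------------
# (ii) sliding-window Haralick


def quantize(channel: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of an image onto ``levels`` gray levels."""
    channel = np.asarray(channel, dtype=float)
    lo, hi = channel.min(), channel.max()
    if hi == lo:
        return np.zeros(channel.shape, dtype=np.int64)
    q = ((channel - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _window_sum(ind: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel count of True entries in the window clipped to the image."""
    sums = ndimage.uniform_filter(
        ind.astype(np.float32), size=window, mode="constant", cval=0.0
    ) * float(window * window)
    return np.rint(sums)  # counts are integers; remove filter round-off


def windowed_glcm(
    q: np.ndarray,
    levels: int,
    window: int,
    offsets: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Per-pixel symmetric normalized GLCM, shape (H, W, levels, levels).

    A pair ``(p, p + offset)`` contributes to the GLCM of every pixel whose
    window contains ``p``, provided ``p + offset`` lies inside the image;
    the matrix is symmetrized over pair order, averaged over offsets and
    normalized to sum 1.
    """
    q = np.asarray(q)
    h, w = q.shape
    counts = np.zeros((h, w, levels, levels), dtype=np.float32)
    for dr, dc in offsets:
        valid = np.zeros((h, w), dtype=bool)
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        valid[r0:r1, c0:c1] = True
        partner = np.zeros_like(q)
        partner[valid] = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        for i in range(levels):
            here = (q == i) & valid
            if not here.any():
                continue
            for j in range(levels):
                ind = here & (partner == j)
                if ind.any():
                    counts[:, :, i, j] += _window_sum(ind, window)
    counts = counts + counts.transpose(0, 1, 3, 2)
    total = counts.sum(axis=(2, 3), keepdims=True)
    total[total == 0] = 1.0
    return counts / total


def haralick_from_glcm(glcm: np.ndarray) -> dict[str, np.ndarray]:
    """Contrast, correlation, energy, homogeneity and entropy maps."""
    levels = glcm.shape[-1]
    i = np.arange(levels, dtype=np.float64)
    diff2 = (i[:, None] - i[None, :]) ** 2
    p = glcm.astype(np.float64)
    contrast = np.einsum("...ij,ij->...", p, diff2)
    energy = np.einsum("...ij,...ij->...", p, p)
    homogeneity = np.einsum("...ij,ij->...", p, 1.0 / (1.0 + diff2))
    logs = np.log2(p, out=np.zeros_like(p), where=p > 0)
    entropy = -np.einsum("...ij,...ij->...", p, logs)
    # symmetric GLCM: marginal means/vars are equal for rows and columns
    pi = p.sum(axis=-1)
    mu = np.einsum("...i,i->...", pi, i)
    var = np.einsum("...i,i->...", pi, (i - 0.0) ** 2) - mu**2
    cross = np.einsum("...ij,i,j->...", p, i, i)
    with np.errstate(divide="ignore", invalid="ignore"):
        correlation = np.where(var > 1e-12, (cross - mu**2) / np.where(var > 1e-12, var, 1.0), 1.0)
    return {
        "haralick_contrast": contrast,
        "haralick_correlation": correlation,
        "haralick_energy": energy,
        "haralick_homogeneity": homogeneity,
        "haralick_entropy": entropy,
    }


def haralick_maps(channel: np.ndarray, cfg: FeatureConfig | None = None) -> dict[str, np.ndarray]:
    """Sliding-window Haralick texture statistic maps."""
    cfg = cfg or FeatureConfig()
    q = quantize(channel, cfg.haralick_levels)
    glcm = windowed_glcm(q, cfg.haralick_levels, cfg.haralick_window, cfg.haralick_offsets)
    return haralick_from_glcm(glcm)


# ---------------------------------------------------------------------------
# (iii) local entropy


def local_entropy(channel: np.ndarray, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Shannon entropy (bits) of the windowed intensity histogram.

    The histogram uses ``entropy_bins`` equal-width bins over the image's
    intensity range; the window is clipped to the image bounds.
    """
    cfg = cfg or FeatureConfig()
    q = quantize(channel, cfg.entropy_bins)
    h, w = q.shape
    counts = np.empty((cfg.entropy_bins, h, w), dtype=np.float32)
    for b in range(cfg.entropy_bins):
        counts[b] = _window_sum(q == b, cfg.entropy_window)
    counts = counts.astype(np.float64)
    total = counts.sum(axis=0)
    total[total == 0] = 1.0
    p = counts / total
    terms = p * np.log2(p, out=np.zeros_like(p), where=p > 0)
    return -terms.sum(axis=0)


# ---------------------------------------------------------------------------
# (iv) membrane detector: steerable ridge filter + stick tensor voting


def ridge_filter(
    channel: np.ndarray, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Bright-ridge strength and orientation from the smoothed Hessian.

    Second derivatives of the Gaussian-smoothed image are the three basis
    responses of the steerable second-derivative filter; the direction of
    minimal second derivative (most negative curvature) is available in
    closed form, and the ridge runs perpendicular to it.  Strength is the
    eigenvalue contrast restricted to bright ridges:
    ``max(0, -lambda_min) - max(0, -lambda_max)``, which vanishes on
    isotropic blobs and on dark lines.

    Returns ``(strength, orientation)`` with orientation in ``[0, pi)``
    measured from the +col axis toward +row.
    """
    channel = np.asarray(channel, dtype=float)
    s2 = sigma * sigma
    rcc = s2 * ndimage.gaussian_filter(channel, sigma, order=(0, 2), mode="reflect")
    rrr = s2 * ndimage.gaussian_filter(channel, sigma, order=(2, 0), mode="reflect")
    rrc = s2 * ndimage.gaussian_filter(channel, sigma, order=(1, 1), mode="reflect")
    half_sum = 0.5 * (rcc + rrr)
    half_diff = 0.5 * (rcc - rrr)
    root = np.hypot(half_diff, rrc)
    lam_max = half_sum + root
    lam_min = half_sum - root
    strength = np.maximum(0.0, -lam_min) - np.maximum(0.0, -lam_max)
    strength = np.maximum(strength, 0.0)
    # direction minimizing the steered second derivative, then rotate 90 deg
    theta_min = 0.5 * np.arctan2(-rrc, -half_diff)
    orientation = np.mod(theta_min + np.pi / 2.0, np.pi)
    return strength, orientation


def _stick_vote_kernel(phi: float, sigma: float) -> tuple[np.ndarray, float, float, float]:
    """Voting field for sticks at angle ``phi``: spatial weights and tensor."""
    radius = int(np.ceil(3.0 * sigma))
    dr, dc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    d2 = dr.astype(float) ** 2 + dc.astype(float) ** 2
    decay = np.exp(-d2 / (2.0 * sigma * sigma))
    join = np.arctan2(dr.astype(float), dc.astype(float))
    # alignment of the join vector with the stick direction (mod pi): cos^4
    align = np.cos(join - phi) ** 2
    align = align * align
    weights = decay * align
    weights[radius, radius] = 1.0  # self vote
    c, s = np.cos(phi), np.sin(phi)
    return weights, c * c, s * s, c * s


def cmd_map(channel: np.ndarray, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Curvilinear (membrane-like) saliency by dense stick tensor voting.

    Ridge pixels cast orientation-aligned, distance-decaying votes carrying
    their stick tensor; orientations are discretized into
    ``n_voting_orientations`` bins over ``[0, pi)`` and each bin's votes are
    accumulated by convolution.  Saliency is ``lambda1 - lambda2`` of the
    accumulated tensor, large where votes agree in orientation along a
    curve and small for isotropic clutter.
    """
    cfg = cfg or FeatureConfig()
    strength, orientation = ridge_filter(channel, cfg.ridge_sigma)
    k = cfg.n_voting_orientations
    # bin centers at multiples of pi/k so that axis-aligned ridges are
    # robustly assigned and 90-degree rotations shift bins exactly by k/4
    bins = np.mod(np.round(orientation / (np.pi / k)).astype(int), k)
    txx = np.zeros_like(strength)
    tyy = np.zeros_like(strength)
    txy = np.zeros_like(strength)
    for b in range(k):
        sel = bins == b
        if not sel.any():
            continue
        src = np.where(sel, strength, 0.0)
        if not np.any(src):
            continue
        phi = b * np.pi / k
        weights, wxx, wyy, wxy = _stick_vote_kernel(phi, cfg.voting_sigma)
        voted = signal.oaconvolve(src, weights, mode="same")
        txx += wxx * voted
        tyy += wyy * voted
        txy += wxy * voted
    return np.hypot(txx - tyy, 2.0 * txy)


# ---------------------------------------------------------------------------
# (v) extracellular component size


def ecs_map(stack: ChannelStack, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Area of the extracellular connected component containing each pixel.

    Tissue is the structural channel at or above its Otsu threshold; the
    complement is labeled (8-connectivity) and every extracellular pixel
    receives the area of its component.  Tissue pixels receive 0.
    """
    if not stack.corrected:
        raise ValueError("stack must be illumination-corrected")
    structural = stack.structural
    if np.ptp(structural) == 0:
        return np.zeros(structural.shape, dtype=float)
    tissue = structural >= threshold_otsu(structural)
    labels = _label_binary(~tissue, connectivity=8)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    return areas[labels].astype(float)


# ---------------------------------------------------------------------------
# map assembly, per-nucleus summaries, per-image scaling


def _family_names(cfg: FeatureConfig) -> list[str]:
    names = [
        f"fhog_m{m}_s{s:g}"
        for m in range(cfg.hog_max_order + 1)
        for s in cfg.hog_radial_sigmas
    ]
    names += [f"haralick_{s}" for s in HARALICK_STATS]
    names += ["entropy", "cmd_saliency"]
    return names


def feature_names(cfg: FeatureConfig | None = None) -> list[str]:
    """Canonical descriptor column order; a pure function of the config."""
    cfg = cfg or FeatureConfig()
    cols = []
    for role in CHANNEL_ROLES:
        maps = _family_names(cfg)
        if role == "structural":
            maps = maps + ["ecs"]
        for name in maps:
            for region in REGIONS:
                for stat in STATISTICS:
                    cols.append(f"{role}.{name}.{region}.{stat}")
    return cols


def compute_feature_maps(stack: ChannelStack, cfg: FeatureConfig | None = None) -> PixelFeatureMaps:
    """All five feature families on the nuclear and structural channels.

    The ECS map is derived from the structural channel's tissue mask and is
    stored once, under the structural role.  The marker channel is never
    featurized: it must not influence classification.
    """
    cfg = cfg or FeatureConfig()
    if not stack.corrected:
        raise ValueError("stack must be illumination-corrected")
    per_channel: dict[str, dict[str, np.ndarray]] = {}
    for role in CHANNEL_ROLES:
        chan = stack.channels()[role]
        maps: dict[str, np.ndarray] = {}
        maps.update(fourier_hog(chan, cfg))
        maps.update(haralick_maps(chan, cfg))
        maps["entropy"] = local_entropy(chan, cfg)
        maps["cmd_saliency"] = cmd_map(chan, cfg)
        per_channel[role] = maps
    per_channel["structural"]["ecs"] = ecs_map(stack, cfg)
    return PixelFeatureMaps(image_id=stack.image_id, per_channel=per_channel)


def _region_stats(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        return {s: 0.0 for s in STATISTICS}
    med = float(np.median(values))
    return {
        "mean": float(values.mean()),
        "median": med,
        "std": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "mad": float(np.median(np.abs(values - med))),
    }


def nucleus_regions(
    nucleus: NucleusRecord, shape: tuple[int, int], ring_radius: int
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Pixel index arrays for the nucleus and its surrounding ring.

    The ring is the morphological dilation of the nucleus by a disk of
    ``ring_radius`` minus the nucleus itself, clipped to the image bounds;
    computed on a cropped window for speed.
    """
    rr, cc = nucleus.coords()
    r0 = max(0, rr.min() - ring_radius)
    r1 = min(shape[0], rr.max() + ring_radius + 1)
    c0 = max(0, cc.min() - ring_radius)
    c1 = min(shape[1], cc.max() + ring_radius + 1)
    crop = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    crop[rr - r0, cc - c0] = True
    dilated = ndimage.binary_dilation(crop, structure=disk(ring_radius))
    ring = dilated & ~crop
    ring_r, ring_c = np.nonzero(ring)
    return (rr, cc), (ring_r + r0, ring_c + c0)


def summarize_nucleus(
    maps: PixelFeatureMaps, nucleus: NucleusRecord, cfg: FeatureConfig | None = None
) -> NucleusFeatureVector:
    """Four statistics of every map over the nucleus and its ring."""
    cfg = cfg or FeatureConfig()
    if maps.image_id != nucleus.image_id:
        raise ValueError("feature maps and nucleus belong to different images")
    shape = next(iter(maps.per_channel["nuclear"].values())).shape
    (nr, nc), (gr, gc) = nucleus_regions(nucleus, shape, cfg.ring_radius)
    if gr.size == 0:
        warnings.warn(
            f"nucleus {nucleus.nucleus_id} in {nucleus.image_id} has an empty ring",
            stacklevel=2,
        )
    values: dict[str, float] = {}
    for role in CHANNEL_ROLES:
        for name, grid in maps.per_channel[role].items():
            for region, (ir, ic) in (("nucleus", (nr, nc)), ("ring", (gr, gc))):
                stats = _region_stats(grid[ir, ic])
                for stat in STATISTICS:
                    values[f"{role}.{name}.{region}.{stat}"] = stats[stat]
    return NucleusFeatureVector(
        nucleus_id=nucleus.nucleus_id, image_id=nucleus.image_id, values=values
    )


def scale_per_image(vectors: Sequence[NucleusFeatureVector]) -> list[NucleusFeatureVector]:
    """Standardize each descriptor column to zero mean, unit sample variance.

    Scaling uses only the nuclei of the one image the vectors belong to, so
    descriptors are comparable across images with different staining
    intensity.  Constant columns map to 0; with fewer than two nuclei every
    column is set to 0 (and a warning is issued) since no variance exists.
    """
    if not vectors:
        return []
    image_ids = {v.image_id for v in vectors}
    if len(image_ids) != 1:
        raise ValueError("scale_per_image expects vectors from a single image")
    names = list(vectors[0].values.keys())
    for v in vectors[1:]:
        if list(v.values.keys()) != names:
            raise ValueError("inconsistent feature ordering across vectors")
    mat = np.array([[v.values[n] for n in names] for v in vectors], dtype=float)
    if len(vectors) < 2:
        warnings.warn(
            f"image {vectors[0].image_id} has fewer than 2 nuclei; "
            "features set to 0",
            stacklevel=2,
        )
        scaled = np.zeros_like(mat)
    else:
        mean = mat.mean(axis=0)
        std = mat.std(axis=0, ddof=1)
        safe = np.where(std > 0, std, 1.0)
        scaled = (mat - mean) / safe
        scaled[:, std == 0] = 0.0
    return [
        NucleusFeatureVector(
            nucleus_id=v.nucleus_id,
            image_id=v.image_id,
            values=dict(zip(names, row)),
        )
        for v, row in zip(vectors, scaled)
    ]


def featurize_image(
    stack: ChannelStack,
    nuclei: Sequence[NucleusRecord],
    cfg: FeatureConfig | None = None,
    scale: bool = True,
) -> list[NucleusFeatureVector]:
    """Maps + per-nucleus summaries (+ per-image scaling) in one call."""
    cfg = cfg or FeatureConfig()
    maps = compute_feature_maps(stack, cfg)
    vectors = [summarize_nucleus(maps, n, cfg) for n in nuclei]
    return scale_per_image(vectors) if (scale and vectors) else vectors


def features_to_frame(vectors: Sequence[NucleusFeatureVector]) -> pd.DataFrame:
    """Feature table: nucleus_id, image_id, then one column per descriptor."""
    rows = [
        {"nucleus_id": v.nucleus_id, "image_id": v.image_id, **v.values}
        for v in vectors
    ]
    return pd.DataFrame(rows)


def frame_to_vectors(frame: pd.DataFrame) -> list[NucleusFeatureVector]:
    cols = [c for c in frame.columns if c not in ("nucleus_id", "image_id")]
    return [
        NucleusFeatureVector(
            nucleus_id=int(row["nucleus_id"]),
            image_id=str(row["image_id"]),
            values={c: float(row[c]) for c in cols},
        )
        for _, row in frame.iterrows()
    ]
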