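"""Seeded synthetic tissue scenes with known ground truth.

Real training data for this problem are fluorescence images of tissue in
which the target cell type (e.g. cardiomyocytes) shows a bright, striated
structural stain around its nuclei while interstitial cells sit in diffuse,
dimmer surroundings.  The generator emulates exactly the image properties
the pipeline exploits: elliptical nuclei in the nuclear channel, sinusoidal
striation painted in disks around target nuclei in the structural channel,
a diffuse extracellular background, marker signal over a chosen subset of
nuclei, a smooth multiplicative illumination gain over all channels, and
additive Gaussian noise.  All randomness flows from the seed, so scenes are
byte-reproducible.

Default parameters define the standard study conditions used throughout the
tests: 8 images of 384x384 px with ~150 nuclei each, 30% of them targets,
20% of targets (5% of others) marker-positive, strong striation contrast,
noise sigma 0.03 and a 0.5-strength linear illumination ramp.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import ChannelStack


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene; defaults are the study conditions."""

    height: int = 384
    width: int = 384
    n_target_nuclei: int = 45
    n_other_nuclei: int = 105
    nucleus_radius_range: tuple[float, float] = (3.0, 6.0)
    nucleus_aspect_range: tuple[float, float] = (1.0, 2.0)
    nucleus_intensity: float = 1.0
    nuclear_background_level: float = 0.0  # DAPI off-nucleus signal is ~black
    stripe_period: float = 6.0
    stripe_amplitude: float = 0.9
    stripe_orientation_jitter: float = 0.3  # radians
    striation_disk_radius: float = 20.0
    interstitial_background_level: float = 0.5
    diffuse_texture_amplitude: float = 0.1
    diffuse_texture_sigma: float = 3.0
    marker_positive_fraction_target: float = 0.20
    marker_positive_fraction_other: float = 0.05
    illumination_gain: str = "none"  # none | linear | vignette
    gain_strength: float = 0.5
    noise_sigma: float = 0.03
    min_center_separation: float = 13.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_target_nuclei < 0 or self.n_other_nuclei < 0:
            raise ValueError("nucleus counts must be >= 0")
        if self.nucleus_radius_range[0] < 2:
            raise ValueError("nucleus radii below 2 px do not survive the area filter")
        for f in (self.marker_positive_fraction_target, self.marker_positive_fraction_other):
            if not 0.0 <= f <= 1.0:
                raise ValueError("marker fractions must be in [0, 1]")
        if self.illumination_gain not in ("none", "linear", "vignette"):
            raise ValueError("illumination_gain must be none, linear or vignette")


@dataclass(frozen=True)
class TruthNucleus:
    center: tuple[float, float]  # (row, col)
    radius: float  # semi-major axis
    is_target: bool
    is_marker_positive: bool


@dataclass
class SyntheticScene:
    stack: ChannelStack
    truth: list[TruthNucleus]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": self.stack.image_id,
                "row": [t.center[0] for t in self.truth],
                "col": [t.center[1] for t in self.truth],
                "radius": [t.radius for t in self.truth],
                "is_target": [t.is_target for t in self.truth],
                "is_marker_positive": [t.is_marker_positive for t in self.truth],
            }
        )


def _place_centers(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_target_nuclei + spec.n_other_nuclei
    margin = spec.nucleus_radius_range[1] + 2.0
    lo = (margin, margin)
    hi = (spec.height - margin, spec.width - margin)
    if hi[0] <= lo[0] or hi[1] <= lo[1]:
        raise ValueError("field too small for the nucleus radii")
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 400 * max(n, 1)
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} nuclei with separation "
                f"{spec.min_center_separation} in a {spec.height}x{spec.width} field"
            )
        r = rng.uniform(lo[0], hi[0])
        c = rng.uniform(lo[1], hi[1])
        if all(
            np.hypot(r - rr, c - cc) >= spec.min_center_separation
            for rr, cc in centers
        ):
            centers.append((r, c))
    return np.asarray(centers)


def _paint_ellipse(
    grid: np.ndarray,
    center: tuple[float, float],
    a: float,
    b: float,
    angle: float,
    value: float,
) -> None:
    r0, c0 = center
    rad = int(np.ceil(a)) + 1
    rmin, rmax = max(0, int(r0) - rad), min(grid.shape[0], int(r0) + rad + 1)
    cmin, cmax = max(0, int(c0) - rad), min(grid.shape[1], int(c0) + rad + 1)
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    dr, dc = rr - r0, cc - c0
    u = np.cos(angle) * dc + np.sin(angle) * dr
    v = -np.sin(angle) * dc + np.cos(angle) * dr
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    patch = grid[rmin:rmax, cmin:cmax]
    patch[inside] = np.maximum(patch[inside], value)


def _gain_field(spec: SceneSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    if spec.illumination_gain == "none":
        return np.ones((h, w))
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    s = spec.gain_strength
    if spec.illumination_gain == "linear":
        return 1.0 + s * (cc / (w - 1) - 0.5)
    # radial vignette: brightest at the center, dimming toward corners
    d2 = ((rr - (h - 1) / 2) ** 2 + (cc - (w - 1) / 2) ** 2)
    return 1.0 + s * (0.5 - d2 / d2.max())


def generate_scene(spec: SceneSpec, image_id: str | None = None) -> SyntheticScene:
    """Render one scene; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_target_nuclei + spec.n_other_nuclei
    centers = _place_centers(spec, rng)
    is_target = np.zeros(n_total, dtype=bool)
    is_target[rng.permutation(n_total)[: spec.n_target_nuclei]] = True

    # marker positives: exact planted counts within each class
    marker = np.zeros(n_total, dtype=bool)
    for cls, frac in ((True, spec.marker_positive_fraction_target),
                      (False, spec.marker_positive_fraction_other)):
        idx = np.nonzero(is_target == cls)[0]
        n_pos = int(round(frac * idx.size))
        marker[rng.choice(idx, size=n_pos, replace=False)] = True

    h, w = spec.height, spec.width
    nuclear = np.full((h, w), spec.nuclear_background_level)
    # diffuse interstitial staining: dim but nonzero, with smooth mottle so
    # the background estimate stays well-conditioned everywhere
    structural = np.full((h, w), spec.interstitial_background_level)
    if spec.diffuse_texture_amplitude > 0:
        from scipy import ndimage

        mottle = ndimage.gaussian_filter(
            rng.standard_normal((h, w)), spec.diffuse_texture_sigma
        )
        mottle /= max(np.abs(mottle).max(), 1e-12)
        structural = structural + spec.diffuse_texture_amplitude * mottle
        structural = np.clip(structural, 0.05, None)
    marker_chan = np.full((h, w), 0.03)

    truth: list[TruthNucleus] = []
    rr_grid, cc_grid = np.mgrid[0:h, 0:w].astype(float)
    for i in range(n_total):
        a = rng.uniform(*spec.nucleus_radius_range)
        aspect = rng.uniform(*spec.nucleus_aspect_range)
        b = a / aspect
        angle = rng.uniform(0, np.pi)
        value = spec.nucleus_intensity * rng.uniform(0.85, 1.15)
        _paint_ellipse(nuclear, tuple(centers[i]), a, b, angle, value)
        if marker[i]:
            _paint_ellipse(marker_chan, tuple(centers[i]), a, b, angle,
                           rng.uniform(0.9, 1.1))
        if is_target[i]:
            phi = rng.uniform(0, np.pi) if spec.stripe_orientation_jitter > 0 else 0.0
            r0, c0 = centers[i]
            rad = spec.striation_disk_radius
            rmin, rmax_ = max(0, int(r0 - rad)), min(h, int(r0 + rad) + 1)
            cmin, cmax_ = max(0, int(c0 - rad)), min(w, int(c0 + rad) + 1)
            dr = rr_grid[rmin:rmax_, cmin:cmax_] - r0
            dc = cc_grid[rmin:rmax_, cmin:cmax_] - c0
            disk = dr**2 + dc**2 <= rad**2
            u = np.cos(phi) * dc + np.sin(phi) * dr
            stripes = spec.interstitial_background_level + spec.stripe_amplitude * (
                0.5 + 0.5 * np.sin(2 * np.pi * u / spec.stripe_period)
            )
            patch = structural[rmin:rmax_, cmin:cmax_]
            patch[disk] = np.maximum(patch[disk], stripes[disk])
        truth.append(
            TruthNucleus(
                center=(float(centers[i][0]), float(centers[i][1])),
                radius=float(a),
                is_target=bool(is_target[i]),
                is_marker_positive=bool(marker[i]),
            )
        )

    gain = _gain_field(spec)
    channels = []
    for chan in (nuclear, structural, marker_chan):
        out = chan * gain
        if spec.noise_sigma > 0:
            out = out + rng.normal(0.0, spec.noise_sigma, size=out.shape)
        channels.append(np.clip(out, 0.0, None))

    stack = ChannelStack(
        image_id=image_id or f"scene_seed{spec.seed}",
        nuclear=channels[0],
        structural=channels[1],
        marker=channels[2],
        corrected=False,
    )
    return SyntheticScene(stack=stack, truth=truth)


@dataclass
class RaterSimConfig:
    """Hit/false-alarm model of a human rater dotting target nuclei."""

    n_raters: int = 4
    hit_rate: float = 0.9
    fp_rate: float = 0.05
    jitter_sigma: float = 2.0  # px, on dot placement around the true center


@dataclass
class SyntheticDataset:
    scenes: list[SyntheticScene]
    rater_dots: dict[str, dict[str, list[tuple[float, float]]]]
    """rater id -> image id -> dot list"""

    def truth_frame(self) -> pd.DataFrame:
        return pd.concat([s.truth_frame() for s in self.scenes], ignore_index=True)


def generate_dataset(
    spec: SceneSpec | None = None,
    n_images: int = 8,
    base_seed: int = 0,
    rater_cfg: RaterSimConfig | None = None,
) -> SyntheticDataset:
    """A multi-image dataset with simulated rater annotations.

    Image ``i`` uses seed ``base_seed + i``; raters dot each true target
    with probability ``hit_rate`` (jittered around the true center) and dot
    each non-target with probability ``fp_rate``.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images (leave-image-out requires it)")
    spec = spec or SceneSpec()
    rater_cfg = rater_cfg or RaterSimConfig()
    scenes = [
        generate_scene(replace(spec, seed=base_seed + i), image_id=f"img{i:03d}")
        for i in range(n_images)
    ]
    rater_dots: dict[str, dict[str, list[tuple[float, float]]]] = {}
    rater_rng = np.random.default_rng(base_seed + 990_001)
    for j in range(rater_cfg.n_raters):
        rid = f"rater{j + 1}"
        rater_dots[rid] = {}
        for scene in scenes:
            dots: list[tuple[float, float]] = []
            for t in scene.truth:
                p = rater_cfg.hit_rate if t.is_target else rater_cfg.fp_rate
                if rater_rng.random() < p:
                    jitter = rater_rng.normal(0, rater_cfg.jitter_sigma, 2)
                    dots.append((t.center[0] + jitter[0], t.center[1] + jitter[1]))
            rater_dots[rid][scene.stack.image_id] = dots
    return SyntheticDataset(scenes=scenes, rater_dots=rater_dots)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path, spec: SceneSpec) -> None:
    """Per-image 3-channel TIFF + truth CSV + rater dot CSVs + spec JSON."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for scene in dataset.scenes:
        stack = scene.stack
        tifffile.imwrite(
            out / f"{stack.image_id}.tif",
            np.stack([stack.nuclear, stack.structural, stack.marker]).astype(
                np.float32
            ),
            photometric="minisblack",
        )
    dataset.truth_frame().to_csv(out / "truth.csv", index=False)
    for rid, per_image in dataset.rater_dots.items():
        rows = [
            {"image_id": image_id, "row": r, "col": c}
            for image_id, dots in per_image.items()
            for r, c in dots
        ]
        pd.DataFrame(rows, columns=["image_id", "row", "col"]).to_csv(
            out / f"dots_{rid}.csv", index=False
        )
    (out / "scene_spec.json").write_text(json.dumps(asdict(spec), indent=1))
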