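"""Image loading, illumination correction and nucleus segmentation.

Tissue sections are imaged in up to three fluorescence channels: a nuclear
stain (DAPI-like, "blue"), a structural stain marking the cytoplasm of the
target cell type (alpha-actin/tropomyosin-like, "red") and an optional
marker stain (EdU/TUNEL-like, "green").  Confocal images carry a smooth
multiplicative illumination gradient; it is removed by dividing every
channel by a heavily blurred version of the structural channel, which acts
as a local background estimate.  Nuclei are then segmented from the
corrected nuclear channel as connected components above an Otsu threshold,
discarding specks below a minimum area.

Coordinates are 0-based (row, col) with the origin at the top-left pixel
center; all lengths are in pixels.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label


@dataclass
class PreprocessConfig:
    """Parameters of illumination correction and nucleus segmentation.

    Attributes
    ----------
    background_sigma : float
        Standard deviation, in pixels, of the Gaussian used to estimate the
        local background from the structural channel (default 10).
    min_nucleus_area : int
        Connected components with area strictly below this many pixels are
        discarded as noise (default 5: area 4 removed, area 5 kept).
    connectivity : int
        Pixel connectivity for component labeling, 4 or 8 (default 8).
    background_floor_epsilon : float
        The background is floored at ``epsilon * max(background)`` before
        division; pixels at or below the floor are set to 0.
    """

    background_sigma: float = 10.0
    min_nucleus_area: int = 5
    connectivity: int = 8
    background_floor_epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if self.background_sigma <= 0:
            raise ValueError("background_sigma must be > 0")
        if self.min_nucleus_area < 1:
            raise ValueError("min_nucleus_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class ChannelStack:
    """A registered set of 2-D intensity grids for one image."""

    image_id: str
    nuclear: np.ndarray
    structural: np.ndarray
    marker: np.ndarray | None = None
    corrected: bool = False

    def __post_init__(self) -> None:
        self.nuclear = np.asarray(self.nuclear, dtype=float)
        self.structural = np.asarray(self.structural, dtype=float)
        if self.marker is not None:
            self.marker = np.asarray(self.marker, dtype=float)
        shapes = {self.nuclear.shape, self.structural.shape}
        if self.marker is not None:
            shapes.add(self.marker.shape)
        if len(shapes) != 1:
            raise ValueError(f"channels of mismatched shape: {shapes}")
        if self.nuclear.ndim != 2:
            raise ValueError("channels must be 2-D")
        for name in ("nuclear", "structural", "marker"):
            ch = getattr(self, name)
            if ch is not None and np.any(ch < 0):
                raise ValueError(f"{name} channel has negative intensities")

    @property
    def height(self) -> int:
        return self.nuclear.shape[0]

    @property
    def width(self) -> int:
        return self.nuclear.shape[1]

    def channels(self) -> dict[str, np.ndarray]:
        out = {"nuclear": self.nuclear, "structural": self.structural}
        if self.marker is not None:
            out["marker"] = self.marker
        return out


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus: id, pixel set, area and centroid."""

    nucleus_id: int
    image_id: str
    pixels: frozenset[tuple[int, int]]
    area: int
    centroid: tuple[float, float]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of this nucleus on a grid of the given shape."""
        m = np.zeros(shape, dtype=bool)
        rr, cc = self.coords()
        m[rr, cc] = True
        return m

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel coordinates as (rows, cols) integer arrays, sorted."""
        pts = sorted(self.pixels)
        arr = np.asarray(pts, dtype=int).reshape(-1, 2)
        return arr[:, 0], arr[:, 1]


def read_image(
    path: str | Path, channel_map: Mapping[str, int], image_id: str | None = None
) -> ChannelStack:
    """Read a multi-channel TIFF or PNG into a :class:`ChannelStack`.

    ``channel_map`` assigns channel roles to indices, e.g.
    ``{"nuclear": 2, "structural": 0, "marker": 1}`` for an RGB image with
    blue nuclei, red structure and green marker.  The ``marker`` role is
    optional.  Multi-page TIFFs are read as (channel, H, W); RGB images as
    (H, W, channel).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if "nuclear" not in channel_map or "structural" not in channel_map:
        raise ValueError("channel_map must name 'nuclear' and 'structural' roles")

    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = np.asarray(tifffile.imread(str(path)))
    else:
        import imageio.v3 as iio

        data = np.asarray(iio.imread(str(path)))

    if data.ndim == 2:
        data = data[None, :, :]
    elif data.ndim == 3 and data.shape[-1] <= 4 and data.shape[0] > 4:
        # (H, W, C) interleaved -> (C, H, W)
        data = np.moveaxis(data, -1, 0)
    elif data.ndim != 3:
        raise ValueError(f"unsupported image dimensionality: {data.shape}")

    n_channels = data.shape[0]

    def pick(role: str) -> np.ndarray:
        idx = channel_map[role]
        if not 0 <= idx < n_channels:
            raise IndexError(
                f"channel index {idx} for role '{role}' out of range "
                f"(image has {n_channels} channels)"
            )
        return data[idx].astype(float)

    marker = pick("marker") if "marker" in channel_map else None
    return ChannelStack(
        image_id=image_id or path.stem,
        nuclear=pick("nuclear"),
        structural=pick("structural"),
        marker=marker,
        corrected=False,
    )


def correct_illumination(
    stack: ChannelStack, cfg: PreprocessConfig | None = None
) -> ChannelStack:
    """Divide every channel by the blurred structural channel.

    The local background is a Gaussian blur (``background_sigma``,
    reflective boundary) of the structural channel; each channel is divided
    by it pixelwise.  The background is floored at
    ``epsilon * max(background)``; pixels at or below the floor (dead
    regions) are output as 0.  A constant image therefore maps to the
    constant 1 in the channel used for background estimation.
    """
    cfg = cfg or PreprocessConfig()
    if stack.corrected:
        raise ValueError("stack is already corrected")
    if not np.any(stack.structural > 0):
        raise ValueError(
            "structural channel is identically zero: no background estimable"
        )
    background = ndimage.gaussian_filter(
        stack.structural, sigma=cfg.background_sigma, mode="reflect"
    )
    floor = cfg.background_floor_epsilon * background.max()
    dead = background <= floor
    denom = np.where(dead, 1.0, background)

    def div(ch: np.ndarray | None) -> np.ndarray | None:
        if ch is None:
            return None
        out = ch / denom
        out[dead] = 0.0
        return out

    return ChannelStack(
        image_id=stack.image_id,
        nuclear=div(stack.nuclear),
        structural=div(stack.structural),
        marker=div(stack.marker),
        corrected=True,
    )


def _label_binary(mask: np.ndarray, connectivity: int) -> np.ndarray:
    # skimage connectivity: 1 -> 4-neighborhood, 2 -> 8-neighborhood
    return cc_label(mask, connectivity=1 if connectivity == 4 else 2)


def segment_nuclei(
    stack: ChannelStack, cfg: PreprocessConfig | None = None
) -> list[NucleusRecord]:
    """Segment candidate nuclei from the corrected nuclear channel.

    The nuclear channel is binarized by Otsu's threshold, connected
    components are labeled at the configured connectivity, components with
    area strictly below ``min_nucleus_area`` are discarded, and records are
    returned sorted by centroid (row, then col) with ids consecutive from 1.
    """
    cfg = cfg or PreprocessConfig()
    if not stack.corrected:
        raise ValueError("stack must be illumination-corrected before segmentation")
    chan = stack.nuclear
    if np.ptp(chan) == 0:
        return []
    mask = chan >= threshold_otsu(chan)
    labels = _label_binary(mask, cfg.connectivity)
    records: list[NucleusRecord] = []
    for lab in range(1, labels.max() + 1):
        rr, cc = np.nonzero(labels == lab)
        area = rr.size
        if area < cfg.min_nucleus_area:
            continue
        records.append(
            NucleusRecord(
                nucleus_id=0,
                image_id=stack.image_id,
                pixels=frozenset(zip(rr.tolist(), cc.tolist())),
                area=int(area),
                centroid=(float(rr.mean()), float(cc.mean())),
            )
        )
    records.sort(key=lambda r: r.centroid)
    return [dataclasses.replace(r, nucleus_id=i + 1) for i, r in enumerate(records)]


def nuclei_to_frame(nuclei: Sequence[NucleusRecord]) -> pd.DataFrame:
    """Nuclei table with columns nucleus_id,image_id,row,col,area."""
    return pd.DataFrame(
        {
            "nucleus_id": [n.nucleus_id for n in nuclei],
            "image_id": [n.image_id for n in nuclei],
            "row": [round(n.centroid[0], 3) for n in nuclei],
            "col": [round(n.centroid[1], 3) for n in nuclei],
            "area": [n.area for n in nuclei],
        }
    )


def write_nuclei_csv(nuclei: Sequence[NucleusRecord], path: str | Path) -> None:
    nuclei_to_frame(nuclei).to_csv(path, index=False)
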