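"""Bright-field segmentation: binarize, clean, size-gate and crop worms.

Worms appear darker than the agarose background, so a pixel is called
foreground when its intensity falls below ``(1 - threshold)`` times the
local mean over a square neighborhood.  Connected components are then
cleaned (small objects, edge-touchers, interior holes, jagged boundaries)
and retained only when their area is plausible for a single worm relative
to the other objects on the plate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import sobel

from .config import ThresholdParams
from .io import PlateImage

# 8-connectivity structuring element, matching the regionprops convention.
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class ComponentRecord:
    """One connected component surviving the size gate."""

    area: int
    bbox: tuple[int, int, int, int]  # (row, col, height, width), 0-based half-open
    label: int


@dataclass
class WormCrop:
    """A single worm's binary mask plus aligned raw channel crops.

    The crop is padded by one background pixel on all sides, so the mask
    never touches its own border; pixels of neighbouring worms that fall
    inside the bounding box are zeroed out of the mask.
    """

    mask: np.ndarray
    channel_crops: dict[str, np.ndarray]
    bbox: tuple[int, int, int, int]
    worm_index: int
    source_image: str = ""
    #: Sobel edge magnitude of the BF crop, kept for visualization only —
    #: no feature depends on it.
    edge_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("worm crop mask is empty")
        border = np.concatenate(
            [self.mask[0], self.mask[-1], self.mask[:, 0], self.mask[:, -1]]
        )
        if border.any():
            raise ValueError("worm mask touches its crop border; padding missing")
        for ch, arr in self.channel_crops.items():
            if arr.shape != self.mask.shape:
                raise ValueError(f"channel {ch!r} crop shape {arr.shape} != mask {self.mask.shape}")


def adaptive_threshold(bf: np.ndarray, params: ThresholdParams) -> np.ndarray:
    """Local-mean adaptive thresholding of a [0, 1] bright-field image.

    Foreground (1) where ``intensity < (1 - threshold) * local_mean`` with
    the local mean taken over the ``neighborhood`` square (replicate-padded
    at the borders, integral-image implementation).  With
    ``invert_polarity`` the comparison flips for bright worms on a dark
    field.
    """
    bf = np.asarray(bf, dtype=np.float64)
    n = params.neighborhood
    if n > min(bf.shape):
        raise ValueError(f"neighborhood {n} exceeds image size {bf.shape}")
    local_mean = ndimage.uniform_filter(bf, size=n, mode="nearest")
    if params.invert_polarity:
        mask = (1.0 - bf) < (1.0 - params.threshold) * (1.0 - local_mean)
    else:
        mask = bf < (1.0 - params.threshold) * local_mean
    return mask


def _remove_small_and_border(mask: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_CONN8)
    if n == 0:
        return mask.astype(bool)
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    border_labels = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    keep[border_labels] = False
    return keep[labels]


def _majority_smooth(mask: np.ndarray, max_iter: int = 10) -> np.ndarray:
    """Iterate a 3x3 majority filter to a fixed point (boundary de-jagging)."""
    current = mask.astype(bool)
    for _ in range(max_iter):
        counts = ndimage.convolve(current.astype(np.uint8), np.ones((3, 3), np.uint8), mode="constant")
        smoothed = counts >= 5
        if np.array_equal(smoothed, current):
            break
        current = smoothed
    return current


def clean_mask(mask: np.ndarray, params: ThresholdParams) -> np.ndarray:
    """Remove implausible objects and tidy the survivors.

    Deletes components (8-connected) smaller than ``min_object_area`` and
    any component touching an image edge (unlikely to be a whole worm),
    fills interior holes, and majority-smooths boundaries.  The pass is
    iterated to a fixed point, so the operation is idempotent.
    """
    current = np.asarray(mask).astype(bool)
    for _ in range(10):
        step = _remove_small_and_border(current, params.min_object_area)
        step = ndimage.binary_fill_holes(step)
        step = _majority_smooth(step)
        if np.array_equal(step, current):
            break
        current = step
    return current


def segment_worms(mask: np.ndarray, params: ThresholdParams) -> list[ComponentRecord]:
    """Label a cleaned mask and retain worm-sized components.

    A component counts as a worm when its area lies within
    ``area_range × median(component areas)`` of the same image.  Records are
    sorted by bounding-box origin (row, then column) so worm numbering is
    deterministic.
    """
    labels, n = ndimage.label(np.asarray(mask).astype(bool), structure=_CONN8)
    if n == 0:
        return []
    slices = ndimage.find_objects(labels)
    areas = np.bincount(labels.ravel())[1:]
    median_area = float(np.median(areas))
    lo, hi = params.area_range
    records = []
    for lab, (sl, area) in enumerate(zip(slices, areas), start=1):
        if not lo * median_area <= area <= hi * median_area:
            continue
        r, c = sl[0].start, sl[1].start
        records.append(
            ComponentRecord(
                area=int(area),
                bbox=(r, c, sl[0].stop - r, sl[1].stop - c),
                label=lab,
            )
        )
    records.sort(key=lambda rec: (rec.bbox[0], rec.bbox[1]))
    return records


def crop_worms(
    image: PlateImage,
    mask: np.ndarray,
    components: list[ComponentRecord],
    *,
    start_index: int = 0,
) -> list[WormCrop]:
    """Cut each retained component into its own :class:`WormCrop`.

    Crops extend one background pixel beyond the bounding box on every side;
    the channel crops are sliced from the raw (unstretched) channels so that
    fluorescence quantification is unaffected by detection-time stretching.
    """
    labels, _ = ndimage.label(np.asarray(mask).astype(bool), structure=_CONN8)
    crops = []
    for k, rec in enumerate(components):
        r, c, h, w = rec.bbox
        r0, c0 = r - 1, c - 1
        r1, c1 = r + h + 1, c + w + 1
        # Edge-touching components were removed in cleaning, so the padded
        # window stays inside the image.
        crop_mask = labels[r0:r1, c0:c1] == rec.label
        channel_crops = {ch: arr[r0:r1, c0:c1].copy() for ch, arr in image.channels.items()}
        crops.append(
            WormCrop(
                mask=crop_mask,
                channel_crops=channel_crops,
                bbox=(r0, c0, r1 - r0, c1 - c0),
                worm_index=start_index + k,
                source_image=image.source_path,
                edge_map=sobel(channel_crops["BF"]),
            )
        )
    return crops
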