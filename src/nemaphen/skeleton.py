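"""Worm midline extraction: thinning plus median-filter debranching.

A worm mask is thinned to a one-pixel line.  Jagged or disfigured masks
thin to branched skeletons; those are resolved by median-filtering a
*temporary copy* of the mask (15x15 window) and re-thinning, up to five
attempts.  The original mask is never modified — area and width
measurements always use it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import thin

_CONN8 = np.ones((3, 3), dtype=bool)
_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)

#: Median-filter window used for debranching, and the attempt cap.
DEBRANCH_WINDOW = 15
MAX_SMOOTHING_ATTEMPTS = 5


@dataclass
class Skeleton:
    """Ordered one-pixel midline of a worm mask.

    ``path`` holds (row, col) skeleton pixels ordered from end A to end B
    when the skeleton is continuous (exactly two endpoints, no branch
    points); otherwise it holds the unordered pixel set of the final
    thinning attempt.
    """

    path: np.ndarray
    branch_point_count: int
    smoothing_attempts: int
    continuous: bool
    endpoints: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def __len__(self) -> int:
        return len(self.path)

    @property
    def n_pixels(self) -> int:
        return len(self.path)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")


def branch_points(skel: np.ndarray) -> np.ndarray:
    """(row, col) array of skeleton pixels with more than two neighbors."""
    counts = _neighbor_counts(skel)
    return np.argwhere(skel & (counts > 2))


def endpoints(skel: np.ndarray) -> np.ndarray:
    """(row, col) array of skeleton pixels with exactly one neighbor."""
    counts = _neighbor_counts(skel)
    return np.argwhere(skel & (counts == 1))


def _trace_path(skel: np.ndarray, start: tuple[int, int]) -> np.ndarray:
    """Walk an unbranched skeleton from one endpoint to the other."""
    visited = np.zeros_like(skel, dtype=bool)
    path = [start]
    visited[start] = True
    r, c = start
    while True:
        nxt = None
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1]:
                    if skel[rr, cc] and not visited[rr, cc]:
                        nxt = (rr, cc)
                        break
            if nxt:
                break
        if nxt is None:
            break
        visited[nxt] = True
        path.append(nxt)
        r, c = nxt
    return np.array(path, dtype=int)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_CONN8)
    if n <= 1:
        return mask
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    return labels == int(np.argmax(areas))


def skeletonize_debranch(mask: np.ndarray) -> Skeleton:
    """Thin a single-worm mask to an ordered midline, debranching as needed.

    While branch points remain and fewer than five attempts were made, a
    15x15 median filter is applied to a temporary copy of the mask and the
    copy is re-thinned.  ``continuous`` is true when the final skeleton has
    exactly two endpoints and no branch points; a closed loop (zero
    endpoints) is therefore never continuous.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot skeletonize an empty mask")

    work = mask.copy()
    attempts = 0
    skel = thin(work)
    while len(branch_points(skel)) > 0 and attempts < MAX_SMOOTHING_ATTEMPTS:
        attempts += 1
        work = ndimage.median_filter(
            work.astype(np.uint8), size=DEBRANCH_WINDOW, mode="constant"
        ).astype(bool)
        work = _largest_component(work)
        if not work.any():
            break
        skel = thin(work)

    bp = branch_points(skel)
    ep = endpoints(skel)
    continuous = len(bp) == 0 and len(ep) == 2

    if continuous:
        # Deterministic orientation: start from the lexicographically
        # smaller endpoint.
        order = np.lexsort((ep[:, 1], ep[:, 0]))
        start = tuple(ep[order[0]])
        path = _trace_path(skel, start)
        if len(path) != int(skel.sum()):  # disconnected fragments remain
            continuous = False
            path = np.argwhere(skel)
    else:
        path = np.argwhere(skel)

    return Skeleton(
        path=path,
        branch_point_count=len(bp),
        smoothing_attempts=attempts,
        continuous=continuous,
        endpoints=ep,
    )
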