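"""Morphological features of a single worm: size, midline widths, end profiles.

All size features derive from the mask pixel count and the skeleton pixel
count scaled by the physical pixel size (square pixels assumed); thickness
is defined as area/length, so ``thickness x length == area`` holds exactly.
Cross-section widths are measured by walking the local normal of the
midline through the mask at subpixel steps.

The two skeleton ends are profiled for the head/tail decision: worm heads
are brighter in bright field, and male tails show a characteristic
thick-then-slim diameter signature captured by the D1/D2 ratio (thickest
section near the end over slimmest section just interior to it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .skeleton import Skeleton, skeletonize_debranch

#: Skeletons shorter than this (pixels) cannot support the end-window scan.
MIN_SKELETON_PX = 30

#: Half-window (skeleton steps) of the local tangent fit.
TANGENT_HALF_WINDOW = 5

#: Subpixel step (pixels) when walking the cross-section normal.
NORMAL_STEP = 0.25


@dataclass
class CrossSection:
    position: int
    width_px: float


@dataclass
class EndProfile:
    """Diameter and brightness profile of one skeleton end (A or B)."""

    end: str
    d1_px: float
    d1_position: int
    d2_px: float
    ratio: float
    bf_brightness: float = math.nan


@dataclass
class MorphRecord:
    """One worm's morphological feature vector (micrometre units)."""

    area_um2: float = math.nan
    length_um: float = math.nan
    thickness_um: float = math.nan
    midwidth_um: float = math.nan
    head_bf: float = math.nan
    tail_bf: float = math.nan
    head_ratio: float = math.nan
    tail_ratio: float = math.nan
    head_end: str = ""
    head_confidence: float = math.nan
    flags: set[str] = field(default_factory=set)


def area(mask: np.ndarray, pixel_height_um: float, pixel_width_um: float) -> float:
    """Worm area: foreground pixel count times the physical pixel area."""
    return float(np.count_nonzero(mask)) * pixel_height_um * pixel_width_um


def skeleton_length(
    skeleton: Skeleton, pixel_height_um: float, *, euclidean: bool = False
) -> float:
    """Worm length from the midline.

    Default metric is the skeleton pixel count times the pixel size, which
    undercounts diagonal runs by up to sqrt(2); ``euclidean=True`` instead
    sums the chain distances between consecutive path pixels.
    """
    if not skeleton.continuous:
        raise ValueError("length requires a continuous skeleton")
    if euclidean:
        # The raw thinned path staircases around the true midline, which
        # inflates chain length; a short moving average removes the jitter.
        path = skeleton.path.astype(float)
        if len(path) > 5:
            kernel = np.ones(5) / 5.0
            smoothed = np.column_stack(
                [np.convolve(path[:, j], kernel, mode="valid") for j in (0, 1)]
            )
            path = np.vstack([path[:1], smoothed, path[-1:]])
        diffs = np.diff(path, axis=0)
        return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum()) * pixel_height_um
    return float(len(skeleton.path)) * pixel_height_um


def thickness(area_um2: float, length_um: float) -> float:
    """Mean body thickness defined as area over length."""
    if length_um <= 0:
        raise ValueError("thickness requires positive length")
    return area_um2 / length_um


def _tangent_at(path: np.ndarray, idx: int) -> np.ndarray:
    """Unit tangent by principal axis of the path pixels within +-5 steps."""
    lo = max(0, idx - TANGENT_HALF_WINDOW)
    hi = min(len(path), idx + TANGENT_HALF_WINDOW + 1)
    pts = path[lo:hi].astype(float)
    centered = pts - pts.mean(axis=0)
    # Principal axis of the 2x2 scatter matrix; robust to vertical runs.
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    return v[:, np.argmax(w)]


def _walk_normal(mask: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> float:
    """Distance travelled from ``origin`` along ``direction`` while inside the mask."""
    h, wd = mask.shape
    t = NORMAL_STEP
    last_inside = 0.0
    while True:
        r = int(round(origin[0] + t * direction[0]))
        c = int(round(origin[1] + t * direction[1]))
        if not (0 <= r < h and 0 <= c < wd) or not mask[r, c]:
            break
        last_inside = t
        t += NORMAL_STEP
    return last_inside


def cross_section_width(mask: np.ndarray, skeleton: Skeleton, position: int) -> CrossSection:
    """Width of the worm along the normal through one skeleton pixel.

    The local tangent comes from a least-squares (principal-axis) fit over
    skeleton pixels within five arc steps; the normal is walked in both
    directions at quarter-pixel steps and the width is the traversed
    distance plus the centre pixel's own extent.
    """
    if not skeleton.continuous:
        raise ValueError("cross sections require a continuous skeleton")
    if not 0 <= position < len(skeleton.path):
        raise ValueError(f"position {position} outside skeleton of length {len(skeleton.path)}")
    tangent = _tangent_at(skeleton.path, position)
    normal = np.array([-tangent[1], tangent[0]])
    origin = skeleton.path[position].astype(float)
    # The traversed distance on each side reaches the half-pixel boundary of
    # the outermost mask pixel, so the two legs together span the full width.
    width = _walk_normal(mask, origin, normal) + _walk_normal(mask, origin, -normal)
    return CrossSection(position=position, width_px=float(width))


def midwidth(mask: np.ndarray, skeleton: Skeleton, pixel_height_um: float) -> float:
    """Cross-section width at the arc-length midpoint, in micrometres."""
    mid = len(skeleton.path) // 2
    return cross_section_width(mask, skeleton, mid).width_px * pixel_height_um


def diameter_ratio_from_widths(widths_from_end: np.ndarray, *, d1_offset_px: int = 10,
                               d2_offset_px: int = 20) -> tuple[float, int, float, float]:
    """Apply the two-window diameter-ratio rule to a width profile.

    ``widths_from_end[d]`` is the cross-section width ``d`` skeleton pixels
    from the end.  D1 is the *largest* width between ``d1_offset_px`` pixels
    and 10% of the worm length from the end; when the maximum sits exactly
    on the 10% boundary (a still-thickening profile), D1 is instead re-read
    at 2.5% of the length.  D2 is the *smallest* width between 20 pixels
    past D1's location and 20% of the length.  The ratio D1/D2 is large for
    bulb-then-taper (male-like) tails and near 1 for smooth tapers.

    Returns ``(d1, d1_position, d2, ratio)``.

    Raises
    ------
    ValueError
        If either search window is empty for this profile length.
    """
    widths = np.asarray(widths_from_end, dtype=float)
    length = len(widths)
    h1 = int(round(0.10 * length))
    if h1 < d1_offset_px:
        raise ValueError("worm too short: empty D1 window")
    window = widths[d1_offset_px : h1 + 1]
    arg = int(np.argmax(window))
    d1_pos = d1_offset_px + arg
    d1 = float(window[arg])
    if d1_pos == h1:
        fallback = int(round(0.025 * length))
        d1 = float(widths[fallback])
    lo2 = d1_pos + d2_offset_px
    h2 = int(round(0.20 * length))
    h2 = min(h2, length - 1)
    if lo2 > h2:
        raise ValueError("worm too short: empty D2 window")
    d2 = float(np.min(widths[lo2 : h2 + 1]))
    ratio = d1 / d2
    return d1, d1_pos, d2, ratio


def end_diameter_profile(mask: np.ndarray, skeleton: Skeleton, end: str) -> EndProfile:
    """Measure the D1/D2 diameter profile of skeleton end ``"A"`` or ``"B"``.

    Cross-section widths are measured along the skeleton walking inward
    from the chosen end, then fed to :func:`diameter_ratio_from_widths`.
    """
    if end not in ("A", "B"):
        raise ValueError("end must be 'A' or 'B'")
    if not skeleton.continuous:
        raise ValueError("end profiles require a continuous skeleton")
    length = len(skeleton.path)
    if length < MIN_SKELETON_PX:
        raise ValueError(f"skeleton of {length} px is too short to profile")
    indices = range(length) if end == "A" else range(length - 1, -1, -1)
    index_from_end = list(indices)
    h2 = min(int(round(0.20 * length)), length - 1)
    widths = np.empty(length)
    widths.fill(np.nan)
    for d in range(h2 + 1):  # the rule never reads past 20% of arc length
        widths[d] = cross_section_width(mask, skeleton, index_from_end[d]).width_px
    d1, d1_pos, d2, ratio = diameter_ratio_from_widths(widths)
    return EndProfile(end=end, d1_px=d1, d1_position=d1_pos, d2_px=d2, ratio=ratio)


def end_brightness(
    bf_crop: np.ndarray,
    mask: np.ndarray,
    skeleton: Skeleton,
    end: str,
    radius_px: float = 10.0,
) -> float:
    """Mean raw bright-field intensity near one skeleton end.

    Averages over mask pixels within ``radius_px`` (Euclidean) of the end
    pixel — worm heads image brighter than tails.
    """
    if end not in ("A", "B"):
        raise ValueError("end must be 'A' or 'B'")
    tip = skeleton.path[0] if end == "A" else skeleton.path[-1]
    rr, cc = np.nonzero(mask)
    dist2 = (rr - tip[0]) ** 2 + (cc - tip[1]) ** 2
    sel = dist2 <= radius_px**2
    if not sel.any():
        sel = np.ones_like(dist2, dtype=bool)
    return float(bf_crop[rr[sel], cc[sel]].mean())


def assign_head_tail(
    end_a: EndProfile,
    end_b: EndProfile,
    *,
    brightness_weight: float = 1.0,
    diameter_weight: float = 1.0,
) -> tuple[str, float]:
    """Vote on which end is the head.

    Two cues are combined: the brighter end tends to be the head
    (brightness vote), and the end with the larger D1/D2 ratio tends to be
    the tail, so the *other* end gets the head vote (diameter vote).  Each
    vote is weighted by its normalized difference; ties fall back to the
    brightness vote alone and then deterministically to end A.

    The diameter cue only discriminates through the bulb-then-taper male
    tail, whose ratio exceeds 1; smooth tapered ends all sit at or below 1
    and differ only by measurement noise.  The vote therefore weighs the
    excess of each ratio above 1, staying silent for two smooth ends
    rather than biasing against hermaphrodite tails.

    Returns ``(head_end, confidence)`` with confidence the absolute score
    difference.
    """
    eps = 1e-12
    bf_a, bf_b = end_a.bf_brightness, end_b.bf_brightness
    bright_diff = (bf_a - bf_b) / (abs(bf_a) + abs(bf_b) + eps)
    excess_a = max(end_a.ratio - 1.0, 0.0)
    excess_b = max(end_b.ratio - 1.0, 0.0)
    ratio_diff = (excess_b - excess_a) / (excess_a + excess_b + eps) if (excess_a or excess_b) else 0.0
    score_a = brightness_weight * bright_diff + diameter_weight * ratio_diff
    confidence = abs(score_a)
    if score_a > 0:
        return "A", confidence
    if score_a < 0:
        return "B", confidence
    if bright_diff > 0:
        return "A", confidence
    if bright_diff < 0:
        return "B", confidence
    return "A", 0.0


def measure_morphology(
    mask: np.ndarray,
    bf_crop: np.ndarray,
    pixel_height_um: float,
    pixel_width_um: float,
    *,
    end_brightness_radius_px: float = 10.0,
    euclidean_length: bool = False,
) -> tuple[MorphRecord, Skeleton]:
    """Compute the full morphological record for one worm crop.

    Features that cannot be measured (branched skeleton, too-short worm,
    empty diameter windows) are left missing and the corresponding quality
    flags are recorded; no value is ever silently zeroed.
    """
    record = MorphRecord()
    record.area_um2 = area(mask, pixel_height_um, pixel_width_um)
    skel = skeletonize_debranch(mask)

    if not skel.continuous:
        record.flags.add("skeleton_branched")
        return record, skel

    record.length_um = skeleton_length(skel, pixel_height_um, euclidean=euclidean_length)
    if record.length_um > 0:
        record.thickness_um = thickness(record.area_um2, record.length_um)
    record.midwidth_um = midwidth(mask, skel, pixel_height_um)

    if len(skel.path) < MIN_SKELETON_PX:
        record.flags.add("short_skeleton")
        return record, skel

    profiles: dict[str, EndProfile] = {}
    for end in ("A", "B"):
        try:
            prof = end_diameter_profile(mask, skel, end)
        except ValueError:
            record.flags.add("window_empty")
            continue
        prof.bf_brightness = end_brightness(
            bf_crop, mask, skel, end, radius_px=end_brightness_radius_px
        )
        profiles[end] = prof

    if len(profiles) == 2:
        head, confidence = assign_head_tail(profiles["A"], profiles["B"])
        tail = "B" if head == "A" else "A"
        record.head_end = head
        record.head_confidence = confidence
        record.head_bf = profiles[head].bf_brightness
        record.tail_bf = profiles[tail].bf_brightness
        record.head_ratio = profiles[head].ratio
        record.tail_ratio = profiles[tail].ratio
    return record, skel
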