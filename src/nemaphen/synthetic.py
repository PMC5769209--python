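"""Synthetic plate generator with exact ground truth.

Emulates the input regime of bright-field worm-plate imaging: a bright
agarose background with darker, elongated, curved worm bodies whose ends
taper; optional fluorescence channels with in-worm puncta; and faulty
objects (self-touching loops, merged worm pairs, debris blobs, fragments)
for training and testing quality control.

Worms are rendered by sweeping a disk of radius ``w(s)/2`` along a smooth
random midline, which gives analytic oracles: the midline arc length, the
width profile ``w(s)`` and the planted puncta are all known exactly.  Two
parameter poles model sexual dimorphism — a hermaphrodite-like class
(longer, wider, centre bulge from eggs, smooth tail taper, brighter head)
and a male-like class (smaller, bulb-then-taper tail, darker tail) — and a
mixing coefficient ``lam`` in [0, 1] interpolates every parameter between
them for continuous intersex phenotypes.

Everything is deterministic for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import PlateImage
from .segment import WormCrop


class PlacementError(RuntimeError):
    """Raised when worms cannot be placed at the required separation."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WormParams:
    """Render parameters of a single worm phenotype."""

    length_px: float = 340.0
    max_width_px: float = 14.0
    end_taper_frac: float = 0.15     # arc fraction over which each end tapers
    tail_taper_frac: float = 0.15    # tail-side taper (sharper for males)
    center_bulge: float = 0.25       # relative extra width at mid-body (eggs)
    tail_bulb: float = 0.0           # relative bulb amplitude near the tail
    tail_bulb_pos: float = 0.93      # bulb centre as arc fraction (0=head)
    curvature_max: float = 0.012     # per-pixel curvature bound of the midline
    body_brightness: float = 0.35    # BF level of the body
    head_brightness: float = 0.46    # BF level at the head end
    tail_brightness: float = 0.32    # BF level at the tail end


#: Hermaphrodite-like pole: long, wide, egg bulge, smooth taper, bright head.
HERMAPHRODITE_PARAMS = WormParams()

#: Male-like pole: smaller, no bulge, bulb-then-sharp-taper tail, darker tail.
MALE_PARAMS = WormParams(
    length_px=270.0,
    max_width_px=11.0,
    center_bulge=0.0,
    tail_bulb=0.55,
    tail_taper_frac=0.05,
    head_brightness=0.44,
    tail_brightness=0.24,
)


def interpolate_params(lam: float) -> WormParams:
    """Blend the hermaphrodite (lam=0) and male (lam=1) parameter poles."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    a, b = HERMAPHRODITE_PARAMS, MALE_PARAMS
    mixed = {
        name: (1 - lam) * getattr(a, name) + lam * getattr(b, name)
        for name in a.__dataclass_fields__
    }
    return WormParams(**mixed)


@dataclass(frozen=True)
class FluorSpec:
    """One synthetic fluorescence channel."""

    worm_base: float = 0.30          # in-worm baseline intensity (before scale)
    scale: float = 1.0               # per-condition intensity scale factor
    background: float = 0.05
    noise_sigma: float = 0.005
    puncta_count: int = 5            # planted puncta per worm
    puncta_amplitude: float = 0.5    # peak height above baseline (before scale)
    puncta_sigma: float = 2.0        # Gaussian radius, px
    puncta_min_separation: float = 14.0  # centre spacing, px


@dataclass(frozen=True)
class FaultySpec:
    """Mixture of faulty-object modes planted on a plate."""

    loop_probability: float = 0.0
    blob_count: int = 0
    merge_probability: float = 0.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic plate."""

    n_worms: int = 20
    image_size: tuple[int, int] = (1000, 1000)
    background: float = 0.90
    noise_sigma: float = 0.012
    worm: WormParams = field(default_factory=lambda: HERMAPHRODITE_PARAMS)
    lam: float | None = None         # when set, overrides `worm` by interpolation
    fluor: dict[str, FluorSpec] = field(default_factory=lambda: {"GFP": FluorSpec()})
    faulty: FaultySpec = field(default_factory=FaultySpec)
    min_separation_px: int = 3
    seed: int = 0


@dataclass
class WormTruth:
    """Ground truth for one planted worm."""

    mask: np.ndarray                 # full-image boolean mask of this worm
    bbox: tuple[int, int, int, int]
    midline_length_px: float
    width_profile: np.ndarray        # w(s) at the midline samples, px
    head_rc: tuple[float, float]     # head-end midline coordinate (row, col)
    tail_rc: tuple[float, float]
    lam: float | None
    label: str
    fluor_scale: float = 1.0
    puncta_centers: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class GroundTruth:
    worms: list[WormTruth]
    faulty_object_count: int = 0


# ---------------------------------------------------------------------------
# Single-worm rendering
# ---------------------------------------------------------------------------

def _smooth_midline(params: WormParams, rng: np.random.Generator, ds: float = 0.5) -> np.ndarray:
    """Random smooth open curve of the requested arc length (no self-contact)."""
    n = int(round(params.length_px / ds))
    for _attempt in range(25):
        # Curvature as a smooth random signal bounded by curvature_max.
        n_ctrl = 8
        ctrl = rng.uniform(-1.0, 1.0, n_ctrl)
        kappa = np.interp(np.linspace(0, n_ctrl - 1, n), np.arange(n_ctrl), ctrl)
        kappa *= params.curvature_max
        theta = rng.uniform(0, 2 * math.pi) + np.cumsum(kappa) * ds
        pts = np.cumsum(np.stack([np.sin(theta), np.cos(theta)], axis=1) * ds, axis=0)
        # Self-contact check: non-neighbouring samples must stay further
        # apart than the body width.
        stride = max(1, int(2 * params.max_width_px / ds))
        ok = True
        for i in range(0, n, stride // 2 or 1):
            d = np.hypot(pts[:, 0] - pts[i, 0], pts[:, 1] - pts[i, 1])
            near = d < params.max_width_px * 1.2
            lo = max(0, i - 3 * stride)
            hi = min(n, i + 3 * stride)
            near[lo:hi] = False
            if near.any():
                ok = False
                break
        if ok:
            return pts
        params = replace(params, curvature_max=params.curvature_max * 0.7)
    raise PlacementError("could not draw a self-avoiding midline")


def width_profile(params: WormParams, s: np.ndarray) -> np.ndarray:
    """Body width w(s) in pixels; s in [0, 1] runs head -> tail."""
    s = np.asarray(s, dtype=float)
    head_ramp = np.clip(s / params.end_taper_frac, 0.0, 1.0)
    tail_ramp = np.clip((1.0 - s) / params.tail_taper_frac, 0.0, 1.0)
    base = np.minimum(np.sqrt(head_ramp), np.sqrt(tail_ramp))
    bulge = 1.0 + params.center_bulge * np.exp(-(((s - 0.5) / 0.12) ** 2))
    bulb = 1.0 + params.tail_bulb * np.exp(-(((s - params.tail_bulb_pos) / 0.03) ** 2))
    return params.max_width_px * base * bulge * bulb


@dataclass
class _Render:
    mask: np.ndarray
    bf_paint: np.ndarray   # worm-only BF intensities (0 outside the body)
    midline: np.ndarray    # local (row, col) float samples, head first
    widths: np.ndarray
    arc_length: float


def render_worm(params: WormParams, rng: np.random.Generator, ds: float = 0.5) -> _Render:
    """Sweep a disk of radius w(s)/2 along a random smooth midline."""
    pts = _smooth_midline(params, rng, ds)
    n = len(pts)
    s = np.arange(n) / (n - 1)
    w = width_profile(params, s)
    brightness = params.head_brightness + (params.tail_brightness - params.head_brightness) * s
    # Head-end flattening keeps the head region contiguous in brightness.
    margin = int(math.ceil(params.max_width_px)) + 3
    lo = pts.min(axis=0) - margin
    pts_local = pts - lo
    shape = tuple((pts.max(axis=0) - lo + margin).astype(int) + 1)
    mask = np.zeros(shape, dtype=bool)
    paint = np.zeros(shape, dtype=np.float64)

    radius_max = int(math.ceil(w.max() / 2)) + 1
    yy, xx = np.mgrid[-radius_max : radius_max + 1, -radius_max : radius_max + 1]
    dist2 = yy**2 + xx**2
    for i in range(n):
        r = w[i] / 2.0
        if r <= 0:
            continue
        disk = dist2 <= r * r
        cr, cc = int(round(pts_local[i, 0])), int(round(pts_local[i, 1]))
        r0, c0 = cr - radius_max, cc - radius_max
        sub = mask[r0 : r0 + disk.shape[0], c0 : c0 + disk.shape[1]]
        sub |= disk
        psub = paint[r0 : r0 + disk.shape[0], c0 : c0 + disk.shape[1]]
        psub[disk] = brightness[i]

    arc = float(ds * (n - 1))
    return _Render(mask=mask, bf_paint=paint, midline=pts_local, widths=w, arc_length=arc)


# ---------------------------------------------------------------------------
# Faulty objects
# ---------------------------------------------------------------------------

def render_loop_worm(params: WormParams, rng: np.random.Generator, ds: float = 0.5) -> np.ndarray:
    """A worm whose midline closes on itself (head touches body)."""
    n = int(round(params.length_px / ds))
    radius = params.length_px / (2 * math.pi) * 0.92  # slight over-closure
    theta = np.linspace(0, 2.05 * math.pi, n) + rng.uniform(0, 2 * math.pi)
    pts = radius * np.stack([np.sin(theta), np.cos(theta)], axis=1)
    s = np.arange(n) / (n - 1)
    w = width_profile(replace(params, tail_bulb=0.0), s)
    margin = int(math.ceil(params.max_width_px)) + 3
    lo = pts.min(axis=0) - margin
    pts_local = pts - lo
    shape = tuple((pts.max(axis=0) - lo + margin).astype(int) + 1)
    mask = np.zeros(shape, dtype=bool)
    radius_max = int(math.ceil(w.max() / 2)) + 1
    yy, xx = np.mgrid[-radius_max : radius_max + 1, -radius_max : radius_max + 1]
    dist2 = yy**2 + xx**2
    for i in range(n):
        r = w[i] / 2.0
        if r <= 0:
            continue
        disk = dist2 <= r * r
        cr, cc = int(round(pts_local[i, 0])), int(round(pts_local[i, 1]))
        mask[cr - radius_max : cr + radius_max + 1, cc - radius_max : cc + radius_max + 1] |= disk
    return mask


def render_blob(rng: np.random.Generator, radius_px: float = 25.0) -> np.ndarray:
    """Compact debris blob: a noisy ellipse."""
    a = radius_px * rng.uniform(0.7, 1.3)
    b = radius_px * rng.uniform(0.7, 1.3)
    phi = rng.uniform(0, math.pi)
    m = int(math.ceil(max(a, b))) + 3
    yy, xx = np.mgrid[-m : m + 1, -m : m + 1]
    u = xx * math.cos(phi) + yy * math.sin(phi)
    v = -xx * math.sin(phi) + yy * math.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_merged_pair(params: WormParams, rng: np.random.Generator) -> np.ndarray:
    """Two worms crossing each other: a single 8-connected faulty object."""
    for _ in range(20):
        r1 = render_worm(params, rng)
        r2 = render_worm(params, rng)
        # Overlay r2 so that its midline midpoint hits r1's midline midpoint.
        c1 = r1.midline[len(r1.midline) // 2]
        c2 = r2.midline[len(r2.midline) // 2]
        off = np.round(c1 - c2).astype(int)
        org1 = np.maximum(0, -off)
        org2 = np.maximum(0, off)
        h = max(r1.mask.shape[0] + org1[0], r2.mask.shape[0] + org2[0])
        w = max(r1.mask.shape[1] + org1[1], r2.mask.shape[1] + org2[1])
        canvas = np.zeros((h, w), dtype=bool)
        canvas[org1[0] : org1[0] + r1.mask.shape[0], org1[1] : org1[1] + r1.mask.shape[1]] |= r1.mask
        canvas[org2[0] : org2[0] + r2.mask.shape[0], org2[1] : org2[1] + r2.mask.shape[1]] |= r2.mask
        _, n = ndimage.label(canvas, structure=np.ones((3, 3), bool))
        if n == 1:
            return canvas
    raise PlacementError("could not render a merged worm pair")


def render_fragmented_worm(params: WormParams, rng: np.random.Generator) -> np.ndarray:
    """A worm mask broken into pieces by erased bands."""
    r = render_worm(params, rng)
    mask = r.mask.copy()
    n = len(r.midline)
    band = int(params.max_width_px)
    for frac in rng.uniform(0.2, 0.8, size=3):
        cr = int(r.midline[int(frac * (n - 1)), 0])
        mask[max(0, cr - band // 2) : cr + band // 2 + 1, :] = False
    return mask


# ---------------------------------------------------------------------------
# Plate assembly
# ---------------------------------------------------------------------------

def _place(
    occupied: np.ndarray,
    obj: np.ndarray,
    rng: np.random.Generator,
    separation: int,
    attempts: int = 1000,
) -> tuple[int, int]:
    """Find a top-left offset where ``obj`` fits clear of occupied pixels."""
    big = ndimage.binary_dilation(obj, iterations=separation) if separation else obj
    h, w = occupied.shape
    oh, ow = big.shape
    if oh >= h - 2 or ow >= w - 2:
        raise PlacementError("object larger than the plate")
    for _ in range(attempts):
        r = int(rng.integers(1, h - oh - 1))
        c = int(rng.integers(1, w - ow - 1))
        if not (occupied[r : r + oh, c : c + ow] & big).any():
            occupied[r : r + oh, c : c + ow] |= big
            return r, c
    raise PlacementError("could not place object after 1000 attempts")


def generate_plate(
    spec: SyntheticSpec,
    *,
    pixel_height_um: float = 1.14,
    pixel_width_um: float = 1.14,
) -> tuple[PlateImage, GroundTruth]:
    """Render a full synthetic plate with its ground truth.

    The bright-field channel is background plus Gaussian noise with darker
    worms (lightly blurred for soft edges); each configured fluorescence
    channel carries the per-worm base intensity times its scale factor plus
    planted Gaussian puncta.  Deterministic for a given spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    occupied = np.zeros((h, w), dtype=bool)
    bf = np.full((h, w), spec.background, dtype=np.float64)
    fl = {name: np.full((h, w), fs.background, dtype=np.float64) for name, fs in spec.fluor.items()}

    params = interpolate_params(spec.lam) if spec.lam is not None else spec.worm
    label = "gradient" if spec.lam is not None else "A"

    worms: list[WormTruth] = []
    for _ in range(spec.n_worms):
        render = render_worm(params, rng)
        r0, c0 = _place(occupied, render.mask, rng, spec.min_separation_px)
        oh, ow = render.mask.shape
        full_mask = np.zeros((h, w), dtype=bool)
        full_mask[r0 : r0 + oh, c0 : c0 + ow] = render.mask
        region = bf[r0 : r0 + oh, c0 : c0 + ow]
        region[render.mask] = render.bf_paint[render.mask]

        puncta_centers: dict[str, np.ndarray] = {}
        for name, fs in spec.fluor.items():
            sub = fl[name][r0 : r0 + oh, c0 : c0 + ow]
            sub[render.mask] = fs.background + fs.worm_base * fs.scale
            centers = _plant_puncta(sub, render.mask, fs, rng)
            puncta_centers[name] = centers + np.array([r0, c0])

        rows, cols = np.nonzero(full_mask)
        bbox = (int(rows.min()), int(cols.min()),
                int(rows.max() - rows.min() + 1), int(cols.max() - cols.min() + 1))
        head = render.midline[0] + np.array([r0, c0])
        tail = render.midline[-1] + np.array([r0, c0])
        worms.append(
            WormTruth(
                mask=full_mask,
                bbox=bbox,
                midline_length_px=render.arc_length,
                width_profile=render.widths,
                head_rc=(float(head[0]), float(head[1])),
                tail_rc=(float(tail[0]), float(tail[1])),
                lam=spec.lam,
                label=label,
                fluor_scale=next(iter(spec.fluor.values())).scale if spec.fluor else 1.0,
                puncta_centers=puncta_centers,
            )
        )

    n_faulty = 0
    for _ in range(spec.faulty.blob_count):
        blob = render_blob(rng)
        r0, c0 = _place(occupied, blob, rng, spec.min_separation_px)
        region = bf[r0 : r0 + blob.shape[0], c0 : c0 + blob.shape[1]]
        region[blob] = params.body_brightness
        n_faulty += 1
    if rng.random() < spec.faulty.loop_probability:
        loop = render_loop_worm(params, rng)
        r0, c0 = _place(occupied, loop, rng, spec.min_separation_px)
        region = bf[r0 : r0 + loop.shape[0], c0 : c0 + loop.shape[1]]
        region[loop] = params.body_brightness
        n_faulty += 1

    # Soft edges, then sensor noise.
    bf = ndimage.gaussian_filter(bf, sigma=0.6)
    bf = np.clip(bf + rng.normal(0.0, spec.noise_sigma, size=bf.shape), 0.0, 1.0)
    channels = {"BF": bf}
    for name, fs in spec.fluor.items():
        img = ndimage.gaussian_filter(fl[name], sigma=0.6)
        channels[name] = np.clip(img + rng.normal(0.0, fs.noise_sigma, size=img.shape), 0.0, 1.0)

    plate = PlateImage(
        channels=channels,
        pixel_height_um=pixel_height_um,
        pixel_width_um=pixel_width_um,
        source_path=f"synthetic(seed={spec.seed})",
    )
    return plate, GroundTruth(worms=worms, faulty_object_count=n_faulty)


def _plant_puncta(
    sub: np.ndarray, mask: np.ndarray, fs: FluorSpec, rng: np.random.Generator
) -> np.ndarray:
    """Add well-separated Gaussian puncta inside the mask; returns centres."""
    if fs.puncta_count <= 0:
        return np.empty((0, 2))
    # Candidate centres away from the body edge so puncta stay inside.
    interior = ndimage.binary_erosion(mask, iterations=2)
    coords = np.argwhere(interior if interior.any() else mask)
    centers: list[np.ndarray] = []
    order = rng.permutation(len(coords))
    for idx in order:
        cand = coords[idx]
        if all(np.hypot(*(cand - c)) >= fs.puncta_min_separation for c in centers):
            centers.append(cand)
        if len(centers) == fs.puncta_count:
            break
    if not centers:
        return np.empty((0, 2))
    yy, xx = np.mgrid[: sub.shape[0], : sub.shape[1]]
    for cr, cc in centers:
        blob = fs.puncta_amplitude * fs.scale * np.exp(
            -(((yy - cr) ** 2 + (xx - cc) ** 2) / (2 * fs.puncta_sigma**2))
        )
        sub += blob * mask
    return np.array(centers, dtype=float)


# ---------------------------------------------------------------------------
# Population and corpus generators
# ---------------------------------------------------------------------------

def _render_to_crop(
    render: _Render,
    params: WormParams,
    rng: np.random.Generator,
    index: int,
    background: float = 0.90,
    noise_sigma: float = 0.012,
    source: str = "synthetic",
) -> WormCrop:
    """Wrap a single rendered worm as a stand-alone crop with BF background."""
    mask = render.mask
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min() - 1, rows.max() + 2
    c0, c1 = cols.min() - 1, cols.max() + 2
    mask_c = mask[r0:r1, c0:c1]
    bf = np.full(mask_c.shape, background)
    bf[mask_c] = render.bf_paint[r0:r1, c0:c1][mask_c]
    bf = ndimage.gaussian_filter(bf, 0.6)
    bf = np.clip(bf + rng.normal(0, noise_sigma, bf.shape), 0, 1)
    crop = WormCrop(
        mask=mask_c,
        channel_crops={"BF": bf},
        bbox=(int(r0), int(c0), int(r1 - r0), int(c1 - c0)),
        worm_index=index,
        source_image=source,
    )
    # Crop-local ground truth for downstream accuracy checks.
    offset = np.array([r0, c0], dtype=float)
    truth = {
        "head_rc": tuple(render.midline[0] - offset),
        "tail_rc": tuple(render.midline[-1] - offset),
        "arc_length_px": render.arc_length,
        "width_profile": render.widths,
    }
    return crop, truth


def generate_dimorphic_population(
    n_per_class: int,
    lam_list: list[float] | None = None,
    n_per_lam: int = 0,
    *,
    seed: int = 0,
) -> tuple[list[WormCrop], list[dict]]:
    """Crops of hermaphrodite-like (class A) and male-like (class B) worms.

    Optionally adds gradient worms at each mixing coefficient in
    ``lam_list`` (``n_per_lam`` each).  Returns the crops plus one metadata
    dict per crop with keys ``label`` ("A", "B" or "gradient"), ``lam`` and
    crop-local ground truth (``head_rc``, ``tail_rc``, ``arc_length_px``,
    ``width_profile``).
    """
    rng = np.random.default_rng(seed)
    crops: list[WormCrop] = []
    meta: list[dict] = []
    idx = 0
    groups = [("A", 0.0, n_per_class), ("B", 1.0, n_per_class)]
    groups += [("gradient", lam, n_per_lam) for lam in (lam_list or [])]
    for label, lam, count in groups:
        params = interpolate_params(lam)
        for _ in range(count):
            render = render_worm(params, rng)
            crop, truth = _render_to_crop(render, params, rng, idx, source=f"dimorphic_seed{seed}")
            crops.append(crop)
            meta.append({"label": label, "lam": lam, **truth})
            idx += 1
    return crops, meta


def gaussian_feature_table(
    n_per_class: int,
    *,
    n_features: int = 2,
    separation_sd: float = 4.0,
    seed: int = 0,
    label_column: str = "sex",
    labels: tuple[str, str] = ("hermaphrodite", "male"),
):
    """Feature-level two-class fixture with a known pooled-SD separation.

    Both classes are unit-variance Gaussians; the class-mean shift is
    spread over the features so the total Mahalanobis distance equals
    ``separation_sd``.  Useful when the quantity under test concerns the
    analysis layer rather than image processing: the Bayes error is known
    in closed form (``Phi(-separation_sd / 2)``).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    delta = separation_sd / math.sqrt(n_features)
    cols = [f"f{i}" for i in range(n_features)]
    a = rng.normal(0.0, 1.0, (n_per_class, n_features))
    b = rng.normal(delta, 1.0, (n_per_class, n_features))
    table = pd.DataFrame(np.vstack([a, b]), columns=cols)
    table[label_column] = [labels[0]] * n_per_class + [labels[1]] * n_per_class
    return table


def generate_faulty_masks(
    n_valid: int, n_faulty: int, *, seed: int = 0
) -> tuple[list[np.ndarray], np.ndarray]:
    """Labelled mask corpus for training the mask-quality classifier.

    Valid masks are normal rendered worms (label 0); faulty masks (label 1)
    cycle through self-touching loops, compact blobs, merged worm pairs and
    fragmented worms.
    """
    if n_valid <= 0 or n_faulty <= 0:
        raise ValueError("both classes need at least one example")
    rng = np.random.default_rng(seed)
    masks: list[np.ndarray] = []
    labels: list[int] = []
    for _ in range(n_valid):
        lam = float(rng.uniform(0, 1))
        masks.append(render_worm(interpolate_params(lam), rng).mask)
        labels.append(0)
    makers = (
        lambda: render_loop_worm(HERMAPHRODITE_PARAMS, rng),
        lambda: render_blob(rng, radius_px=float(rng.uniform(15, 40))),
        lambda: render_merged_pair(MALE_PARAMS, rng),
        lambda: render_fragmented_worm(HERMAPHRODITE_PARAMS, rng),
    )
    for i in range(n_faulty):
        masks.append(makers[i % len(makers)]())
        labels.append(1)
    return masks, np.array(labels, dtype=int)
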