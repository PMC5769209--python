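"""Image and table input/output.

Plates are read from TIFF (single or multi-page, 8/16-bit) or PNG.  All
channels are normalized to a common [0, 1] scale on load; the raw dynamic
range never reaches downstream code.  A mandatory bright-field channel
("BF") carries the worms; fluorescence channels are optional and stay
aligned with it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .config import MIN_CONTRAST, AcquisitionPreset, PipelineConfig

if TYPE_CHECKING:  # pragma: no cover
    from .segment import WormCrop

# ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
_LUMA = np.array([0.2989, 0.5870, 0.1140])


class ContrastError(ValueError):
    """Raised when a bright-field image fails the contrast admission gate."""


@dataclass
class PlateImage:
    """A multi-channel plate acquisition on a common [0, 1] intensity scale.

    Attributes
    ----------
    channels : dict
        Channel name -> 2-D float array; all arrays share one shape and a
        channel named ``"BF"`` must be present.
    pixel_height_um, pixel_width_um : float
        Physical pixel pitch.
    """

    channels: dict[str, np.ndarray]
    pixel_height_um: float
    pixel_width_um: float
    source_path: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if "BF" not in self.channels:
            raise ValueError("a 'BF' (bright-field) channel is required")
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels["BF"].shape

    @property
    def bf(self) -> np.ndarray:
        return self.channels["BF"]


def _normalize_unit(arr: np.ndarray, bit_depth: int) -> np.ndarray:
    """Scale integer data to [0, 1] by its dtype full range; floats pass through."""
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(np.float64)
        if out.size and out.max() > 1.0 + 1e-9:
            out = out / out.max()
        return out
    return arr.astype(np.float64) / float(2**bit_depth - 1)


def _to_gray(page: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) page to grayscale by luminance weighting."""
    if page.ndim == 2:
        return page
    if page.ndim == 3 and page.shape[-1] in (3, 4):
        return np.tensordot(page[..., :3].astype(np.float64), _LUMA, axes=([-1], [0]))
    raise ValueError(f"unsupported page shape {page.shape}")


def load_plate_image(
    path: str | Path,
    preset: AcquisitionPreset | None = None,
    *,
    pixel_height_um: float | None = None,
    pixel_width_um: float | None = None,
    channel_map: Mapping[int, str] | None = None,
    max_input_bytes: int = 1_000_000_000,
) -> PlateImage:
    """Read a TIFF/PNG plate image into a normalized :class:`PlateImage`.

    Multi-page TIFFs map page index -> channel name through ``channel_map``
    (default: page 0 is "BF", later pages "FL1", "FL2", ...).  RGB input is
    grayscaled by luminance weighting.  Pixel sizes come from ``preset``
    unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if os.path.getsize(path) > max_input_bytes:
        raise ValueError(f"{path} exceeds the configured input size limit ({max_input_bytes} bytes)")

    if path.suffix.lower() in (".tif", ".tiff"):
        pages = [np.asarray(p.asarray()) for p in tifffile.TiffFile(path).pages]
        bit_depth = 8 if pages and pages[0].dtype == np.uint8 else 16
    else:
        with Image.open(path) as im:
            pages = [np.asarray(im)]
        bit_depth = 8

    if not pages or any(p.size == 0 for p in pages):
        raise ValueError(f"{path} contains a zero-size image")

    channel_map = dict(channel_map or {0: "BF"})
    channels: dict[str, np.ndarray] = {}
    for i, page in enumerate(pages):
        name = channel_map.get(i, "BF" if i == 0 else f"FL{i}")
        channels[name] = _to_gray(_normalize_unit(page, bit_depth))

    if pixel_height_um is None or pixel_width_um is None:
        if preset is None:
            raise ValueError("either a preset or explicit pixel sizes are required")
        pixel_height_um = pixel_height_um or preset.pixel_height_um
        pixel_width_um = pixel_width_um or preset.pixel_width_um

    return PlateImage(
        channels=channels,
        pixel_height_um=float(pixel_height_um),
        pixel_width_um=float(pixel_width_um),
        source_path=str(path),
        bit_depth=bit_depth,
    )


def check_contrast(image: PlateImage | np.ndarray) -> float:
    """Standard deviation of the grayscale bright-field channel on [0, 1].

    This is the admission statistic: the pipeline refuses plates scoring
    below 0.04 — typically slides rather than agarose plates.  Computed on
    the raw normalized grayscale, before any detection-time stretching.
    """
    bf = image.bf if isinstance(image, PlateImage) else np.asarray(image, dtype=np.float64)
    return float(np.std(bf))


def require_contrast(image: PlateImage, minimum: float = MIN_CONTRAST) -> float:
    """Enforce the contrast gate, raising :class:`ContrastError` with the measured score."""
    score = check_contrast(image)
    if score < minimum:
        raise ContrastError(
            f"bright-field contrast {score:.4f} is below the admissible minimum {minimum}; "
            "image the worms on agarose plates rather than slides"
        )
    return score


def stretch_contrast(bf: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Linear percentile stretch used for detection only.

    Returns a working copy rescaled so that the ``low_pct``/``high_pct``
    percentiles map to 0/1.  Raw intensities are never overwritten:
    fluorescence quantification always reads the unstretched channels.
    """
    lo, hi = np.percentile(bf, [low_pct, high_pct])
    if hi - lo < 1e-12:
        return bf.copy()
    return np.clip((bf - lo) / (hi - lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Per-worm crop output layout
# ---------------------------------------------------------------------------

def write_worm_outputs(
    crops: "Iterable[WormCrop]",
    out_dir: str | Path,
    *,
    overwrite: bool = False,
) -> list[str]:
    """Write per-worm crops into one folder per channel plus a ``Masks`` folder.

    Worm *i* is saved as ``worm_0007.tif`` with the same zero-padded stem in
    every folder, so crops join across channels by filename.  Returns the
    manifest of written paths (relative to ``out_dir``).
    """
    out_dir = Path(out_dir)
    crops = list(crops)
    channel_names = sorted({ch for crop in crops for ch in crop.channel_crops})
    for folder in channel_names + ["Masks"]:
        (out_dir / folder).mkdir(parents=True, exist_ok=True)

    manifest: list[str] = []
    for crop in crops:
        stem = f"worm_{crop.worm_index:04d}.tif"
        targets = [("Masks", (crop.mask.astype(np.uint8) * 255))]
        targets += [
            (ch, np.clip(crop.channel_crops[ch] * 65535, 0, 65535).astype(np.uint16))
            for ch in crop.channel_crops
        ]
        for folder, data in targets:
            dest = out_dir / folder / stem
            if dest.exists() and not overwrite:
                raise FileExistsError(f"{dest} exists; pass overwrite=True to replace")
            tifffile.imwrite(dest, data)
            manifest.append(str(Path(folder) / stem))
    return manifest


# ---------------------------------------------------------------------------
# Feature table round-trip
# ---------------------------------------------------------------------------

#: Fixed morphological column order; fluorescence columns are suffixed per
#: channel and appended after these.
MORPH_COLUMNS = [
    "source_image",
    "worm_index",
    "area_um2",
    "length_um",
    "thickness_um",
    "midwidth_um",
    "head_bf",
    "tail_bf",
    "head_ratio",
    "tail_ratio",
    "head_end",
    "qc_flags",
]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-worm feature table as CSV with empty fields for missing values."""
    table.to_csv(path, index=False, na_rep="")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path)
    for col in ("head_end", "qc_flags", "source_image"):
        if col in df.columns:
            df[col] = df[col].astype("string").fillna("")
    return df
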