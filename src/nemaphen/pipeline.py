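"""End-to-end orchestration: plate image -> crops -> feature table.

The three stages mirror how the tool is used at the bench: segment every
plate of a batch with identical parameters, extract morphological and
fluorescence features per worm, then flag suspect records for review.
Per-image failures (e.g. a sub-contrast plate) are logged and skipped so
one bad acquisition never aborts a batch.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .fluorescence import measure_fluorescence
from .io import (
    ContrastError,
    PlateImage,
    load_plate_image,
    require_contrast,
    stretch_contrast,
    write_feature_table,
    write_worm_outputs,
)
from .morphology import MorphRecord, measure_morphology
from .qc import FlagReport, flag_outliers, retention_summary
from .segment import WormCrop, adaptive_threshold, clean_mask, crop_worms, segment_worms
from .skeleton import Skeleton

logger = logging.getLogger(__name__)

FLUOR_COLUMNS = ("peak_count", "peak_mean", "peak_std", "ctwf", "rid",
                 "background_mean", "puncta_mean_relsize_pct")


def process_plate(plate: PlateImage, config: PipelineConfig | None = None) -> list[WormCrop]:
    """Segment one plate into per-worm crops.

    Enforces the contrast gate, stretches a working copy of the BF channel
    for detection (raw intensities are preserved in the crops), thresholds,
    cleans, size-gates and crops.
    """
    config = config or PipelineConfig()
    require_contrast(plate)
    working = stretch_contrast(plate.bf)
    mask = adaptive_threshold(working, config.threshold_params)
    mask = clean_mask(mask, config.threshold_params)
    components = segment_worms(mask, config.threshold_params)
    return crop_worms(plate, mask, components)


def extract_features(
    crop: WormCrop,
    pixel_height_um: float,
    pixel_width_um: float,
    config: PipelineConfig | None = None,
) -> tuple[dict, MorphRecord, Skeleton]:
    """Morphological plus per-channel fluorescence features for one crop."""
    config = config or PipelineConfig()
    morph, skel = measure_morphology(
        crop.mask,
        crop.channel_crops["BF"],
        pixel_height_um,
        pixel_width_um,
        end_brightness_radius_px=config.end_brightness_radius_px,
        euclidean_length=config.euclidean_length,
    )
    row: dict = {
        "source_image": crop.source_image,
        "worm_index": crop.worm_index,
        "area_um2": morph.area_um2,
        "length_um": morph.length_um,
        "thickness_um": morph.thickness_um,
        "midwidth_um": morph.midwidth_um,
        "head_bf": morph.head_bf,
        "tail_bf": morph.tail_bf,
        "head_ratio": morph.head_ratio,
        "tail_ratio": morph.tail_ratio,
        "head_end": morph.head_end,
    }
    for name, fl_crop in crop.channel_crops.items():
        if name == "BF":
            continue
        rec = measure_fluorescence(fl_crop, crop.mask, config.peak_params)
        row.update(
            {
                f"peak_count_{name}": rec.peak_count,
                f"peak_mean_{name}": rec.peak_mean,
                f"peak_std_{name}": rec.peak_std,
                f"ctwf_{name}": rec.ctwf,
                f"rid_{name}": rec.rid,
                f"background_mean_{name}": rec.background_mean,
                f"puncta_mean_relsize_pct_{name}": rec.puncta_mean_relsize_pct,
            }
        )
    return row, morph, skel


def build_feature_table(
    crops: list[WormCrop],
    pixel_height_um: float,
    pixel_width_um: float,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, list[FlagReport]]:
    """Feature table plus batch-level QC flags for a list of crops."""
    rows, morphs, skels, keys = [], [], [], []
    for crop in crops:
        row, morph, skel = extract_features(crop, pixel_height_um, pixel_width_um, config)
        rows.append(row)
        morphs.append(morph)
        skels.append(skel)
        keys.append((crop.source_image, crop.worm_index))
    reports = flag_outliers(morphs, skels, keys) if crops else []
    df = pd.DataFrame(rows)
    if len(df):
        df["qc_flags"] = [";".join(sorted(r.flags)) for r in reports]
        df["z_area"] = [r.z_area for r in reports]
        df["z_length"] = [r.z_length for r in reports]
    return df, reports


def run_batch(
    inputs: list,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    *,
    drop_flagged: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Process a batch of plates with identical parameters.

    ``inputs`` may mix file paths and in-memory :class:`PlateImage`
    objects.  Failing images are logged and skipped.  When ``out_dir`` is
    given, per-worm crops, ``features.csv`` and ``run.log`` are written
    there.  Returns the feature table and a summary dict (per-image status
    and QC retention).
    """
    if not inputs:
        raise ValueError("empty batch")
    config = config or PipelineConfig()
    acq = config.acquisition

    all_crops: list[WormCrop] = []
    status: dict[str, str] = {}
    worm_counter = 0
    for item in inputs:
        try:
            plate = (
                item
                if isinstance(item, PlateImage)
                else load_plate_image(
                    item,
                    acq,
                    channel_map=config.channel_map,
                    max_input_bytes=config.max_input_bytes,
                )
            )
            crops = process_plate(plate, config)
        except ContrastError as exc:
            key = item if isinstance(item, str) else getattr(item, "source_path", str(item))
            logger.warning("skipping %s: %s", key, exc)
            status[str(key)] = f"skipped: {exc}"
            continue
        except Exception as exc:  # per-image failure must not abort the batch
            key = item if isinstance(item, str) else getattr(item, "source_path", str(item))
            logger.error("failed on %s: %s", key, exc)
            status[str(key)] = f"failed: {exc}"
            continue
        for crop in crops:  # unique numbering across the batch
            crop.worm_index = worm_counter
            worm_counter += 1
        all_crops.extend(crops)
        status[plate.source_path or "in-memory"] = f"ok: {len(crops)} worms"

    table, reports = build_feature_table(
        all_crops, acq.pixel_height_um, acq.pixel_width_um, config
    )
    summary = {"images": status, "qc": retention_summary(reports)}

    export = table
    if drop_flagged and len(table):
        export = table[table["qc_flags"] == ""].reset_index(drop=True)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_worm_outputs(all_crops, out_dir, overwrite=True)
        write_feature_table(export, out_dir / "features.csv")
        with open(out_dir / "run.log", "w") as fh:
            fh.write(f"preset={config.preset} um_per_pixel={acq.um_per_pixel}\n")
            fh.write(f"threshold_params={config.threshold_params}\n")
            fh.write(f"peak_params={config.peak_params}\n")
            for key, val in status.items():
                fh.write(f"{key}: {val}\n")
            fh.write(f"qc={summary['qc']}\n")
    return export, summary
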