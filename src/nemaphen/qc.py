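"""Quality control: batch-level outlier flagging and retention bookkeeping.

Flags never alter feature values — a flagged worm stays in the table,
marked for review, and is dropped only at export time when the caller asks
for it.  Batch z-scores use the sample standard deviation (ddof=1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .morphology import MorphRecord
from .skeleton import Skeleton

logger = logging.getLogger(__name__)

#: Worms whose standardized area or length deviates beyond this many
#: standard deviation units are flagged for review.
OUTLIER_Z = 1.5

#: More than this many debranching attempts marks a suspicious mask even
#: when the final skeleton is continuous.
MAX_BENIGN_ATTEMPTS = 2

FLAG_NAMES = (
    "area_outlier",
    "length_outlier",
    "skeleton_attempts",
    "skeleton_branched",
    "short_skeleton",
    "window_empty",
    "net_noise",
)


@dataclass
class FlagReport:
    """QC verdict for one worm within its batch."""

    worm_key: tuple[str, int]
    flags: set[str] = field(default_factory=set)
    z_area: float = math.nan
    z_length: float = math.nan
    net_score: float = math.nan

    @property
    def flagged(self) -> bool:
        return bool(self.flags)


def _zscores(values: np.ndarray) -> np.ndarray:
    valid = np.isfinite(values)
    if valid.sum() < 3:
        return np.full_like(values, np.nan)
    mean = values[valid].mean()
    std = values[valid].std(ddof=1)
    if std == 0:
        return np.full_like(values, np.nan)
    out = np.full_like(values, np.nan)
    out[valid] = (values[valid] - mean) / std
    return out


def flag_outliers(
    records: list[MorphRecord],
    skeletons: list[Skeleton],
    keys: list[tuple[str, int]] | None = None,
) -> list[FlagReport]:
    """Flag morphological outliers and disfigured skeletons within one batch.

    Area and length are standardized across the batch; worms beyond
    ±1.5 standard deviation units get ``area_outlier``/``length_outlier``.
    Masks that needed more than two debranching attempts get
    ``skeleton_attempts``; skeletons still branched (or looped) after the
    attempt cap get ``skeleton_branched``.  Batches smaller than three
    yield no outlier flags (z-scores are meaningless) and log a warning.
    """
    n = len(records)
    if len(skeletons) != n:
        raise ValueError("records and skeletons must align")
    if keys is None:
        keys = [("", i) for i in range(n)]

    areas = np.array([r.area_um2 for r in records], dtype=float)
    lengths = np.array([r.length_um for r in records], dtype=float)
    if n < 3:
        logger.warning("batch of %d worms: outlier z-scores undefined, skipping", n)
        z_area = np.full(n, np.nan)
        z_length = np.full(n, np.nan)
    else:
        z_area = _zscores(areas)
        z_length = _zscores(lengths)
        if np.isnan(z_area).all():
            logger.warning("degenerate area distribution: no area outlier flags")
        if np.isnan(z_length).all():
            logger.warning("degenerate length distribution: no length outlier flags")

    reports = []
    for i, (rec, skel) in enumerate(zip(records, skeletons)):
        flags = set(rec.flags)
        if np.isfinite(z_area[i]) and abs(z_area[i]) > OUTLIER_Z:
            flags.add("area_outlier")
        if np.isfinite(z_length[i]) and abs(z_length[i]) > OUTLIER_Z:
            flags.add("length_outlier")
        if skel.smoothing_attempts > MAX_BENIGN_ATTEMPTS:
            flags.add("skeleton_attempts")
        if not skel.continuous:
            flags.add("skeleton_branched")
        reports.append(
            FlagReport(
                worm_key=keys[i],
                flags=flags,
                z_area=float(z_area[i]),
                z_length=float(z_length[i]),
            )
        )
    return reports


def retention_summary(reports: list[FlagReport]) -> dict:
    """Fraction of worms surviving QC, as reported per experiment."""
    n = len(reports)
    kept = sum(not r.flagged for r in reports)
    return {
        "n_objects": n,
        "n_retained": kept,
        "retention_fraction": kept / n if n else math.nan,
    }
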