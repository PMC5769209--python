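"""Per-worm fluorescence quantification.

Three families of measures are computed from a raw fluorescence crop and
the worm mask:

* **Peaks** — 2-D local intensity maxima (e.g. neuronal reporters), found
  with a square suppression neighborhood and a threshold relative to the
  crop maximum.
* **Integrated intensities** — corrected total worm fluorescence (CTWF)
  and raw integrated density (RID), both background-corrected using the
  mean intensity of the non-worm pixels of the same crop:

  .. math::

     \\mathrm{CTWF} = (\\bar I_{worm} - \\bar I_{bg})\\,A, \\qquad
     \\mathrm{RID} = \\textstyle\\sum_{worm} I - \\bar I_{bg}\\,A

  where :math:`A` is the mask pixel count.  The two are algebraically
  identical when computed over the same region; both are reported.
* **Puncta morphometry** — sizes of discrete bright foci (e.g.
  polyglutamine aggregates), reported relative to the worm area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import PeakParams

_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class PeakSet:
    """Accepted fluorescence peaks within one worm crop."""

    coordinates: np.ndarray  # (n, 2) int, crop-relative (row, col)
    intensities: np.ndarray

    @property
    def count(self) -> int:
        return len(self.intensities)

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensities)) if self.count else math.nan

    @property
    def std_intensity(self) -> float:
        if self.count == 0:
            return math.nan
        if self.count == 1:
            return 0.0
        return float(np.std(self.intensities, ddof=0))


@dataclass
class FluorRecord:
    """One worm's fluorescence features for a single channel."""

    peak_count: int = 0
    peak_mean: float = math.nan
    peak_std: float = math.nan
    ctwf: float = math.nan
    rid: float = math.nan
    background_mean: float = math.nan
    puncta_sizes_px: list[int] = field(default_factory=list)
    puncta_mean_relsize_pct: float = math.nan


def find_peaks(fl_crop: np.ndarray, mask: np.ndarray, params: PeakParams) -> PeakSet:
    """Locate local intensity maxima within the worm mask.

    A candidate is a pixel that (a) reaches ``threshold_frac`` of the crop
    maximum and (b) matches the maximum of its ``neighborhood`` square
    (plateau tops qualify, like the usual local-maxima finders).
    Candidates outside the mask are discarded, then greedy suppression in
    descending intensity order (ties broken by row, then column) rejects
    any candidate inside an accepted peak's neighborhood square.
    """
    fl = np.asarray(fl_crop, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    peak_floor = params.threshold_frac * float(fl.max(initial=0.0))
    if fl.size == 0 or fl.max() <= 0:
        return PeakSet(np.empty((0, 2), dtype=int), np.empty(0))

    n = params.neighborhood
    neighbor_max = ndimage.maximum_filter(fl, size=n, mode="constant", cval=-np.inf)
    candidate = (fl >= neighbor_max) & (fl >= peak_floor) & mask
    coords = np.argwhere(candidate)
    if len(coords) == 0:
        return PeakSet(np.empty((0, 2), dtype=int), np.empty(0))

    vals = fl[coords[:, 0], coords[:, 1]]
    order = np.lexsort((coords[:, 1], coords[:, 0], -vals))
    half = n // 2
    accepted: list[int] = []
    for idx in order:
        r, c = coords[idx]
        ok = True
        for j in accepted:
            if abs(int(coords[j, 0]) - r) <= half and abs(int(coords[j, 1]) - c) <= half:
                ok = False
                break
        if ok:
            accepted.append(int(idx))
    accepted_coords = coords[accepted]
    return PeakSet(accepted_coords, fl[accepted_coords[:, 0], accepted_coords[:, 1]])


def background_mean(fl_crop: np.ndarray, mask: np.ndarray) -> float:
    """Mean raw intensity of the non-worm pixels of the crop."""
    mask = np.asarray(mask).astype(bool)
    outside = ~mask
    if not outside.any():
        raise ValueError("mask fills the crop; background cannot be estimated")
    return float(np.asarray(fl_crop, dtype=np.float64)[outside].mean())


def ctwf(fl_crop: np.ndarray, mask: np.ndarray, background: float) -> float:
    """Corrected total worm fluorescence: (mean worm − mean background) × area."""
    mask = np.asarray(mask).astype(bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("mask is empty")
    worm_mean = float(np.asarray(fl_crop, dtype=np.float64)[mask].mean())
    return (worm_mean - background) * n_px


def rid(fl_crop: np.ndarray, mask: np.ndarray, background: float) -> float:
    """Raw integrated density: Σ worm intensities − mean background × area."""
    mask = np.asarray(mask).astype(bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("mask is empty")
    total = float(np.asarray(fl_crop, dtype=np.float64)[mask].sum())
    return total - background * n_px


def puncta_morphometry(
    fl_crop: np.ndarray,
    mask: np.ndarray,
    peaks: PeakSet,
    params: PeakParams,
) -> tuple[list[int], float]:
    """Segment bright puncta and report sizes relative to worm area.

    Puncta are the connected components of ``fl >= threshold_frac × max``
    (within the mask) that contain at least one accepted peak.  Returns the
    per-punctum pixel areas and their mean as a percentage of the worm mask
    area (natural-log transformation, when wanted, is left to the analysis
    layer).
    """
    mask = np.asarray(mask).astype(bool)
    if peaks.count == 0:
        return [], math.nan
    fl = np.asarray(fl_crop, dtype=np.float64)
    inside_max = float(fl[mask].max())
    bright = (fl >= params.threshold_frac * inside_max) & mask
    labels, _ = ndimage.label(bright, structure=_CONN8)
    peak_labels = {
        int(labels[r, c]) for r, c in peaks.coordinates if labels[r, c] != 0
    }
    if not peak_labels:
        return [], math.nan
    areas = np.bincount(labels.ravel())
    sizes = sorted(int(areas[lab]) for lab in peak_labels)
    mean_rel = float(np.mean(sizes)) / float(mask.sum()) * 100.0
    return sizes, mean_rel


def measure_fluorescence(
    fl_crop: np.ndarray, mask: np.ndarray, params: PeakParams
) -> FluorRecord:
    """Full fluorescence record (peaks, CTWF/RID, puncta) for one channel."""
    record = FluorRecord()
    peaks = find_peaks(fl_crop, mask, params)
    record.peak_count = peaks.count
    record.peak_mean = peaks.mean_intensity
    record.peak_std = peaks.std_intensity
    try:
        bg = background_mean(fl_crop, mask)
    except ValueError:
        return record
    record.background_mean = bg
    record.ctwf = ctwf(fl_crop, mask, bg)
    record.rid = rid(fl_crop, mask, bg)
    record.puncta_sizes_px, record.puncta_mean_relsize_pct = puncta_morphometry(
        fl_crop, mask, peaks, params
    )
    return record
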