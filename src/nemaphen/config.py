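"""Acquisition presets and pipeline parameter containers.

Plate images arrive with a physical pixel size set by the objective used at
acquisition.  Three named presets cover the common magnifications for worm
plates (10X, 4X and 2X objectives); each preset also carries sensible
defaults for the segmentation parameters, which scale with resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

#: Minimum admissible bright-field contrast (standard deviation of the
#: grayscale image on the [0, 1] scale).  Images below this cannot be
#: segmented reliably and are refused before any processing.
MIN_CONTRAST = 0.04

#: Contrast range typically observed on well-prepared agarose plates.
TYPICAL_CONTRAST_RANGE = (0.06, 0.15)


@dataclass(frozen=True)
class AcquisitionPreset:
    """Named bundle of pixel size plus default segmentation parameters.

    Attributes
    ----------
    name : str
        One of ``high``, ``medium``, ``low``.
    um_per_pixel : float
        Physical pixel pitch in micrometres (square pixels assumed).
    neighborhood : int
        Default adaptive-threshold window (pixels, odd).
    threshold : float
        Default relative-intensity sensitivity for thresholding.
    min_object_area : int
        Default minimum connected-component area (pixels).
    """

    name: str
    um_per_pixel: float
    neighborhood: int = 101
    threshold: float = 0.10
    min_object_area: int = 200

    @property
    def pixel_height_um(self) -> float:
        return self.um_per_pixel

    @property
    def pixel_width_um(self) -> float:
        return self.um_per_pixel


# 10X objective = 0.45 um/px, 4X = 1.14 um/px, 2X = 5.14 um/px.  Window and
# area defaults scale roughly with the number of pixels an adult worm spans.
PRESETS: dict[str, AcquisitionPreset] = {
    "high": AcquisitionPreset("high", 0.45, neighborhood=251, threshold=0.10, min_object_area=1200),
    "medium": AcquisitionPreset("medium", 1.14, neighborhood=101, threshold=0.10, min_object_area=200),
    "low": AcquisitionPreset("low", 5.14, neighborhood=25, threshold=0.10, min_object_area=30),
}


def get_preset(name: str) -> AcquisitionPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None


@dataclass(frozen=True)
class ThresholdParams:
    """Free parameters of binarization, cleaning and size gating.

    ``neighborhood`` is the side of the square window used for the local
    mean; ``threshold`` the relative sensitivity (a pixel is foreground when
    darker than ``(1 - threshold)`` times its local mean); ``area_range``
    bounds retained component areas relative to the per-image median
    component area.
    """

    neighborhood: int = 101
    threshold: float = 0.10
    min_object_area: int = 200
    area_range: tuple[float, float] = (0.3, 3.0)
    invert_polarity: bool = False

    def __post_init__(self) -> None:
        if self.neighborhood < 3 or self.neighborhood % 2 == 0:
            raise ValueError(f"neighborhood must be odd and >= 3, got {self.neighborhood}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be non-negative")
        lo, hi = self.area_range
        if not lo < 1.0 < hi:
            raise ValueError(f"area_range must bracket 1.0, got {self.area_range}")

    @classmethod
    def from_preset(cls, preset: AcquisitionPreset, **overrides) -> "ThresholdParams":
        base = dict(
            neighborhood=preset.neighborhood,
            threshold=preset.threshold,
            min_object_area=preset.min_object_area,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class PeakParams:
    """Parameters of fluorescence peak detection.

    ``neighborhood`` is the side of the square suppression window around an
    accepted peak; ``threshold_frac`` the minimum intensity as a fraction of
    the crop maximum.
    """

    neighborhood: int = 11
    threshold_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.neighborhood < 3 or self.neighborhood % 2 == 0:
            raise ValueError(f"neighborhood must be odd and >= 3, got {self.neighborhood}")
        if not 0.0 < self.threshold_frac <= 1.0:
            raise ValueError(f"threshold_frac must lie in (0, 1], got {self.threshold_frac}")


@dataclass
class PipelineConfig:
    """Full run configuration, loadable from JSON or YAML.

    ``channel_map`` maps TIFF page index to channel name; page 0 defaults to
    the mandatory bright-field ("BF") channel.  ``max_input_bytes`` is
    enforced before decode to avoid memory exhaustion on oversized inputs.
    """

    preset: str = "medium"
    um_per_pixel: float | None = None
    channel_map: dict[int, str] = field(default_factory=lambda: {0: "BF"})
    threshold_params: ThresholdParams = field(default_factory=ThresholdParams)
    peak_params: PeakParams = field(default_factory=PeakParams)
    max_input_bytes: int = 1_000_000_000
    end_brightness_radius_px: int = 10
    euclidean_length: bool = False

    @property
    def acquisition(self) -> AcquisitionPreset:
        preset = get_preset(self.preset)
        if self.um_per_pixel is not None:
            preset = replace(preset, um_per_pixel=self.um_per_pixel)
        return preset

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for key in ("preset", "um_per_pixel", "max_input_bytes", "end_brightness_radius_px"):
            if key in raw:
                kwargs[key] = raw[key]
        if "channel_map" in raw:
            kwargs["channel_map"] = {int(k): str(v) for k, v in raw["channel_map"].items()}
        preset = get_preset(kwargs.get("preset", "medium"))
        tp_keys = ("neighborhood", "threshold", "min_area_px", "area_range", "invert_polarity")
        tp: dict = {}
        for key in tp_keys:
            if key in raw:
                tp["min_object_area" if key == "min_area_px" else key] = (
                    tuple(raw[key]) if key == "area_range" else raw[key]
                )
        kwargs["threshold_params"] = ThresholdParams.from_preset(preset, **tp)
        pp: dict = {}
        if "peak_neighborhood" in raw:
            pp["neighborhood"] = raw["peak_neighborhood"]
        if "peak_threshold_frac" in raw:
            pp["threshold_frac"] = raw["peak_threshold_frac"]
        if pp:
            kwargs["peak_params"] = PeakParams(**pp)
        return cls(**kwargs)
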