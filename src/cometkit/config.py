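"""Pipeline configuration.

All stage parameters live in one dataclass so a single object (or a flat
key-value file) fully determines a run.  Defaults reflect 8-bit fluorescence
micrographs of comet assays: a dark, nearly uniform background with bright
compact heads and rightward-decaying tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal


@dataclass
class PipelineConfig:
    """Parameters for the four-stage comet analysis pipeline.

    Parameters
    ----------
    smoothing_method
        ``"median"`` or ``"mean"`` moving-window filter applied before
        thresholding; ``"none"`` disables smoothing.
    smoothing_window
        Odd window size in pixels for the smoothing filter.
    histogram_bins
        Number of uniform intensity bins over [0, 255].
    histogram_smooth_window
        Odd moving-average window applied to histogram counts before the
        first-valley search.
    threshold_method
        ``"valley"`` (first histogram valley after the background peak,
        falling back to Otsu when no valley exists) or ``"otsu"``.
    head_threshold
        HT, the user-specified fraction of the peak profile intensity that
        delimits the head.  The default 0.5 puts the head edge at the
        profile's half-maximum; much lower values let the head swallow the
        near tail on connected comets, because the head/tail junction of
        any connected mask integrates well above a few percent of the peak.
    small_fragment_fraction
        Components smaller than this fraction of total image pixels are
        merged into the nearest larger component.
    fourier_roundness_min
        Minimum share of contour-spectrum amplitude carried by the two
        lowest (+/-1) frequencies for a chunk to count as a cell.
    area_ratio_min
        Minimum chunk area as a fraction of its parent mask's area.
    wavelet_level
        Decomposition depth of the Haar smoothing applied to the distance
        relief before watershed.
    seed_prominence_h
        Regional maxima of the smoothed relief shallower than this
        prominence (in distance units) are suppressed before seeding the
        watershed; 0 disables the suppression.
    horizontal_overlap_min
        Column-range overlap fraction (of the smaller chunk) above which
        vertically stacked watershed chunks are merged back together.
    centroid_match_radius_px
        Matching radius for centroid-based detection scoring.
    tail_direction
        ``"+x"`` when tails extend rightward (the usual acquisition),
        ``"-x"`` for mirrored images.
    channel
        RGB-to-gray conversion: ``"luminance"`` (0.299R+0.587G+0.114B) or
        one of ``"r"/"g"/"b"`` to select a single channel.
    """

    smoothing_method: Literal["median", "mean", "none"] = "median"
    smoothing_window: int = 5
    histogram_bins: int = 256
    histogram_smooth_window: int = 5
    threshold_method: Literal["valley", "otsu"] = "valley"
    head_threshold: float = 0.5
    small_fragment_fraction: float = 0.001
    fourier_roundness_min: float = 0.70
    area_ratio_min: float = 0.03
    wavelet_level: int = 2
    seed_prominence_h: float = 1.5
    horizontal_overlap_min: float = 0.5
    centroid_match_radius_px: float = 15.0
    tail_direction: Literal["+x", "-x"] = "+x"
    channel: Literal["luminance", "r", "g", "b"] = "luminance"
    contour_points: int = 64
    overlap_correction: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("smoothing_window", "histogram_smooth_window"):
            w = getattr(self, name)
            if w < 1 or w % 2 == 0:
                raise ValueError(f"{name} must be an odd positive integer, got {w}")
        if not 0.0 < self.head_threshold <= 1.0:
            raise ValueError("head_threshold must lie in (0, 1]")
        for name in ("small_fragment_fraction", "fourier_roundness_min",
                     "area_ratio_min", "horizontal_overlap_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        if self.centroid_match_radius_px <= 0:
            raise ValueError("centroid_match_radius_px must be positive")
        if self.wavelet_level < 1:
            raise ValueError("wavelet_level must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key = value`` (or ``key: value``) config file."""
        text = Path(path).read_text()
        kwargs: dict = {}
        fields = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in ("=", ":"):
                if sep in line:
                    key, val = (s.strip() for s in line.split(sep, 1))
                    break
            else:
                raise ValueError(f"cannot parse config line: {raw!r}")
            if key not in fields:
                raise KeyError(f"unknown config key: {key}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes", "on")
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)
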