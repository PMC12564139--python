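"""CT contrast adjustment: linear HU windowing, gamma correction,
percentile (histogram / ROI) windowing and slice-wise CLAHE.

All transforms map an HU volume to a normalized [0, 1] volume. Percentiles
use linear interpolation between order statistics (numpy's default), and the
ROI variant computes the bounds inside the mask plus a Euclidean dilation
("immediate surroundings") but applies them to the whole image.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

from .errors import DegenerateInputError, ParameterError
from .io import Mask, Volume

__all__ = [
    "WindowSpec",
    "WINDOW_METHODS",
    "window_linear",
    "gamma_correct",
    "percentile_window",
    "clahe_slicewise",
    "apply_windowing",
    "study_window_specs",
]

WINDOW_METHODS = ("none", "bone", "bone_gamma", "histogram", "clahe", "roi")


@dataclass(frozen=True)
class WindowSpec:
    """Parameters of one contrast-adjustment method.

    Defaults follow clinical bone-window practice: window level 400 HU,
    width 2000 HU, gamma in {0.5, 1.0, 2.0}, percentile bounds 5/95.
    """

    method: str = "bone"
    level: float = 400.0
    width: float = 2000.0
    gamma: float = 1.0
    lo_pct: float = 5.0
    hi_pct: float = 95.0
    clahe_clip: float = 0.01
    clahe_tiles: int = 8
    roi_dilation_mm: float = 3.0

    def __post_init__(self):
        if self.method not in WINDOW_METHODS:
            raise ParameterError(f"method must be one of {WINDOW_METHODS}, got {self.method!r}")
        if not self.width > 0:
            raise ParameterError(f"window width must be > 0, got {self.width}")
        if not self.gamma > 0:
            raise ParameterError(f"gamma must be > 0, got {self.gamma}")
        if not (0 <= self.lo_pct < self.hi_pct <= 100):
            raise ParameterError(
                f"need 0 <= lo_pct < hi_pct <= 100, got {self.lo_pct}, {self.hi_pct}"
            )
        if self.clahe_tiles < 1:
            raise ParameterError("clahe_tiles must be >= 1")


def window_linear(vol: Volume, level: float = 400.0, width: float = 2000.0) -> Volume:
    """Map [level - width/2, level + width/2] linearly onto [0, 1], clipping."""
    if not width > 0:
        raise ParameterError(f"window width must be > 0, got {width}")
    lo = level - width / 2.0
    return vol.with_data(np.clip((vol.data - lo) / width, 0.0, 1.0))


def gamma_correct(norm_vol: Volume, gamma: float) -> Volume:
    """Pointwise v -> v**gamma on a [0, 1] volume; order-preserving."""
    if not gamma > 0:
        raise ParameterError(f"gamma must be > 0, got {gamma}")
    d = norm_vol.data
    if d.min() < 0 or d.max() > 1:
        raise ParameterError("gamma_correct expects input values in [0, 1]")
    return norm_vol.with_data(d**gamma)


def _dilate_mm(mask: Mask, radius_mm: float) -> np.ndarray:
    if radius_mm <= 0:
        return mask.data.astype(bool)
    dist = ndimage.distance_transform_edt(~mask.data.astype(bool), sampling=mask.spacing)
    return dist <= radius_mm


def percentile_window(
    vol: Volume,
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
    mask: Mask | None = None,
    dilation_mm: float = 3.0,
) -> Volume:
    """Window between intensity percentiles.

    With ``mask=None`` the percentiles come from the whole image
    (histogram-based windowing); with a mask they come from the ROI plus a
    ``dilation_mm`` Euclidean dilation, and are applied uniformly to the
    entire image (ROI-based windowing).
    """
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ParameterError(f"need 0 <= lo_pct < hi_pct <= 100, got {lo_pct}, {hi_pct}")
    if mask is None:
        values = vol.data.ravel()
    else:
        region = _dilate_mm(mask, dilation_mm)
        if not region.any():
            raise DegenerateInputError("percentile source region is empty")
        values = vol.data[region]
    p_lo, p_hi = np.percentile(values, [lo_pct, hi_pct])
    if p_lo == p_hi:
        raise DegenerateInputError(
            f"degenerate window: p{lo_pct} == p{hi_pct} == {p_lo} over the source region"
        )
    return vol.with_data(np.clip((vol.data - p_lo) / (p_hi - p_lo), 0.0, 1.0))


def clahe_slicewise(vol: Volume, clip: float = 0.01, tiles: int = 8) -> Volume:
    """Contrast-limited adaptive histogram equalization per axial slice.

    Input must already be scaled to [0, 1]; constant slices pass through
    unchanged (their histogram is flat after equalization anyway).
    """
    if tiles < 1:
        raise ParameterError("tiles must be >= 1")
    d = vol.data
    if d.min() < 0 or d.max() > 1:
        raise ParameterError("clahe_slicewise expects input values in [0, 1]")
    out = np.empty_like(d)
    nx, ny, _ = d.shape
    kernel = (max(1, nx // tiles), max(1, ny // tiles))
    for k in range(d.shape[2]):
        sl = d[:, :, k]
        if sl.max() == sl.min():
            out[:, :, k] = sl
        else:
            out[:, :, k] = exposure.equalize_adapthist(sl, kernel_size=kernel, clip_limit=clip)
    return vol.with_data(np.clip(out, 0.0, 1.0))


def _minmax(vol: Volume) -> Volume:
    lo, hi = float(vol.data.min()), float(vol.data.max())
    if lo == hi:
        raise DegenerateInputError("constant volume cannot be min-max scaled")
    return vol.with_data((vol.data - lo) / (hi - lo))


def apply_windowing(vol: Volume, spec: WindowSpec, mask: Mask | None = None) -> Volume:
    """Dispatch over the contrast-adjustment methods.

    ``none`` is plain min-max scaling; ``bone_gamma`` is linear bone
    windowing followed by gamma correction; ``roi`` requires a mask.
    """
    m = spec.method
    if m == "none":
        return _minmax(vol)
    if m == "bone":
        return window_linear(vol, spec.level, spec.width)
    if m == "bone_gamma":
        return gamma_correct(window_linear(vol, spec.level, spec.width), spec.gamma)
    if m == "histogram":
        return percentile_window(vol, spec.lo_pct, spec.hi_pct)
    if m == "clahe":
        return clahe_slicewise(_minmax(vol), spec.clahe_clip, spec.clahe_tiles)
    if m == "roi":
        if mask is None:
            raise ParameterError("method 'roi' requires a segmentation mask")
        return percentile_window(vol, spec.lo_pct, spec.hi_pct, mask, spec.roi_dilation_mm)
    raise ParameterError(f"unknown method {m!r}")  # pragma: no cover


def study_window_specs() -> dict:
    """The seven windowing configurations compared in the analysis."""
    return {
        "none": WindowSpec(method="none"),
        "clahe": WindowSpec(method="clahe"),
        "bone": WindowSpec(method="bone"),
        "bone_g0.5": WindowSpec(method="bone_gamma", gamma=0.5),
        "bone_g2.0": WindowSpec(method="bone_gamma", gamma=2.0),
        "histogram": WindowSpec(method="histogram"),
        "roi": WindowSpec(method="roi"),
    }
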