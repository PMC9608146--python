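"""Channel binarization and the per-image differentiation ratio (DR).

Each unmixed stain channel is binarized with a global auto-threshold on its
8-bit histogram; stained pixels are dark (transmittance coding), so a pixel
is positive iff its value <= threshold.  The DR of an image is the area
percentage of the differentiation channel divided by the area percentage of
the counterpart channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_isodata, threshold_mean, threshold_triangle

from .deconvolution import (
    ChannelImage,
    StainBasis,
    concentration_to_channel,
    rgb_to_od,
    unmix_image,
)
from .errors import DegenerateHistogramError, StainQuantError
from .illumination import CalibrationPair, correct_illumination
from .io import RGBImage

THRESHOLD_METHODS = ("otsu", "mean", "isodata", "triangle")


def otsu_threshold(pixels: np.ndarray) -> int:
    """Otsu's threshold on the 256-bin histogram of an 8-bit array.

    Maximizes the between-class variance w0*w1*(mu0 - mu1)^2 over all cuts
    "class 0 = values <= T"; ties are broken by the smallest qualifying T.
    Constant input raises :class:`DegenerateHistogramError`.
    """
    px = np.asarray(pixels)
    if px.dtype != np.uint8:
        raise ValueError("otsu_threshold expects 8-bit input")
    hist = np.bincount(px.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        value = int(np.argmax(hist))
        raise DegenerateHistogramError(
            f"constant channel (value {value}); Otsu threshold undefined", value
        )
    levels = np.arange(256, dtype=np.float64)
    p = hist / total
    w0 = np.cumsum(p)
    m0 = np.cumsum(p * levels)
    mu = m0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu * w0 - m0) ** 2 / (w0 * (1.0 - w0))
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def auto_threshold(channel: ChannelImage | np.ndarray, method: str = "otsu") -> float:
    """Global threshold on an 8-bit channel by the named histogram method."""
    px = channel.pixels if isinstance(channel, ChannelImage) else np.asarray(channel)
    if method not in THRESHOLD_METHODS:
        raise ValueError(
            f"unknown threshold method {method!r}; supported: {THRESHOLD_METHODS}"
        )
    if method == "otsu":
        return float(otsu_threshold(px))
    if px.min() == px.max():
        if method == "isodata":
            raise DegenerateHistogramError(
                f"constant channel (value {int(px.flat[0])}); isodata undefined",
                int(px.flat[0]),
            )
        return float(px.flat[0])
    if method == "mean":
        return float(threshold_mean(px))
    if method == "isodata":
        return float(threshold_isodata(px))
    return float(threshold_triangle(px))


@dataclass
class BinaryMask:
    pixels: np.ndarray  # H x W bool, True = stain-positive
    threshold_used: float
    method: str

    @property
    def positive_count(self) -> int:
        return int(np.count_nonzero(self.pixels))


def binarize(channel: ChannelImage | np.ndarray, threshold: float, method: str = "manual") -> BinaryMask:
    """Positive iff value <= threshold (dark = stained)."""
    px = channel.pixels if isinstance(channel, ChannelImage) else np.asarray(channel)
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return BinaryMask(px <= threshold, float(threshold), method)


def area_fraction(mask: BinaryMask | np.ndarray) -> float:
    """Percentage of positive pixels, 0-100."""
    px = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if px.size == 0:
        raise ValueError("empty mask")
    return 100.0 * float(np.count_nonzero(px)) / px.size


def differentiation_ratio(af1: float, af2: float) -> float:
    """DR = area%_1 / area%_2; NaN (undefined) when the denominator is 0.

    An undefined DR is a value, not an error: the record is retained but
    excluded from donor means.
    """
    if not (0 <= af1 <= 100 and 0 <= af2 <= 100):
        raise ValueError("area fractions must lie in [0, 100]")
    if af2 == 0:
        return math.nan
    return af1 / af2


@dataclass
class QuantRecord:
    """All per-image quantification outputs and the choices that made them."""

    image_id: str
    area_fraction_1: float
    area_fraction_2: float
    dr: float  # NaN when undefined (area_fraction_2 == 0)
    threshold_1: float
    threshold_2: float
    method: str
    od_floor_count: int = 0
    negative_pixel_count: int = 0
    saturation_fraction: float = 0.0

    @property
    def dr_defined(self) -> bool:
        return not math.isnan(self.dr)


def quantify_image(
    image: RGBImage,
    calib: CalibrationPair | None,
    basis: StainBasis,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> QuantRecord:
    """Run one micrograph through the full correct -> unmix -> DR chain.

    Thresholds are computed independently per channel unless
    ``fixed_threshold`` pins both.  ``calib=None`` is allowed only for
    already-corrected (float) input.  Component errors are re-raised with
    the image id attached.
    """
    image_id = image.source_path or "<in-memory>"
    try:
        if image.is_corrected:
            corrected = image
        elif calib is None:
            corrected = image.to_unit()
        else:
            corrected = correct_illumination(image, calib)
        od = rgb_to_od(corrected)
        maps = unmix_image(od, basis)
        ch1 = concentration_to_channel(maps.c1, basis.v1.name)
        ch2 = concentration_to_channel(maps.c2, basis.v2.name)
        if fixed_threshold is not None:
            t1 = t2 = float(fixed_threshold)
            used_method = "fixed"
        else:
            t1 = auto_threshold(ch1, method)
            t2 = auto_threshold(ch2, method)
            used_method = method
        m1 = binarize(ch1, t1, used_method)
        m2 = binarize(ch2, t2, used_method)
        af1 = area_fraction(m1)
        af2 = area_fraction(m2)
        return QuantRecord(
            image_id=image_id,
            area_fraction_1=af1,
            area_fraction_2=af2,
            dr=differentiation_ratio(af1, af2),
            threshold_1=t1,
            threshold_2=t2,
            method=used_method,
            od_floor_count=maps.od_floor_count,
            negative_pixel_count=sum(maps.negative_counts),
            saturation_fraction=float(corrected.meta.get("saturation_fraction", 0.0)),
        )
    except StainQuantError as exc:
        raise type(exc)(f"{image_id}: {exc}") from exc
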