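"""Flat-field correction from a darkfield / brightfield calibration pair.

A ``Dark`` frame (closed illumination path) captures the fixed-pattern
offset of the sensor, including hot pixels; a ``Light`` frame (empty well)
captures the illumination profile.  Each micrograph is corrected per pixel
and per color plane as

    corrected = (Original - Dark) / (Light - Dark)

which maps an empty well to transmittance 1 and cancels both additive
fixed-pattern noise and multiplicative shading.  The result is clipped to
[0, 1]; the fraction of clipped-above-1 pixels (specimen brighter than the
empty well) is recorded in the output's ``meta`` under ``saturation_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import CalibrationError
from .io import RGBImage

#: Invalid (light <= dark) pixels above this fraction abort rather than repair.
MAX_INVALID_FRACTION = 0.01
_REPAIR_ITERATIONS = 10


@dataclass
class CalibrationPair:
    """A matched darkfield/brightfield pair for one acquisition series."""

    dark: RGBImage
    light: RGBImage
    repaired_pixels: int = 0

    def __post_init__(self) -> None:
        if self.dark.shape != self.light.shape:
            raise CalibrationError(
                f"dark {self.dark.shape} and light {self.light.shape} differ in shape"
            )

    @property
    def invalid_mask(self) -> np.ndarray:
        """H x W boolean mask of pixels where any plane has light <= dark."""
        d = self.dark.pixels.astype(np.int32)
        l = self.light.pixels.astype(np.int32)
        return np.any(l <= d, axis=2)

    @property
    def is_valid(self) -> bool:
        return not self.invalid_mask.any()


def _neighbor_median(img: np.ndarray, y: int, x: int, valid: np.ndarray) -> np.ndarray | None:
    h, w = img.shape[:2]
    vals = []
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and valid[ny, nx]:
                vals.append(img[ny, nx])
    if not vals:
        return None
    return np.median(np.stack(vals), axis=0)


def repair_calibration(
    pair: CalibrationPair,
    max_invalid_fraction: float = MAX_INVALID_FRACTION,
) -> CalibrationPair:
    """Replace defective calibration pixels by their valid 8-neighbor median.

    A pixel is defective when light <= dark in any color plane (saturated or
    dead sites that dark subtraction cannot fix).  Both the dark and the
    light value at such sites are replaced by the median over valid
    8-neighbors, iterating up to 10 times until no defective pixel remains.
    More than ``max_invalid_fraction`` defective pixels raises
    :class:`CalibrationError` instead of silently repairing.
    """
    invalid = pair.invalid_mask
    n_invalid = int(invalid.sum())
    if n_invalid == 0:
        return pair
    frac = n_invalid / invalid.size
    if frac > max_invalid_fraction:
        raise CalibrationError(
            f"{n_invalid} of {invalid.size} calibration pixels "
            f"({100 * frac:.2f}%) have light <= dark; recapture the pair"
        )
    dark = pair.dark.pixels.astype(np.float64).copy()
    light = pair.light.pixels.astype(np.float64).copy()
    for _ in range(_REPAIR_ITERATIONS):
        invalid = np.any(light <= dark, axis=2)
        if not invalid.any():
            break
        valid = ~invalid
        coords = np.argwhere(invalid)
        new_dark = {}
        new_light = {}
        for y, x in coords:
            md = _neighbor_median(dark, y, x, valid)
            ml = _neighbor_median(light, y, x, valid)
            if md is not None and ml is not None and np.all(ml > md):
                new_dark[(y, x)] = md
                new_light[(y, x)] = ml
        if not new_dark:
            break
        for (y, x), v in new_dark.items():
            dark[y, x] = v
            light[y, x] = new_light[(y, x)]
    repaired = CalibrationPair(
        dark=replace(pair.dark, pixels=np.round(dark).astype(np.uint8)),
        light=replace(pair.light, pixels=np.round(light).astype(np.uint8)),
        repaired_pixels=n_invalid,
    )
    if not repaired.is_valid:
        raise CalibrationError(
            "calibration pair still has light <= dark pixels after repair"
        )
    return repaired


def correct_illumination(original: RGBImage, calib: CalibrationPair) -> RGBImage:
    """Apply the per-pixel, per-plane flat-field quotient (O - D) / (L - D).

    The calibration pair must already satisfy light > dark everywhere (run
    :func:`repair_calibration` first).  Output values are clipped to [0, 1];
    the pre-clip fraction above 1 is logged in ``meta['saturation_fraction']``
    and the pixel size is carried through unchanged.
    """
    if original.is_corrected:
        raise ValueError("image is already corrected (float pixels)")
    if original.shape != calib.dark.shape:
        raise CalibrationError(
            f"image shape {original.shape} does not match calibration {calib.dark.shape}"
        )
    if not calib.is_valid:
        raise CalibrationError(
            "calibration pair has light <= dark pixels; run repair_calibration first"
        )
    o = original.pixels.astype(np.float64)
    d = calib.dark.pixels.astype(np.float64)
    l = calib.light.pixels.astype(np.float64)
    corrected = (o - d) / (l - d)
    saturation_fraction = float(np.mean(corrected > 1.0))
    corrected = np.clip(corrected, 0.0, 1.0)
    meta = dict(original.meta)
    meta["saturation_fraction"] = saturation_fraction
    meta["calibration_repaired_pixels"] = calib.repaired_pixels
    return RGBImage(
        corrected,
        pixel_size_um=original.pixel_size_um,
        source_path=original.source_path,
        meta=meta,
    )
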