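"""Two-stain color deconvolution via the Beer-Lambert optical-density model.

A brightfield pixel with transmittance ``I`` (per color plane, in [0, 1])
has optical density ``OD = -log10(I)``.  Absorbances of co-localized dyes
add, so the OD vector of a pixel stained by two dyes with unit-norm OD
color vectors v1, v2 is

    od = c1 * v1 + c2 * v2 + c3 * v3

with c_s the per-stain amounts and v3 a residual direction orthogonal to
the stain plane.  Unmixing inverts this 3x3 linear system per pixel.  The
reconstructed per-stain channels are re-encoded as 8-bit transmittance
(255 = unstained, 0 = saturated stain) for thresholding, matching the
convention of brightfield deconvolution software.

Stain color vectors are instrument- and protocol-dependent.  The presets in
:data:`STAIN_PRESETS` are sensible starting points for the dyes of the three
differentiation assays, but a calibration against your own stained material
(``estimate_stain_vector`` on a single-dye region of interest) is
recommended before quantitative use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BasisError, StainEstimationError
from .io import RGBImage, LineageSpec, LINEAGE_SPECS

#: Transmittance floor: one half-step below the smallest nonzero 8-bit level.
OD_EPS = 1.0 / 255.0
#: Largest representable OD per plane, -log10(1/255).
OD_MAX = float(np.log10(255.0))


@dataclass(frozen=True)
class StainVector:
    """Unit-norm optical-density color triple (R, G, B) of one dye."""

    name: str
    od: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.od, dtype=float)
        if v.shape != (3,):
            raise ValueError("stain vector needs exactly 3 components")
        n = float(np.linalg.norm(v))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"stain vector {self.name!r} is not unit-norm (|v|={n})")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.od, dtype=float)


def normalize_stain_vector(raw, name: str = "stain") -> StainVector:
    """Scale a non-negative OD triple to unit Euclidean norm."""
    v = np.asarray(raw, dtype=float)
    if v.shape != (3,):
        raise ValueError("stain vector needs exactly 3 components")
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("zero stain vector cannot be normalized")
    v = v / n
    return StainVector(name, (float(v[0]), float(v[1]), float(v[2])))


#: Raw OD triples per dye (normalized on use).  hematoxylin follows the
#: classic published calibration; the others are plug-in-style defaults for
#: red (Oil Red O, Alizarin Red S, Nuclear Fast Red), blue (Alcian Blue) and
#: purple (non-mineralized osteogenic background) absorbers.  All are
#: calibration-recommended: override via config or estimate_stain_vector.
STAIN_PRESETS: dict[str, tuple[float, float, float]] = {
    "hematoxylin": (0.650, 0.704, 0.286),
    "oil_red_o": (0.170, 0.840, 0.515),
    "alcian_blue": (0.875, 0.458, 0.158),
    "nuclear_fast_red": (0.214, 0.851, 0.478),
    "alizarin_red_s": (0.247, 0.822, 0.511),
    "osteo_purple": (0.583, 0.720, 0.377),
}


def preset_stain_vector(name: str) -> StainVector:
    try:
        raw = STAIN_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown stain preset {name!r}; available: {sorted(STAIN_PRESETS)}"
        ) from None
    return normalize_stain_vector(raw, name)


@dataclass(frozen=True)
class StainBasis:
    """Two stain vectors plus the derived residual, with the unmixing inverse.

    Row i of ``matrix`` is the OD direction of stain i; ``unmix_matrix`` is
    its inverse, so for a pixel OD row-vector ``od``, the stain amounts are
    ``od @ unmix_matrix``.
    """

    v1: StainVector
    v2: StainVector
    v3: StainVector

    @property
    def matrix(self) -> np.ndarray:
        return np.stack([self.v1.array, self.v2.array, self.v3.array])

    @property
    def unmix_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def swapped(self) -> "StainBasis":
        """Basis with channel 1 and channel 2 roles exchanged."""
        return complete_stain_basis(self.v2, self.v1)


def complete_stain_basis(v1: StainVector, v2: StainVector) -> StainBasis:
    """Derive the residual third vector and build the unmixing basis.

    v3 is the normalized cross product v1 x v2, sign-flipped when its
    component sum is negative, so the residual direction leans into the
    positive OD octant where possible.
    """
    a, b = v1.array, v2.array
    if abs(float(a @ b)) >= 1.0 - 1e-6:
        raise BasisError(
            f"stain vectors {v1.name!r} and {v2.name!r} are collinear; "
            "two-stain unmixing is impossible"
        )
    c = np.cross(a, b)
    c = c / np.linalg.norm(c)
    if c.sum() < 0:
        c = -c
    v3 = StainVector("residual", (float(c[0]), float(c[1]), float(c[2])))
    return StainBasis(v1, v2, v3)


def lineage_basis(lineage: str | LineageSpec) -> StainBasis:
    """Preset basis for one differentiation lineage."""
    spec = LINEAGE_SPECS[lineage] if isinstance(lineage, str) else lineage
    return complete_stain_basis(
        preset_stain_vector(spec.stain_1), preset_stain_vector(spec.stain_2)
    )


def rgb_to_od(image: RGBImage | np.ndarray) -> np.ndarray:
    """Optical density -log10(I) per plane, floored at transmittance 1/255.

    The input must be corrected (real-valued in [0, 1]); raw 8-bit images
    must pass through ``correct_illumination`` or ``RGBImage.to_unit`` first.
    """
    px = image.pixels if isinstance(image, RGBImage) else np.asarray(image)
    if not np.issubdtype(px.dtype, np.floating):
        raise TypeError(
            "rgb_to_od expects corrected real-valued input in [0, 1]; run "
            "correct_illumination (or .to_unit() for an explicit /255 conversion)"
        )
    return -np.log10(np.clip(px, OD_EPS, 1.0))


@dataclass
class ConcentrationMaps:
    """Per-stain OD contribution maps from unmixing one image."""

    c1: np.ndarray
    c2: np.ndarray
    c3: np.ndarray
    od_floor_count: int = 0
    negative_counts: tuple[int, int, int] = (0, 0, 0)


def unmix_image(od: np.ndarray, basis: StainBasis) -> ConcentrationMaps:
    """Invert the Beer-Lambert mixture per pixel.

    Negative amounts (OD outside the stain cone, from noise or dyes not in
    the basis) are floored to zero after counting; the count per channel is
    kept for QC.  ``od_floor_count`` counts pixels clamped at the
    transmittance floor in any plane.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 OD array, got {od.shape}")
    conc = od @ basis.unmix_matrix
    negative_counts = tuple(
        int(np.count_nonzero(conc[:, :, i] < 0)) for i in range(3)
    )
    conc = np.maximum(conc, 0.0)
    floor_count = int(np.count_nonzero(np.any(od >= OD_MAX - 1e-12, axis=2)))
    return ConcentrationMaps(
        c1=conc[:, :, 0],
        c2=conc[:, :, 1],
        c3=conc[:, :, 2],
        od_floor_count=floor_count,
        negative_counts=negative_counts,
    )


@dataclass
class ChannelImage:
    """8-bit transmittance-coded single-stain channel (255 = no stain)."""

    pixels: np.ndarray
    stain: str

    def __post_init__(self) -> None:
        if self.pixels.dtype != np.uint8:
            raise ValueError("channel images are 8-bit")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # x >= 0 throughout the pipeline, so half-away == floor(x + 0.5)
    return np.floor(x + 0.5)


def concentration_to_channel(c: np.ndarray, stain: str = "") -> ChannelImage:
    """Re-encode a concentration map as 8-bit transmittance 255 * 10^-c."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative (floored)")
    vals = _round_half_away(255.0 * np.power(10.0, -c))
    return ChannelImage(np.clip(vals, 0, 255).astype(np.uint8), stain)


def estimate_stain_vector(
    pixels: np.ndarray, name: str = "estimated", min_od_norm: float = 0.05
) -> StainVector:
    """Estimate a dye's color vector from corrected RGB pixels of an ROI.

    This mechanizes the calibration step of picking a single-dye region on a
    collage of differentiated and control wells: the mean OD vector over the
    ROI, normalized to unit length.  Requires >= 10 pixels and a visibly
    stained ROI (mean OD norm >= ``min_od_norm``).
    """
    pts = np.asarray(pixels, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 10:
        raise StainEstimationError(
            f"need at least 10 ROI pixels to estimate a stain vector, got {pts.shape[0]}"
        )
    od = -np.log10(np.clip(pts, OD_EPS, 1.0))
    mean_od = od.mean(axis=0)
    if float(np.linalg.norm(mean_od)) < min_od_norm:
        raise StainEstimationError("ROI contains no stain (mean OD norm below 0.05)")
    return normalize_stain_vector(mean_od, name)
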