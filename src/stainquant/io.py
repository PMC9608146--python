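"""Image and table I/O plus study-tree discovery.

The directory convention for a study is::

    <root>/<donor>/<condition>/<well>/<image>.{png,tif,tiff}

where ``condition`` is ``differentiated`` or ``control``.  Chondrogenic
studies omit the well level: each paraffin section image sits directly under
the condition directory and is treated as its own single-image replicate, so
the nested mean (images -> well -> donor) degenerates to the plain mean over
sections, as intended.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, LayoutError

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff")
CONDITIONS = ("differentiated", "control")
LINEAGES = ("adipogenic", "chondrogenic", "osteogenic")


@dataclass
class RGBImage:
    """An H x W x 3 brightfield micrograph.

    ``pixels`` is uint8 in [0, 255] on ingest and float64 in [0, 1] after
    flat-field correction.  ``pixel_size_um`` is the physical edge length of
    one pixel in micrometres and must come from the acquisition config, not
    from image metadata.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    source_path: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(
                f"expected an H x W x 3 array, got shape {px.shape}"
                + (f" ({self.source_path})" if self.source_path else "")
            )
        if px.dtype == np.uint8:
            pass
        elif np.issubdtype(px.dtype, np.floating):
            if px.size and (px.min() < -1e-9 or px.max() > 1 + 1e-9):
                raise FormatError(
                    "float image values must lie in [0, 1] (corrected form)"
                )
        else:
            raise FormatError(
                f"unsupported pixel dtype {px.dtype}; expected uint8 or float"
            )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be strictly positive")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    @property
    def is_corrected(self) -> bool:
        """True once pixels are real-valued transmittance in [0, 1]."""
        return np.issubdtype(self.pixels.dtype, np.floating)

    def to_unit(self) -> "RGBImage":
        """Explicit /255 conversion for images that need no flat-field step."""
        if self.is_corrected:
            return self
        return RGBImage(
            self.pixels.astype(np.float64) / 255.0,
            pixel_size_um=self.pixel_size_um,
            source_path=self.source_path,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class LineageSpec:
    """Names the stain pair of one differentiation lineage.

    ``stain_1`` is the differentiation dye (channel 1, the numerator of the
    DR); ``stain_2`` is the counterpart signal (channel 2): nuclei for the
    adipogenic and chondrogenic assays, non-mineralized cell-culture area for
    the osteogenic assay.  Dye-dense pixels are dark in the reconstructed
    transmittance channel, so positivity is value <= threshold.
    """

    lineage: str
    stain_1: str
    stain_2: str
    denominator: str  # "nuclear" or "culture-area"

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}; expected one of {LINEAGES}")
        if self.stain_1 == self.stain_2:
            raise ValueError("stain_1 and stain_2 must differ")


#: Default stain pairing per lineage: Oil Red O vs hematoxylin nuclei
#: (adipogenic), Alcian Blue vs Nuclear Fast Red nuclei (chondrogenic),
#: Alizarin Red S vs the purple non-mineralized signal (osteogenic).
LINEAGE_SPECS: dict[str, LineageSpec] = {
    "adipogenic": LineageSpec("adipogenic", "oil_red_o", "hematoxylin", "nuclear"),
    "chondrogenic": LineageSpec("chondrogenic", "alcian_blue", "nuclear_fast_red", "nuclear"),
    "osteogenic": LineageSpec("osteogenic", "alizarin_red_s", "osteo_purple", "culture-area"),
}


def read_rgb_image(
    path: str | Path,
    pixel_size_um: float = 1.0,
    allow_downscale: bool = False,
) -> RGBImage:
    """Read an 8-bit RGB raster (PNG/TIFF) without silent bit-depth changes.

    RGBA input is accepted only when the alpha plane is constant (it is then
    dropped).  16-bit input is rejected unless ``allow_downscale`` is set, in
    which case the top 8 bits are kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 2:
        raise FormatError(f"grayscale input rejected (need 3-channel RGB): {path}")
    if arr.ndim != 3:
        raise FormatError(f"cannot interpret {path} with shape {arr.shape} as RGB")
    if arr.shape[2] == 4:
        alpha = arr[:, :, 3]
        if alpha.min() != alpha.max():
            raise FormatError(f"RGBA with varying alpha rejected: {path}")
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise FormatError(f"expected 3 color planes, got {arr.shape[2]}: {path}")
    if arr.dtype == np.uint16:
        if not allow_downscale:
            raise FormatError(
                f"16-bit input rejected: {path}; supply 8-bit images or pass "
                "allow_downscale=True for an explicit >>8 conversion"
            )
        arr = (arr >> 8).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise FormatError(f"unsupported bit depth {arr.dtype} in {path}; need 8-bit")
    return RGBImage(arr, pixel_size_um=pixel_size_um, source_path=str(path))


def write_rgb_image(image: RGBImage, path: str | Path) -> Path:
    """Write an 8-bit RGBImage to PNG or TIFF (by extension)."""
    path = Path(path)
    if image.is_corrected:
        raise FormatError("only 8-bit images are written to disk")
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, image.pixels)
    return path


@dataclass
class DonorLayout:
    donor: str
    #: condition -> well name -> ordered image paths
    conditions: dict[str, dict[str, list[Path]]]
    warnings: list[str] = field(default_factory=list)

    def n_images(self, condition: str) -> int:
        wells = self.conditions.get(condition, {})
        return sum(len(v) for v in wells.values())


@dataclass
class StudyLayout:
    lineage: str
    root: Path
    donors: dict[str, DonorLayout]
    calibration: dict[str, Path] = field(default_factory=dict)

    @property
    def n_images(self) -> int:
        return sum(
            d.n_images(c) for d in self.donors.values() for c in d.conditions
        )

    def iter_images(self):
        """Yield (donor, condition, well, path) in deterministic order."""
        for donor in sorted(self.donors):
            dl = self.donors[donor]
            for condition in sorted(dl.conditions):
                for well in sorted(dl.conditions[condition]):
                    for path in dl.conditions[condition][well]:
                        yield donor, condition, well, path


def discover_study(
    root: str | Path,
    lineage: str = "adipogenic",
    conditions: Sequence[str] = CONDITIONS,
) -> StudyLayout:
    """Walk a study tree into a deterministic :class:`StudyLayout`.

    Ordering is lexicographic at every level regardless of on-disk order, so
    the layout is a pure function of the set of paths.  A donor present in
    only one condition is retained with a warning; normalization may later
    use the pooled-control fallback.
    """
    root = Path(root)
    if not root.is_dir():
        raise LayoutError(f"study root is not a directory: {root}")
    donors: dict[str, DonorLayout] = {}
    reserved = {"calibration"}
    for donor_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        if donor_dir.name in reserved:
            continue
        cond_map: dict[str, dict[str, list[Path]]] = {}
        for cond in conditions:
            cond_dir = donor_dir / cond
            if not cond_dir.is_dir():
                continue
            wells: dict[str, list[Path]] = {}
            subdirs = sorted(p for p in cond_dir.iterdir() if p.is_dir())
            if subdirs:
                for well_dir in subdirs:
                    imgs = sorted(
                        p for p in well_dir.iterdir()
                        if p.suffix.lower() in IMAGE_EXTENSIONS
                    )
                    if imgs:
                        wells[well_dir.name] = imgs
            else:
                # section-per-file layout (chondrogenic): one image = one replicate
                for img in sorted(
                    p for p in cond_dir.iterdir()
                    if p.suffix.lower() in IMAGE_EXTENSIONS
                ):
                    wells[img.stem] = [img]
            if wells:
                cond_map[cond] = wells
        if not cond_map:
            continue
        dl = DonorLayout(donor_dir.name, cond_map)
        missing = [c for c in conditions if c not in cond_map]
        for c in missing:
            msg = f"donor {donor_dir.name!r} has no images in condition {c!r}"
            dl.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
        donors[donor_dir.name] = dl
    if not donors or not any(
        dl.n_images(c) for dl in donors.values() for c in dl.conditions
    ):
        raise LayoutError(f"no images found under {root}")
    calibration = {}
    calib_dir = root / "calibration"
    if calib_dir.is_dir():
        for key in ("dark", "light"):
            for ext in IMAGE_EXTENSIONS:
                candidate = calib_dir / f"{key}{ext}"
                if candidate.exists():
                    calibration[key] = candidate
                    break
    return StudyLayout(lineage=lineage, root=root, donors=donors, calibration=calibration)


def write_measurements(records: Sequence, path: str | Path) -> Path:
    """Write dataclass records (QuantRecord, DonorSummary, ...) to CSV.

    Column order follows the dataclass field order; floats are written at
    full round-trip precision so re-reading reproduces values exactly.
    """
    if not records:
        raise ValueError("no records to write; file not created")
    path = Path(path)
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            row = dataclasses.asdict(rec)
        elif isinstance(rec, dict):
            row = dict(rec)
        else:
            raise TypeError(f"cannot serialize record of type {type(rec)!r}")
        rows.append({k: v for k, v in row.items() if not isinstance(v, (np.ndarray, list, dict))})
    frame = pd.DataFrame(rows)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read back a measurement CSV written by :func:`write_measurements`."""
    return pd.read_csv(path)
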