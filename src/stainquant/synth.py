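"""Forward Beer-Lambert renderer for ground-truth synthetic micrographs.

Every pipeline stage is testable without deposited micrographs: a
:class:`SyntheticScene` lists stained regions (disks, ellipses, organic
blobs) with per-stain concentrations, a multiplicative radial vignette, a
constant sensor dark level, fixed-pattern hot pixels (additive dark-current
offsets present in every exposure, which is exactly what a Dark frame
cancels) and additive Gaussian intensity noise.  The renderer applies the
forward model

    I = round(dark + hot + A * vignette * 10^(-(c1*v1 + c2*v2)) + noise)

per color plane (A = illumination_scale * 255), clipped to [0, 255], and
emits the exact ground truth (concentration fields, positive masks, area
fractions, true DR) alongside.  ``make_calibration_pair`` renders the
matching Dark/Light frames, so render -> correct -> unmix round-trips are
exact up to 8-bit quantization.

The default study generator emulates the replicate design of a tri-lineage
differentiation experiment: per donor, two conditions (differentiated /
non-induced control), three wells with four fields of view each for the
monolayer assays, or three sections for the pellet assay; differentiated
wells carry a stained-area fraction equal to a per-donor effect multiplier
times the control fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .deconvolution import StainBasis, lineage_basis
from .illumination import CalibrationPair
from .io import RGBImage, write_rgb_image


# --------------------------------------------------------------------------
# scene description


@dataclass(frozen=True)
class Disk:
    cy: float
    cx: float
    radius: float
    stain: int  # 1 or 2
    concentration: float


@dataclass(frozen=True)
class Ellipse:
    cy: float
    cx: float
    semi_y: float
    semi_x: float
    stain: int
    concentration: float
    angle_deg: float = 0.0


@dataclass(frozen=True)
class Blob:
    """Organic stained region covering an exact pixel fraction.

    The mask is the top ``fraction`` quantile of a Gaussian-smoothed noise
    field, optionally excluding pixels already stained by the other channel
    (disjoint regions).  The pixel count is exact: round(fraction * H * W).
    """

    stain: int
    concentration: float
    fraction: float
    smooth_sigma: float = 3.0
    avoid_other: bool = True


@dataclass
class SyntheticScene:
    height: int = 128
    width: int = 128
    regions: list = field(default_factory=list)
    vignette_corner_gain: float = 1.0  # 1.0 = flat illumination
    illumination_scale: float = 1.0
    dark_level: float = 0.0
    hot_pixels: list[tuple[int, int, float]] = field(default_factory=list)  # (y, x, offset)
    noise_sigma: float = 0.0
    pixel_size_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.vignette_corner_gain <= 1:
            raise ValueError("vignette_corner_gain must lie in (0, 1]")
        for r in self.regions:
            if r.concentration < 0:
                raise ValueError("concentrations must be non-negative")


@dataclass
class GroundTruth:
    c1: np.ndarray
    c2: np.ndarray
    mask1: np.ndarray
    mask2: np.ndarray
    area_fraction_1: float
    area_fraction_2: float
    dr: float


def vignette_field(height: int, width: int, corner_gain: float) -> np.ndarray:
    """Radial multiplicative shading: gain 1 at center, ``corner_gain`` at corners."""
    y = np.arange(height) - (height - 1) / 2.0
    x = np.arange(width) - (width - 1) / 2.0
    r2 = y[:, None] ** 2 + x[None, :] ** 2
    r2_corner = ((height - 1) / 2.0) ** 2 + ((width - 1) / 2.0) ** 2
    if r2_corner == 0:
        return np.ones((height, width))
    return 1.0 - (1.0 - corner_gain) * r2 / r2_corner


def concentration_fields(scene: SyntheticScene) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the scene's regions into per-stain concentration maps."""
    h, w = scene.height, scene.width
    c = {1: np.zeros((h, w)), 2: np.zeros((h, w))}
    yy, xx = np.mgrid[0:h, 0:w]
    rng = np.random.default_rng(scene.seed)
    for region in scene.regions:
        if isinstance(region, Disk):
            mask = (yy - region.cy) ** 2 + (xx - region.cx) ** 2 <= region.radius**2
        elif isinstance(region, Ellipse):
            th = math.radians(region.angle_deg)
            dy, dx = yy - region.cy, xx - region.cx
            u = dx * math.cos(th) + dy * math.sin(th)
            v = -dx * math.sin(th) + dy * math.cos(th)
            mask = (u / region.semi_x) ** 2 + (v / region.semi_y) ** 2 <= 1.0
        elif isinstance(region, Blob):
            fld = gaussian_filter(rng.standard_normal((h, w)), region.smooth_sigma)
            if region.avoid_other:
                other = 2 if region.stain == 1 else 1
                fld = np.where(c[other] > 0, -np.inf, fld)
            k = int(round(region.fraction * h * w))
            mask = np.zeros((h, w), dtype=bool)
            if k > 0:
                flat = fld.ravel()
                k = min(k, int(np.isfinite(flat).sum()))
                idx = np.argpartition(-flat, k - 1)[:k]
                mask.ravel()[idx] = True
        else:
            raise TypeError(f"unknown region type {type(region)!r}")
        c[region.stain][mask] += region.concentration
    return c[1], c[2]


def _round8(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)  # half away from zero for non-negative input


def _hot_map(scene: SyntheticScene) -> np.ndarray:
    hot = np.zeros((scene.height, scene.width))
    for y, x, offset in scene.hot_pixels:
        hot[y, x] = offset
    return hot


def render_stained_image(
    scene: SyntheticScene, basis: StainBasis
) -> tuple[RGBImage, GroundTruth]:
    """Render the scene under its illumination and emit exact ground truth."""
    c1, c2 = concentration_fields(scene)
    od = c1[:, :, None] * basis.v1.array + c2[:, :, None] * basis.v2.array
    trans = np.power(10.0, -od)
    vig = vignette_field(scene.height, scene.width, scene.vignette_corner_gain)
    amp = scene.illumination_scale * 255.0
    signal = scene.dark_level + _hot_map(scene)[:, :, None] + amp * vig[:, :, None] * trans
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed + 1)
        signal = signal + rng.normal(0.0, scene.noise_sigma, signal.shape)
    pixels = np.clip(_round8(signal), 0, 255).astype(np.uint8)
    mask1, mask2 = c1 > 0, c2 > 0
    af1 = 100.0 * mask1.mean()
    af2 = 100.0 * mask2.mean()
    truth = GroundTruth(
        c1=c1,
        c2=c2,
        mask1=mask1,
        mask2=mask2,
        area_fraction_1=af1,
        area_fraction_2=af2,
        dr=af1 / af2 if af2 > 0 else math.nan,
    )
    return RGBImage(pixels, pixel_size_um=scene.pixel_size_um, source_path=None), truth


def make_calibration_pair(scene: SyntheticScene) -> CalibrationPair:
    """Dark/Light frames matching the scene's illumination and sensor pattern.

    Dark is the constant dark level plus hot-pixel offsets; Light adds the
    full vignetted illumination of an empty well.  Calibration frames are
    noise-free (in practice they would be averaged exposures).
    """
    vig = vignette_field(scene.height, scene.width, scene.vignette_corner_gain)
    hot = _hot_map(scene)
    amp = scene.illumination_scale * 255.0
    dark = np.clip(_round8(scene.dark_level + hot), 0, 255).astype(np.uint8)
    light = np.clip(
        _round8(scene.dark_level + hot + amp * vig), 0, 255
    ).astype(np.uint8)
    to_rgb = lambda a: RGBImage(
        np.repeat(a[:, :, None], 3, axis=2), pixel_size_um=scene.pixel_size_um
    )
    return CalibrationPair(dark=to_rgb(dark), light=to_rgb(light))


# --------------------------------------------------------------------------
# whole-study generation


#: Study-level rendering defaults: the replicate structure of the monolayer
#: assays (3 wells x 4 fields), a 5% control stained fraction with 15%
#: counterstained (nuclear) area, mild vignetting, a small sensor offset
#: with a few hot pixels, and sigma-2 intensity noise.
STUDY_DEFAULTS = dict(
    n_wells=3,
    n_images_per_well=4,
    n_sections=3,
    image_size=(128, 128),
    control_fraction=0.05,
    counter_fraction=0.15,
    stain_concentration=1.0,
    counter_concentration=0.7,
    vignette_corner_gain=0.85,
    illumination_scale=0.8,
    dark_level=6.0,
    n_hot_pixels=5,
    hot_offset=40.0,
    noise_sigma=2.0,
    jitter_cv=0.08,
    pixel_size_um=1.0,
)


def _image_scene(
    rng: np.random.Generator,
    p1: float,
    p2: float,
    params: dict,
) -> SyntheticScene:
    h, w = params["image_size"]
    scene = SyntheticScene(
        height=h,
        width=w,
        vignette_corner_gain=params["vignette_corner_gain"],
        illumination_scale=params["illumination_scale"],
        dark_level=params["dark_level"],
        noise_sigma=params["noise_sigma"],
        pixel_size_um=params["pixel_size_um"],
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    scene.regions = [
        Blob(stain=2, concentration=params["counter_concentration"], fraction=p2),
        Blob(stain=1, concentration=params["stain_concentration"], fraction=p1),
    ]
    return scene


def generate_synthetic_study(
    root: str | Path,
    n_donors: int = 2,
    effect_multipliers: Sequence[float] | None = None,
    lineage: str = "adipogenic",
    basis: StainBasis | None = None,
    seed: int = 0,
    **overrides,
) -> dict:
    """Write a discover_study-compatible tree with exact ground truth.

    Differentiated images of donor ``i`` carry a channel-1 stained-area
    fraction of ``effect_multipliers[i]`` times the control fraction (times
    a small lognormal per-image jitter); the counterstain fraction is
    condition-independent.  One shared calibration pair, a per-image truth
    table (``truth.csv``), a per-donor expected-DR^N table
    (``truth_donors.csv``) and a ready-to-run ``config.yaml`` are written
    into the tree.  The seed fully determines every byte.
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        raise FileExistsError(f"refusing to write into non-empty directory {root}")
    if n_donors < 2:
        raise ValueError("a study needs at least 2 donors")
    if effect_multipliers is None:
        effect_multipliers = [4.0] * n_donors
    if len(effect_multipliers) != n_donors:
        raise ValueError("need one effect multiplier per donor")
    if any(m < 0 for m in effect_multipliers):
        raise ValueError("effect multipliers must be non-negative")
    params = dict(STUDY_DEFAULTS)
    unknown = set(overrides) - set(params)
    if unknown:
        raise TypeError(f"unknown study parameters: {sorted(unknown)}")
    params.update(overrides)
    if basis is None:
        basis = lineage_basis(lineage)
    rng = np.random.default_rng(seed)
    root.mkdir(parents=True, exist_ok=True)

    calib_scene = SyntheticScene(
        height=params["image_size"][0],
        width=params["image_size"][1],
        vignette_corner_gain=params["vignette_corner_gain"],
        illumination_scale=params["illumination_scale"],
        dark_level=params["dark_level"],
        pixel_size_um=params["pixel_size_um"],
    )
    calib_scene.hot_pixels = [
        (
            int(rng.integers(0, calib_scene.height)),
            int(rng.integers(0, calib_scene.width)),
            params["hot_offset"],
        )
        for _ in range(params["n_hot_pixels"])
    ]
    pair = make_calibration_pair(calib_scene)
    dark_path = write_rgb_image(pair.dark, root / "calibration" / "dark.png")
    light_path = write_rgb_image(pair.light, root / "calibration" / "light.png")

    chondro = lineage == "chondrogenic"
    rows = []
    for i in range(n_donors):
        donor = f"donor_{i + 1:02d}"
        for condition in ("differentiated", "control"):
            mult = effect_multipliers[i] if condition == "differentiated" else 1.0
            if chondro:
                replicates = [(f"section_{s + 1}", [s]) for s in range(params["n_sections"])]
            else:
                replicates = [
                    (f"well_{wi + 1}", list(range(params["n_images_per_well"])))
                    for wi in range(params["n_wells"])
                ]
            for well, images in replicates:
                for img_i in images:
                    jitter = lambda: float(
                        rng.lognormal(mean=0.0, sigma=params["jitter_cv"])
                    )
                    p1 = min(params["control_fraction"] * mult * jitter(), 0.5)
                    p2 = min(params["counter_fraction"] * jitter(), 0.5)
                    scene = _image_scene(rng, p1, p2, params)
                    scene.hot_pixels = list(calib_scene.hot_pixels)
                    img, truth = render_stained_image(scene, basis)
                    if chondro:
                        rel = Path(donor) / condition / f"{well}.png"
                    else:
                        rel = Path(donor) / condition / well / f"img_{img_i + 1}.png"
                    write_rgb_image(img, root / rel)
                    rows.append(
                        dict(
                            path=str(rel),
                            donor=donor,
                            condition=condition,
                            well=well,
                            multiplier=mult,
                            true_af1=truth.area_fraction_1,
                            true_af2=truth.area_fraction_2,
                            true_dr=truth.dr,
                        )
                    )
    truth_frame = pd.DataFrame(rows)
    truth_path = root / "truth.csv"
    truth_frame.to_csv(truth_path, index=False)

    donor_rows = []
    for donor, grp in truth_frame.groupby("donor", sort=True):
        means = {}
        for condition, cgrp in grp.groupby("condition"):
            well_means = cgrp.groupby("well")["true_dr"].mean()
            means[condition] = float(well_means.mean())
        donor_rows.append(
            dict(
                donor=donor,
                multiplier=float(grp["multiplier"].max()),
                true_mean_dr_differentiated=means["differentiated"],
                true_mean_dr_control=means["control"],
                expected_dr_normalized=means["differentiated"] / means["control"],
            )
        )
    donors_path = root / "truth_donors.csv"
    pd.DataFrame(donor_rows).to_csv(donors_path, index=False)

    config = {
        "root": str(root),
        "lineage": lineage,
        "calibration": {"dark": str(dark_path), "light": str(light_path)},
        "pixel_size_um": params["pixel_size_um"],
        "threshold_method": "otsu",
        "stains": {
            "channel1": {"name": basis.v1.name, "od": list(basis.v1.od)},
            "channel2": {"name": basis.v2.name, "od": list(basis.v2.od)},
        },
    }
    import yaml

    config_path = root / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return {
        "root": root,
        "truth": truth_path,
        "truth_donors": donors_path,
        "config": config_path,
        "n_images": len(rows),
    }


# --------------------------------------------------------------------------
# statistical-level study simulation (no rendering)


def simulate_dr_study(
    n_donors: int = 6,
    effect: float = 1.0,
    n_wells: int = 3,
    n_images_per_well: int = 4,
    base_dr: float = 0.5,
    donor_cv: float = 0.25,
    image_cv: float = 0.30,
    rng: np.random.Generator | int | None = None,
) -> dict[str, tuple[float, float]]:
    """Simulate donor-level (differentiated, control) mean-DR pairs.

    Image-level DRs are lognormal around a donor-specific baseline
    (``base_dr`` times a lognormal donor factor of coefficient of variation
    ``donor_cv``), with independent lognormal image scatter (``image_cv``);
    the differentiated condition is scaled by ``effect`` (1 = null).  Means
    are aggregated through :func:`stainquant.study.aggregate_donor`, i.e.
    exactly the nested-mean path the pipeline uses, so this simulator
    exercises the statistics layer without rendering pixels.
    """
    from .quantify import QuantRecord
    from .study import aggregate_donor

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sigma_d = math.sqrt(math.log(1 + donor_cv**2))
    sigma_i = math.sqrt(math.log(1 + image_cv**2))
    out: dict[str, tuple[float, float]] = {}
    for i in range(n_donors):
        donor_level = base_dr * rng.lognormal(-0.5 * sigma_d**2, sigma_d)
        means = []
        for condition_scale in (effect, 1.0):
            wells = {}
            for wi in range(n_wells):
                recs = []
                for _ in range(n_images_per_well):
                    dr = condition_scale * donor_level * rng.lognormal(
                        -0.5 * sigma_i**2, sigma_i
                    )
                    recs.append(
                        QuantRecord(
                            image_id="sim",
                            area_fraction_1=math.nan,
                            area_fraction_2=math.nan,
                            dr=dr,
                            threshold_1=math.nan,
                            threshold_2=math.nan,
                            method="sim",
                        )
                    )
                wells[f"well_{wi}"] = recs
            means.append(aggregate_donor(wells))
        out[f"donor_{i + 1:02d}"] = (means[0], means[1])
    return out
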