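"""Donor-level aggregation, normalized DR, pellet area and study statistics.

Image-level DRs are aggregated as nested means — images averaged within a
well, well means averaged within a donor — which equals the grand mean for
balanced designs and stays well-defined under dropouts.  A donor's
normalized DR (DR^N) is the mean DR of differentiated wells divided by the
mean DR of that donor's non-induced controls; when a donor has no usable
controls, the mean of the other donors' control means stands in
(pooled-fallback).  DR^N < 1 reads as less signal than non-induced controls,
DR^N > 1 as more.

The condition effect (differentiated vs control) is tested per lineage with
a two-condition repeated-measures ANOVA on donor-level means: a univariate
within-subject decomposition with condition as the fixed factor and donor
as the random factor, F = MS_condition / MS_(donor x condition) on
(1, n_donors - 1) degrees of freedom.  With two conditions this F is
identically the squared paired t statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats

from .deconvolution import (
    StainBasis,
    concentration_to_channel,
    rgb_to_od,
    unmix_image,
)
from .errors import AggregationError, DegenerateHistogramError, StudyError
from .illumination import CalibrationPair, correct_illumination
from .io import RGBImage, StudyLayout, read_rgb_image
from .quantify import QuantRecord, area_fraction, auto_threshold, binarize, quantify_image


def aggregate_donor(well_records: Mapping[str, Sequence[QuantRecord]]) -> float:
    """Nested mean DR for one donor x condition: images -> well -> donor.

    Undefined DRs are excluded (and counted); a well with no defined DR is
    dropped from the well mean.  Raises :class:`AggregationError` when no
    defined DR exists at all.
    """
    well_means = []
    n_undefined = 0
    for well in sorted(well_records):
        drs = [r.dr for r in well_records[well] if not math.isnan(r.dr)]
        n_undefined += sum(1 for r in well_records[well] if math.isnan(r.dr))
        if drs:
            well_means.append(float(np.mean(drs)))
    if not well_means:
        raise AggregationError("no defined DR in any well for this donor/condition")
    if n_undefined:
        warnings.warn(f"excluded {n_undefined} undefined DR(s) from nested mean", stacklevel=2)
    return float(np.mean(well_means))


def normalized_dr(mean_diff: float, mean_ctrl: float) -> float:
    """DR^N = mean differentiated DR / mean control DR; NaN when control is 0."""
    if mean_diff < 0 or mean_ctrl < 0:
        raise ValueError("mean DRs are non-negative by construction")
    if mean_ctrl == 0:
        return math.nan
    return mean_diff / mean_ctrl


def fallback_control(mean_ctrl_others: Sequence[float]) -> float:
    """Pooled control mean over the other donors of the same lineage/species."""
    vals = [v for v in mean_ctrl_others if not math.isnan(v)]
    if not vals:
        raise AggregationError("no other donor has a defined control mean to pool")
    return float(np.mean(vals))


def classify_dr_normalized(drn: float) -> str | None:
    """'below-control' (< 1), 'neutral' (= 1) or 'above-control' (> 1)."""
    if math.isnan(drn):
        return None
    if drn < 0:
        raise ValueError("DR^N is non-negative")
    if drn < 1:
        return "below-control"
    if drn > 1:
        return "above-control"
    return "neutral"


@dataclass
class DonorSummary:
    donor: str
    lineage: str
    mean_dr_differentiated: float
    mean_dr_control: float
    dr_normalized: float
    classification: str | None
    control_source: str  # "own" | "pooled-fallback" | "none"
    n_images_differentiated: int
    n_images_control: int


# ---------------------------------------------------------------------------
# pellet area


@dataclass
class PelletMeasurement:
    section_id: str
    area_mm2: float
    mode: str  # "manual-ellipse" | "auto-mask"
    major_mm: float | None = None
    minor_mm: float | None = None


def ellipse_area(major_mm: float, minor_mm: float) -> float:
    """Area of the manually fitted pellet ellipse, pi * a * b / 4 in mm^2."""
    if not (minor_mm > 0 and major_mm >= minor_mm):
        raise ValueError("need major >= minor > 0 (both in mm)")
    return math.pi * (major_mm / 2.0) * (minor_mm / 2.0)


def manual_pellet_area(section_id: str, major_mm: float, minor_mm: float) -> PelletMeasurement:
    return PelletMeasurement(
        section_id, ellipse_area(major_mm, minor_mm), "manual-ellipse", major_mm, minor_mm
    )


def auto_pellet_area(
    image: RGBImage,
    basis: StainBasis,
    calib: CalibrationPair | None = None,
    method: str = "otsu",
) -> PelletMeasurement:
    """Pellet cross-section area from the stained foreground.

    Foreground is the union of both binarized stain channels; the largest
    connected component's pixel count is converted to mm^2 with the image's
    pixel size.  A blank section yields area 0 with a warning.
    """
    section_id = image.source_path or "<in-memory>"
    if image.is_corrected:
        corrected = image
    elif calib is None:
        corrected = image.to_unit()
    else:
        corrected = correct_illumination(image, calib)
    maps = unmix_image(rgb_to_od(corrected), basis)
    fg = np.zeros(maps.c1.shape, dtype=bool)
    for c, name in ((maps.c1, basis.v1.name), (maps.c2, basis.v2.name)):
        channel = concentration_to_channel(c, name)
        try:
            t = auto_threshold(channel, method)
        except DegenerateHistogramError:
            continue  # constant channel: nothing stained in this dye
        fg |= binarize(channel, t, method).pixels
    if not fg.any():
        warnings.warn(f"{section_id}: empty foreground, pellet area 0", stacklevel=2)
        return PelletMeasurement(section_id, 0.0, "auto-mask")
    labels, n = ndimage.label(fg)
    counts = np.bincount(labels.ravel())[1:]
    largest = int(counts.max())
    mm_per_px = image.pixel_size_um / 1000.0
    return PelletMeasurement(section_id, largest * mm_per_px**2, "auto-mask")


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass
class AnovaResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    mean_differentiated: float
    mean_control: float
    n_donors: int
    excluded_donors: tuple[str, ...] = ()


def rm_anova_two_condition(
    donor_means: Mapping[str, tuple[float, float]] | Sequence[tuple[float, float]],
) -> AnovaResult:
    """Two-condition repeated-measures ANOVA on donor (differentiated, control) means.

    Univariate decomposition on the donor x condition table (one value per
    cell): SS_condition on 1 df, SS_error = donor x condition interaction on
    n - 1 df, F = MS_condition / MS_error, p from F(1, n - 1).  Donors
    missing either condition are excluded with a warning.  Zero interaction
    SS with a nonzero condition effect yields F = +inf, p = 0 (degenerate
    but reproducible); a fully null table yields F = 0, p = 1.
    """
    if isinstance(donor_means, Mapping):
        items = [(k, donor_means[k]) for k in sorted(donor_means)]
    else:
        items = [(str(i), pair) for i, pair in enumerate(donor_means)]
    excluded = tuple(
        k for k, (a, b) in items if math.isnan(a) or math.isnan(b)
    )
    pairs = np.array(
        [[a, b] for k, (a, b) in items if not (math.isnan(a) or math.isnan(b))],
        dtype=float,
    )
    if excluded:
        warnings.warn(
            f"excluded donors missing a condition: {excluded}", stacklevel=2
        )
    n = len(pairs)
    if n < 2:
        raise ValueError(f"repeated-measures ANOVA needs >= 2 complete donors, got {n}")
    grand = pairs.mean()
    cond_means = pairs.mean(axis=0)
    donor_means_arr = pairs.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    # interaction SS from explicit residuals (numerically stable near degeneracy)
    resid = pairs - donor_means_arr[:, None] - cond_means[None, :] + grand
    ss_err = float(np.sum(resid**2))
    # sums of squares at rounding-noise level are exact zeros
    tol = 1e-14 * (float(np.sum(pairs**2)) + 1.0)
    ss_cond = 0.0 if ss_cond < tol else ss_cond
    ss_err = 0.0 if ss_err < tol else ss_err
    df_num, df_den = 1, n - 1
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    if ms_err == 0.0:
        if ms_cond == 0.0:
            f, p = 0.0, 1.0
        else:
            warnings.warn(
                "zero donor x condition interaction: F degenerates to +inf", stacklevel=2
            )
            f, p = math.inf, 0.0
    else:
        f = ms_cond / ms_err
        p = float(stats.f.sf(f, df_num, df_den))
    return AnovaResult(
        f_statistic=float(f),
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        mean_differentiated=float(cond_means[0]),
        mean_control=float(cond_means[1]),
        n_donors=n,
        excluded_donors=excluded,
    )


# ---------------------------------------------------------------------------
# whole-study driver


@dataclass
class StudyResult:
    lineage: str
    records: list[QuantRecord]
    summaries: list[DonorSummary]
    anova: AnovaResult | None
    pellets: list[PelletMeasurement] = field(default_factory=list)
    pellet_anova: AnovaResult | None = None
    failures: list[tuple[str, str]] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def process_study(
    layout: StudyLayout,
    basis: StainBasis,
    calib: CalibrationPair | None,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    pixel_size_um: float = 1.0,
    measure_pellets: bool | None = None,
) -> StudyResult:
    """Quantify every image of a study and aggregate to donor and study level.

    Per-image failures are recorded and skipped; the run aborts with
    :class:`StudyError` only when more than half of the images fail.
    ``measure_pellets`` defaults to True for chondrogenic studies.
    """
    if measure_pellets is None:
        measure_pellets = layout.lineage == "chondrogenic"
    log: list[str] = []
    failures: list[tuple[str, str]] = []
    records: list[QuantRecord] = []
    # donor -> condition -> well -> [QuantRecord]
    by_donor: dict[str, dict[str, dict[str, list[QuantRecord]]]] = {}
    pellets: list[PelletMeasurement] = []
    pellet_by_donor: dict[str, dict[str, list[float]]] = {}
    n_total = 0
    for donor, condition, well, path in layout.iter_images():
        n_total += 1
        try:
            img = read_rgb_image(path, pixel_size_um=pixel_size_um)
            rec = quantify_image(img, calib, basis, method, fixed_threshold)
        except Exception as exc:  # noqa: BLE001 - batch mode records and moves on
            failures.append((str(path), str(exc)))
            log.append(f"FAIL {path}: {exc}")
            continue
        records.append(rec)
        by_donor.setdefault(donor, {}).setdefault(condition, {}).setdefault(well, []).append(rec)
        log.append(
            f"OK {path}: af1={rec.area_fraction_1:.4f}% af2={rec.area_fraction_2:.4f}% "
            f"dr={rec.dr:.6g} t1={rec.threshold_1:g} t2={rec.threshold_2:g}"
        )
        if measure_pellets:
            pm = auto_pellet_area(img, basis, calib, method)
            pellets.append(pm)
            pellet_by_donor.setdefault(donor, {}).setdefault(condition, []).append(pm.area_mm2)
    if n_total == 0:
        raise StudyError("study layout contains no images")
    if len(failures) > 0.5 * n_total:
        raise StudyError(
            f"{len(failures)} of {n_total} images failed; study aborted"
        )
    # donor-level means per condition
    cond_means: dict[str, dict[str, float]] = {}
    counts: dict[str, dict[str, int]] = {}
    for donor in sorted(by_donor):
        cond_means[donor] = {}
        counts[donor] = {}
        for condition, wells in by_donor[donor].items():
            counts[donor][condition] = sum(len(v) for v in wells.values())
            try:
                cond_means[donor][condition] = aggregate_donor(wells)
            except AggregationError as exc:
                log.append(f"WARN {donor}/{condition}: {exc}")
    summaries: list[DonorSummary] = []
    for donor in sorted(cond_means):
        mean_diff = cond_means[donor].get("differentiated", math.nan)
        mean_ctrl = cond_means[donor].get("control", math.nan)
        control_source = "own"
        if math.isnan(mean_ctrl):
            others = [
                cond_means[d]["control"]
                for d in sorted(cond_means)
                if d != donor and "control" in cond_means[d]
            ]
            try:
                mean_ctrl = fallback_control(others)
                control_source = "pooled-fallback"
                log.append(
                    f"FALLBACK {donor}: pooled control mean {mean_ctrl:.6g} "
                    f"from {len(others)} other donor(s)"
                )
            except AggregationError:
                control_source = "none"
        drn = (
            normalized_dr(mean_diff, mean_ctrl)
            if not (math.isnan(mean_diff) or math.isnan(mean_ctrl))
            else math.nan
        )
        summaries.append(
            DonorSummary(
                donor=donor,
                lineage=layout.lineage,
                mean_dr_differentiated=mean_diff,
                mean_dr_control=mean_ctrl,
                dr_normalized=drn,
                classification=classify_dr_normalized(drn),
                control_source=control_source,
                n_images_differentiated=counts[donor].get("differentiated", 0),
                n_images_control=counts[donor].get("control", 0),
            )
        )
    anova = None
    pairs = {
        d: (cond_means[d].get("differentiated", math.nan), cond_means[d].get("control", math.nan))
        for d in cond_means
    }
    complete = {d: p for d, p in pairs.items() if not any(math.isnan(v) for v in p)}
    if len(complete) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova = rm_anova_two_condition(pairs)
        log.append(
            f"ANOVA {layout.lineage}: F(1,{anova.df_den})={anova.f_statistic:.6g} "
            f"p={anova.p_value:.6g} on {anova.n_donors} donors"
        )
    else:
        log.append("ANOVA skipped: fewer than 2 donors with both conditions")
    pellet_anova = None
    if measure_pellets and pellet_by_donor:
        ppairs = {
            d: (
                float(np.mean(v["differentiated"])) if "differentiated" in v else math.nan,
                float(np.mean(v["control"])) if "control" in v else math.nan,
            )
            for d, v in pellet_by_donor.items()
        }
        if sum(1 for p in ppairs.values() if not any(math.isnan(x) for x in p)) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pellet_anova = rm_anova_two_condition(ppairs)
            log.append(
                f"PELLET ANOVA: F(1,{pellet_anova.df_den})={pellet_anova.f_statistic:.6g} "
                f"p={pellet_anova.p_value:.6g}"
            )
    return StudyResult(
        lineage=layout.lineage,
        records=records,
        summaries=summaries,
        anova=anova,
        pellets=pellets,
        pellet_anova=pellet_anova,
        failures=failures,
        log=log,
    )


def write_study_result(result: StudyResult, outdir: str | Path) -> dict[str, Path]:
    """Write records.csv, summary.csv, anova.csv and the run log."""
    from .io import write_measurements  # local import to avoid cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if result.records:
        paths["records"] = write_measurements(result.records, outdir / "records.csv")
    if result.summaries:
        paths["summary"] = write_measurements(result.summaries, outdir / "summary.csv")
    anova_rows = []
    if result.anova is not None:
        anova_rows.append({"measure": "dr", "lineage": result.lineage, **_anova_row(result.anova)})
    if result.pellet_anova is not None:
        anova_rows.append(
            {"measure": "pellet_area_mm2", "lineage": result.lineage, **_anova_row(result.pellet_anova)}
        )
    if anova_rows:
        paths["anova"] = write_measurements(anova_rows, outdir / "anova.csv")
    if result.pellets:
        paths["pellets"] = write_measurements(result.pellets, outdir / "pellets.csv")
    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(result.log) + "\n")
    paths["log"] = log_path
    return paths


def _anova_row(a: AnovaResult) -> dict:
    return {
        "f_statistic": a.f_statistic,
        "df_num": a.df_num,
        "df_den": a.df_den,
        "p_value": a.p_value,
        "mean_differentiated": a.mean_differentiated,
        "mean_control": a.mean_control,
        "n_donors": a.n_donors,
    }
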