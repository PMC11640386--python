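"""Synthetic IHC slides and cohorts with exact ground truth.

Real archival slides carry no machine-readable truth, so every stage
of the package is exercised on synthetic data instead: H-DAB fields
of counterstained nuclei with a controllable Ki-67-positive fraction,
cytoplasmic DAB fields with a controllable positive-area fraction, and
cohort tables with subtype structure.  Images are rendered through the
same Beer-Lambert optics the analysis inverts (OD mixing with the
default H-DAB stain vectors), plus smooth background drift, Gaussian
sensor noise, and the two artifact types the size filter exists for:
staining sprinkles below 13 um^2 and clumps above 130 um^2.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .grading import HistoFeatures, assign_grade
from .scoring import allred_score
from .stain import RGBImage, StainMatrix, default_hdab_matrix, od_to_rgb

__all__ = [
    "SlideSpec",
    "GroundTruth",
    "PackingError",
    "generate_ki67_slide",
    "generate_opn_slide",
    "CohortEffect",
    "generate_cohort",
]


class PackingError(RuntimeError):
    """Raised when the requested objects cannot be placed without overlap."""


@dataclass(frozen=True)
class SlideSpec:
    """Stated world for one synthetic Ki-67 field of view.

    Nucleus areas are lognormal with central mass inside the 13-130
    um^2 analysis window; stain peak ODs sit in the range typical of
    well-stained H-DAB slides, background drift and noise are mild but
    nonzero so the background-subtraction and normalization stages do
    real work.
    """

    shape: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.5
    n_nuclei: int = 550
    positive_fraction: float = 0.2
    area_median_um2: float = 45.0  # lognormal median
    area_sigma_log: float = 0.35  # lognormal sigma; 95% mass ~ [22, 90] um^2
    hematoxylin_od: float = 0.8  # peak OD of negative (counterstained) nuclei
    dab_od: float = 0.9  # peak OD of positive nuclei
    drift_od: float = 0.06  # amplitude of smooth neutral background drift
    n_sprinkles: int = 40  # DAB specks, 1-8 um^2 (below the 13 um^2 cutoff)
    n_clumps: int = 3  # stain clumps, 150-300 um^2 (above the 130 um^2 cutoff)
    noise_sd: float = 2.0  # Gaussian sensor noise, 8-bit intensity units
    seed: int = 0
    stain_matrix: StainMatrix | None = None

    def __post_init__(self):
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew (realized, not requested)."""

    nuclei: tuple[dict, ...] = ()  # center, area_um2, positive per nucleus
    true_li_percent: float = float("nan")
    true_opn_area_fraction: float = float("nan")  # percent
    class_map: np.ndarray | None = None  # 4-class truth for OPN slides


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean, unit-max-abs smooth random field (for drift / blobs)."""
    f = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
    f -= f.mean()
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _place_ellipse(rng, occupied, area_px, margin, max_tries=200):
    """Find a free spot for an ellipse of the given pixel area.

    Returns (rr, cc, center) and marks a 2-px-dilated footprint in
    ``occupied`` so objects never touch.
    """
    h, w = occupied.shape
    aspect = rng.uniform(0.7, 1.0)
    b = math.sqrt(area_px / (math.pi * aspect))  # minor semi-axis? see below
    a = area_px / (math.pi * b)
    theta = rng.uniform(0, math.pi)
    r_ext = max(a, b) + 2
    for _ in range(max_tries):
        r0 = rng.uniform(margin + r_ext, h - margin - r_ext)
        c0 = rng.uniform(margin + r_ext, w - margin - r_ext)
        rr, cc = draw_ellipse(r0, c0, a + 2, b + 2, shape=occupied.shape, rotation=theta)
        if not occupied[rr, cc].any():
            occupied[rr, cc] = True
            rr, cc = draw_ellipse(r0, c0, a, b, shape=occupied.shape, rotation=theta)
            return rr, cc, (r0, c0)
    raise PackingError(
        f"could not place an object of {area_px:.0f} px^2 after {max_tries} tries; "
        "reduce n_nuclei or enlarge the image"
    )


def generate_ki67_slide(spec: SlideSpec) -> tuple[RGBImage, GroundTruth]:
    """Render one Ki-67 field with exact per-nucleus truth.

    Non-overlapping ellipses are painted as hematoxylin (negative) or
    DAB (positive) optical density; the number of positive nuclei is
    ``round(n_nuclei * positive_fraction)`` (banker's rounding) and
    the recorded truth is the realized tally.  Artifacts are placed in
    free space so they perturb counting only through the size filter,
    as on a real slide after non-overlap segmentation.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    px_area = spec.pixel_size_um**2
    conc_h = np.zeros(spec.shape)
    conc_d = np.zeros(spec.shape)
    occupied = np.zeros(spec.shape, dtype=bool)

    n_pos = int(round(spec.n_nuclei * spec.positive_fraction))
    positive = np.zeros(spec.n_nuclei, dtype=bool)
    positive[:n_pos] = True
    rng.shuffle(positive)

    # nucleus areas: lognormal, clipped to keep the central mass inside
    # the 13-130 um^2 analysis window
    areas = np.exp(rng.normal(math.log(spec.area_median_um2), spec.area_sigma_log, spec.n_nuclei))
    areas = np.clip(areas, 16.0, 120.0)

    nuclei = []
    for i in range(spec.n_nuclei):
        rr, cc, center = _place_ellipse(rng, occupied, areas[i] / px_area, margin=3)
        od = (spec.dab_od if positive[i] else spec.hematoxylin_od) * rng.uniform(0.85, 1.15)
        target = conc_d if positive[i] else conc_h
        target[rr, cc] = np.maximum(target[rr, cc], od)
        nuclei.append({"center": center, "area_um2": float(areas[i]), "positive": bool(positive[i])})

    # artifacts: DAB sprinkles below the small-particle cutoff ...
    for _ in range(spec.n_sprinkles):
        area = rng.uniform(1.0, 8.0) / px_area
        rr, cc, _ = _place_ellipse(rng, occupied, max(area, 1.5), margin=3)
        conc_d[rr, cc] = spec.dab_od * rng.uniform(0.7, 1.2)
    # ... and stain clumps above the large-particle cutoff
    for _ in range(spec.n_clumps):
        area = rng.uniform(150.0, 300.0) / px_area
        rr, cc, _ = _place_ellipse(rng, occupied, area, margin=3)
        stain = conc_d if rng.random() < 0.5 else conc_h
        stain[rr, cc] = 0.9 * rng.uniform(0.8, 1.1)

    # soften edges (optical blur) and add smooth neutral drift
    conc_h = ndi.gaussian_filter(conc_h, 0.6)
    conc_d = ndi.gaussian_filter(conc_d, 0.6)
    drift = spec.drift_od * (0.5 + 0.5 * _smooth_field(rng, spec.shape, sigma=min(h, w) / 8))

    stains = spec.stain_matrix if spec.stain_matrix is not None else default_hdab_matrix()
    od = (
        conc_h[..., None] * stains.matrix[0]
        + conc_d[..., None] * stains.matrix[1]
        + drift[..., None]  # neutral (gray) absorbance
    )
    rgb = od_to_rgb(od).astype(np.float64)
    rgb += rng.normal(0.0, spec.noise_sd, rgb.shape)
    image = RGBImage(np.clip(np.rint(rgb), 0, 255).astype(np.uint8), spec.pixel_size_um)

    n_pos_real = int(sum(n["positive"] for n in nuclei))
    li = 100.0 * n_pos_real / len(nuclei) if nuclei else float("nan")
    return image, GroundTruth(nuclei=tuple(nuclei), true_li_percent=li)


#: mean DAB OD painted for each visual intensity level (weak/moderate/strong)
OPN_INTENSITY_OD = {1: 0.25, 2: 0.45, 3: 0.70}


def generate_opn_slide(
    true_fraction: float,
    intensity_level: int = 3,
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 1.0,
    seed: int = 0,
    gap_fraction: float = 0.05,
    n_scribbles_per_class: int = 200,
    stain_matrix: StainMatrix | None = None,
) -> tuple[RGBImage, GroundTruth, np.ndarray]:
    """Render one osteopontin field with a per-pixel truth map.

    A blob-shaped tissue section is placed on empty slide; inside it,
    vessel-like gaps (class 2) and OPN-positive fields (class 3, DAB
    OD set by ``intensity_level``) are carved out of negative tissue
    (class 4) by thresholding smooth random fields at quantiles, so
    the realized positive fraction matches the request to within
    rasterization.  Also emits sparse scribbles for all four classes
    (sampled away from class boundaries, as a human would draw them).
    """
    if not (0.0 <= true_fraction <= 1.0):
        raise ValueError("true_fraction must lie in [0, 1]")
    if intensity_level not in OPN_INTENSITY_OD:
        raise ValueError("intensity_level must be 1, 2 or 3")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]

    # tissue: noisy ellipse filling most of the field
    d = ((yy - h / 2) / (0.42 * h)) ** 2 + ((xx - w / 2) / (0.42 * w)) ** 2
    tissue = d + 0.25 * _smooth_field(rng, shape, sigma=min(h, w) / 6) < 1.0

    class_map = np.ones(shape, dtype=np.uint8)  # 1 = outside background
    gaps_field = _smooth_field(rng, shape, sigma=4)
    inside = np.flatnonzero(tissue)
    if inside.size:
        gap_cut = np.quantile(gaps_field.ravel()[inside], 1.0 - gap_fraction)
        gaps = tissue & (gaps_field >= gap_cut)
        work = tissue & ~gaps
        pos_field = _smooth_field(rng, shape, sigma=min(h, w) / 10)
        widx = np.flatnonzero(work)
        if true_fraction >= 1.0:
            positive = work
        elif true_fraction <= 0.0:
            positive = np.zeros(shape, dtype=bool)
        else:
            cut = np.quantile(pos_field.ravel()[widx], 1.0 - true_fraction)
            positive = work & (pos_field >= cut)
        class_map[gaps] = 2
        class_map[work & ~positive] = 4
        class_map[positive] = 3

    # render: positive tissue carries DAB + light counterstain,
    # negative tissue counterstain only, gaps almost clear
    dab_od = OPN_INTENSITY_OD[intensity_level]
    texture = 1.0 + 0.1 * _smooth_field(rng, shape, sigma=3)
    conc_d = np.where(class_map == 3, dab_od, 0.0) * texture
    conc_h = (
        np.where(class_map == 3, 0.12, 0.0)
        + np.where(class_map == 4, 0.35, 0.0)
        + np.where(class_map == 2, 0.04, 0.0)
    ) * texture
    conc_d = ndi.gaussian_filter(conc_d, 1.0)
    conc_h = ndi.gaussian_filter(conc_h, 1.0)
    stains = stain_matrix if stain_matrix is not None else default_hdab_matrix()
    od = conc_h[..., None] * stains.matrix[0] + conc_d[..., None] * stains.matrix[1]
    od += 0.02 * (0.5 + 0.5 * _smooth_field(rng, shape, sigma=min(h, w) / 8))[..., None]
    rgb = od_to_rgb(od).astype(np.float64)
    rgb += rng.normal(0.0, 2.0, rgb.shape)
    image = RGBImage(np.clip(np.rint(rgb), 0, 255).astype(np.uint8), pixel_size_um)

    # scribbles: sparse labels from the eroded truth (off boundaries)
    scribbles = np.zeros(shape, dtype=np.uint8)
    for cls in (1, 2, 3, 4):
        region = class_map == cls
        eroded = ndi.binary_erosion(region, iterations=2)
        idx = np.flatnonzero(eroded if eroded.any() else region)
        if idx.size == 0:
            continue
        pick = rng.choice(idx, size=min(n_scribbles_per_class, idx.size), replace=False)
        scribbles.ravel()[pick] = cls

    counts = np.bincount(class_map.ravel(), minlength=5)
    tissue_px = counts[3] + counts[4]
    frac = 100.0 * counts[3] / tissue_px if tissue_px else float("nan")
    truth = GroundTruth(true_opn_area_fraction=frac, class_map=class_map)
    return image, truth, scribbles


# ---------------------------------------------------------------------------
# cohort tables

#: cohort composition of the reference population (53 tumors)
DEFAULT_SUBTYPE_N = {
    "fibrous": 22,
    "transitional": 23,
    "fibrous/transitional": 6,
    "transitional/meningothelial": 2,
}

#: staining intensity prevalence: weak 7, moderate 14, strong 32 of 53
INTENSITY_P = (7 / 53, 14 / 53, 32 / 53)

#: sex category prevalence: 19 FN, 7 FE, 27 MN, 0 ME
SEX_P = (19 / 53, 7 / 53, 27 / 53, 0.0)
SEX_CATEGORIES = ("female_neutered", "female_entire", "male_neutered", "male_entire")


@dataclass(frozen=True)
class CohortEffect:
    """Structure injected into a synthetic cohort.

    ``li_log_shift`` shifts a subtype's Ki-67 LI distribution on the
    log scale (0 everywhere = null cohort); ``rank_correlation`` is a
    Gaussian-copula rho between Ki-67 LI and the OPN positive percent,
    globally or per subtype.
    """

    li_log_shift: Mapping[str, float] = field(default_factory=dict)
    rank_correlation: float | Mapping[str, float] = 0.0


def generate_cohort(
    n_per_subtype: Mapping[str, int] | None = None,
    effect: CohortEffect | None = None,
    seed: int = 0,
) -> tuple["pd.DataFrame", dict]:
    """Draw a cohort table with subtype-structured score distributions.

    Ki-67 LI is right-skewed lognormal (median ~6, mean ~9, matching a
    typical meningioma cohort); OPN positive percent is a clipped
    normal around 51%; the visual intensity is drawn with the
    weak/moderate/strong prevalence of the reference cohort; the OPN
    IHC and Allred columns are computed from percent and intensity with
    the scoring module's own formulas, so they satisfy every score
    invariant by construction.  WHO grade comes from drawn histologic
    features passed through the grading rules (brain invasion at the
    reference prevalence 3/53).
    """
    import pandas as pd

    if n_per_subtype is None:
        n_per_subtype = DEFAULT_SUBTYPE_N
    if effect is None:
        effect = CohortEffect()
    rng = np.random.default_rng(seed)
    mu_log, sd_log = math.log(6.1), 0.9

    rows = []
    for subtype, n in n_per_subtype.items():
        shift = effect.li_log_shift.get(subtype, 0.0)
        rho = (
            effect.rank_correlation.get(subtype, 0.0)
            if isinstance(effect.rank_correlation, Mapping)
            else effect.rank_correlation
        )
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + math.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
        li = np.clip(np.exp(mu_log + shift + sd_log * z1), 0.0, 100.0)
        percent = np.clip(51.0 + 20.0 * z2, 0.0, 100.0)
        for i in range(n):
            pct = float(percent[i])
            intensity = int(rng.choice((1, 2, 3), p=INTENSITY_P)) if pct > 0 else 0
            hist = HistoFeatures(brain_invasion=bool(rng.random() < 3 / 53), subtype_label=subtype)
            rows.append(
                {
                    "sample_id": f"{subtype[:3]}-{i:03d}",
                    "subtype": subtype,
                    "grade": assign_grade(hist).grade,
                    "ki67_li": float(li[i]),
                    "opn_area_percent": pct,
                    "opn_intensity": intensity,
                    "opn_ihc": intensity * pct,
                    "allred": allred_score(pct, intensity).total,
                    "sex": str(rng.choice(SEX_CATEGORIES, p=SEX_P)),
                }
            )
    table = pd.DataFrame(rows)
    truth = {
        "li_log_mu": mu_log,
        "li_log_sd": sd_log,
        "li_log_shift": dict(effect.li_log_shift),
        "rank_correlation": effect.rank_correlation,
        "percent_mean": 51.0,
        "percent_sd": 20.0,
    }
    return table, truth
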