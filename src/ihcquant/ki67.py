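"""Ki-67 labeling index from deconvolved H-DAB channels.

The labeling index (LI) is the percentage of tumor nuclei positive for
the Ki-67 proliferation marker among all tumor nuclei.  The pipeline
mirrors the standard FIJI-based workflow: color deconvolution into
hematoxylin (all nuclei) and DAB (Ki-67-positive nuclei) channels,
rolling-ball background subtraction, percentile contrast normalization,
Otsu segmentation of all nuclei, a physical size filter that removes
staining sprinkles (< 13 um^2) and clumped artifacts (> 130 um^2), and
a per-particle positive/negative call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import block_reduce
from skimage.transform import resize

from .stain import RGBImage, StainMatrix, deconvolve, rgb_to_od

__all__ = [
    "Ki67Config",
    "NucleusRecord",
    "Ki67Result",
    "subtract_background",
    "normalize_contrast",
    "segment_nuclei",
    "filter_particles",
    "classify_positivity",
    "compute_li",
    "run_ki67",
]


@dataclass(frozen=True)
class Ki67Config:
    """Tunable parameters of the Ki-67 pipeline.

    Defaults follow the FIJI conventions: rolling-ball radius 50 px,
    0.35% contrast saturation, Otsu thresholding, and the 13-130 um^2
    particle size window.  ``pixel_size_um`` converts the physical size
    bounds to pixel areas (default 0.25 um/px, a typical 20x scan).
    """

    rolling_ball_radius_px: float = 50.0
    saturation_fraction: float = 0.0035
    threshold_method: str = "otsu"
    min_area_um2: float = 13.0
    max_area_um2: float = 130.0
    pixel_size_um: float = 0.25
    stain_matrix: StainMatrix | None = None

    def __post_init__(self):
        if self.rolling_ball_radius_px <= 0:
            raise ValueError("rolling_ball_radius_px must be > 0")
        if not (0 <= self.saturation_fraction < 0.5):
            raise ValueError("saturation_fraction must lie in [0, 0.5)")
        if not (0 < self.min_area_um2 < self.max_area_um2):
            raise ValueError("need 0 < min_area_um2 < max_area_um2")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented particle that survived the size filter."""

    label: int
    centroid: tuple[float, float]  # (row, col), pixels
    area_um2: float
    mean_dab_od: float
    mean_hematoxylin_od: float
    positivity: str  # "positive" | "negative"


@dataclass(frozen=True)
class Ki67Result:
    n_positive: int
    n_negative: int
    labeling_index: float  # percent; NaN when no nuclei survive
    excluded_small: int
    excluded_large: int
    nuclei: tuple[NucleusRecord, ...] = field(default=(), repr=False)

    @property
    def n_total(self) -> int:
        return self.n_positive + self.n_negative


def _ball_structure(radius: float) -> np.ndarray:
    """Non-flat structuring element: the upper-half-ball height profile."""
    n = int(np.ceil(radius))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    d2 = yy**2 + xx**2
    heights = np.sqrt(np.clip(radius**2 - d2, 0.0, None))
    heights[d2 > radius**2] = -np.inf  # outside the ball's support
    return heights


def _ball_opening(channel: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening by the ball: the rolling-ball background."""
    s = _ball_structure(radius)
    return ndi.grey_dilation(ndi.grey_erosion(channel, structure=s), structure=s)


def _shrink_factor(radius_px: float) -> int:
    # FIJI's schedule: exact rolling ball for small radii, block-min
    # downscaling for large ones (the ball cannot resolve structure
    # finer than the shrink block anyway).
    if radius_px <= 10:
        return 1
    if radius_px <= 30:
        return 2
    if radius_px <= 100:
        return 4
    return 8


def subtract_background(channel: np.ndarray, radius_px: float) -> np.ndarray:
    """Rolling-ball background subtraction (grayscale opening by a ball).

    A ball of the given radius is rolled under the intensity surface;
    the surface it traces is the background estimate, which is
    subtracted.  Flat images and additive offsets are removed exactly.
    For radii > 10 px the image is block-minimum downscaled first and
    the background upsampled back, the standard large-radius
    approximation.  If the radius exceeds the image extent the
    background degenerates to the global minimum (with a warning).
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be > 0")
    channel = np.asarray(channel, dtype=np.float64)
    if radius_px >= min(channel.shape):
        warnings.warn(
            "rolling-ball radius exceeds image extent; using the global "
            "minimum as background",
            stacklevel=2,
        )
        return channel - channel.min()
    shrink = _shrink_factor(radius_px)
    if shrink == 1:
        background = _ball_opening(channel, radius_px)
    else:
        pad = [(-s) % shrink for s in channel.shape]
        padded = np.pad(channel, ((0, pad[0]), (0, pad[1])), mode="edge")
        small = block_reduce(padded, (shrink, shrink), np.min)
        bg_small = _ball_opening(small, radius_px / shrink)
        background = resize(bg_small, padded.shape, order=1, preserve_range=True)
        background = background[: channel.shape[0], : channel.shape[1]]
        # the true background never exceeds the signal
        background = np.minimum(background, channel)
    return np.clip(channel - background, 0.0, None)


def normalize_contrast(channel: np.ndarray, saturation_fraction: float = 0.0035) -> np.ndarray:
    """Linear percentile stretch to [0, 1].

    The ``saturation_fraction`` lower and upper percentiles map to 0
    and 1; values outside are clipped (FIJI's "Enhance Contrast" with
    0.35% saturated pixels by default).  Constant images map to 0.
    """
    if not (0 <= saturation_fraction < 0.5):
        raise ValueError("saturation_fraction must lie in [0, 0.5)")
    channel = np.asarray(channel, dtype=np.float64)
    lo = np.percentile(channel, 100.0 * saturation_fraction)
    hi = np.percentile(channel, 100.0 * (1.0 - saturation_fraction))
    if hi <= lo:
        return np.zeros_like(channel)
    return np.clip((channel - lo) / (hi - lo), 0.0, 1.0)


def segment_nuclei(channel: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Threshold + 8-connected components; each component is a particle.

    An empty foreground (all-background image) yields an all-zero
    label map, not an error.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    if np.ptp(channel) == 0:
        return np.zeros(channel.shape, dtype=np.int32)
    mask = channel > threshold_otsu(channel)
    labels, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    return labels.astype(np.int32)


def filter_particles(
    labels: np.ndarray,
    min_area_um2: float = 13.0,
    max_area_um2: float = 130.0,
    pixel_size_um: float = 0.25,
) -> tuple[np.ndarray, int, int]:
    """Remove particles outside the physical size window.

    Areas are pixel counts times ``pixel_size_um**2``.  The bounds are
    strict: area < min is dropped as a sprinkle, area > max as a clump;
    a particle exactly at either bound is kept.  Returns the filtered
    (relabeled) map and the two exclusion tallies.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    labels = np.asarray(labels)
    n = int(labels.max())
    if n == 0:
        return np.zeros_like(labels, dtype=np.int32), 0, 0
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    areas_um2 = counts[1:] * pixel_size_um**2
    small = areas_um2 < min_area_um2
    large = areas_um2 > max_area_um2
    keep = ~(small | large)
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1:][keep] = np.arange(1, int(keep.sum()) + 1)
    return remap[labels], int(small.sum()), int(large.sum())


def classify_positivity(
    labels: np.ndarray,
    dab_channel: np.ndarray,
    hema_channel: np.ndarray,
    pixel_size_um: float = 0.25,
) -> list[NucleusRecord]:
    """Call each particle positive or negative.

    A particle is Ki-67 positive when its mean unmixed DAB
    concentration exceeds its mean hematoxylin concentration (argmax
    over the two stains) — parameter-free, relying on the deconvolution
    itself to separate marker from counterstain.
    """
    labels = np.asarray(labels)
    if labels.shape != dab_channel.shape or labels.shape != hema_channel.shape:
        raise ValueError("channels must be aligned with the label map")
    ids = np.arange(1, int(labels.max()) + 1)
    if ids.size == 0:
        return []
    mean_dab = ndi.mean(dab_channel, labels=labels, index=ids)
    mean_hema = ndi.mean(hema_channel, labels=labels, index=ids)
    centroids = ndi.center_of_mass(np.ones(labels.shape), labels=labels, index=ids)
    counts = np.bincount(labels.ravel(), minlength=ids.size + 1)[1:]
    records = []
    for i, lab in enumerate(ids):
        records.append(
            NucleusRecord(
                label=int(lab),
                centroid=(float(centroids[i][0]), float(centroids[i][1])),
                area_um2=float(counts[i]) * pixel_size_um**2,
                mean_dab_od=float(mean_dab[i]),
                mean_hematoxylin_od=float(mean_hema[i]),
                positivity="positive" if mean_dab[i] > mean_hema[i] else "negative",
            )
        )
    return records


def compute_li(n_positive: int, n_negative: int) -> float:
    """LI = 100 * positive / (positive + negative); NaN when undefined."""
    if n_positive < 0 or n_negative < 0:
        raise ValueError("counts must be >= 0")
    total = n_positive + n_negative
    if total == 0:
        warnings.warn("no nuclei counted; labeling index is undefined", stacklevel=2)
        return float("nan")
    return 100.0 * n_positive / total


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # annotate with the failing stage
        raise type(exc)(f"[{name}] {exc}") from exc


def run_ki67(
    image: RGBImage,
    roi_mask: np.ndarray | None = None,
    config: Ki67Config | None = None,
) -> Ki67Result:
    """Full Ki-67 pipeline on one field of view.

    ``roi_mask`` (same H x W as the image, nonzero = tumor) restricts
    the analysis to a manually outlined tumor region; the image is
    cropped to the mask's bounding box and pixels outside the mask are
    blanked, so a rectangular mask is equivalent to pre-cropping.
    """
    if config is None:
        config = Ki67Config(pixel_size_um=image.pixel_size_um)
    elif config.pixel_size_um != image.pixel_size_um:
        config = replace(config, pixel_size_um=image.pixel_size_um)

    pixels = image.pixels
    mask = None
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask).astype(bool)
        if roi_mask.shape != image.shape:
            raise ValueError("roi_mask shape must match the image")
        if not roi_mask.any():
            warnings.warn("empty ROI mask; nothing to analyze", stacklevel=2)
            return Ki67Result(0, 0, float("nan"), 0, 0)
        rows = np.flatnonzero(roi_mask.any(axis=1))
        cols = np.flatnonzero(roi_mask.any(axis=0))
        sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
        pixels = pixels[sl]
        mask = roi_mask[sl]

    od = _stage("rgb_to_od", rgb_to_od, pixels, pixel_size_um=config.pixel_size_um)
    channels = _stage("deconvolve", deconvolve, od, config.stain_matrix)
    hema, dab = channels.hematoxylin, channels.dab
    if mask is not None:
        hema = np.where(mask, hema, 0.0)
        dab = np.where(mask, dab, 0.0)
    hema_flat = _stage("subtract_background", subtract_background, hema, config.rolling_ball_radius_px)
    dab_flat = _stage("subtract_background", subtract_background, dab, config.rolling_ball_radius_px)
    hema_norm = _stage("normalize_contrast", normalize_contrast, hema_flat, config.saturation_fraction)
    dab_norm = _stage("normalize_contrast", normalize_contrast, dab_flat, config.saturation_fraction)
    # all nuclei appear in one channel or the other; segment their union
    nuclear = np.maximum(hema_norm, dab_norm)
    labels = _stage("segment_nuclei", segment_nuclei, nuclear, config.threshold_method)
    labels, excl_small, excl_large = _stage(
        "filter_particles",
        filter_particles,
        labels,
        config.min_area_um2,
        config.max_area_um2,
        config.pixel_size_um,
    )
    records = _stage("classify_positivity", classify_positivity, labels, dab, hema, config.pixel_size_um)
    n_pos = sum(r.positivity == "positive" for r in records)
    n_neg = len(records) - n_pos
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        li = compute_li(n_pos, n_neg)
    return Ki67Result(n_pos, n_neg, li, excl_small, excl_large, tuple(records))
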