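"""Color deconvolution of hematoxylin / DAB brightfield images.

Brightfield IHC images are linear mixtures of stain absorbances, not
intensities: by the Beer-Lambert law the optical density of each RGB
channel is (approximately) the sum of per-stain densities weighted by
stain-specific absorption vectors.  Converting to optical density and
inverting the 3x3 stain matrix therefore separates a slide into
per-stain concentration maps ("color deconvolution", Ruifrok &
Johnston 2001).  This module provides that conversion for the standard
hematoxylin + DAB combination used for nuclear (Ki-67) and cytoplasmic
(osteopontin) markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RGBImage",
    "StainMatrix",
    "ODImage",
    "StainChannels",
    "rgb_to_od",
    "od_to_rgb",
    "default_hdab_matrix",
    "stain_matrix_from_csv",
    "deconvolve",
    "recompose",
]

#: Ruifrok & Johnston absorption vectors for hematoxylin and DAB
#: (the values preset in FIJI's colour-deconvolution "H DAB" mode).
_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
_DAB = np.array([0.268, 0.570, 0.776])

#: guard added to pixel intensities before the log so OD stays finite
#: at pixel value 0; one 8-bit intensity unit.
DEFAULT_EPS = 1.0


@dataclass(frozen=True)
class RGBImage:
    """A calibrated 8-bit brightfield field of view.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
        RGB intensities in [0, 255].
    pixel_size_um : float
        Physical edge length of one pixel in micrometres; must be
        finite and positive.
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) RGB array, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("RGB values must lie in [0, 255]")
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be finite and > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class StainMatrix:
    """Rows are unit optical-density absorption vectors (H, DAB, residual)."""

    matrix: np.ndarray
    names: tuple[str, str, str] = ("hematoxylin", "dab", "residual")

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain rows must have unit norm, got norms {norms}")
        if not np.isfinite(np.linalg.cond(m)):
            raise ValueError("stain matrix is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass(frozen=True)
class ODImage:
    """Per-channel optical densities (Beer-Lambert absorbances), >= 0."""

    od: np.ndarray
    pixel_size_um: float


@dataclass(frozen=True)
class StainChannels:
    """Unmixed per-stain concentration maps.

    ``hematoxylin`` and ``dab`` are clipped at zero for downstream
    counting; ``raw`` keeps the unclipped solution so the linear
    round trip (``recompose``) stays exact for diagnostics.
    """

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray
    pixel_size_um: float
    raw: np.ndarray = field(repr=False, default=None)


def rgb_to_od(image: RGBImage | np.ndarray, white_level: float = 255.0,
              eps: float = DEFAULT_EPS, pixel_size_um: float | None = None) -> ODImage:
    """Convert RGB intensities to optical density.

    od = -log10((I + eps) / white_level), clipped at 0 so that pixels at
    (or numerically above) the white level carry no absorbance.
    """
    if white_level <= 0:
        raise ValueError(f"white_level must be > 0, got {white_level}")
    if isinstance(image, RGBImage):
        pixels, psz = image.pixels, image.pixel_size_um
    else:
        pixels = np.asarray(image)
        psz = 1.0 if pixel_size_um is None else pixel_size_um
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) array, got shape {pixels.shape}")
    od = -np.log10((pixels.astype(np.float64) + eps) / float(white_level))
    return ODImage(np.clip(od, 0.0, None), psz)


def od_to_rgb(od: ODImage | np.ndarray, white_level: float = 255.0,
              eps: float = DEFAULT_EPS) -> np.ndarray:
    """Invert :func:`rgb_to_od`; returns uint8 intensities."""
    arr = od.od if isinstance(od, ODImage) else np.asarray(od)
    intensity = float(white_level) * np.power(10.0, -arr) - eps
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def default_hdab_matrix() -> StainMatrix:
    """Standard H-DAB stain matrix.

    Hematoxylin and DAB rows are the Ruifrok-Johnston presets; the
    residual row is their normalized cross product, i.e. the direction
    orthogonal to both stains.
    """
    h = _HEMATOXYLIN / np.linalg.norm(_HEMATOXYLIN)
    d = _DAB / np.linalg.norm(_DAB)
    r = np.cross(h, d)
    r /= np.linalg.norm(r)
    return StainMatrix(np.stack([h, d, r]))


def stain_matrix_from_csv(path) -> StainMatrix:
    """Load a user-calibrated 3x3 stain matrix (rows H, DAB, residual).

    Rows are re-normalized to unit length so users may supply raw OD
    measurements.
    """
    m = np.loadtxt(path, delimiter=",", dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"stain CSV must contain a 3x3 matrix, got {m.shape}")
    norms = np.linalg.norm(m, axis=1)
    if np.any(norms == 0):
        raise ValueError("stain CSV contains an all-zero row")
    return StainMatrix(m / norms[:, None])


def deconvolve(od: ODImage, stains: StainMatrix | None = None) -> StainChannels:
    """Unmix an OD image into per-stain concentration maps.

    Solves od = c @ M per pixel, i.e. c = od @ M^-1.  The hematoxylin
    and DAB maps are clipped at 0 (negative concentrations are
    unmixing noise); the unclipped solution is retained in ``raw``.
    """
    if stains is None:
        stains = default_hdab_matrix()
    conc = od.od @ stains.inverse
    return StainChannels(
        hematoxylin=np.clip(conc[..., 0], 0.0, None),
        dab=np.clip(conc[..., 1], 0.0, None),
        residual=conc[..., 2],
        pixel_size_um=od.pixel_size_um,
        raw=conc,
    )


def recompose(channels: StainChannels, stains: StainMatrix | None = None) -> ODImage:
    """Re-mix concentration maps into an OD image (od = c @ M).

    Uses the unclipped solution when available so that
    ``recompose(deconvolve(od))`` is the identity.
    """
    if stains is None:
        stains = default_hdab_matrix()
    if channels.raw is not None:
        conc = channels.raw
    else:
        conc = np.stack([channels.hematoxylin, channels.dab, channels.residual], axis=-1)
    od = conc @ stains.matrix
    return ODImage(od, channels.pixel_size_um)
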