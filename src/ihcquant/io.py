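"""Reading and writing the package's file formats.

Images are plain 8-bit RGB TIFF or PNG fields of view (whole-slide
pyramid formats are out of scope).  The pixel size comes from an
explicit argument or, for TIFF, from the resolution tags when present.
Segmentations are written as indexed PNGs with a fixed 4-class
palette.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .stain import RGBImage

__all__ = ["load_rgb", "save_rgb", "save_segmentation_png", "SEGMENTATION_PALETTE"]

#: RGB palette for segmentation PNGs: 1 white (outside), 2 gray (gaps),
#: 3 brown (OPN-positive), 4 blue (OPN-negative); 0 black (unlabeled)
SEGMENTATION_PALETTE = {
    0: (0, 0, 0),
    1: (255, 255, 255),
    2: (160, 160, 160),
    3: (160, 82, 45),
    4: (70, 100, 180),
}


def _tiff_pixel_size_um(path: Path) -> float | None:
    """Pixel size from TIFF XResolution/ResolutionUnit, if stored."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is None or unit is None:
            return None
        num, den = res.value
        if num == 0:
            return None
        per_unit = num / den  # pixels per unit
        unit = getattr(unit.value, "value", unit.value)
        if unit == 2:  # inch
            return 25400.0 / per_unit
        if unit == 3:  # centimetre
            return 10000.0 / per_unit
    return None


def load_rgb(path, pixel_size_um: float | None = None) -> RGBImage:
    """Load an 8-bit RGB TIFF/PNG as a calibrated image.

    An explicit ``pixel_size_um`` wins; otherwise TIFF resolution tags
    are consulted; otherwise an error asks for the calibration.
    """
    path = Path(path)
    if pixel_size_um is None and path.suffix.lower() in (".tif", ".tiff"):
        pixel_size_um = _tiff_pixel_size_um(path)
    if pixel_size_um is None:
        raise ValueError(
            f"{path.name}: no pixel size found; pass pixel_size_um "
            "(--pixel-size-um on the command line)"
        )
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[..., :3]
    return RGBImage(pixels, pixel_size_um)


def save_rgb(path, image: RGBImage) -> None:
    """Write an image; TIFF output carries the calibration as tags."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px_per_cm = 10000.0 / image.pixel_size_um
        tifffile.imwrite(
            path,
            image.pixels,
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
        )
    else:
        iio.imwrite(path, image.pixels)


def save_segmentation_png(path, class_map: np.ndarray) -> None:
    """Write a 4-class segmentation as a paletted RGB PNG."""
    class_map = np.asarray(class_map)
    rgb = np.zeros((*class_map.shape, 3), dtype=np.uint8)
    for cls, color in SEGMENTATION_PALETTE.items():
        rgb[class_map == cls] = color
    iio.imwrite(Path(path), rgb)
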