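"""Osteopontin-positive area fraction by supervised pixel classification.

Osteopontin is a secreted protein with cytoplasmic DAB staining, so a
nucleus count is meaningless; the quantity of interest is the fraction
of tissue area that stains positive.  Following the ilastik-style
workflow, a random forest is trained on sparse user scribbles to label
every pixel as one of four classes:

1. background outside the tissue section,
2. background inside the tissue (vessels and other gaps),
3. OPN-positive tissue,
4. OPN-negative tissue,

and the positive area fraction is class-3 area over class-3 + class-4
area — both background classes are excluded from the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "CLASS_NAMES",
    "TissueSegmentation",
    "OPNAreaResult",
    "extract_pixel_features",
    "validate_scribbles",
    "PixelClassifier",
    "train_pixel_classifier",
    "classify_pixels",
    "area_fraction",
]

CLASS_NAMES = {
    1: "background-outside-tissue",
    2: "background-in-tissue",
    3: "opn-positive",
    4: "opn-negative",
}

DEFAULT_SCALES = (1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class TissueSegmentation:
    """Dense four-class label map with per-class pixel counts."""

    class_map: np.ndarray  # H x W, values in {1, 2, 3, 4}
    pixel_size_um: float

    def __post_init__(self):
        cm = np.asarray(self.class_map)
        if not np.isin(cm, list(CLASS_NAMES)).all():
            raise ValueError("class map must contain only classes 1-4")
        object.__setattr__(self, "class_map", cm)

    @property
    def class_counts(self) -> dict[int, int]:
        counts = np.bincount(self.class_map.ravel(), minlength=5)
        return {c: int(counts[c]) for c in CLASS_NAMES}


@dataclass(frozen=True)
class OPNAreaResult:
    positive_area_um2: float
    negative_area_um2: float
    background_area_um2: float
    area_fraction_percent: float  # NaN when there is no tissue


def extract_pixel_features(
    image: np.ndarray, scales: tuple[float, ...] = DEFAULT_SCALES
) -> tuple[np.ndarray, list[str]]:
    """Multi-scale per-pixel feature stack.

    For each RGB channel and each Gaussian scale sigma: smoothed
    intensity, gradient magnitude, and Laplacian of Gaussian; plus the
    three raw channels.  Feature count is ``3 + 9 * len(scales)``.

    Returns the (H, W, F) float32 stack and the feature names; the
    names are the layout contract checked at prediction time.
    """
    pixels = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got {pixels.shape}")
    if len(scales) == 0 or any(s <= 0 for s in scales):
        raise ValueError("scales must be nonempty and positive")
    img = pixels.astype(np.float32) / 255.0
    stacks, names = [], []
    for c, cname in enumerate("rgb"):
        stacks.append(img[..., c])
        names.append(f"raw_{cname}")
    for sigma in scales:
        for c, cname in enumerate("rgb"):
            chan = img[..., c].astype(np.float64)
            stacks.append(ndi.gaussian_filter(chan, sigma))
            names.append(f"gauss_{cname}_s{sigma:g}")
            stacks.append(ndi.gaussian_gradient_magnitude(chan, sigma))
            names.append(f"gradmag_{cname}_s{sigma:g}")
            stacks.append(ndi.gaussian_laplace(chan, sigma))
            names.append(f"log_{cname}_s{sigma:g}")
    return np.stack(stacks, axis=-1).astype(np.float32), names


def validate_scribbles(scribbles: np.ndarray) -> np.ndarray:
    """Check a sparse scribble label map (0 = unlabeled, 1-4 = classes)."""
    scribbles = np.asarray(scribbles)
    if not np.isin(scribbles, [0, 1, 2, 3, 4]).all():
        raise ValueError("scribble values must lie in {0, 1, 2, 3, 4}")
    missing = [c for c in CLASS_NAMES if not (scribbles == c).any()]
    if missing:
        names = ", ".join(f"{c} ({CLASS_NAMES[c]})" for c in missing)
        raise ValueError(f"scribbles missing class(es): {names}")
    return scribbles


class PixelClassifier:
    """Random forest over multi-scale features, ilastik-style.

    100 trees, default depth, reproducible for a fixed seed.  The
    training feature names are stored and enforced (with reordering)
    at prediction time.
    """

    def __init__(self, feature_names: list[str], seed: int = 0, n_estimators: int = 100):
        self.feature_names = list(feature_names)
        self.seed = int(seed)
        self.forest = RandomForestClassifier(
            n_estimators=n_estimators, random_state=self.seed, n_jobs=1
        )

    def fit(self, features: np.ndarray, scribbles: np.ndarray) -> "PixelClassifier":
        scribbles = validate_scribbles(scribbles)
        if features.shape[:2] != scribbles.shape:
            raise ValueError("feature stack and scribbles must share H x W")
        sel = scribbles > 0
        self.forest.fit(features[sel], scribbles[sel])
        return self

    def _align(self, features: np.ndarray, feature_names: list[str] | None) -> np.ndarray:
        if feature_names is None:
            if features.shape[-1] != len(self.feature_names):
                raise ValueError(
                    f"feature stack has {features.shape[-1]} layers, classifier "
                    f"was trained on {len(self.feature_names)}"
                )
            return features
        if sorted(feature_names) != sorted(self.feature_names):
            raise ValueError("feature names do not match the training layout")
        order = [feature_names.index(n) for n in self.feature_names]
        return features[..., order]

    def predict_map(self, features: np.ndarray, feature_names: list[str] | None = None) -> np.ndarray:
        features = self._align(features, feature_names)
        flat = features.reshape(-1, features.shape[-1])
        # sklearn breaks probability ties toward the first class, i.e.
        # the lower class id — the tie rule we want.
        return self.forest.predict(flat).reshape(features.shape[:2]).astype(np.uint8)

    def save(self, path) -> None:
        joblib.dump({"feature_names": self.feature_names, "seed": self.seed,
                     "forest": self.forest}, path)

    @classmethod
    def load(cls, path) -> "PixelClassifier":
        state = joblib.load(path)
        obj = cls.__new__(cls)
        obj.feature_names = state["feature_names"]
        obj.seed = state["seed"]
        obj.forest = state["forest"]
        return obj


def train_pixel_classifier(
    features: np.ndarray,
    scribbles: np.ndarray,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> PixelClassifier:
    """Fit the four-class random forest on the scribbled pixels only."""
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(features.shape[-1])]
    return PixelClassifier(feature_names, seed=seed).fit(features, scribbles)


def classify_pixels(
    classifier: PixelClassifier,
    features: np.ndarray,
    pixel_size_um: float = 1.0,
    feature_names: list[str] | None = None,
) -> TissueSegmentation:
    """Dense per-pixel argmax classification into the four classes."""
    return TissueSegmentation(
        classifier.predict_map(features, feature_names), pixel_size_um
    )


def area_fraction(seg: TissueSegmentation) -> OPNAreaResult:
    """Positive area fraction of the tissue, background excluded.

    fraction = 100 * area(class 3) / (area(class 3) + area(class 4));
    classes 1 and 2 never enter the denominator, so the result is
    invariant to how much empty slide or vessel lumen the field
    contains.
    """
    counts = seg.class_counts
    a = seg.pixel_size_um**2
    pos, neg = counts[3] * a, counts[4] * a
    bg = (counts[1] + counts[2]) * a
    if pos + neg == 0:
        warnings.warn("no tissue pixels; area fraction is undefined", stacklevel=2)
        return OPNAreaResult(pos, neg, bg, float("nan"))
    return OPNAreaResult(pos, neg, bg, 100.0 * pos / (pos + neg))
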