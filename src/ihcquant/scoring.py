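"""Manual IHC scoring systems: the OPN IHC score and the Allred score.

Both systems summarize a slide by staining intensity (0 = absent,
1 = weak, 2 = moderate, 3 = strong) and the percentage of positive
staining.  The OPN IHC score (an H-score variant) multiplies the two,
giving a range of 0-300.  The Allred score sums a binned proportion
score (0-5) and the intensity score (0-3); because any staining forces
both components to be at least 1, the achievable totals are 0 and 2-8
— a total of 1 is impossible.

The percentage bins of the proportion score are published with shared
edges (1-10%, 10-33%, 33-67%, 67-100%); this implementation uses
left-closed / right-open bins with the last bin closed at 100, so the
mapping is total and deterministic.  The bin edges are an argument for
users who prefer a different edge convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AllredScore",
    "opn_ihc_score",
    "allred_proportion_score",
    "allred_score",
    "estimate_intensity",
]

#: proportion-score bin edges: 0 -> 0, (0,1) -> 1, [1,10) -> 2,
#: [10,33) -> 3, [33,67) -> 4, [67,100] -> 5
DEFAULT_PROPORTION_EDGES = (1.0, 10.0, 33.0, 67.0)

#: default cutoffs mapping a mean positive-area DAB optical density to
#: an intensity score (weak / moderate / strong)
DEFAULT_INTENSITY_OD_CUTOFFS = (0.15, 0.35, 0.60)


def _check_percent(percent: float) -> float:
    percent = float(percent)
    if not (0.0 <= percent <= 100.0) or not np.isfinite(percent):
        raise ValueError(f"percent must lie in [0, 100], got {percent}")
    return percent


def _check_intensity(intensity: int) -> int:
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity score must be one of 0-3, got {intensity}")
    return int(intensity)


def opn_ihc_score(intensity: int, percent: float) -> float:
    """Intensity (0-3) times positive percentage (0-100); range 0-300."""
    return _check_intensity(intensity) * _check_percent(percent)


def allred_proportion_score(
    percent: float, edges: tuple[float, float, float, float] = DEFAULT_PROPORTION_EDGES
) -> int:
    """Bin a positive-staining percentage into the Allred proportion score.

    0 for no staining; 1 for < 1%; then 2-5 for the published bins
    under the left-closed convention.
    """
    percent = _check_percent(percent)
    if percent == 0.0:
        return 0
    return 1 + int(np.searchsorted(np.asarray(edges), percent, side="right"))


@dataclass(frozen=True)
class AllredScore:
    proportion_score: int  # 0-5
    intensity_score: int  # 0-3
    total: int  # 0 or 2-8


def allred_score(
    percent: float,
    intensity: int,
    edges: tuple[float, float, float, float] = DEFAULT_PROPORTION_EDGES,
) -> AllredScore:
    """Allred total = proportion score + intensity score.

    Consistency is enforced: staining present (percent > 0) requires
    intensity >= 1, and percent == 0 requires intensity == 0.  This is
    what confines the totals to {0} | {2..8}.
    """
    percent = _check_percent(percent)
    intensity = _check_intensity(intensity)
    if percent > 0 and intensity == 0:
        raise ValueError("staining present (percent > 0) but intensity 0 is inconsistent")
    if percent == 0 and intensity != 0:
        raise ValueError("no staining (percent 0) but nonzero intensity is inconsistent")
    ps = allred_proportion_score(percent, edges)
    return AllredScore(ps, intensity, ps + intensity)


def estimate_intensity(
    mean_positive_dab_od: float,
    thresholds: tuple[float, float, float] = DEFAULT_INTENSITY_OD_CUTOFFS,
    any_positive: bool | None = None,
) -> int:
    """Quantitative surrogate for the visual intensity score.

    Bins the mean DAB optical density of the positive area at three
    ascending cutoffs.  When any positive area exists the score is
    floored at 1 (weak), preserving the Allred consistency rule; with
    no positive area the score is 0.  ``any_positive`` defaults to
    ``mean_positive_dab_od > 0``.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("intensity thresholds must be ascending")
    od = float(mean_positive_dab_od)
    if any_positive is None:
        any_positive = od > 0
    if not any_positive:
        return 0
    raw = int(np.searchsorted(np.asarray(thresholds), od, side="right"))
    return max(raw, 1)
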