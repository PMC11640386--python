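"""WHO (2016) meningioma grading from pathologist-supplied features.

The grade is a deterministic function of the histologic findings; this
module only encodes the rules — detecting brain invasion, counting
mitoses or recognizing subtypes remains the pathologist's job and
enters as input.

Grade III: mitotic rate >= 20 per 10 HPF, or an anaplastic / papillary
/ rhabdoid subtype.  Grade II: mitotic rate 4-19 per 10 HPF, brain
invasion, or at least three of five atypical features (spontaneous or
geographic necrosis, patternless sheets, prominent nucleoli, high
cellularity, small cells with high N:C ratio).  Otherwise grade I.

A mitotic count of exactly 20 sits between the published grade-II band
(4-19) and the "above 20" grade-III wording; it is assigned grade III
here, matching the human WHO 2016 convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = ["ATYPICAL_FEATURES", "HistoFeatures", "WHOGrade", "assign_grade", "grade_cohort"]

ATYPICAL_FEATURES = frozenset(
    {
        "necrosis",  # spontaneous or geographic necrosis
        "patternless_sheets",
        "prominent_nucleoli",
        "high_cellularity",
        "small_cells_high_nc_ratio",
    }
)


@dataclass(frozen=True)
class HistoFeatures:
    """Histologic findings for one sample, as read out by a pathologist."""

    mitoses_per_10hpf: int = 0
    brain_invasion: bool = False
    atypical_features: frozenset[str] = field(default_factory=frozenset)
    subtype_label: str = ""  # metadata only; never affects the grade
    malignant_subtype: bool = False  # anaplastic / papillary / rhabdoid

    def __post_init__(self):
        if self.mitoses_per_10hpf < 0:
            raise ValueError("mitoses_per_10hpf must be >= 0")
        feats = frozenset(self.atypical_features)
        unknown = feats - ATYPICAL_FEATURES
        if unknown:
            raise ValueError(
                f"unknown atypical feature(s) {sorted(unknown)}; "
                f"valid names: {sorted(ATYPICAL_FEATURES)}"
            )
        object.__setattr__(self, "atypical_features", feats)


@dataclass(frozen=True)
class WHOGrade:
    grade: str  # "I" | "II" | "III"
    triggering_criteria: tuple[str, ...]


def assign_grade(f: HistoFeatures) -> WHOGrade:
    """Apply the grading rules; every fired rule is reported."""
    grade3, grade2 = [], []
    if f.mitoses_per_10hpf >= 20:
        grade3.append("mitoses>=20/10HPF")
    if f.malignant_subtype:
        grade3.append("anaplastic/papillary/rhabdoid subtype")
    if 4 <= f.mitoses_per_10hpf <= 19:
        grade2.append("mitoses 4-19/10HPF")
    if f.brain_invasion:
        grade2.append("brain invasion")
    if len(f.atypical_features) >= 3:
        grade2.append(f">=3 atypical features ({len(f.atypical_features)})")
    if grade3:
        return WHOGrade("III", tuple(grade3 + grade2))
    if grade2:
        return WHOGrade("II", tuple(grade2))
    return WHOGrade("I", ())


def grade_cohort(features: Iterable[HistoFeatures] | pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Grade every sample and tabulate the grade distribution.

    Accepts either a sequence of :class:`HistoFeatures` or a DataFrame
    with columns ``mitoses_per_10hpf``, ``brain_invasion``,
    ``atypical_features`` (semicolon-separated names), ``subtype`` and
    ``malignant_subtype``.  Returns a per-sample table and the grade
    percentages rounded to one decimal.
    """
    if isinstance(features, pd.DataFrame):
        rows = []
        for _, r in features.iterrows():
            feats = r.get("atypical_features", "")
            if not isinstance(feats, str):  # NaN from an empty CSV cell
                feats = ""
            feats = frozenset(x.strip() for x in feats.split(";") if x.strip())
            rows.append(
                HistoFeatures(
                    mitoses_per_10hpf=int(r.get("mitoses_per_10hpf", 0)),
                    brain_invasion=bool(r.get("brain_invasion", False)),
                    atypical_features=feats,
                    subtype_label=str(r.get("subtype", "")),
                    malignant_subtype=bool(r.get("malignant_subtype", False)),
                )
            )
        features = rows
    else:
        features = list(features)
    if not features:
        raise ValueError("empty cohort")
    graded = [assign_grade(f) for f in features]
    table = pd.DataFrame(
        {
            "subtype": [f.subtype_label for f in features],
            "mitoses_per_10hpf": [f.mitoses_per_10hpf for f in features],
            "brain_invasion": [f.brain_invasion for f in features],
            "grade": [g.grade for g in graded],
            "triggering_criteria": ["; ".join(g.triggering_criteria) for g in graded],
        }
    )
    n = len(graded)
    distribution = {
        g: round(100.0 * sum(t.grade == g for t in graded) / n, 1) for g in ("I", "II", "III")
    }
    return table, distribution
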