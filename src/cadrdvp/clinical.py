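"""Deterministic clinical scoring utilities.

SCORTEN is the seven-factor severity-of-illness score for epidermal
necrolysis; its category-wise predicted mortality comes from the original
validation study (categories 0-1, 2, 3, 4, >=5). CADR severity is
classified from the detached body-surface area: TEN above 30%, SJS-TEN
overlap for 10-30% (boundaries inclusive), SJS below 10%. The murine
disease model is scored on three 0-3 ordinal components (oedema, rubor,
epidermal disruption) summed to a 0-9 clinical score, and group contrasts
use a one-tailed Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ScortenInput",
    "scorten",
    "classify_cadr_severity",
    "MouseScoreInput",
    "mouse_ten_score",
    "welch_t_one_tailed",
]

#: predicted mortality (%) per SCORTEN category from the score's
#: original validation cohort
SCORTEN_MORTALITY = {
    "0-1": 3.2,
    "2": 12.1,
    "3": 35.3,
    "4": 58.3,
    ">=5": 90.0,
}


@dataclass(frozen=True)
class ScortenInput:
    """The seven binary SCORTEN risk factors."""

    age_ge_40: bool = False
    malignancy: bool = False
    heart_rate_ge_120: bool = False
    initial_detachment_gt_10pct: bool = False
    urea_gt_10mM: bool = False
    glucose_gt_14mM: bool = False
    bicarbonate_lt_20mM: bool = False

    def __post_init__(self):
        for f in fields(self):
            if not isinstance(getattr(self, f.name), (bool, np.bool_)):
                raise ValidationError(f"SCORTEN factor {f.name} must be boolean")


def scorten(factors: ScortenInput) -> tuple[int, float]:
    """SCORTEN score (count of positive factors) and predicted mortality in %."""
    score = sum(bool(getattr(factors, f.name)) for f in fields(factors))
    if score <= 1:
        category = "0-1"
    elif score >= 5:
        category = ">=5"
    else:
        category = str(score)
    return score, SCORTEN_MORTALITY[category]


def classify_cadr_severity(bsa_detached_percent: float) -> str:
    """SJS / SJS-TEN overlap / TEN from the detached body-surface area (%)."""
    bsa = float(bsa_detached_percent)
    if not 0 <= bsa <= 100:
        raise ValidationError(f"BSA percentage out of range [0, 100]: {bsa}")
    if bsa > 30:
        return "TEN"
    if bsa >= 10:
        return "SJS-TEN overlap"
    return "SJS"


@dataclass(frozen=True)
class MouseScoreInput:
    """Ordinal 0-3 components of the murine clinical score."""

    oedema: int
    rubor: int
    epidermal_disruption: int

    def __post_init__(self):
        for f in fields(self):
            value = getattr(self, f.name)
            if value not in (0, 1, 2, 3):
                raise ValidationError(
                    f"mouse score component {f.name} must be in {{0,1,2,3}}, "
                    f"got {value!r}")


def mouse_ten_score(components: MouseScoreInput) -> int:
    """Overall murine clinical score: sum of the three components (0-9)."""
    return components.oedema + components.rubor + components.epidermal_disruption


def welch_t_one_tailed(group_a, group_b, direction: str = "greater"
                       ) -> tuple[float, float]:
    """Welch's unequal-variance t-test, one-tailed.

    ``direction='greater'`` tests mean(a) > mean(b); ``'less'`` the reverse.
    Satterthwaite degrees of freedom; returns (t, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 observations")
    if direction not in ("greater", "less"):
        raise ValidationError(f"direction must be 'greater' or 'less', "
                              f"got {direction!r}")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 0.5
        t = np.inf if a[0] > b[0] else -np.inf
        p = 0.0 if (t > 0) == (direction == "greater") else 1.0
        return float(t), p
    res = stats.ttest_ind(a, b, equal_var=False, alternative=direction)
    return float(res.statistic), float(res.pvalue)
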