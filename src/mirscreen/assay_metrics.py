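"""Small exactly-specified assay formulas used around the screen.

Relative quantification of qPCR by the ddCt method with one or more
reference genes, the modified-ellipsoid xenograft tumour-volume formula,
a three-point immunohistochemistry staining rubric, and sulphorhodamine-B
relative growth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger(__name__)

_INTENSITY_RANK = {"weak": 0, "moderate": 1, "strong": 2}


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target Ct plus reference-gene Cts."""

    sample_id: str
    condition: str  # "treated" | "control"
    target_ct: float
    reference_cts: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.reference_cts:
            raise ValueError("at least one reference gene required")
        for ct in (self.target_ct, *self.reference_cts):
            if not (math.isfinite(ct) and ct > 0):
                raise ValueError("Ct values must be positive and finite")

    @property
    def delta_ct(self) -> float:
        # arithmetic mean of reference Cts == geometric-mean normalizer on
        # the linear (2^-Ct) scale, the standard multi-reference practice
        return self.target_ct - sum(self.reference_cts) / len(self.reference_cts)


def ddct_fold_change(treated: CtRecord, control: CtRecord) -> float:
    """Fold change 2^-(dCt_treated - dCt_control) of target expression."""
    if len(treated.reference_cts) != len(control.reference_cts):
        raise ValueError("reference-gene lists differ between records")
    ddct = treated.delta_ct - control.delta_ct
    return 2.0 ** (-ddct)


def tumour_volume(width: float, length: float) -> float:
    """Modified-ellipsoid xenograft volume, width^2 x length / 2 (mm^3).

    Width is the shorter caliper axis by convention; swapped inputs are
    corrected with a logged warning rather than rejected.
    """
    if width <= 0 or length <= 0:
        raise ValueError("dimensions must be positive")
    if width > length:
        logger.warning("width %g > length %g: swapping to enforce convention", width, length)
        width, length = length, width
    return width**2 * length / 2.0


def ihc_score(intensity: str, pct_positive: float) -> tuple[int, bool]:
    """Staining score 1-3 from intensity grade and percent positive cells.

    Rubric: 1 = weak in <10% of cells; 2 = weak in <=20% or moderate in
    <=10%; 3 = moderate or strong in >10%. Cells the rubric leaves open are
    completed monotonically — (weak, >20%) -> 2 and (strong, <=10%) -> 2 —
    and flagged via the second return value (True = extrapolated).
    """
    if intensity not in _INTENSITY_RANK:
        raise ValueError(f"unknown intensity {intensity!r}; expected weak/moderate/strong")
    if not 0 <= pct_positive <= 100:
        raise ValueError("pct_positive outside [0, 100]")
    if intensity == "weak":
        if pct_positive < 10:
            return 1, False
        if pct_positive <= 20:
            return 2, False
        return 2, True  # rubric gap: weak staining in >20% of cells
    if intensity == "moderate":
        return (2, False) if pct_positive <= 10 else (3, False)
    # strong
    return (3, False) if pct_positive > 10 else (2, True)  # gap: strong, <=10%


def relative_growth(absorbance_day_t: float, absorbance_day_0: float) -> float:
    """SRB relative cell growth: day-t absorbance over day-0 absorbance."""
    if absorbance_day_0 <= 0:
        raise ValueError("day-0 absorbance must be > 0")
    return absorbance_day_t / absorbance_day_0
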