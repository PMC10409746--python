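"""Host-side readouts from the gnotobiotic-mouse arm.

Composite intestinal pathology scoring (sum of four histology sub-scores
with fixed inflammation bands) and the cecal-to-body-weight ratio. Group
comparisons of these readouts reuse the shared two-sided Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

from .metabolites import welch_ttest  # shared test implementation
from .types import ValidationError

_RANGES = {
    "edema": (0, 3),
    "pmn_infiltration": (0, 4),
    "goblet_loss": (0, 3),
    "epithelial_damage": (0, 3),
}

#: Inflammation bands over the total score 0-13 (inclusive, gap-free).
BANDS = (
    (0, 3, "no inflammation"),
    (4, 8, "mild inflammation"),
    (9, 13, "profound inflammation"),
)


@dataclass(frozen=True)
class HistologySubscores:
    """Blinded histology sub-scores of one intestinal section."""

    edema: int
    pmn_infiltration: int
    goblet_loss: int
    epithelial_damage: int

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi) or int(v) != v:
                raise ValidationError(f"{name} must be an integer in [{lo}, {hi}], got {v}")


def pathology_score(sub: HistologySubscores) -> tuple[int, str]:
    """Sum the four sub-scores and map to the inflammation category band."""
    total = sub.edema + sub.pmn_infiltration + sub.goblet_loss + sub.epithelial_damage
    for lo, hi, name in BANDS:
        if lo <= total <= hi:
            return total, name
    raise AssertionError("total outside 0-13; sub-score validation should prevent this")


def cecal_ratio(cecal_weight: float, body_weight: float) -> float:
    """Cecal weight over body weight (both grams; dimensionless)."""
    if cecal_weight <= 0:
        raise ValidationError(f"cecal_weight must be > 0, got {cecal_weight}")
    if body_weight <= 0:
        raise ValidationError(f"body_weight must be > 0, got {body_weight}")
    return cecal_weight / body_weight


def compare_groups(a, b) -> float:
    """Two-sided Welch t-test p-value between two groups of host readouts."""
    return welch_ttest(a, b)
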