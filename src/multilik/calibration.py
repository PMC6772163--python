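"""Evidence-type calibration from cross-tabs of classified variants.

A cross-tab counts (likely) benign and (likely) pathogenic variants per
evidence category.  The per-category LR towards pathogenicity is the ratio of
class-conditional proportions, with a conservative single-variant substitution
for empty cells, a log-scale Wald 95% confidence interval, and a mapping of
LR magnitudes onto ACMG/AMP evidence-code strengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

__all__ = [
    "CrossTab",
    "LREstimate",
    "EvidenceDirection",
    "EvidenceStrength",
    "crosstab_lr",
    "inverse_lr",
    "acmg_strength",
    "concordance_table",
    "format_lr_value",
]

Z_95 = 1.96


@dataclass(frozen=True)
class CrossTab:
    """Counts of benign and pathogenic variants per evidence category."""

    categories: tuple[str, ...]
    benign_counts: tuple[int, ...]
    pathogenic_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.categories)
        if len(self.benign_counts) != n or len(self.pathogenic_counts) != n:
            raise ValueError("count vectors must match the category list")
        if any(c < 0 for c in self.benign_counts + self.pathogenic_counts):
            raise ValueError("counts must be nonnegative")
        if len(set(self.categories)) != n:
            raise ValueError("categories must be unique")

    @property
    def benign_total(self) -> int:
        return sum(self.benign_counts)

    @property
    def pathogenic_total(self) -> int:
        return sum(self.pathogenic_counts)

    def index(self, category: str) -> int:
        try:
            return self.categories.index(category)
        except ValueError:
            raise KeyError(f"unknown category {category!r}") from None


@dataclass(frozen=True)
class LREstimate:
    lr: float
    ci_low: float
    ci_high: float
    zero_cell_adjusted: bool
    adjusted_counts: tuple[float, int, float, int]  # (a, n1, c, n2) used for the point estimate

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.lr <= self.ci_high):
            raise ValueError("require 0 < ci_low <= lr <= ci_high")


def _point_counts(counts: Sequence[int], idx: int) -> float:
    """Count used in the proportion for cell *idx* after zero-cell handling.

    An empty cell is assumed to hold a single variant.  In a two-category
    table the borrowed variant is taken from the complementary cell, so the
    class proportions still sum to one.
    """
    raw = counts[idx]
    if raw > 0:
        if len(counts) == 2 and counts[1 - idx] == 0:
            return float(raw - 1)
        return float(raw)
    return 1.0


def crosstab_lr(tab: CrossTab, category: str) -> LREstimate:
    """LR towards pathogenicity for one category of a cross-tab.

    Point estimate: ratio of pathogenic to benign class-conditional
    proportions, with the single-variant zero-cell substitution.  The 95% CI
    is a log-scale Wald interval; its variance uses the observed cell counts
    where they are nonzero (so a proportion of one contributes no variance)
    and the substituted single variant where the observed count is zero.
    """
    n1 = tab.pathogenic_total
    n2 = tab.benign_total
    if n1 == 0 or n2 == 0:
        raise ValueError("both class totals must be positive")
    idx = tab.index(category)
    a_raw = tab.pathogenic_counts[idx]
    c_raw = tab.benign_counts[idx]
    if a_raw == 0 and c_raw == 0:
        raise ValueError(f"category {category!r} unobserved in both classes")

    a = _point_counts(tab.pathogenic_counts, idx)
    c = _point_counts(tab.benign_counts, idx)
    lr = (a / n1) / (c / n2)

    a_se = a_raw if a_raw > 0 else 1
    c_se = c_raw if c_raw > 0 else 1
    se = math.sqrt(max(1.0 / a_se - 1.0 / n1 + 1.0 / c_se - 1.0 / n2, 0.0))
    half = Z_95 * se
    return LREstimate(
        lr=lr,
        ci_low=lr * math.exp(-half),
        ci_high=lr * math.exp(half),
        zero_cell_adjusted=(a_raw == 0 or c_raw == 0),
        adjusted_counts=(a, n1, c, n2),
    )


def inverse_lr(est: LREstimate) -> LREstimate:
    """The same estimate expressed in the opposite direction."""
    a, n1, c, n2 = est.adjusted_counts
    return LREstimate(
        lr=1.0 / est.lr,
        ci_low=1.0 / est.ci_high,
        ci_high=1.0 / est.ci_low,
        zero_cell_adjusted=est.zero_cell_adjusted,
        adjusted_counts=(c, n2, a, n1),
    )


class EvidenceDirection(str, Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    UNINFORMATIVE = "uninformative"


class EvidenceStrength(str, Enum):
    SUPPORTING = "supporting"
    MODERATE = "moderate"
    STRONG = "strong"
    VERY_STRONG = "very_strong"


#: Lower bounds of the pathogenic-direction strength bins (half-open on the
#: right; LR exactly 4.3 is moderate).  Benign bins sit at the reciprocals.
ACMG_BOUNDS = (
    (350.0, EvidenceStrength.VERY_STRONG),
    (18.7, EvidenceStrength.STRONG),
    (4.3, EvidenceStrength.MODERATE),
    (2.08, EvidenceStrength.SUPPORTING),
)


def acmg_strength(lr: float) -> tuple[EvidenceDirection, Optional[EvidenceStrength]]:
    """Map an LR to an ACMG/AMP evidence direction and strength."""
    if not lr > 0:
        raise ValueError("LR must be positive")
    if lr >= ACMG_BOUNDS[-1][0]:
        for bound, strength in ACMG_BOUNDS:
            if lr >= bound:
                return EvidenceDirection.PATHOGENIC, strength
    if lr <= 1.0 / ACMG_BOUNDS[-1][0]:
        inv = 1.0 / lr
        for bound, strength in ACMG_BOUNDS:
            if inv >= bound:
                return EvidenceDirection.BENIGN, strength
    return EvidenceDirection.UNINFORMATIVE, None


_EXTERNAL_PATHOGENIC = frozenset({"P", "LP"})
_EXTERNAL_BENIGN = frozenset({"B", "LB"})
_EXTERNAL_UNCERTAIN = frozenset({"VUS"})


def _internal_group(iarc_class) -> str:
    value = getattr(iarc_class, "value", iarc_class)
    if value in ("C4", "C5"):
        return "LP"
    if value in ("C1", "C2"):
        return "LB"
    if value == "C3":
        return "VUS"
    raise ValueError(f"unknown class {iarc_class!r}")


def concordance_table(
    internal: Mapping[str, object], external: Mapping[str, Sequence[str]]
) -> dict[tuple[str, str], int]:
    """Cross-count internal class groups against external assertion lists.

    External status uses at-least-one-assertion semantics with priority
    (L)P > (L)B > VUS; variants with no external record are counted under
    ``absent``.
    """
    counts: dict[tuple[str, str], int] = {}
    for variant, iarc_class in internal.items():
        group = _internal_group(iarc_class)
        assertions = external.get(variant)
        if not assertions:
            status = "absent"
        else:
            unknown = set(assertions) - _EXTERNAL_PATHOGENIC - _EXTERNAL_BENIGN - _EXTERNAL_UNCERTAIN
            if unknown:
                raise ValueError(f"{variant}: unknown external assertions {sorted(unknown)}")
            if _EXTERNAL_PATHOGENIC & set(assertions):
                status = "LP"
            elif _EXTERNAL_BENIGN & set(assertions):
                status = "LB"
            else:
                status = "VUS"
        counts[(group, status)] = counts.get((group, status), 0) + 1
    return counts


def format_lr_value(value: float) -> str:
    """Render an LR or CI bound at two decimals for tabular reports.

    Positive values that would round to 0.00 are displayed as 0.01 so that a
    bound is never shown as exactly zero.
    """
    if value <= 0:
        raise ValueError("LR values are positive")
    rounded = round(value, 2)
    if rounded < 0.01:
        rounded = 0.01
    return f"{rounded:.2f}"
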