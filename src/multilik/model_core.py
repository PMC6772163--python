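"""Bayesian core of the multifactorial likelihood classification model.

A variant enters the model with a prior probability of pathogenicity (assigned
upstream from bioinformatic prediction) and one or more likelihood ratios (LRs)
from independent clinical evidence types.  LRs are combined multiplicatively,
an informativeness gate suppresses classification when the combined LR sits in
the indeterminate band, and the Bayes posterior is mapped onto the IARC
five-tier scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

__all__ = [
    "COMPONENT_NAMES",
    "GATE_LOWER",
    "GATE_UPPER",
    "Gene",
    "VariantKind",
    "IARCClass",
    "ClassThresholds",
    "DEFAULT_THRESHOLDS",
    "PriorSpec",
    "VariantEvidence",
    "ClassificationResult",
    "assign_prior",
    "combine_lrs",
    "is_informative",
    "posterior",
    "classify",
    "classify_variant",
    "baseline_common_class1",
]

#: Evidence types recognised by the model.
COMPONENT_NAMES = (
    "segregation",
    "pathology",
    "cooccurrence",
    "family_history",
    "case_control",
)

#: Combined LRs strictly inside (GATE_LOWER, GATE_UPPER) are considered to
#: carry too little observational data for a valid integrated analysis; no
#: posterior is computed for them.  The band is open: an LR of exactly 0.5 or
#: 2.0 is informative.
GATE_LOWER = 0.5
GATE_UPPER = 2.0


class Gene(str, Enum):
    BRCA1 = "BRCA1"
    BRCA2 = "BRCA2"


class VariantKind(str, Enum):
    MISSENSE = "missense"
    INTRONIC = "intronic"
    SYNONYMOUS = "synonymous"
    INFRAME_INDEL = "inframe_indel"
    LARGE_REARRANGEMENT = "large_rearrangement"
    OTHER = "other"


class IARCClass(str, Enum):
    """IARC five-tier classes, C1 (benign) through C5 (pathogenic)."""

    C1 = "C1"
    C2 = "C2"
    C3 = "C3"
    C4 = "C4"
    C5 = "C5"

    @property
    def label(self) -> str:
        return {
            "C1": "Benign",
            "C2": "Likely Benign",
            "C3": "Uncertain",
            "C4": "Likely Pathogenic",
            "C5": "Pathogenic",
        }[self.value]


@dataclass(frozen=True)
class ClassThresholds:
    """Posterior-probability boundaries between the five tiers.

    ``c5_min`` is an exclusive lower bound (posterior must exceed it for C5);
    the remaining bounds are inclusive lower bounds of their tier.  A posterior
    of exactly 0.95 or 0.99 is therefore Likely Pathogenic, and exactly 0.05
    falls in the Uncertain tier.
    """

    c5_min: float = 0.99
    c4_min: float = 0.95
    c3_min: float = 0.05
    c2_min: float = 0.001

    def __post_init__(self) -> None:
        bounds = (self.c2_min, self.c3_min, self.c4_min, self.c5_min)
        if not all(0.0 < lo < hi < 1.0 for lo, hi in zip(bounds, bounds[1:], strict=False)):
            raise ValueError(f"class thresholds must be strictly increasing in (0, 1): {bounds}")


DEFAULT_THRESHOLDS = ClassThresholds()


@dataclass(frozen=True)
class PriorSpec:
    """Candidate prior probabilities for a single variant.

    ``per_base_priors`` carries one prior per deleted base for in-frame
    deletions that cannot be scored as a single substitution.
    """

    missense_prior: Optional[float] = None
    splicing_prior: Optional[float] = None
    per_base_priors: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        for name, value in (
            ("missense_prior", self.missense_prior),
            ("splicing_prior", self.splicing_prior),
        ):
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.per_base_priors is not None:
            if len(self.per_base_priors) == 0:
                raise ValueError("per_base_priors must be non-empty when given")
            if any(not 0.0 <= p <= 1.0 for p in self.per_base_priors):
                raise ValueError("per_base_priors must lie in [0, 1]")


def assign_prior(spec: PriorSpec) -> float:
    """Return the prior probability of pathogenicity for *spec*.

    The rule is a maximum over the available candidates: the higher of the
    missense and splicing priors, where an in-frame deletion contributes the
    highest per-deleted-base prior as its missense candidate.
    """
    candidates = []
    if spec.per_base_priors is not None:
        candidates.append(max(spec.per_base_priors))
    if spec.missense_prior is not None:
        candidates.append(spec.missense_prior)
    if spec.splicing_prior is not None:
        candidates.append(spec.splicing_prior)
    if not candidates:
        raise ValueError("no prior available")
    return max(candidates)


@dataclass
class VariantEvidence:
    """Prior and per-component likelihood ratios for one variant."""

    gene: Gene
    hgvs_c: str
    prior: float
    hgvs_p: Optional[str] = None
    variant_kind: VariantKind = VariantKind.OTHER
    components: Mapping[str, Sequence[float]] = field(default_factory=dict)
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene = Gene(self.gene)
        self.variant_kind = VariantKind(self.variant_kind)
        if not 0.0 <= self.prior <= 1.0:
            raise ValueError(f"{self.hgvs_c}: prior must lie in [0, 1], got {self.prior}")
        for name, lrs in self.components.items():
            if name not in COMPONENT_NAMES:
                raise ValueError(f"{self.hgvs_c}: unknown component {name!r}")
            for lr in lrs:
                if not lr > 0:
                    raise ValueError(f"{self.hgvs_c}: component {name} has nonpositive LR {lr}")

    @property
    def component_lrs(self) -> dict[str, float]:
        """Per-component product of LR data points."""
        return {name: math.prod(lrs) for name, lrs in self.components.items() if lrs}


@dataclass(frozen=True)
class ClassificationResult:
    combined_lr: float
    informative: bool
    posterior: Optional[float] = None
    iarc_class: Optional[IARCClass] = None
    component_lrs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.informative != (self.posterior is not None):
            raise ValueError("posterior must be present exactly when the result is informative")
        if self.posterior is not None and not 0.0 <= self.posterior <= 1.0:
            raise ValueError(f"posterior must lie in [0, 1], got {self.posterior}")


def combine_lrs(components: Mapping[str, Sequence[float]]) -> float:
    """Multiply every LR data point of every component; empty input gives 1."""
    product = 1.0
    for name, lrs in components.items():
        for lr in lrs:
            if not lr > 0:
                raise ValueError(f"component {name} has nonpositive LR {lr}")
            product *= lr
    return product


def is_informative(combined_lr: float, lower: float = GATE_LOWER, upper: float = GATE_UPPER) -> bool:
    """True unless the combined LR lies strictly inside the gate band."""
    if not combined_lr > 0:
        raise ValueError(f"combined LR must be positive, got {combined_lr}")
    return not (lower < combined_lr < upper)


def posterior(prior: float, combined_lr: float) -> float:
    """Odds-form Bayes update of *prior* by *combined_lr*.

    Computed as ``prior * LR / (prior * LR + 1 - prior)``, i.e. prior odds are
    multiplied by the LR and converted back to a probability.
    """
    if not 0.0 <= prior <= 1.0:
        raise ValueError(f"prior must lie in [0, 1], got {prior}")
    if not combined_lr > 0:
        raise ValueError(f"combined LR must be positive, got {combined_lr}")
    if prior == 1.0:
        return 1.0
    numerator = prior * combined_lr
    return numerator / (numerator + (1.0 - prior))


def classify(post: float, thresholds: ClassThresholds = DEFAULT_THRESHOLDS) -> IARCClass:
    """Map a posterior probability onto the IARC five-tier scale."""
    if not 0.0 <= post <= 1.0:
        raise ValueError(f"posterior must lie in [0, 1], got {post}")
    if post > thresholds.c5_min:
        return IARCClass.C5
    if post >= thresholds.c4_min:
        return IARCClass.C4
    if post >= thresholds.c3_min:
        return IARCClass.C3
    if post >= thresholds.c2_min:
        return IARCClass.C2
    return IARCClass.C1


def classify_variant(
    evidence: VariantEvidence, thresholds: ClassThresholds = DEFAULT_THRESHOLDS
) -> ClassificationResult:
    """Run the full pipeline for one variant.

    Gated variants (combined LR inside the indeterminate band) are returned
    with ``informative=False`` and no posterior or class.
    """
    combined = combine_lrs(evidence.components)
    per_component = evidence.component_lrs
    if not is_informative(combined):
        return ClassificationResult(
            combined_lr=combined, informative=False, component_lrs=per_component
        )
    post = posterior(evidence.prior, combined)
    return ClassificationResult(
        combined_lr=combined,
        informative=True,
        posterior=post,
        iarc_class=classify(post, thresholds),
        component_lrs=per_component,
    )


def baseline_common_class1(freq, maf_threshold: float = 0.01) -> bool:
    """True if the variant is common enough for baseline Class 1 assignment.

    The rule is strict: minor allele frequency must exceed *maf_threshold* in
    at least one designated outbred reference subpopulation.
    """
    from .evidence_components import OUTBRED_POPULATIONS

    combined = freq.combined()
    usable = False
    for pop in OUTBRED_POPULATIONS:
        ac, an = combined.get(pop, (0, 0))
        if an == 0:
            continue
        usable = True
        if ac / an > maf_threshold:
            return True
    if not usable:
        raise ValueError("no frequency data")
    return False
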