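"""Non-segregation evidence components.

Pathology lookups, co-occurrence with a known pathogenic variant in trans,
reported family-history lookups, case-control profile-likelihood ratios, and
reference-population frequency categorisation.  The co-occurrence and
case-control forms are parameterised reconstructions of externally published
methods; every constant lives in configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from scipy import optimize, stats

__all__ = [
    "OUTBRED_POPULATIONS",
    "FOUNDER_POPULATIONS",
    "ReceptorStatus",
    "TumorRecord",
    "PathologyLREntry",
    "PathologyLRTable",
    "FrequencyEntry",
    "FrequencyTable",
    "FrequencyCategory",
    "pathology_lr",
    "cooccurrence_lr",
    "family_history_lr",
    "case_control_lr",
    "frequency_category",
]

#: Designated outbred (non-founder) reference subpopulations.
OUTBRED_POPULATIONS = ("NFE", "AFR", "AMR", "SAS", "EAS")
#: Founder sample sets; a lone observation here excludes the variant from
#: frequency-based evidence instead of counting as "observed".
FOUNDER_POPULATIONS = ("FIN", "ASJ")


class ReceptorStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class TumorRecord:
    """One breast tumor of one individual."""

    member_id: str
    diagnosis_order: int
    age_diagnosis: float
    grade: Optional[int] = None
    er: Optional[ReceptorStatus] = None
    pr: Optional[ReceptorStatus] = None
    her2: Optional[ReceptorStatus] = None

    def __post_init__(self) -> None:
        if self.grade is not None and self.grade not in (1, 2, 3):
            raise ValueError(f"grade must be 1, 2 or 3, got {self.grade}")
        if self.age_diagnosis < 0:
            raise ValueError("diagnosis age must be nonnegative")

    @property
    def informative(self) -> bool:
        return any(v is not None for v in (self.grade, self.er, self.pr, self.her2))


@dataclass(frozen=True)
class PathologyLREntry:
    """One row of a pathology LR lookup table.

    Unset marker fields are wildcards; the information level of an entry is
    the number of marker fields it constrains.  ``age_max`` bounds the
    diagnosis age (exclusive); ``age_min`` is inclusive.
    """

    gene: str
    lr: float
    grade: Optional[int] = None
    er: Optional[ReceptorStatus] = None
    pr: Optional[ReceptorStatus] = None
    her2: Optional[ReceptorStatus] = None
    age_min: float = 0.0
    age_max: float = math.inf

    def __post_init__(self) -> None:
        if not self.lr > 0:
            raise ValueError("pathology LR must be positive")
        if self.level == 0:
            raise ValueError("entry must constrain at least one marker")

    @property
    def level(self) -> int:
        return sum(v is not None for v in (self.grade, self.er, self.pr, self.her2))

    def matches(self, tumor: TumorRecord) -> bool:
        if not self.age_min <= tumor.age_diagnosis < self.age_max:
            return False
        for want, have in (
            (self.grade, tumor.grade),
            (self.er, tumor.er),
            (self.pr, tumor.pr),
            (self.her2, tumor.her2),
        ):
            if want is not None and have != want:
                return False
        return True


@dataclass(frozen=True)
class PathologyLRTable:
    entries: tuple[PathologyLREntry, ...]

    def for_gene(self, gene: str) -> tuple[PathologyLREntry, ...]:
        out = tuple(e for e in self.entries if e.gene == str(gene))
        if not out:
            raise KeyError(f"pathology table has no entries for gene {gene}")
        return out


def pathology_lr(
    tumors: Sequence[TumorRecord], table: PathologyLRTable, gene: str
) -> Optional[float]:
    """Single pathology LR for an individual's tumors, or ``None``.

    The earliest-diagnosed tumor with any informative marker is selected and
    exactly one LR assigned from the richest (most specific) matching entry.
    """
    entries = table.for_gene(gene)
    ordered = sorted(tumors, key=lambda t: (t.diagnosis_order, t.age_diagnosis))
    for tumor in ordered:
        if not tumor.informative:
            continue
        matching = [e for e in entries if e.matches(tumor)]
        if not matching:
            raise LookupError(
                f"no pathology LR entry for gene={gene} grade={tumor.grade} "
                f"er={tumor.er} pr={tumor.pr} her2={tumor.her2} age={tumor.age_diagnosis}"
            )
        best_level = max(e.level for e in matching)
        best = [e for e in matching if e.level == best_level]
        if len(best) > 1:
            raise LookupError(
                f"ambiguous pathology LR entries at information level {best_level} for "
                f"gene={gene}; patterns must be mutually exclusive per level"
            )
        return best[0].lr
    return None


def cooccurrence_lr(
    n_tested: int, k_trans: int, theta_path: float, theta_neutral: float
) -> float:
    """Binomial LR for observed in-trans co-occurrences with pathogenic variants.

    ``theta_path`` is the (near-zero) probability of a deleterious variant
    co-occurring in trans with a pathogenic one; ``theta_neutral`` is roughly
    the population pathogenic-carrier frequency.
    """
    if not (0 < theta_path < 1 and 0 < theta_neutral < 1):
        raise ValueError("theta parameters must lie in (0, 1)")
    if not 0 <= k_trans <= n_tested:
        raise ValueError("need 0 <= k_trans <= n_tested")
    return ((1.0 - theta_path) / (1.0 - theta_neutral)) ** (n_tested - k_trans) * (
        theta_path / theta_neutral
    ) ** k_trans


def family_history_lr(category: str, table: Mapping[str, float]) -> float:
    """Pass-through lookup of an externally calibrated family-history LR."""
    try:
        return table[category]
    except KeyError:
        raise KeyError(f"unknown family-history category {category!r}") from None


def _case_frequency(q: float, rr: float) -> float:
    """Carrier frequency among cases implied by relative risk *rr* (odds scale)."""
    return rr * q / (1.0 - q + rr * q)


def case_control_lr(
    case_carriers: int,
    n_cases: int,
    control_carriers: int,
    n_controls: int,
    assumed_rr: float,
) -> float:
    """Profile-likelihood ratio for case-control carrier counts.

    The binomial likelihood of the observed counts is maximised over the
    nuisance population carrier frequency ``q`` twice: once with the case
    frequency implied by *assumed_rr* and once under no association; the LR is
    the ratio of the two maxima.
    """
    if not assumed_rr > 0:
        raise ValueError("assumed_rr must be positive")
    for k, n in ((case_carriers, n_cases), (control_carriers, n_controls)):
        if not 0 <= k <= n:
            raise ValueError("carrier counts must lie within sample sizes")
    if assumed_rr == 1.0 or case_carriers + control_carriers == 0:
        return 1.0

    def negloglik(q: float, rr: float) -> float:
        qc = _case_frequency(q, rr)
        return -(
            stats.binom.logpmf(case_carriers, n_cases, qc)
            + stats.binom.logpmf(control_carriers, n_controls, q)
        )

    eps = 1e-12

    def profile(rr: float) -> float:
        res = optimize.minimize_scalar(
            negloglik,
            bounds=(eps, 1.0 - eps),
            args=(rr,),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return -res.fun

    # Under no association the pooled frequency is the exact maximiser.
    pooled = (case_carriers + control_carriers) / (n_cases + n_controls)
    pooled = min(max(pooled, eps), 1.0 - eps)
    null_loglik = -negloglik(pooled, 1.0)
    return math.exp(profile(assumed_rr) - null_loglik)


class FrequencyCategory(str, Enum):
    NOT_OBSERVED = "not_observed"
    SINGLE_OBSERVATION = "single_observation"
    LOW = "low"  # 0 < max MAF < 1e-4
    MID = "mid"  # 1e-4 <= max MAF < 0.01
    EXCLUDED_NA = "excluded_na"


@dataclass(frozen=True)
class FrequencyEntry:
    population: str
    allele_count: int
    allele_number: int
    cohort: str = "exome"

    def __post_init__(self) -> None:
        if self.allele_count < 0 or self.allele_number < 0:
            raise ValueError("allele counts must be nonnegative")
        if self.allele_count > self.allele_number:
            raise ValueError(
                f"{self.population}/{self.cohort}: AC {self.allele_count} exceeds "
                f"AN {self.allele_number}"
            )


@dataclass(frozen=True)
class FrequencyTable:
    """Per-population allele counts, possibly split across sequencing cohorts."""

    entries: tuple[FrequencyEntry, ...]

    @classmethod
    def from_counts(cls, counts: Mapping[str, tuple[int, int]]) -> "FrequencyTable":
        return cls(
            tuple(
                FrequencyEntry(pop, ac, an, cohort="combined")
                for pop, (ac, an) in counts.items()
            )
        )

    def combined(self) -> dict[str, tuple[int, int]]:
        """Sum AC and AN across cohorts for each population."""
        out: dict[str, list[int]] = {}
        for e in self.entries:
            acc = out.setdefault(e.population, [0, 0])
            acc[0] += e.allele_count
            acc[1] += e.allele_number
        return {pop: (ac, an) for pop, (ac, an) in out.items()}

    def maf(self, population: str) -> Optional[float]:
        ac, an = self.combined().get(population, (0, 0))
        if an == 0:
            if ac > 0:
                raise ValueError(f"{population}: AC > 0 with AN = 0")
            return None
        return ac / an


def frequency_category(
    table: FrequencyTable,
    low_bound: float = 1e-4,
    mid_bound: float = 0.01,
) -> FrequencyCategory:
    """Categorise a variant by its highest outbred-population MAF.

    Allele counts (not carrier counts) are used throughout.  A variant absent
    from the outbred sets but present in a founder set is excluded from
    frequency evidence, as is a variant at or above *mid_bound* (already
    handled by the common-variant rule).
    """
    combined = table.combined()
    outbred_ac = 0
    max_maf = 0.0
    for pop in OUTBRED_POPULATIONS:
        ac, an = combined.get(pop, (0, 0))
        if ac > 0 and an == 0:
            raise ValueError(f"{pop}: AC > 0 with AN = 0")
        outbred_ac += ac
        if an > 0:
            max_maf = max(max_maf, ac / an)
    founder_ac = sum(combined.get(pop, (0, 0))[0] for pop in FOUNDER_POPULATIONS)
    for pop in FOUNDER_POPULATIONS:
        ac, an = combined.get(pop, (0, 0))
        if ac > 0 and an == 0:
            raise ValueError(f"{pop}: AC > 0 with AN = 0")

    if outbred_ac == 0:
        if founder_ac >= 1:
            return FrequencyCategory.EXCLUDED_NA
        return FrequencyCategory.NOT_OBSERVED
    if outbred_ac == 1:
        return FrequencyCategory.SINGLE_OBSERVATION
    if max_maf >= mid_bound:
        return FrequencyCategory.EXCLUDED_NA
    if max_maf >= low_bound:
        return FrequencyCategory.MID
    return FrequencyCategory.LOW
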