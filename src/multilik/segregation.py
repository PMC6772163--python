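"""Co-segregation Bayes factors from pedigrees with partial genotyping.

The family likelihood ratio contrasts two hypotheses about the assessed
variant: *causal* (carriers develop cancer at carrier rates, taken from an
age-bracket hazard model with per-bracket hazard ratios) and *neutral*
(everybody experiences population rates).  Untyped genotypes are summed out by
exact variable elimination over the pedigree graph; both hypothesis
likelihoods are conditioned on the proband's own genotype and phenotype, a
single-ascertainment correction for families recruited through an affected
carrier index case.

Genotype model: rare autosomal dominant with two states, carrier
(heterozygote) and noncarrier.  Founder carrier probability is twice the
variant allele frequency; homozygote carriers are ignored.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Sex",
    "GenotypeCall",
    "Phenotype",
    "SurgeryType",
    "Surgery",
    "PedigreeMember",
    "Pedigree",
    "PedigreeError",
    "IneligibleFamilyError",
    "PenetranceModel",
    "AGE_BRACKET_STARTS",
    "effective_censoring_age",
    "phenotype_likelihood",
    "family_segregation_lr",
    "variant_segregation_lr",
]

#: Start ages of the seven brackets (<30, 30-39, ..., 70-79, 80+).
AGE_BRACKET_STARTS = (0.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)

#: Age at which an affected member with no recorded diagnosis age is assumed
#: to have been diagnosed (midpoint of the 40-49 bracket).
DEFAULT_DIAGNOSIS_AGE = 45.0


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class GenotypeCall(str, Enum):
    CARRIER = "carrier"
    NONCARRIER = "noncarrier"
    UNTYPED = "untyped"


class Phenotype(str, Enum):
    UNAFFECTED = "unaffected"
    BREAST_CANCER = "breast_cancer"
    OVARIAN_CANCER = "ovarian_cancer"
    OTHER = "other"


class SurgeryType(str, Enum):
    MASTECTOMY = "mastectomy"
    OOPHORECTOMY = "oophorectomy"


@dataclass(frozen=True)
class Surgery:
    kind: SurgeryType
    age: float

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("surgery age must be nonnegative")


@dataclass
class PedigreeMember:
    member_id: str
    sex: Sex
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    genotype: GenotypeCall = GenotypeCall.UNTYPED
    proband: bool = False
    phenotype: Phenotype = Phenotype.UNAFFECTED
    age_diagnosis: Optional[float] = None
    age_last_observed: Optional[float] = None
    surgeries: tuple[Surgery, ...] = ()
    test_date_inferred_age: Optional[float] = None

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.genotype = GenotypeCall(self.genotype)
        self.phenotype = Phenotype(self.phenotype)
        if (self.father_id is None) != (self.mother_id is None):
            raise ValueError(f"{self.member_id}: both parents or neither must be given")
        for age in (self.age_diagnosis, self.age_last_observed, self.test_date_inferred_age):
            if age is not None and age < 0:
                raise ValueError(f"{self.member_id}: ages must be nonnegative")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


class PedigreeError(ValueError):
    """Structural problem with a pedigree."""


class IneligibleFamilyError(PedigreeError):
    """Family does not meet the eligibility rule for segregation analysis."""


class Pedigree:
    """Acyclic two-allele pedigree; loops (consanguinity) are rejected."""

    def __init__(self, family_id: str, members: Iterable[PedigreeMember]):
        self.family_id = family_id
        self.members: dict[str, PedigreeMember] = {}
        for m in members:
            if m.member_id in self.members:
                raise PedigreeError(f"duplicate member id {m.member_id}")
            self.members[m.member_id] = m
        self._validate()

    def _validate(self) -> None:
        for m in self.members.values():
            if m.is_founder:
                continue
            for pid, want in ((m.father_id, Sex.MALE), (m.mother_id, Sex.FEMALE)):
                parent = self.members.get(pid)
                if parent is None:
                    raise PedigreeError(f"{m.member_id}: unknown parent {pid}")
                if parent.sex != want:
                    raise PedigreeError(f"{m.member_id}: parent {pid} has inconsistent sex")
        self._topological = self._topological_order()
        self._reject_loops()

    def _topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(mid: str) -> None:
            if state.get(mid) == 2:
                return
            if state.get(mid) == 1:
                raise PedigreeError("pedigree contains a cycle")
            state[mid] = 1
            m = self.members[mid]
            if not m.is_founder:
                visit(m.father_id)
                visit(m.mother_id)
            state[mid] = 2
            order.append(mid)

        for mid in self.members:
            visit(mid)
        return order

    def _ancestors(self, mid: str) -> set[str]:
        out: set[str] = set()
        stack = [mid]
        while stack:
            m = self.members[stack.pop()]
            if not m.is_founder:
                for pid in (m.father_id, m.mother_id):
                    if pid not in out:
                        out.add(pid)
                        stack.append(pid)
        return out

    def _reject_loops(self) -> None:
        couples = {
            (m.father_id, m.mother_id) for m in self.members.values() if not m.is_founder
        }
        for father, mother in couples:
            shared = (self._ancestors(father) | {father}) & (self._ancestors(mother) | {mother})
            if shared:
                raise PedigreeError(
                    f"consanguineous mating {father} x {mother} (shared ancestors {sorted(shared)}); "
                    "looped pedigrees are not supported"
                )

    @property
    def topological_order(self) -> list[str]:
        return list(self._topological)

    @property
    def proband(self) -> PedigreeMember:
        probands = [m for m in self.members.values() if m.proband]
        if len(probands) != 1:
            raise PedigreeError(f"pedigree {self.family_id} must have exactly one proband")
        return probands[0]

    @property
    def genotyped(self) -> list[PedigreeMember]:
        return [m for m in self.members.values() if m.genotype != GenotypeCall.UNTYPED]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PenetranceModel:
    """Piecewise-constant age-bracket hazards with carrier hazard ratios.

    ``baseline`` and ``hazard_ratio`` map a cancer type (``breast_female``,
    ``ovarian``, optionally ``breast_male``) to one per-year hazard (resp.
    multiplicative carrier ratio) per age bracket.  ``allele_frequency`` is the
    population frequency of the variant allele, used for founder genotype
    priors; the founder carrier probability is twice this value.
    """

    baseline: Mapping[str, tuple[float, ...]]
    hazard_ratio: Mapping[str, tuple[float, ...]]
    allele_frequency: float = 0.001
    bracket_starts: tuple[float, ...] = AGE_BRACKET_STARTS
    open_bracket_width: float = 20.0

    def __post_init__(self) -> None:
        n = len(self.bracket_starts)
        if list(self.bracket_starts) != sorted(self.bracket_starts):
            raise ValueError("bracket starts must be increasing")
        for name, values in self.baseline.items():
            if len(values) != n:
                raise ValueError(f"{name}: expected {n} baseline hazards")
            if any(h < 0 for h in values):
                raise ValueError(f"{name}: hazards must be nonnegative")
        for name, values in self.hazard_ratio.items():
            if name not in self.baseline:
                raise ValueError(f"hazard ratio given for unknown cancer type {name}")
            if len(values) != n:
                raise ValueError(f"{name}: expected {n} hazard ratios")
            if any(r <= 0 for r in values):
                raise ValueError(f"{name}: hazard ratios must be positive")
        if not 0.0 <= self.allele_frequency <= 0.5:
            raise ValueError("allele frequency must lie in [0, 0.5]")

    @property
    def carrier_probability(self) -> float:
        return 2.0 * self.allele_frequency

    def cancer_types_for(self, sex: Sex) -> tuple[str, ...]:
        if sex == Sex.FEMALE:
            return tuple(t for t in ("breast_female", "ovarian") if t in self.baseline)
        return tuple(t for t in ("breast_male",) if t in self.baseline)

    def bracket_index(self, age: float) -> int:
        if age < 0:
            raise ValueError("age must be nonnegative")
        idx = 0
        for i, start in enumerate(self.bracket_starts):
            if age >= start:
                idx = i
        return idx

    def bracket_width(self, index: int) -> float:
        if index + 1 < len(self.bracket_starts):
            return self.bracket_starts[index + 1] - self.bracket_starts[index]
        return self.open_bracket_width

    def hazard(self, cancer_type: str, index: int, carrier: bool) -> float:
        h = self.baseline[cancer_type][index]
        if carrier:
            h *= self.hazard_ratio[cancer_type][index]
        return h

    def cumulative_hazard(self, cancer_type: str, age: float, carrier: bool) -> float:
        """Integral of the piecewise-constant hazard from birth to *age*."""
        total = 0.0
        for i, start in enumerate(self.bracket_starts):
            if age <= start:
                break
            end = start + self.bracket_width(i)
            years = min(age, end) - start
            if years > 0:
                total += years * self.hazard(cancer_type, i, carrier)
        return total

    def survival(self, sex: Sex, age: float, carrier: bool) -> float:
        """Probability of remaining free of all modelled cancers to *age*."""
        lam = sum(
            self.cumulative_hazard(ct, age, carrier) for ct in self.cancer_types_for(sex)
        )
        return math.exp(-lam)


def effective_censoring_age(member: PedigreeMember) -> Optional[float]:
    """Censoring age for an unaffected member.

    The earlier of the last-observed age (falling back to an age inferred from
    the genotyping test date) and the earliest prophylactic surgery.  Returns
    ``None``, with a warning, when no usable age exists; such members
    contribute likelihood 1.
    """
    base = member.age_last_observed
    if base is None:
        base = member.test_date_inferred_age
    candidates = [base] if base is not None else []
    candidates.extend(s.age for s in member.surgeries)
    if not candidates:
        warnings.warn(
            f"member {member.member_id} has no usable censoring age; treated as uninformative",
            stacklevel=2,
        )
        return None
    return min(candidates)


_PHENOTYPE_TO_CANCER = {
    (Phenotype.BREAST_CANCER, Sex.FEMALE): "breast_female",
    (Phenotype.BREAST_CANCER, Sex.MALE): "breast_male",
    (Phenotype.OVARIAN_CANCER, Sex.FEMALE): "ovarian",
}


def phenotype_likelihood(
    member: PedigreeMember, carrier: bool, model: PenetranceModel
) -> float:
    """Probability of the member's phenotype data given carrier status.

    Affected members contribute the probability of a first diagnosis in their
    bracket (survive all modelled cancers to the bracket start, then a
    cause-specific event within the bracket).  Unaffected members contribute
    survival to their censoring age.  Cancers other than breast/ovarian censor
    at the diagnosis age.  Ovarian cases diagnosed at 20-29 borrow the 30-39
    bracket penetrance.
    """
    if member.phenotype in (Phenotype.BREAST_CANCER, Phenotype.OVARIAN_CANCER):
        cancer_type = _PHENOTYPE_TO_CANCER.get((member.phenotype, member.sex))
        if cancer_type is None or cancer_type not in model.baseline:
            warnings.warn(
                f"member {member.member_id}: no penetrance model for "
                f"{member.phenotype.value}/{member.sex.value}; treated as uninformative",
                stacklevel=2,
            )
            return 1.0
        age = member.age_diagnosis
        if age is None:
            age = DEFAULT_DIAGNOSIS_AGE
        if age < 0:
            raise ValueError("negative diagnosis age")
        idx = model.bracket_index(age)
        event_idx = idx
        if member.phenotype == Phenotype.OVARIAN_CANCER and 20.0 <= age < 30.0:
            event_idx = model.bracket_index(30.0)
        start = model.bracket_starts[idx]
        surv = model.survival(member.sex, start, carrier)
        # competing-risks attribution within the bracket: the diagnosed cancer
        # uses the (possibly borrowed) event-bracket hazard, other modelled
        # cancers compete at the bracket's own hazard
        hazards = {ct: model.hazard(ct, idx, carrier) for ct in model.cancer_types_for(member.sex)}
        hazards[cancer_type] = model.hazard(cancer_type, event_idx, carrier)
        h_total = sum(hazards.values())
        if h_total <= 0.0:
            return 0.0
        width = model.bracket_width(idx)
        return (
            surv
            * (hazards[cancer_type] / h_total)
            * (1.0 - math.exp(-h_total * width))
        )

    if member.phenotype == Phenotype.OTHER:
        censor = member.age_diagnosis
        if censor is None:
            censor = effective_censoring_age(member)
    else:
        censor = effective_censoring_age(member)
    if censor is None:
        return 1.0
    if censor < 0:
        raise ValueError("negative censoring age")
    return model.survival(member.sex, censor, carrier)


# --- exact genotype elimination -------------------------------------------
# Genotype states are indexed 0 = carrier, 1 = noncarrier.

def _transmission_table() -> np.ndarray:
    """P(child genotype | father, mother) for the rare-dominant model."""
    t = np.empty((2, 2, 2))
    for gf, gm in itertools.product((0, 1), repeat=2):
        n_carrier_parents = (gf == 0) + (gm == 0)
        p_child_carrier = {0: 0.0, 1: 0.5, 2: 0.75}[n_carrier_parents]
        t[gf, gm, 0] = p_child_carrier
        t[gf, gm, 1] = 1.0 - p_child_carrier
    return t


_TRANSMISSION = _transmission_table()


class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, variables: tuple[str, ...], table: np.ndarray):
        self.vars = variables
        self.table = table


def _multiply(f1: _Factor, f2: _Factor) -> _Factor:
    merged = list(f1.vars) + [v for v in f2.vars if v not in f1.vars]
    shape1 = [2 if v in f1.vars else 1 for v in merged]
    shape2 = [2 if v in f2.vars else 1 for v in merged]
    a1 = f1.table.reshape([2] * len(f1.vars))
    a1 = np.transpose(a1, [f1.vars.index(v) for v in merged if v in f1.vars]) if f1.vars else a1
    a1 = a1.reshape(shape1)
    a2 = f2.table.reshape([2] * len(f2.vars))
    a2 = np.transpose(a2, [f2.vars.index(v) for v in merged if v in f2.vars]) if f2.vars else a2
    a2 = a2.reshape(shape2)
    return _Factor(tuple(merged), a1 * a2)


def _sum_out(f: _Factor, var: str) -> _Factor:
    axis = f.vars.index(var)
    table = f.table.sum(axis=axis)
    variables = tuple(v for v in f.vars if v != var)
    return _Factor(variables, table)


def _eliminate(factors: list[_Factor], variables: Sequence[str]) -> float:
    """Sum-product over all *variables* with a greedy min-degree order."""
    factors = list(factors)
    remaining = set(variables)
    while remaining:
        # pick the variable appearing in the fewest factors / smallest joint scope
        def cost(v: str) -> int:
            scope: set[str] = set()
            for f in factors:
                if v in f.vars:
                    scope.update(f.vars)
            return len(scope)

        var = min(remaining, key=cost)
        remaining.discard(var)
        involved = [f for f in factors if var in f.vars]
        others = [f for f in factors if var not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = _multiply(prod, f)
        others.append(_sum_out(prod, var))
        factors = others
    result = 1.0
    for f in factors:
        if f.vars:
            raise RuntimeError("unexpected free variable after elimination")
        result *= float(f.table)
    return result


def _pedigree_likelihood(
    pedigree: Pedigree,
    model: PenetranceModel,
    causal: bool,
    genotype_evidence: Optional[frozenset] = None,
) -> float:
    """Joint probability of phenotypes and clamped genotypes, others summed out.

    *genotype_evidence* restricts which members' observed genotypes are
    clamped; ``None`` clamps every genotyped member.
    """
    pi = model.carrier_probability
    factors: list[_Factor] = []
    for mid in pedigree.topological_order:
        m = pedigree.members[mid]
        if m.is_founder:
            factors.append(_Factor((mid,), np.array([pi, 1.0 - pi])))
        else:
            factors.append(_Factor((m.father_id, m.mother_id, mid), _TRANSMISSION.copy()))
        clamp = m.genotype != GenotypeCall.UNTYPED and (
            genotype_evidence is None or mid in genotype_evidence
        )
        if clamp:
            obs = np.array([1.0, 0.0]) if m.genotype == GenotypeCall.CARRIER else np.array([0.0, 1.0])
            factors.append(_Factor((mid,), obs))
        carrier_l = phenotype_likelihood(m, carrier=causal, model=model)
        noncarrier_l = phenotype_likelihood(m, carrier=False, model=model)
        factors.append(_Factor((mid,), np.array([carrier_l, noncarrier_l])))
    return _eliminate(factors, list(pedigree.members))


def family_segregation_lr(pedigree: Pedigree, model: PenetranceModel) -> float:
    """Co-segregation Bayes factor (causal vs neutral) for one family.

    Eligibility requires at least two genotyped members including the proband,
    and the proband must be a carrier.  The LR is the probability of the
    relatives' observed genotypes given every phenotype and the proband's
    carrier genotype, contrasted between hypotheses:

    ``LR = P(g_rel | phenotypes, g_pro; causal) / P(g_rel | phenotypes, g_pro;
    neutral)``.

    Conditioning on all phenotypes and on the index case's own data is the
    single-ascertainment correction for families recruited through an affected
    carrier proband; it makes a tested affected noncarrier relative count
    against pathogenicity and gives the LR unit expectation under the neutral
    hypothesis.
    """
    proband = pedigree.proband
    if proband.genotype != GenotypeCall.CARRIER:
        raise IneligibleFamilyError(
            f"family {pedigree.family_id} not eligible: proband is not a genotyped carrier"
        )
    if len(pedigree.genotyped) < 2:
        raise IneligibleFamilyError(
            f"family {pedigree.family_id} not eligible: fewer than two genotyped members"
        )
    proband_only = frozenset({proband.member_id})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        num = _pedigree_likelihood(pedigree, model, causal=True)
        den = _pedigree_likelihood(pedigree, model, causal=False)
        cond_num = _pedigree_likelihood(pedigree, model, causal=True, genotype_evidence=proband_only)
        cond_den = _pedigree_likelihood(pedigree, model, causal=False, genotype_evidence=proband_only)
    if den <= 0.0 or cond_den <= 0.0 or cond_num <= 0.0:
        raise PedigreeError(
            f"family {pedigree.family_id}: zero likelihood; genotype data inconsistent "
            "with the pedigree structure"
        )
    return (num / cond_num) / (den / cond_den)


def variant_segregation_lr(
    families: Sequence[Pedigree], model: PenetranceModel, skip_ineligible: bool = True
) -> float:
    """Product of per-family segregation LRs across families.

    Ineligible families are skipped (they contribute no evidence) when
    *skip_ineligible* is set; at least one family must be eligible.
    """
    product = 1.0
    n_eligible = 0
    for pedigree in families:
        try:
            product *= family_segregation_lr(pedigree, model)
        except IneligibleFamilyError:
            if not skip_ineligible:
                raise
            continue
        n_eligible += 1
    if n_eligible == 0:
        raise IneligibleFamilyError("no eligible family")
    return product
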