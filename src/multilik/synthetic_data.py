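"""Seeded generators for pedigrees, evidence cohorts and frequency tables.

Everything the analysis consumes can be produced here with known generating
parameters, so each pipeline stage is testable without external data.  All
generators draw from a single ``numpy`` Generator stream derived from the
config seed; identical configs produce identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evidence_components import (
    FOUNDER_POPULATIONS,
    OUTBRED_POPULATIONS,
    FrequencyCategory,
    FrequencyEntry,
    FrequencyTable,
)
from .segregation import (
    GenotypeCall,
    Pedigree,
    PedigreeMember,
    PenetranceModel,
    Phenotype,
    Sex,
)

__all__ = [
    "FamilyShape",
    "CohortConfig",
    "FrequencyConfig",
    "SimulationConfig",
    "default_simulation_penetrance",
    "simulate_pedigree",
    "simulate_pedigrees",
    "simulate_evidence_cohort",
    "crosstab_counts_from_cohort",
    "simulate_population_frequencies",
]


def default_simulation_penetrance() -> PenetranceModel:
    """Penetrance used by the simulators unless one is supplied.

    Hazards are deliberately elevated relative to any real cancer incidence so
    that ascertainment through an affected carrier proband is cheap to
    simulate; they are synthetic parameters, not published estimates.
    """
    return PenetranceModel(
        baseline={
            "breast_female": (0.001, 0.004, 0.008, 0.010, 0.010, 0.010, 0.010),
            "ovarian": (0.0002, 0.001, 0.002, 0.003, 0.003, 0.003, 0.003),
        },
        hazard_ratio={
            "breast_female": (5.0,) * 7,
            "ovarian": (5.0,) * 7,
        },
        allele_frequency=0.15,
    )


@dataclass(frozen=True)
class FamilyShape:
    """Family structure parameters: generations and sibship sizes."""

    generations: int = 3
    sibship_poisson_mean: float = 2.0  # sibship size is 1 + Poisson(mean)
    partner_probability: float = 0.6  # chance a child founds a sibship of their own

    def __post_init__(self) -> None:
        if self.generations not in (2, 3):
            raise ValueError("generations must be 2 or 3")
        if not 0.0 <= self.partner_probability <= 1.0:
            raise ValueError("partner_probability must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Evidence-cohort parameters for calibration experiments."""

    n_variants: int = 500
    pathogenic_fraction: float = 0.2
    categories: tuple[str, ...] = ("none", "partial", "complete")
    benign_probs: tuple[float, ...] = (0.8, 0.15, 0.05)
    pathogenic_probs: tuple[float, ...] = (0.05, 0.25, 0.7)
    classification_accuracy: float = 0.95
    pathogenic_log_lr: float = 4.0
    benign_log_lr: float = -4.0
    log_lr_sd: float = 1.0

    def __post_init__(self) -> None:
        for name, probs in (("benign_probs", self.benign_probs), ("pathogenic_probs", self.pathogenic_probs)):
            if len(probs) != len(self.categories):
                raise ValueError(f"{name} must have one entry per category")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if not 0.0 <= self.pathogenic_fraction <= 1.0:
            raise ValueError("pathogenic_fraction must lie in [0, 1]")
        if not 0.0 <= self.classification_accuracy <= 1.0:
            raise ValueError("classification_accuracy must lie in [0, 1]")


@dataclass(frozen=True)
class FrequencyConfig:
    """Per-population sample sizes and category mix for frequency tables."""

    n_variants: int = 50
    allele_numbers: tuple[tuple[str, int], ...] = (
        ("NFE", 118174),
        ("AFR", 23620),
        ("AMR", 35108),
        ("SAS", 30526),
        ("EAS", 19252),
        ("FIN", 25000),
        ("ASJ", 10000),
    )
    category_weights: tuple[float, ...] = (0.3, 0.2, 0.2, 0.2, 0.1)

    def __post_init__(self) -> None:
        if any(an <= 0 for _, an in self.allele_numbers):
            raise ValueError("allele numbers must be positive")
        if len(self.category_weights) != 5 or abs(sum(self.category_weights) - 1.0) > 1e-9:
            raise ValueError("category_weights must be 5 probabilities summing to 1")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_families: int = 1
    hypothesis: str = "neutral"  # or "causal"
    penetrance: PenetranceModel = field(default_factory=default_simulation_penetrance)
    family_shape: FamilyShape = field(default_factory=FamilyShape)
    genotyping_probability: float = 0.9
    max_resamples: int = 10_000
    cohort: CohortConfig = field(default_factory=CohortConfig)
    frequency: FrequencyConfig = field(default_factory=FrequencyConfig)

    def __post_init__(self) -> None:
        if self.hypothesis not in ("neutral", "causal"):
            raise ValueError("hypothesis must be 'neutral' or 'causal'")
        if not 0.0 <= self.genotyping_probability <= 1.0:
            raise ValueError("genotyping_probability must lie in [0, 1]")


# --- pedigrees -------------------------------------------------------------


@dataclass
class _ProtoMember:
    member_id: str
    sex: Sex
    father_id: Optional[str]
    mother_id: Optional[str]
    generation: int
    current_age: float


def _build_structure(rng: np.random.Generator, shape: FamilyShape) -> list[_ProtoMember]:
    members: list[_ProtoMember] = [
        _ProtoMember("F0", Sex.MALE, None, None, 0, float(rng.uniform(65, 90))),
        _ProtoMember("M0", Sex.FEMALE, None, None, 0, float(rng.uniform(65, 90))),
    ]
    n_children = 1 + int(rng.poisson(shape.sibship_poisson_mean))
    children: list[_ProtoMember] = []
    for i in range(n_children):
        sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
        child = _ProtoMember(f"C{i}", sex, "F0", "M0", 1, float(rng.uniform(40, 65)))
        members.append(child)
        children.append(child)
    # bias towards at least one female in the middle generation (proband pool)
    if not any(c.sex == Sex.FEMALE for c in children):
        children[0].sex = Sex.FEMALE
    if shape.generations >= 3:
        for i, child in enumerate(children):
            if rng.random() >= shape.partner_probability:
                continue
            spouse_sex = Sex.FEMALE if child.sex == Sex.MALE else Sex.MALE
            spouse = _ProtoMember(
                f"S{i}", spouse_sex, None, None, 1, float(rng.uniform(40, 65))
            )
            members.append(spouse)
            father = child if child.sex == Sex.MALE else spouse
            mother = child if child.sex == Sex.FEMALE else spouse
            for j in range(1 + int(rng.poisson(shape.sibship_poisson_mean))):
                sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
                members.append(
                    _ProtoMember(
                        f"G{i}_{j}",
                        sex,
                        father.member_id,
                        mother.member_id,
                        2,
                        float(rng.uniform(20, 40)),
                    )
                )
    return members


def _draw_genotypes(
    rng: np.random.Generator, members: list[_ProtoMember], carrier_probability: float
) -> dict[str, bool]:
    carrier: dict[str, bool] = {}
    for m in members:  # construction order is topological
        if m.father_id is None:
            carrier[m.member_id] = bool(rng.random() < carrier_probability)
        else:
            n = carrier[m.father_id] + carrier[m.mother_id]
            p = {0: 0.0, 1: 0.5, 2: 0.75}[n]
            carrier[m.member_id] = bool(rng.random() < p)
    return carrier


def _draw_phenotype(
    rng: np.random.Generator,
    member: _ProtoMember,
    is_carrier: bool,
    model: PenetranceModel,
    causal: bool,
) -> tuple[Phenotype, Optional[float], float]:
    """Simulate (phenotype, diagnosis age, censoring age) up to the current age."""
    use_carrier = causal and is_carrier
    types = model.cancer_types_for(member.sex)
    age = 0.0
    for i, start in enumerate(model.bracket_starts):
        if start >= member.current_age:
            break
        width = min(model.bracket_width(i), member.current_age - start)
        hazards = [model.hazard(ct, i, use_carrier) for ct in types]
        total = sum(hazards)
        if total <= 0:
            continue
        wait = rng.exponential(1.0 / total)
        if wait < width:
            cause = types[int(rng.choice(len(types), p=[h / total for h in hazards]))]
            phenotype = (
                Phenotype.OVARIAN_CANCER if cause == "ovarian" else Phenotype.BREAST_CANCER
            )
            return phenotype, start + wait, start + wait
    return Phenotype.UNAFFECTED, None, member.current_age


def simulate_pedigree(
    config: SimulationConfig,
    hypothesis: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> Pedigree:
    """Simulate one pedigree ascertained through an affected carrier proband.

    A proband slot is fixed in advance (a random female outside the founder
    generation) and genotypes/phenotypes are resampled until that member is an
    affected carrier, which keeps the simulated data distributed exactly as
    the segregation model's proband-conditioned likelihood assumes.
    """
    hypothesis = hypothesis or config.hypothesis
    causal = hypothesis == "causal"
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = config.penetrance
    structure = _build_structure(rng, config.family_shape)
    candidates = [m for m in structure if m.generation >= 1 and m.sex == Sex.FEMALE]
    proband_id = candidates[int(rng.integers(len(candidates)))].member_id

    for _ in range(config.max_resamples):
        carrier = _draw_genotypes(rng, structure, model.carrier_probability)
        phenotypes = {
            m.member_id: _draw_phenotype(rng, m, carrier[m.member_id], model, causal)
            for m in structure
        }
        phenotype, _, _ = phenotypes[proband_id]
        if carrier[proband_id] and phenotype != Phenotype.UNAFFECTED:
            break
    else:
        raise RuntimeError(
            f"no affected carrier proband after {config.max_resamples} resamples; "
            "check penetrance and allele frequency settings"
        )

    members = []
    for m in structure:
        phenotype, age_dx, censor_age = phenotypes[m.member_id]
        typed = m.member_id == proband_id or rng.random() < config.genotyping_probability
        genotype = (
            (GenotypeCall.CARRIER if carrier[m.member_id] else GenotypeCall.NONCARRIER)
            if typed
            else GenotypeCall.UNTYPED
        )
        members.append(
            PedigreeMember(
                member_id=m.member_id,
                sex=m.sex,
                father_id=m.father_id,
                mother_id=m.mother_id,
                genotype=genotype,
                proband=m.member_id == proband_id,
                phenotype=phenotype,
                age_diagnosis=age_dx,
                age_last_observed=None if phenotype != Phenotype.UNAFFECTED else censor_age,
            )
        )
    return Pedigree(family_id=f"SIM{config.seed}", members=members)


def simulate_pedigrees(config: SimulationConfig) -> list[Pedigree]:
    """Simulate ``config.n_families`` pedigrees from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(config.n_families):
        ped = simulate_pedigree(config, rng=rng)
        ped.family_id = f"SIM{config.seed}_{i}"
        out.append(ped)
    return out


# --- evidence cohorts ------------------------------------------------------


def simulate_evidence_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a cohort of variants with categories and component LRs.

    Returns a frame with one row per variant (truth label, evidence category,
    prior, and a single segregation-component LR drawn so that classification
    matches the truth label at roughly the configured accuracy) plus the truth
    labels as a Series.
    """
    c = config.cohort
    rng = np.random.default_rng(config.seed)
    is_path = rng.random(c.n_variants) < c.pathogenic_fraction
    categories = np.empty(c.n_variants, dtype=object)
    n_path = int(is_path.sum())
    categories[is_path] = rng.choice(c.categories, size=n_path, p=c.pathogenic_probs)
    categories[~is_path] = rng.choice(
        c.categories, size=c.n_variants - n_path, p=c.benign_probs
    )
    concordant = rng.random(c.n_variants) < c.classification_accuracy
    target_path = is_path == concordant
    mu = np.where(target_path, c.pathogenic_log_lr, c.benign_log_lr)
    log_lr = rng.normal(mu, c.log_lr_sd)
    prior = np.where(is_path, 0.81, 0.03)
    frame = pd.DataFrame(
        {
            "variant_id": [f"V{i:05d}" for i in range(c.n_variants)],
            "truth": np.where(is_path, "pathogenic", "benign"),
            "category": categories,
            "prior": prior,
            "component": "segregation",
            "lr": np.exp(log_lr),
        }
    )
    truth = frame.set_index("variant_id")["truth"]
    return frame, truth


def crosstab_counts_from_cohort(
    frame: pd.DataFrame, categories: Sequence[str]
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """(benign_counts, pathogenic_counts) per category from a cohort frame."""
    benign = []
    pathogenic = []
    for cat in categories:
        rows = frame[frame["category"] == cat]
        benign.append(int((rows["truth"] == "benign").sum()))
        pathogenic.append(int((rows["truth"] == "pathogenic").sum()))
    return tuple(benign), tuple(pathogenic)


# --- population frequencies -------------------------------------------------


def _frequency_for_category(
    rng: np.random.Generator,
    category: FrequencyCategory,
    allele_numbers: dict[str, int],
) -> FrequencyTable:
    entries = []
    outbred = [p for p in OUTBRED_POPULATIONS if p in allele_numbers]
    founder = [p for p in FOUNDER_POPULATIONS if p in allele_numbers]
    ac = {pop: 0 for pop in allele_numbers}
    if category == FrequencyCategory.SINGLE_OBSERVATION:
        ac[outbred[int(rng.integers(len(outbred)))]] = 1
    elif category == FrequencyCategory.EXCLUDED_NA:
        ac[founder[int(rng.integers(len(founder)))]] = 1
    elif category in (FrequencyCategory.LOW, FrequencyCategory.MID):
        pop = max(outbred, key=lambda p: allele_numbers[p])
        an = allele_numbers[pop]
        if category == FrequencyCategory.LOW:
            hi = max(int(1e-4 * an) - 1, 2)
            ac[pop] = int(rng.integers(2, hi + 1))
        else:
            lo = max(int(math.ceil(1e-4 * an)), 2)
            hi = max(int(0.01 * an) - 1, lo)
            ac[pop] = int(rng.integers(lo, hi + 1))
    for pop, an in allele_numbers.items():
        entries.append(FrequencyEntry(pop, ac[pop], an, cohort="combined"))
    return FrequencyTable(tuple(entries))


def simulate_population_frequencies(
    config: SimulationConfig,
) -> tuple[list[FrequencyTable], list[FrequencyCategory]]:
    """Simulate per-variant frequency tables covering all five categories.

    The first five variants receive one table per category (so every category
    is represented at any cohort size >= 5); the remainder draw categories
    from the configured weights.
    """
    f = config.frequency
    rng = np.random.default_rng(config.seed)
    allele_numbers = dict(f.allele_numbers)
    order = (
        FrequencyCategory.NOT_OBSERVED,
        FrequencyCategory.SINGLE_OBSERVATION,
        FrequencyCategory.LOW,
        FrequencyCategory.MID,
        FrequencyCategory.EXCLUDED_NA,
    )
    categories: list[FrequencyCategory] = []
    for i in range(f.n_variants):
        if i < len(order):
            categories.append(order[i])
        else:
            categories.append(order[int(rng.choice(5, p=f.category_weights))])
    tables = [_frequency_for_category(rng, cat, allele_numbers) for cat in categories]
    return tables, categories
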