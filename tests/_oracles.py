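"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's efficient implementations: genotype
sums are exhaustive enumerations and the profile likelihood is a grid search.
"""

from __future__ import annotations

import itertools
import math

from scipy import stats

from multilik.segregation import GenotypeCall, Pedigree, PenetranceModel, phenotype_likelihood

_TRANSMISSION = {0: 0.0, 1: 0.5, 2: 0.75}


def enumeration_segregation_lr(pedigree: Pedigree, model: PenetranceModel) -> float:
    """Family LR by exhaustive enumeration over genotype assignments.

    Computes P(relatives' genotypes | all phenotypes, proband genotype) under
    each hypothesis by enumerating the free genotype configurations of the
    joint and of the conditioning marginal.
    """
    pi = model.carrier_probability
    proband_id = pedigree.proband.member_id

    def joint_sum(causal: bool, clamped_ids) -> float:
        free = [m.member_id for m in pedigree.members.values() if m.member_id not in clamped_ids]
        total = 0.0
        for assignment in itertools.product((True, False), repeat=len(free)):
            carrier = dict(zip(free, assignment))
            for mid in clamped_ids:
                carrier[mid] = pedigree.members[mid].genotype == GenotypeCall.CARRIER
            prob = 1.0
            for m in pedigree.members.values():
                if m.is_founder:
                    prob *= pi if carrier[m.member_id] else 1.0 - pi
                else:
                    p_carrier = _TRANSMISSION[carrier[m.father_id] + carrier[m.mother_id]]
                    prob *= p_carrier if carrier[m.member_id] else 1.0 - p_carrier
                prob *= phenotype_likelihood(m, causal and carrier[m.member_id], model)
            total += prob
        return total

    genotyped = [
        m.member_id for m in pedigree.members.values() if m.genotype != GenotypeCall.UNTYPED
    ]
    numerator = joint_sum(True, genotyped) / joint_sum(True, [proband_id])
    denominator = joint_sum(False, genotyped) / joint_sum(False, [proband_id])
    return numerator / denominator


def grid_case_control_lr(
    case_carriers: int,
    n_cases: int,
    control_carriers: int,
    n_controls: int,
    assumed_rr: float,
    q_grid=None,
) -> float:
    """Profile-likelihood ratio by brute-force grid search over q."""
    if q_grid is None:
        q_grid = [i / 2_000_000 for i in range(1, 20001)]  # (0, 0.01]

    def loglik(q: float, rr: float) -> float:
        qc = rr * q / (1.0 - q + rr * q)
        return stats.binom.logpmf(case_carriers, n_cases, qc) + stats.binom.logpmf(
            control_carriers, n_controls, q
        )

    best_alt = max(loglik(q, assumed_rr) for q in q_grid)
    best_null = max(loglik(q, 1.0) for q in q_grid)
    return math.exp(best_alt - best_null)


def direct_cooccurrence_lr(n: int, k: int, theta_path: float, theta_neutral: float) -> float:
    """Ratio of binomial pmfs evaluated directly via scipy."""
    return float(
        stats.binom.pmf(k, n, theta_path) / stats.binom.pmf(k, n, theta_neutral)
    )
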