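import math
import warnings

import numpy as np
import pytest

from _oracles import enumeration_segregation_lr
from multilik.segregation import (
    GenotypeCall,
    IneligibleFamilyError,
    Pedigree,
    PedigreeError,
    PedigreeMember,
    PenetranceModel,
    Phenotype,
    Sex,
    Surgery,
    SurgeryType,
    effective_censoring_age,
    family_segregation_lr,
    phenotype_likelihood,
    variant_segregation_lr,
)
from multilik.synthetic_data import (
    SimulationConfig,
    default_simulation_penetrance,
    simulate_pedigree,
)


class TestEffectiveCensoringAge:
    def test_surgery_precedes_last_observation(self):
        member = PedigreeMember(
            "a",
            Sex.FEMALE,
            age_last_observed=60.0,
            surgeries=(Surgery(SurgeryType.OOPHORECTOMY, 42.0),),
        )
        assert effective_censoring_age(member) == 42.0

    def test_last_observed_only(self):
        member = PedigreeMember("a", Sex.FEMALE, age_last_observed=55.0)
        assert effective_censoring_age(member) == 55.0

    def test_test_date_fallback(self):
        member = PedigreeMember("a", Sex.FEMALE, test_date_inferred_age=48.0)
        assert effective_censoring_age(member) == 48.0

    def test_no_usable_age_warns_and_returns_none(self):
        member = PedigreeMember("a", Sex.FEMALE)
        with pytest.warns(UserWarning, match="no usable censoring age"):
            assert effective_censoring_age(member) is None


class TestPhenotypeLikelihood:
    def test_zero_hazards_degenerate(self):
        model = PenetranceModel(
            baseline={"breast_female": (0.0,) * 7},
            hazard_ratio={"breast_female": (1.0,) * 7},
        )
        unaffected = PedigreeMember("a", Sex.FEMALE, age_last_observed=50.0)
        affected = PedigreeMember(
            "b", Sex.FEMALE, phenotype=Phenotype.BREAST_CANCER, age_diagnosis=45.0
        )
        assert phenotype_likelihood(unaffected, False, model) == 1.0
        assert phenotype_likelihood(affected, False, model) == 0.0

    def test_hazard_ratio_one_null_model(self, default_penetrance):
        model = PenetranceModel(
            baseline=default_penetrance.baseline,
            hazard_ratio={k: (1.0,) * 7 for k in default_penetrance.hazard_ratio},
            allele_frequency=default_penetrance.allele_frequency,
        )
        members = [
            PedigreeMember("a", Sex.FEMALE, age_last_observed=61.5),
            PedigreeMember("b", Sex.FEMALE, phenotype=Phenotype.BREAST_CANCER, age_diagnosis=37.0),
            PedigreeMember("c", Sex.FEMALE, phenotype=Phenotype.OVARIAN_CANCER, age_diagnosis=55.0),
            PedigreeMember("d", Sex.MALE, phenotype=Phenotype.BREAST_CANCER, age_diagnosis=66.0),
        ]
        for member in members:
            assert phenotype_likelihood(member, True, model) == pytest.approx(
                phenotype_likelihood(member, False, model)
            )

    def test_constant_hazard_survival_closed_form(self):
        model = PenetranceModel(
            baseline={"breast_female": (0.01,) * 7},
            hazard_ratio={"breast_female": (1.0,) * 7},
        )
        member = PedigreeMember("a", Sex.FEMALE, age_last_observed=50.0)
        assert phenotype_likelihood(member, False, model) == pytest.approx(math.exp(-0.5))

    def test_ovarian_twenties_borrows_next_bracket(self):
        model = PenetranceModel(
            baseline={"ovarian": (0.0, 0.02, 0.0, 0.0, 0.0, 0.0, 0.0)},
            hazard_ratio={"ovarian": (1.0,) * 7},
        )
        member = PedigreeMember(
            "a", Sex.FEMALE, phenotype=Phenotype.OVARIAN_CANCER, age_diagnosis=25.0
        )
        # survives the empty <30 bracket, then the 30-39 hazard applies over
        # the 30-year bracket width
        assert phenotype_likelihood(member, False, model) == pytest.approx(
            1.0 - math.exp(-0.02 * 30.0)
        )

    def test_other_cancer_censors_at_diagnosis(self, simple_penetrance):
        other = PedigreeMember(
            "a", Sex.FEMALE, phenotype=Phenotype.OTHER, age_diagnosis=40.0
        )
        unaffected = PedigreeMember("b", Sex.FEMALE, age_last_observed=40.0)
        assert phenotype_likelihood(other, True, simple_penetrance) == pytest.approx(
            phenotype_likelihood(unaffected, True, simple_penetrance)
        )

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            PedigreeMember("a", Sex.FEMALE, age_last_observed=-1.0)


class TestPedigreeValidation:
    def test_single_parent_rejected(self):
        with pytest.raises(ValueError, match="both parents"):
            PedigreeMember("kid", Sex.FEMALE, father_id="dad", mother_id=None)

    def test_unknown_parent_rejected(self):
        with pytest.raises(PedigreeError, match="unknown parent"):
            Pedigree(
                "F",
                [PedigreeMember("kid", Sex.FEMALE, father_id="dad", mother_id="mum")],
            )

    def test_consanguineous_loop_rejected(self):
        members = [
            PedigreeMember("gf", Sex.MALE),
            PedigreeMember("gm", Sex.FEMALE),
            PedigreeMember("a", Sex.MALE, father_id="gf", mother_id="gm"),
            PedigreeMember("b", Sex.FEMALE, father_id="gf", mother_id="gm"),
            PedigreeMember("kid", Sex.FEMALE, father_id="a", mother_id="b"),
        ]
        with pytest.raises(PedigreeError, match="consanguineous"):
            Pedigree("F", members)


class TestFamilySegregationLr:
    def test_only_proband_genotyped_excluded(self, trio_pedigree, simple_penetrance):
        members = []
        for m in trio_pedigree.members.values():
            if not m.proband:
                m.genotype = GenotypeCall.UNTYPED
            members.append(m)
        pedigree = Pedigree("F", members)
        with pytest.raises(IneligibleFamilyError, match="not eligible"):
            family_segregation_lr(pedigree, simple_penetrance)

    def test_affected_noncarrier_relative_is_evidence_against(self, simple_penetrance):
        pedigree = Pedigree(
            "F",
            [
                PedigreeMember("dad", Sex.MALE),
                PedigreeMember("mum", Sex.FEMALE),
                PedigreeMember(
                    "pro",
                    Sex.FEMALE,
                    father_id="dad",
                    mother_id="mum",
                    genotype=GenotypeCall.CARRIER,
                    proband=True,
                    phenotype=Phenotype.BREAST_CANCER,
                    age_diagnosis=42.0,
                ),
                PedigreeMember(
                    "sis",
                    Sex.FEMALE,
                    father_id="dad",
                    mother_id="mum",
                    genotype=GenotypeCall.NONCARRIER,
                    phenotype=Phenotype.BREAST_CANCER,
                    age_diagnosis=40.0,
                ),
            ],
        )
        assert family_segregation_lr(pedigree, simple_penetrance) < 1.0

    def test_affected_carrier_relative_is_evidence_for(self, trio_pedigree, simple_penetrance):
        assert family_segregation_lr(trio_pedigree, simple_penetrance) > 1.0

    def test_matches_enumeration_on_trio(self, trio_pedigree, simple_penetrance):
        lr = family_segregation_lr(trio_pedigree, simple_penetrance)
        oracle = enumeration_segregation_lr(trio_pedigree, simple_penetrance)
        assert lr == pytest.approx(oracle, rel=1e-12)

    def test_matches_enumeration_on_simulated_pedigrees(self, default_penetrance):
        model = default_simulation_penetrance()
        compared = 0
        for seed in range(40):
            config = SimulationConfig(seed=seed, genotyping_probability=0.5)
            pedigree = simulate_pedigree(config)
            untyped = sum(
                1 for m in pedigree.members.values() if m.genotype == GenotypeCall.UNTYPED
            )
            if len(pedigree.genotyped) < 2 or untyped > 10 or len(pedigree) > 12:
                continue
            lr = family_segregation_lr(pedigree, model)
            oracle = enumeration_segregation_lr(pedigree, model)
            assert lr == pytest.approx(oracle, rel=1e-10)
            compared += 1
        assert compared >= 20

    def test_hazard_ratio_one_gives_unit_lr(self, trio_pedigree, simple_penetrance):
        flat = PenetranceModel(
            baseline=simple_penetrance.baseline,
            hazard_ratio={"breast_female": (1.0,) * 7},
            allele_frequency=simple_penetrance.allele_frequency,
        )
        assert family_segregation_lr(trio_pedigree, flat) == 1.0


class TestVariantSegregationLr:
    def test_single_family_identity(self, trio_pedigree, simple_penetrance):
        lr = family_segregation_lr(trio_pedigree, simple_penetrance)
        assert variant_segregation_lr([trio_pedigree], simple_penetrance) == pytest.approx(lr)

    def test_product_across_families(self, trio_pedigree, simple_penetrance):
        lr = family_segregation_lr(trio_pedigree, simple_penetrance)
        combined = variant_segregation_lr(
            [trio_pedigree, trio_pedigree], simple_penetrance
        )
        assert combined == pytest.approx(lr * lr)

    def test_no_eligible_family_errors(self, simple_penetrance):
        pedigree = Pedigree(
            "F",
            [
                PedigreeMember("dad", Sex.MALE),
                PedigreeMember("mum", Sex.FEMALE),
                PedigreeMember(
                    "pro",
                    Sex.FEMALE,
                    father_id="dad",
                    mother_id="mum",
                    genotype=GenotypeCall.CARRIER,
                    proband=True,
                    phenotype=Phenotype.BREAST_CANCER,
                    age_diagnosis=42.0,
                ),
            ],
        )
        with pytest.raises(IneligibleFamilyError):
            variant_segregation_lr([pedigree], simple_penetrance)


class TestNeutralCalibration:
    def test_short_martingale(self):
        # a light version of the full neutral-mean check in the acceptance
        # suite: 800 families, 4 standard errors
        model = default_simulation_penetrance()
        values = []
        from multilik.synthetic_data import simulate_pedigrees

        config = SimulationConfig(seed=11, n_families=800)
        for pedigree in simulate_pedigrees(config):
            try:
                values.append(family_segregation_lr(pedigree, model))
            except IneligibleFamilyError:
                continue
        values = np.asarray(values)
        se = values.std(ddof=1) / math.sqrt(len(values))
        assert abs(values.mean() - 1.0) < 4 * se
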