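import pytest

from multilik.io_cli import (
    load_default_component_tables,
    load_default_crosstabs,
    load_default_penetrance,
    load_reference_classifications,
)
from multilik.segregation import (
    GenotypeCall,
    Pedigree,
    PedigreeMember,
    PenetranceModel,
    Phenotype,
    Sex,
)


@pytest.fixture(scope="session")
def reference_frame():
    return load_reference_classifications()


@pytest.fixture(scope="session")
def crosstabs():
    return load_default_crosstabs()


@pytest.fixture(scope="session")
def component_tables():
    return load_default_component_tables()


@pytest.fixture(scope="session")
def default_penetrance():
    return load_default_penetrance()


@pytest.fixture()
def simple_penetrance():
    """Single-cancer model with age-graded hazards, convenient for hand checks."""
    return PenetranceModel(
        baseline={"breast_female": (0.0001, 0.001, 0.005, 0.01, 0.01, 0.01, 0.01)},
        hazard_ratio={"breast_female": (5.0,) * 7},
        allele_frequency=0.1,
    )


@pytest.fixture()
def trio_pedigree():
    """Proband (affected carrier) with mother and an affected sister."""
    return Pedigree(
        "FAM1",
        [
            PedigreeMember("dad", Sex.MALE, age_last_observed=70.0),
            PedigreeMember("mum", Sex.FEMALE, age_last_observed=68.0),
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
                genotype=GenotypeCall.CARRIER,
                phenotype=Phenotype.BREAST_CANCER,
                age_diagnosis=45.0,
            ),
        ],
    )
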