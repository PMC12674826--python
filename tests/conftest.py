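import warnings

import numpy as np
import pytest

from appwt import synthetic as syn
from appwt.data_model import apply_exclusions
from appwt.fitting import PopulationFit
from appwt.structural import IndividualParameters

warnings.filterwarnings("ignore", message=".*overflow.*")
warnings.filterwarnings("ignore", message=".*invalid value.*")


DEFAULT_IND = {
    "L0": 30.0, "SLP": 0.004, "PMAX": 10.0, "Kp": 0.04,
    "WT0": 70.0, "Kin": 0.9, "Imax": 0.35, "IC50": 40.0,
}


def make_individual(**overrides) -> IndividualParameters:
    d = dict(DEFAULT_IND)
    d.update(overrides)
    return IndividualParameters.from_dict(d)


@pytest.fixture(scope="session")
def chemo_pop():
    return syn.chemotherapy_population()


@pytest.fixture(scope="session")
def recovering_pop():
    return syn.recovering_population()


@pytest.fixture(scope="session")
def chemo_cohort_small():
    cohort, _ = apply_exclusions(syn.generate_cohort("chemotherapy", 40, seed=101))
    return cohort


@pytest.fixture(scope="session")
def chemo_truth_fit():
    """Ground-truth 'fit': generator parameters + true individual parameters."""
    cohort, truth = syn.generate_cohort("chemotherapy", 400, seed=7,
                                        return_truth=True)
    cohort, _ = apply_exclusions(cohort)
    ebes = {s.subject_id: truth[s.subject_id] for s in cohort.subjects}
    covs = {s.subject_id: s.covariates for s in cohort.subjects}
    fit = PopulationFit.from_truth(syn.chemotherapy_population(), ebes,
                                   covariates=covs, label="chemotherapy")
    return fit, cohort


TOY_CSV = """ID,TIME,DVID,DV,SEX,ECOG,SMOKING,AGE,OS_MONTHS,OS_EVENT
A,0,appetite,42.5,male,1,current,64,11.5,1
A,21,appetite,47.0,male,1,current,64,11.5,1
A,0,weight,71.25,male,1,current,64,11.5,1
A,21,weight,70.8,male,1,current,64,11.5,1
B,0,appetite,18.0,female,0,never,55,24.0,0
B,14,appetite,15.5,female,0,never,55,24.0,0
B,0,weight,58.1,female,0,never,55,24.0,0
C,0,appetite,60.0,male,2,former,71,5.2,1
C,0,weight,80.0,male,2,former,71,5.2,1
"""


@pytest.fixture()
def toy_csv(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(TOY_CSV)
    return path
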