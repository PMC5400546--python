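import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from psakit.cohort import Cohort, Institution, PatientRecord, RaceCode, RaceEthnicity
from psakit.derivatives import add_derivatives
from psakit.simulate import generate_cohort, preset

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


def make_record(
    id="p1",
    age=60.0,
    race_ethnicity=RaceEthnicity.NHW,
    race_code=RaceCode.WHITE,
    institution=Institution.JHU,
    surname="SMITH",
    height=1.75,
    weight=80.0,
    psa=4.4,
    prostate_weight=44.9,
    tumor_volume=0.37,
    tumor_grid_mm2=None,
):
    return PatientRecord(
        id=id,
        age=age,
        race_ethnicity=race_ethnicity,
        race_code=race_code,
        institution=institution,
        surname=surname,
        height=height,
        weight=weight,
        psa=psa,
        prostate_weight=prostate_weight,
        tumor_volume=tumor_volume,
        tumor_grid_mm2=tumor_grid_mm2,
    )


@pytest.fixture
def small_cohort():
    return Cohort(
        records=[
            make_record(id="a", psa=4.4, prostate_weight=44.9, tumor_volume=0.37),
            make_record(id="b", psa=6.0, prostate_weight=60.0, tumor_volume=0.8,
                        race_ethnicity=RaceEthnicity.NHB, race_code=RaceCode.BLACK),
            make_record(id="c", psa=2.8, prostate_weight=40.0, tumor_volume=0.1,
                        race_ethnicity=RaceEthnicity.HISPANIC_LATINO, surname="GARCIA",
                        institution=Institution.UM),
        ],
        provenance="unit-test",
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the published group sizes (589 records)."""
    return generate_cohort(preset("table1_default"), seed=0)


@pytest.fixture(scope="session")
def derived_frame(default_cohort):
    return add_derivatives(default_cohort.to_frame())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
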