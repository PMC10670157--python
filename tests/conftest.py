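import pytest

from extcontrol import (
    AnalysisSet,
    CovariateProfile,
    LOTRecord,
    fixture_missingness_pattern,
    impute_metastases,
)


def make_profile(**overrides) -> CovariateProfile:
    base = dict(
        ecog=0,
        prior_lines="1",
        brain_met=False,
        liver_met=False,
        bone_met=True,
        lymph_met=False,
        adrenal_met=False,
        pleural_met=False,
        other_met=True,
        age_cat="lt65",
    )
    base.update(overrides)
    return CovariateProfile(**base)


def make_record(patient_id="P1", cohort="RWPC", lot_seq=1, profile=None, **overrides) -> LOTRecord:
    base = dict(
        patient_id=patient_id,
        cohort=cohort,
        lot_seq=lot_seq,
        covariates=profile or make_profile(),
        egfr_tested_before=True,
        prior_platinum=True,
        contains_amivantamab=cohort == "TRIAL",
        response="non_responder",
        pfs_days=100,
        pfs_event=True,
        ttnt_days=120,
        ttnt_event=True,
        os_days=300,
        os_event=False,
    )
    base.update(overrides)
    return LOTRecord(**base)


@pytest.fixture
def mk_record():
    return make_record


@pytest.fixture
def mk_profile():
    return make_profile


@pytest.fixture(scope="session")
def study_fixture() -> AnalysisSet:
    """Deterministic 114-trial + 55-control-LOT set with the chart-review
    missingness layout."""
    return fixture_missingness_pattern()


@pytest.fixture(scope="session")
def imputed_fixture(study_fixture):
    imputed, audit = impute_metastases(study_fixture)
    return imputed, audit
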