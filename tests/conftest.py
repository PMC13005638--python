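import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from adhera import (
    apply_eligibility,
    generate_cohort,
    series_matrix,
    summarize_cohort,
)
from adhera.simulate import gbtm_recovery_config

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

RECOVERY_SEED = 20260921 % 2**16  # fixed seed of the packaged recovery cohort


def make_patient(pid="P1", start="2019-01-01", end="2022-01-01"):
    return {
        "patient_id": pid,
        "birth_year": 1960,
        "sex": "female",
        "enrollment_start": pd.Timestamp(start),
        "enrollment_end": pd.Timestamp(end),
        "smoking_status": "never",
    }


def make_dispensing(pid="P1", drug="mepolizumab", date="2020-01-01", **kw):
    row = {
        "patient_id": pid,
        "drug_code": drug,
        "dispense_date": pd.Timestamp(date),
        "days_supplied": 0,
        "quantity": 1.0,
        "cost": 1000.0,
        "is_biologic": drug
        in {"benralizumab", "dupilumab", "mepolizumab", "omalizumab", "tezepelumab"},
        "steroid_compound": "none",
    }
    row.update(kw)
    return row


def make_diagnosis(pid="P1", code="asthma", date="2019-12-01"):
    return {"patient_id": pid, "code": code, "diagnosis_date": pd.Timestamp(date)}


def make_encounter(pid="P1", etype="ed_visit", start="2020-02-01", end=None,
                   asthma=True, planned=False):
    return {
        "patient_id": pid,
        "encounter_type": etype,
        "start_date": pd.Timestamp(start),
        "end_date": pd.Timestamp(end or start),
        "asthma_related": asthma,
        "planned": planned,
    }


def build_bundle(patients=None, dispensings=None, diagnoses=None, encounters=None):
    from adhera.io import TABLE_COLUMNS, ClaimsBundle, empty_bundle

    empty = empty_bundle()

    def frame(rows, name):
        if not rows:
            return empty.table(name)
        return pd.DataFrame(rows, columns=TABLE_COLUMNS[name])

    return ClaimsBundle(
        patients=frame(patients, "patients"),
        dispensings=frame(dispensings, "dispensings"),
        diagnoses=frame(diagnoses, "diagnoses"),
        encounters=frame(encounters, "encounters"),
    )


def eligible_patient_rows(pid="P1", index="2020-01-01", biologic="mepolizumab"):
    """Minimal records that pass every eligibility criterion."""
    index = pd.Timestamp(index)
    patients = [make_patient(pid, start=index - pd.Timedelta(days=60),
                             end=index + pd.Timedelta(days=400))]
    dispensings = [
        make_dispensing(pid, "ics_laba", index - pd.Timedelta(days=20),
                        days_supplied=30, is_biologic=False),
        make_dispensing(pid, biologic, index),
    ]
    diagnoses = [make_diagnosis(pid, "asthma", index - pd.Timedelta(days=10))]
    return patients, dispensings, diagnoses


@pytest.fixture(scope="session")
def recovery_cohort():
    """The packaged 7-archetype synthetic cohort plus downstream products."""
    bundle, truth = generate_cohort(
        gbtm_recovery_config(n_patients=2500, seed=RECOVERY_SEED), with_truth=True
    )
    result = apply_eligibility(bundle)
    summaries = summarize_cohort(bundle, result.gbtm_set)
    return {
        "bundle": bundle,
        "truth": truth,
        "result": result,
        "summaries": summaries,
        "y": series_matrix(summaries),
        "mpr": np.array([s.mpr for s in summaries]),
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A small no-switch cohort for cheap cross-module tests."""
    bundle, truth = generate_cohort(
        gbtm_recovery_config(n_patients=250, seed=77), with_truth=True
    )
    result = apply_eligibility(bundle)
    summaries = summarize_cohort(bundle, result.mpr_set)
    return {"bundle": bundle, "truth": truth, "result": result, "summaries": summaries}
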