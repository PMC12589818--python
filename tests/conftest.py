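import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from psqakit import GammaCriterion, PSQARecord

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

C33 = GammaCriterion(3, 3)
C22 = GammaCriterion(2, 2)


def make_record(
    key="P00001",
    facility="UniversityHospital",
    site="Pelvis",
    qa_date=dt.date(2020, 1, 1),
    g33=99.0,
    g22=None,
    dose_diff=None,
    machine="Clinac iX",
    device="ArcCHECK",
):
    gamma = {C33: g33}
    if g22 is not None:
        gamma[C22] = g22
    return PSQARecord(
        patient_key=key,
        facility=facility,
        machine=machine,
        qa_device=device,
        site=site,
        qa_date=qa_date,
        gamma_pass=gamma,
        dose_diff_pct=dose_diff,
    )


@pytest.fixture
def small_cohort():
    """Five records, two of them Pelvis, spread over five consecutive days."""
    sites = ["Pelvis", "CNS", "Pelvis", "Chest", "HeadNeck"]
    return [
        make_record(
            key=f"P{i:05d}",
            site=s,
            qa_date=dt.date(2020, 1, 1) + dt.timedelta(days=i),
            g33=99.0 - 0.2 * i,
            dose_diff=0.1 * i,
        )
        for i, s in enumerate(sites)
    ]
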