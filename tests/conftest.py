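import dataclasses

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

from sriloc.cohort_model import (  # noqa: E402
    CorrectionGroup,
    LesionRecord,
    Modality,
    TreatmentPlan,
    VolumeTimeSeries,
)


@pytest.fixture
def base_record():
    """A plain SRS-treated melanoma lesion; tweak via dataclasses.replace."""
    return LesionRecord(
        lesion_id="L1",
        patient_id="P1",
        correction_group=CorrectionGroup.CORRECTED_2D,
        histology="melanoma",
        baseline_volume_cm3=0.5,
        mri_to_treatment_days=9,
        planning_mri_year=2010,
        plans=(TreatmentPlan(Modality.SRS, 1, 18.0, 9),),
        last_followup_day=365,
    )


@pytest.fixture
def make_series():
    def _make(days, volumes, lesion_id="L1"):
        return VolumeTimeSeries(lesion_id, tuple(days), tuple(volumes))

    return _make


@pytest.fixture
def replace():
    return dataclasses.replace
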