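import numpy as np
import pytest

from platformtrial.trial_data import ArmSpec, PatientRecord


@pytest.fixture
def arms():
    return [
        ArmSpec("control", is_control=True),
        ArmSpec("experimental", is_control=False),
    ]


@pytest.fixture
def make_patient():
    """Factory for quick patient records with sensible defaults."""

    counter = {"n": 0}

    def _make(**kw):
        counter["n"] += 1
        defaults = dict(
            patient_id=f"T{counter['n']:04d}",
            rand_day=0,
            arm_id="control",
            hr=False,
            her2=False,
            mp2=False,
            received_treatment=True,
            pcr=0,
        )
        defaults.update(kw)
        defaults.setdefault("surgery_day", defaults["rand_day"] + 165)
        return PatientRecord(**defaults)

    return _make


@pytest.fixture
def twelve_patient_fixture(make_patient):
    """Small deterministic cohort exercising every model feature: both arms,
    several subtypes, old and recent calendar bins, one pending outcome and
    FTV series for the imputation submodel."""
    specs = [
        # (rand_day, arm, hr, her2, mp2, pcr, ftv_pair)
        (900, "control", False, False, False, 1, (30.0, 3.0)),
        (850, "control", True, False, False, 0, (12.0, 8.0)),
        (700, "control", True, True, True, 0, None),
        (600, "experimental", False, False, True, 1, (25.0, 1.5)),
        (500, "experimental", True, False, False, 0, (18.0, 14.0)),
        (400, "control", False, True, False, 1, (40.0, 5.0)),
        (300, "experimental", False, False, False, 1, (22.0, 2.0)),
        (250, "control", True, False, True, 0, (9.0, 7.5)),
        (200, "experimental", True, True, False, 0, (15.0, 12.0)),
        (150, "control", False, False, True, 0, None),
        (100, "experimental", False, False, False, 1, (28.0, 2.5)),
        (60, "experimental", True, False, False, None, (20.0, 6.0)),  # pending
    ]
    patients = []
    for i, (day, arm, hr, her2, mp2, pcr, ftv) in enumerate(specs):
        series = ()
        if ftv is not None:
            series = ((day, ftv[0]), (day + 84, ftv[1]))
        patients.append(
            PatientRecord(
                patient_id=f"F{i:02d}",
                rand_day=day,
                arm_id=arm,
                hr=hr,
                her2=her2,
                mp2=mp2,
                surgery_day=None if pcr is None else day + 165,
                pcr=pcr,
                ftv=series,
            )
        )
    return patients


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
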