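import numpy as np
import pytest

from glucotrig import (
    MetabolicSample,
    VisitRecord,
    default_reference_config,
    reference_meal,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def ref_meal():
    return reference_meal()


@pytest.fixture(scope="session")
def small_cohort():
    """10 subjects x 3 visits, default reference calibration, fixed seed."""
    return simulate_cohort(default_reference_config(seed=1234))


def make_visit(ins0, tg0, ins180, tg180, sid="S001", visit=1, glu0=None, glu180=None):
    return VisitRecord(
        subject_id=sid,
        visit=visit,
        baseline=MetabolicSample(0, insulin=ins0, triglycerides=tg0, glucose=glu0),
        postprandial=MetabolicSample(180, insulin=ins180, triglycerides=tg180, glucose=glu180),
    )
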