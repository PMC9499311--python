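import numpy as np
import pytest

from repairkinetics import KJMAParams, RepairTimeCourse, repair_fraction

STANDARD_TIMES = np.array([20.0, 60.0, 120.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20220912)


def noiseless_course(m, tau, theta, times=STANDARD_TIMES, region_id=""):
    """Exact repair fractions of a KJMA process at the sampled times."""
    p = KJMAParams(m=m, tau=tau, theta=theta)
    return RepairTimeCourse(
        times=np.asarray(times, float),
        values=repair_fraction(p, np.asarray(times, float)),
        region_id=region_id,
    )


@pytest.fixture
def course_factory():
    return noiseless_course
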