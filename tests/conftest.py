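import numpy as np
import pytest

from focaldx.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_synthetic():
    """One default synthetic cohort shared across tests (seed 0)."""
    return generate_cohort(SyntheticConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_reading(**kw):
    """ScanReading with sensible defaults for terse test construction."""
    from focaldx.cohort import ScanReading

    base = dict(
        patient_id="P1",
        tracer="DOPA",
        reader_id="R1",
        timepoint_min=10.0,
        suv_max_lesion=6.0,
        suv_max_reference=4.0,
        reference_region="pancreas_body",
        visual_call="focal",
        visual_location="head",
    )
    base.update(kw)
    return ScanReading(**base)
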