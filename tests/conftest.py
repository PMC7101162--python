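import numpy as np
import pytest

from coccomix import (
    FieldSampleSpec,
    LmRecord,
    MorphotypeSpec,
    SemRecord,
)


@pytest.fixture
def sem_records():
    return [
        SemRecord("s1", "A", 3.36, 2.79, 0.24, 0.22),
        SemRecord("s1", "B", 3.18, 2.66),
        SemRecord("s1", "M", 2.77, 2.23),
        SemRecord("s2", "OA", 3.00, 2.51),
    ]


@pytest.fixture
def lm_records():
    return [
        LmRecord("s1", 3.1, 2.0, 0.124, "overcalcified"),
        LmRecord("s1", 3.2, 2.4, 0.126, "open"),
        LmRecord("s2", 3.4, 2.7, 0.133),
    ]


def make_separated_field_spec() -> FieldSampleSpec:
    """Two well-separated morphotypes: an easy deconvolution target."""
    return FieldSampleSpec(
        sample_id="sep",
        morphotypes={
            "A": MorphotypeSpec(0.70, 3.36, 0.25, 1.21, 0.130, 0.015,
                                ct_l_mean=0.07, ct_l_sd=0.01),
            "B": MorphotypeSpec(0.30, 3.00, 0.25, 1.20, 0.080, 0.015),
        },
        n_coccoliths=400,
        cell_density=20000.0,
    )


@pytest.fixture
def separated_field_spec():
    return make_separated_field_spec()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
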