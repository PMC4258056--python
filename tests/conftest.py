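import io

import numpy as np
import pytest

import funrep as fr


@pytest.fixture()
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture()
def generic3_table():
    """Small unresolved hit table with ambiguous reads."""
    text = io.StringIO(
        "r1\tK00001\t40.0\n"
        "r1\tK00002\t55.0\n"
        "r2\tK00002\t50.0\n"
        "r2\tK00001\t50.0\n"
        "r3\tK00003\t12.5\n"
    )
    return fr.parse_hit_table(text, dialect="generic3", sample_id="s1")


@pytest.fixture()
def small_reference():
    universe = frozenset(f"K{i:05d}" for i in range(1, 31))
    positives = frozenset(f"K{i:05d}" for i in range(1, 11))
    return fr.AnnotationReference(positives=positives, universe=universe)
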