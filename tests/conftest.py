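import numpy as np
import pytest

from addinter import (
    SubjectRecord,
    Variable,
    VariableCodebook,
    default_codebook,
    load_published_tables,
)


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def published():
    return load_published_tables()


@pytest.fixture(scope="session")
def binary_codebook():
    """Codebook for cohorts that carry only already-binary exposures."""
    identity = {"0": 0, "1": 1}
    variables = [
        Variable("hypertension", ("0", "1"), identity, "outcome"),
        Variable("sex", ("male", "female"), None, "matching"),
        Variable("e1", ("0", "1"), identity),
        Variable("e2", ("0", "1"), identity),
    ]
    return VariableCodebook({v.name: v for v in variables})


def make_record(sid, is_case, **exposures):
    return SubjectRecord(
        subject_id=str(sid),
        is_case=is_case,
        sex="male",
        age=50,
        exposures={k: (None if v is None else str(v)) for k, v in exposures.items()},
    )


def records_from_fourfold(a, b, c, d, variable="e1"):
    """Expand 2x2 counts into subject records with a binary-coded exposure."""
    records = []
    i = 0
    for is_case, value, n in ((True, 1, a), (False, 1, b), (True, 0, c), (False, 0, d)):
        for _ in range(int(n)):
            records.append(make_record(f"s{i}", is_case, **{variable: value}))
            i += 1
    return records


def records_from_joint(counts, v1="e1", v2="e2"):
    """Expand 2x2x2 counts {(e1,e2): (cases, controls)} into subject records."""
    records = []
    i = 0
    for (e1, e2), (n_case, n_ctrl) in counts.items():
        for is_case, n in ((True, n_case), (False, n_ctrl)):
            for _ in range(int(n)):
                records.append(make_record(f"s{i}", is_case, **{v1: e1, v2: e2}))
                i += 1
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
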