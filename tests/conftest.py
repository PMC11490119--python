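from __future__ import annotations

import numpy as np
import pytest

from sinekit import synthgen


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The standard end-to-end scenario: 100 kb genome, 20 implants,
    mock hit table (25% dropout) and mock family alignments."""
    workdir = tmp_path_factory.mktemp("fixture")
    return synthgen.build_fixture(workdir, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
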