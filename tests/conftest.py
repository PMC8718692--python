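import numpy as np
import pandas as pd
import pytest

from m6ascore import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic cohort shared across tests (seed 0)."""
    return generate(GeneratorConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_expression(tmp_path):
    """A 3x2 expression TSV on disk."""
    path = tmp_path / "toy.tsv"
    path.write_text("gene\ts1\ts2\nG1\t1.0\t4.0\nG2\t2.0\t5.0\nG3\t3.0\t6.0\n")
    return path
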