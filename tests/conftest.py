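import numpy as np
import pytest

from ghknn.features_188d import PropertyGroupTable, default_tables


@pytest.fixture(scope="session")
def tables():
    return default_tables()


@pytest.fixture
def toy_table():
    """g1={A}, g2={R}, g3=everything else."""
    rest = frozenset("CDEFGHIKLMNPQSTVWY")
    return PropertyGroupTable("toy", (frozenset("A"), frozenset("R"), rest))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(text, name="seqs.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path
    return _write
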