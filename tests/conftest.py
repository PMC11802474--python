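import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seqscope.config import QCConfig
from seqscope.fixtures import LibrarySpec, generate_single_end

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def cfg():
    return QCConfig()


@pytest.fixture(scope="session")
def small_library():
    """2000 plain 150 bp reads with the two-state quality model."""
    return generate_single_end(LibrarySpec(n_reads=2000, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(seq, quals=None, name="r", comment=""):
    from seqscope.records import SeqRecord

    if quals is None:
        quals = np.full(len(seq), 30, dtype=np.uint8)
    return SeqRecord(name=name, comment=comment, sequence=seq, qualities=quals)
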