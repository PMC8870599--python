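import numpy as np
import pytest

from collatmut import Genome, MutationRecord


@pytest.fixture(scope="session")
def toy_genome():
    """Deterministic 50 kb random genome (GC 0.5) for context/motif tests."""
    rng = np.random.default_rng(123)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=50_000)])
    return Genome.from_dict({"chr1": seq})


def sbs(sample, pos, ref="C", alt="A", chrom="chr1", **metrics):
    return MutationRecord(sample, chrom, pos, ref, alt, metrics=dict(metrics))


@pytest.fixture
def make_sbs():
    return sbs
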