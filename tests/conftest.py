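import numpy as np
import pytest

from cpgmpra import MotifAnnotation, PromoterRecord, SimulationConfig, Simulator


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def simulator():
    return Simulator(SimulationConfig(seed=7))


def random_dna(rng, length, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


@pytest.fixture
def annotated_promoter(rng):
    """A CpG-rich promoter with one bound and one unbound motif."""
    seq = random_dna(rng, 400, gc=0.6)
    return PromoterRecord(
        id="promX",
        sequence=seq,
        tss_offset=300,
        motif_annotations=[
            MotifAnnotation(tf="GABPA", start=100, end=111, bound=True),
            MotifAnnotation(tf="SP1", start=200, end=210, bound=False),
        ],
    )
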