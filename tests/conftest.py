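import numpy as np
import pytest

from circbench.circ_simulator import CircularTemplate, build_circular_template
from circbench.io_formats import CircRNARecord, GenomeSequence, TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    """One 300-bp chromosome with a fixed pseudo-random sequence."""
    r = np.random.default_rng(99)
    seq = "".join("ACGT"[i] for i in r.integers(0, 4, size=300))
    return {"chr1": seq}


@pytest.fixture
def toy_transcript():
    """Two-exon transcript: exons (0,10) and (20,30) on the + strand."""
    return TranscriptModel(
        gene_id="g1",
        transcript_id="t1",
        chrom="chr1",
        strand="+",
        exons=((0, 10), (20, 30)),
    )


def make_template(circ_id: str, length: int, seed: int = 0) -> CircularTemplate:
    """A standalone circular template with a random sequence of given spliced length."""
    r = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in r.integers(0, 4, size=length))
    return CircularTemplate(
        circ_id=circ_id, chrom="chrT", start=0, end=length, strand="+", sequence=seq
    )


@pytest.fixture
def template_factory():
    return make_template
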