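import numpy as np
import pytest

from mitovar import AlignedRead, Reference


@pytest.fixture
def ref16() -> Reference:
    """16 bp toy contig for hand-countable examples."""
    return Reference(name="chrM", sequence="ACGTACGTACGTACGT")


@pytest.fixture
def ref_repeat() -> Reference:
    """Homopolymer-bearing contig for left-alignment cases."""
    return Reference(name="chrM", sequence="ATTTTCGGGCATCATCAAA")


def make_read(
    pos: int,
    bases: str,
    qual: int = 30,
    cigar: str | None = None,
    name: str = "read1",
    reverse: bool = False,
    mapq: int = 60,
) -> AlignedRead:
    return AlignedRead(
        name=name,
        pos=pos,
        cigar=cigar or f"{len(bases)}M",
        bases=bases,
        quals=np.full(len(bases), qual, dtype=np.uint8),
        mapq=mapq,
        reverse_strand=reverse,
    )


@pytest.fixture
def mk_read():
    return make_read
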