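import pytest

from ktsquant import AlignedReadRecord, JunctionSpec


@pytest.fixture
def spec():
    """Plus-strand junction spec: canonical donor at 1000, +9 nt alternative
    donor, acceptor at 2000."""
    return JunctionSpec(chrom="chr2", strand="+", donor_minus=1000, acceptor=2000)


@pytest.fixture
def spec_minus():
    """Minus-strand mirror: donor (first intronic base in transcription
    direction) at 2000, acceptor at 1000."""
    return JunctionSpec(chrom="chr2", strand="-", donor_minus=2000, acceptor=1000)


def make_read(
    start,
    blocks,
    chrom="chr2",
    strand="+",
    mapq=60,
    cell="CELL1",
    umi=None,
    read_id="r1",
):
    return AlignedReadRecord(
        read_id=read_id,
        cell=cell,
        umi=umi,
        chrom=chrom,
        strand=strand,
        start=start,
        blocks=tuple(blocks),
        mapq=mapq,
    )


@pytest.fixture
def gapped_read():
    return make_read
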