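import numpy as np
import pytest

from svase.pipeline import call_svase
from svase.readqc import AlignedRead
from svase.simdata import SimConfig, simulate, to_aligned_reads


def make_read(
    read_id="r1",
    chrom="chr1",
    pos=0,
    cigar=(("M", 50),),
    seq=None,
    quals=None,
    mapq=60,
    flag=0,
    nm=0,
):
    """Build an AlignedRead with sensible defaults for unit tests."""
    qlen = sum(n for op, n in cigar if op in "MIS=X")
    if seq is None:
        seq = "A" * qlen
    if quals is None:
        quals = (40,) * len(seq)
    read = AlignedRead(
        read_id=read_id,
        chrom=chrom,
        pos=pos,
        cigar=tuple(cigar),
        seq=seq,
        base_quals=tuple(quals),
        mapq=mapq,
        flag=flag,
        mismatch_count=nm,
    )
    read.mask = np.zeros(len(seq), dtype=bool)
    return read


@pytest.fixture(scope="session")
def tiny_sim():
    """A small but complete dataset: 20 junctions, 5 private plants."""
    return simulate(SimConfig(seed=11, chrom_len=120_000, n_junctions=20, n_variants=5))


@pytest.fixture(scope="session")
def tiny_result(tiny_sim):
    return call_svase(tiny_sim.genome, to_aligned_reads(tiny_sim))
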