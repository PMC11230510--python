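import numpy as np
import pytest

from kataegion.formats_io import Epoch, SnvRecord, SvRecord, SvType


def make_snv(pos, ref="C", alt="T", chrom="chr1", sample="S0", epoch=Epoch.UNKNOWN,
             phase=None, ctx=None):
    return SnvRecord(sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
                     epoch=epoch, phase_group=phase, tricontext=ctx)


def make_sv(pos1, pos2, sv_type=SvType.DEL, chrom1="chr1", chrom2=None, sample="S0"):
    chrom2 = chrom2 or chrom1
    size = abs(pos2 - pos1) if chrom1 == chrom2 else None
    return SvRecord(sample_id=sample, chrom1=chrom1, pos1=pos1, chrom2=chrom2,
                    pos2=pos2, sv_type=sv_type, size_bp=size)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cluster_snvs():
    """6 tightly spaced C>T SNVs inside sparse flanks on one chromosome."""
    positions = [5_000_000 + 100 * i for i in range(6)]
    flanks = [1_000_000, 9_000_000]
    return [make_snv(p) for p in sorted(flanks + positions)]
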