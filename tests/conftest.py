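import numpy as np
import pytest

from seduplex import ErrorDistribution, random_panel
from seduplex.umi import TaggedRead, UmiFamily


@pytest.fixture(scope="session")
def panel():
    return random_panel(n_loci=3, target_length=80, seed=11)


@pytest.fixture(scope="session")
def null_model():
    """Background error model at the magnitude of the dominant type (5e-5)."""
    return ErrorDistribution(beta_alpha=2.0, beta_beta=39998.0)


def make_read(
    base: str,
    site: int = 100,
    start: int = 90,
    length: int = 30,
    qual: int = 40,
    mq: int = 60,
    mismatches: int = 0,
    read_id: str = "r",
    umi: str = "A" * 12,
    strand: str = "TOP",
    ref_seq: str | None = None,
) -> TaggedRead:
    """A read spanning [start, start+length) showing ``base`` at ``site``."""
    off = site - start
    fill = ref_seq[start : start + length] if ref_seq else "A" * length
    seq = fill[:off] + base + fill[off + 1 :]
    return TaggedRead(
        read_id=read_id,
        umi=umi,
        strand_label=strand,
        locus_id="L000",
        chrom="chrSim",
        frag_pos=start,
        start=start,
        seq=seq,
        quals=[qual] * length,
        mapping_quality=mq,
        mismatch_count=mismatches,
    )


def make_family(
    bases: list[str],
    site: int = 100,
    umi: str = "A" * 12,
    strand: str = "TOP",
    frag_pos: int = 90,
    quals: list[int] | None = None,
    mqs: list[int] | None = None,
    mismatches: list[int] | None = None,
) -> UmiFamily:
    fam = UmiFamily("S1", "L000", frag_pos, umi, strand)
    for i, b in enumerate(bases):
        fam.reads.append(
            make_read(
                b,
                site=site,
                start=frag_pos,
                qual=quals[i] if quals else 40,
                mq=mqs[i] if mqs else 60,
                mismatches=mismatches[i] if mismatches else 0,
                read_id=f"r{i}",
                umi=umi,
                strand=strand,
            )
        )
    return fam


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
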