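import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None, database=None)
settings.load_profile("repro")

from epishift import synthgen
from epishift.intervals import GeneModel, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cfg():
    """A compact simulation shared by generator round-trip tests."""
    return synthgen.SimConfig(seed=11, genome=(("chr1", 1_800_000),), n_genes=150)


@pytest.fixture(scope="session")
def small_sim(small_cfg, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    truth = synthgen.simulate_all(small_cfg, outdir)
    return {"cfg": small_cfg, "outdir": outdir, "truth": truth}


@pytest.fixture
def three_exon_gene():
    return GeneModel(
        gene_id="GX",
        chrom="chr1",
        strand="+",
        tx_start=10_000,
        tx_end=16_000,
        exons=((10_000, 11_000), (12_000, 13_000), (14_000, 16_000)),
        utr5=(10_000, 10_200),
        utr3=(15_700, 16_000),
    )


def iv(chrom, start, end, payload=None):
    return GenomicInterval(chrom, start, end, payload=payload)
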