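import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pemave.design import DesignParams, design_library
from pemave.gene import GeneContext
from pemave.pipeline import prepare_records
from pemave.simulate import SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_rng(seed=0):
    return np.random.default_rng(seed)


@pytest.fixture(scope="session")
def tiny_ctx():
    """A 120-bp single-exon plus-strand gene, fully coding, no internal
    stops (built from repeats of non-stop-adjacent codons plus planted
    features used across tests)."""
    # 40 codons; ATG start, TAA stop at the end; interior free of stops
    codons = (
        ["ATG"]
        + ["GCT", "CTG", "TGG", "AAA", "GAA", "TCA", "TAC", "CGG", "ACC"] * 4
        + ["GCA", "TAA"]
    )
    seq = "".join(codons)
    assert len(seq) == 3 * len(codons)
    return GeneContext(
        contig_id="tiny",
        sequence=seq,
        gene_symbol="TINY1",
        transcript_id="NM_TINY1.1",
        strand="+",
        exons=((0, len(seq)),),
        cds=((0, len(seq)),),
    )


@pytest.fixture(scope="session")
def minus_ctx():
    """Same coding content as a plus-strand gene but placed on the minus
    strand of the contig."""
    codons = ["ATG"] + ["TGG", "GAA", "TCA", "TAC", "CTG"] * 6 + ["TAA"]
    cds = "".join(codons)
    from pemave.gene import revcomp

    pad5, pad3 = "GATTACAGATTACA", "ACGTACGTACGTAC"
    seq = pad5 + revcomp(cds) + pad3
    start = len(pad5)
    return GeneContext(
        contig_id="tinyrev",
        sequence=seq,
        gene_symbol="TINYREV",
        transcript_id="NM_TINYREV.1",
        strand="-",
        exons=((start, start + len(cds)),),
        cds=((start, start + len(cds)),),
    )


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def synthetic_study(sim_config, tmp_path_factory):
    """Locus + classified records generated once for the whole session."""
    workdir = tmp_path_factory.mktemp("locus")
    locus, records = prepare_records(sim_config, workdir)
    return locus, records


@pytest.fixture(scope="session")
def synthetic_library(synthetic_study):
    locus, records = synthetic_study
    return design_library(
        locus.ctx, records, params=DesignParams(), strategy="vus", n_target=2
    )
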