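import warnings

import pytest

from chromlink.annotation import GeneModel
from chromlink.intervals import GenomicInterval
from chromlink.pipeline import simulate_and_run
from chromlink.simulate import TruthConfig


@pytest.fixture(scope="session")
def closed_loop(tmp_path_factory):
    """Full closed-loop run at the default study conditions (seed 0)."""
    cfg = TruthConfig(seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results, metrics = simulate_and_run(
            cfg, tmp_path_factory.mktemp("closed_loop")
        )
    return cfg, results, metrics


@pytest.fixture(scope="session")
def small_loop(tmp_path_factory):
    """A reduced closed-loop run for pipeline smoke checks."""
    cfg = TruthConfig(
        seed=11, n_genes=120,
        chrom_sizes={"chr1": 5_000_000, "chr2": 5_000_000,
                     "chrX": 2_000_000},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results, metrics = simulate_and_run(
            cfg, tmp_path_factory.mktemp("small_loop")
        )
    return cfg, results, metrics


@pytest.fixture
def toy_genes():
    """Three genes on one 100 kb chromosome, mixed strands, with UTRs."""
    g1 = GeneModel(
        "gA", "chr1", "+",
        exons=[GenomicInterval("chr1", 10_000, 10_500, "+"),
               GenomicInterval("chr1", 12_000, 13_000, "+")],
        utrs=[GenomicInterval("chr1", 10_000, 10_100, "+")],
    )
    g2 = GeneModel(
        "gB", "chr1", "-",
        exons=[GenomicInterval("chr1", 30_000, 31_000, "-"),
               GenomicInterval("chr1", 34_000, 35_000, "-")],
    )
    # gC's promoter overlaps gA's second exon region end
    g3 = GeneModel(
        "gC", "chr1", "+",
        exons=[GenomicInterval("chr1", 12_900, 14_000, "+")],
    )
    return [g1, g2, g3]


@pytest.fixture
def toy_chrom_sizes():
    return {"chr1": 100_000}
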