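import numpy as np
import pytest

from tfimpact.io_formats import GeneModel, GenomeAnnotation, Peak, PeakSet
from tfimpact.synthetic_data import SimulationConfig, simulate_all

# small fast fixture used by most synthetic/pipeline tests
SMALL_SIM = dict(
    n_genes=120,
    chrom_length=6_000_000,
    n_tfs=3,
    n_target_genes=30,
    background_peaks_per_tf=300,
    n_categories=10,
)


@pytest.fixture
def tiny_annotation():
    return GenomeAnnotation(
        genes=[
            GeneModel("gA", "chr1", "+", 10_000),
            GeneModel("gB", "chr1", "-", 60_000),
            GeneModel("gC", "chr2", "+", 5_000),
        ]
    )


def make_peak(chrom, start, end, summit=None, q=0.5, score=1.0):
    return Peak(chrom=chrom, start=start, end=end, summit=summit, score=score, q_value=q)


@pytest.fixture
def make_peakset():
    def _make(intervals, chrom="chr1", tf="TF", rep="rep1", q=0.5):
        return PeakSet(
            tf_name=tf,
            replicate=rep,
            peaks=[make_peak(chrom, s, e, q=q) for s, e in intervals],
        )

    return _make


@pytest.fixture(scope="session")
def small_sim():
    return simulate_all(SimulationConfig(seed=11, **SMALL_SIM))


@pytest.fixture(scope="session")
def default_sim():
    """The spec's default fixture scale; session-scoped because it is reused."""
    return simulate_all(SimulationConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
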