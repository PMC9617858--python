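import numpy as np
import pytest

from chromoweave.genome import CoverageTrack, GenomeModel


@pytest.fixture
def genome():
    """Two-chromosome toy genome with one gap and one segdup on chr1."""
    return GenomeModel(
        chroms=[("chr1", 1_000_000), ("chr2", 500_000)],
        gaps={"chr1": [(100_000, 200_000)]},
        segdups={"chr1": [(500, 900)]},
    )


@pytest.fixture
def flat_coverage():
    """Mean-30 coverage with one high-coverage window on chr1."""
    cov1 = np.full(100, 30.0)
    cov2 = np.full(50, 30.0)
    return CoverageTrack(10_000, {"chr1": cov1, "chr2": cov2})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
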