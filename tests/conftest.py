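import pytest

from oligomux import GenomicInterval, MiningParams, mine_probes
from oligomux.fixtures import SyntheticGenomeSpec, make_genome


@pytest.fixture(scope="session")
def small_genome():
    """20-kb single-chromosome random genome, no repeats."""
    assembly, truth = make_genome(SyntheticGenomeSpec(lengths={"chr1": 20_000}, seed=1))
    return assembly


@pytest.fixture(scope="session")
def small_paint():
    return GenomicInterval("chr1", 0, 20_000)


@pytest.fixture(scope="session")
def mined_probes(small_genome, small_paint):
    return mine_probes(small_genome, small_paint, MiningParams())
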