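import numpy as np
import pytest

from tadakit.genome import GatcFragmentMap, GenomeIndex, build_fragment_map


@pytest.fixture
def toy_map() -> GatcFragmentMap:
    """Chromosome AAGATCAAGATCAA: GATC at 2 and 8, cuts at 4 and 10,
    fragments [0,4), [4,10), [10,14)."""
    return build_fragment_map({"chr1": "AAGATCAAGATCAA"})


@pytest.fixture
def uniform_map() -> GatcFragmentMap:
    """Synthetic map: 2 chromosomes x 500 fragments of 200 bp each."""
    genome = GenomeIndex.from_lengths({"chr1": 100_000, "chr2": 100_000})
    b = np.arange(501) * 200
    return GatcFragmentMap(genome, {"chr1": b, "chr2": b})


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
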