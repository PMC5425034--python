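import numpy as np
import pytest

import msatabc as m


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def truth_draw():
    """Canonical scenario-2 truth parameters for pseudo-observed data."""
    return m.WOLF_TRUTH_SCENARIO2


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated 3-population dataset at reduced locus count."""
    rng = np.random.default_rng(777)
    return m.simulate_dataset(
        m.SCENARIOS[2], m.WOLF_TRUTH_SCENARIO2, 12, [10, 8, 9], rng
    )


def toy_dataset(genotypes, pop_sizes, motif=2):
    """Build a MicrosatDataset from explicit allele-size genotypes.

    ``genotypes``: list over individuals of list over loci of (a, b) allele
    sizes in nucleotides.  Sizes must be multiples of nothing in
    particular; they are decomposed into (repeat, offset) canonically.
    """
    sizes = np.asarray(genotypes, dtype=np.int64)
    reps = sizes // motif
    offs = sizes - reps * motif
    pop_index = np.repeat(np.arange(len(pop_sizes)), pop_sizes)
    return m.MicrosatDataset(
        repeats=reps,
        offsets=offs,
        pop_index=pop_index,
        pop_names=tuple(f"P{i+1}" for i in range(len(pop_sizes))),
        motif_lengths=np.full(sizes.shape[1], motif, dtype=np.int64),
    )
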