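import numpy as np
import pytest

from ripscape import simulate


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic study shared across tests (fixed seed)."""
    return simulate.simulate_study(seed=1)


@pytest.fixture(scope="session")
def sim_blocks(default_sim):
    """Blocks called and classified on the shared synthetic genome."""
    from ripscape import atblocks, landscape

    genome = default_sim.genome
    summary = landscape.genome_summary(genome, [])
    thresholds = atblocks.BlockThresholds(genome_gc_mean=summary.gc_mean)
    blocks = []
    for seq in genome:
        blocks.extend(
            atblocks.call_at_blocks(landscape.gc_windows(seq), thresholds)
        )
    atblocks.classify_blocks(blocks, {s.id: s.length for s in genome})
    return blocks


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
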