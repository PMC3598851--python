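import numpy as np
import pytest

from bitphylo import simulate
from bitphylo.sequences import ProteinSequence, SequenceSet


@pytest.fixture
def small_family():
    """Hand-built 5-sequence family with two identical members."""
    core = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
    variant = core[:30] + "W" + core[31:]
    rng = np.random.default_rng(7)
    diverged = list(core)
    for pos in rng.choice(len(core), size=18, replace=False):
        diverged[pos] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
    return SequenceSet([
        ProteinSequence("dup1", core),
        ProteinSequence("dup2", core),
        ProteinSequence("var", variant),
        ProteinSequence("div", "".join(diverged)),
        ProteinSequence("tail", core[10:] + "GGSSGG"),
    ])


@pytest.fixture
def sim_family():
    """A 12-taxon simulated family with its reference tree."""
    config = simulate.SimulationConfig(n_taxa=12, length=300, seed=20260901)
    return simulate.simulate_family(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
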