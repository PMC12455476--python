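import numpy as np
import pytest

from condnet.forcefield import load_parameter_table
from condnet.sequences import ResidueSequence
from condnet.trajio import Configuration


@pytest.fixture(scope="session")
def model():
    return load_parameter_table()


@pytest.fixture(scope="session")
def y12():
    return ResidueSequence("Y12", "Y" * 12)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_configuration(rng, n_chains=4, n_beads=20, box=80.0, residues="YSGQ"):
    """Random multi-chain configuration with backbone-ordered beads (bond
    lengths near 3.81 Å, chains loosely collapsed)."""
    chains = []
    letters = []
    for _ in range(n_chains):
        start = rng.random(3) * box
        steps = rng.normal(size=(n_beads - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        pos = np.vstack([start, start + np.cumsum(3.81 * steps, axis=0)])
        chains.append(pos)
        letters.extend(rng.choice(list(residues), size=n_beads).tolist())
    return Configuration(
        box=np.full(3, box),
        positions=np.concatenate(chains),
        residues=np.array(letters),
        chain_ids=np.repeat(np.arange(n_chains), n_beads),
    )


@pytest.fixture()
def random_config(rng):
    return random_configuration(rng)
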