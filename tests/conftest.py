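import numpy as np
import pytest

import adaptiphy as ap


@pytest.fixture(scope="session")
def primate_tree():
    return ap.read_newick(ap.DEFAULT_PRIMATE_NEWICK)


@pytest.fixture(scope="session")
def sim_model():
    return ap.DEFAULT_SIM_MODEL


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def random_model(rng, family="HKY85"):
    """A random valid substitution model for property-style checks."""
    pi = rng.dirichlet(np.full(4, 5.0))
    if family == "HKY85":
        return ap.SubstModel("HKY85", pi=pi, kappa=float(rng.uniform(0.5, 8.0)))
    return ap.SubstModel(
        "GTR", pi=pi, kappa=None, rates=rng.uniform(0.2, 3.0, size=6)
    )


def random_alignment(rng, species, length, missing_prob=0.15):
    """Random (not tree-generated) alignment including missing data."""
    alphabet = np.array(list("ACGTN-"))
    probs = np.array([1, 1, 1, 1, 0, 0], dtype=float)
    probs[4] = probs[5] = 4 * missing_prob / (2 * (1 - missing_prob))
    probs /= probs.sum()
    seqs = [
        "".join(rng.choice(alphabet, p=probs, size=length)) for _ in species
    ]
    return ap.NucAlignment(list(species), seqs)
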