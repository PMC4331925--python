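import numpy as np
import pytest

from auxre.synthetic import generate_training_set


@pytest.fixture(scope="session")
def training_alignment():
    """25 core-centred 106-nt records with a planted 5' Y-patch octamer."""
    aln, truth = generate_training_set(
        planted_couplings=[("TCTCCTYT", "5p", 4)], seed=31
    )
    return aln, truth


@pytest.fixture(scope="session")
def plain_alignment():
    """25 core-centred records with purely random flanks."""
    aln, _ = generate_training_set(seed=32)
    return aln


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])
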