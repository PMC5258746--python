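import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_923)


def random_inframe_pair(rng, n_codons=30, p_mut=0.1):
    """A random in-frame sequence pair (stops allowed; downstream code must
    mask them) with per-base mutation probability p_mut."""
    bases = "ACGT"
    a = "".join(bases[i] for i in rng.integers(0, 4, size=3 * n_codons))
    b = list(a)
    for k in range(len(b)):
        if rng.random() < p_mut:
            b[k] = bases[(bases.index(b[k]) + rng.integers(1, 4)) % 4]
    return a, "".join(b)
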