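import numpy as np
import pytest

from tlsmut.spectra import GenomeRef


@pytest.fixture(scope="session")
def toy_genome() -> GenomeRef:
    """A 200 bp single-contig genome, fixed for hand-checkable contexts."""
    rng = np.random.default_rng(2024)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    return GenomeRef({"chr1": seq})


@pytest.fixture()
def rng() -> np.random.Generator:
    # function-scoped: every test sees the same fresh stream
    return np.random.default_rng(7)
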