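import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests.oracles

from paleomito.seq import CircularSequence


def random_genome(n: int, seed: int, gid: str = "toy", circular: bool = True) -> CircularSequence:
    rng = np.random.default_rng(seed)
    return CircularSequence(gid, "".join("ACGT"[i] for i in rng.integers(0, 4, n)), circular)


@pytest.fixture
def toy_genome():
    return random_genome(400, seed=7)


@pytest.fixture(scope="session")
def study_genomes():
    from paleomito.mitogenome import build_study_genomes

    return build_study_genomes(17)
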