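import random

import pytest

from zfndesign import HBG1_SEGMENT, build_gnn_archive
from zfndesign.archive import FingerModule, ModuleArchive


@pytest.fixture(scope="session")
def gnn_archive():
    return build_gnn_archive()


@pytest.fixture
def hbg1_segment():
    return HBG1_SEGMENT


def random_archive(rng: random.Random, n_two: int = 3, n_one: int = 2, degenerate: bool = True):
    """Small random archive for oracle comparisons: a few 1- and
    2-finger modules, occasionally degenerate or internally
    skip-capable."""
    bases = "ACGT"
    codes = "ACGTRYN"

    def triplet():
        alphabet = codes if degenerate and rng.random() < 0.3 else bases
        return "".join(rng.choice(alphabet) for _ in range(3))

    modules = []
    for i in range(n_one):
        modules.append(FingerModule(id=f"m1_{i}", n_fingers=1, triplets=(triplet(),)))
    for i in range(n_two):
        modules.append(
            FingerModule(
                id=f"m2_{i}",
                n_fingers=2,
                triplets=(triplet(), triplet()),
                skip_capable_internal=rng.random() < 0.5,
            )
        )
    return ModuleArchive(name="random", modules=modules)
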