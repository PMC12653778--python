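import numpy as np
import pandas as pd
import pytest

from markqg.pedigree import Pedigree


@pytest.fixture
def trio_pedigree():
    """Two unrelated founders and their offspring."""
    frame = pd.DataFrame(
        {"animal": ["A", "B", "C"], "sire": ["", "", "A"], "dam": ["", "", "B"]}
    )
    return Pedigree.from_frame(frame)


@pytest.fixture
def fullsib_pedigree():
    """Full-sib mating: E = C x D with C, D both A x B."""
    frame = pd.DataFrame(
        {
            "animal": list("ABCDE"),
            "sire": ["", "", "A", "A", "C"],
            "dam": ["", "", "B", "B", "D"],
        }
    )
    return Pedigree.from_frame(frame)


def random_pedigree(n, n_founders=20, seed=0, allow_selfing=False):
    """Random ordered pedigree; parents drawn uniformly from predecessors."""
    rng = np.random.default_rng(seed)
    sires, dams = [], []
    for i in range(n):
        if i < n_founders:
            sires.append("")
            dams.append("")
        else:
            s, d = rng.integers(0, i, 2)
            if not allow_selfing:
                while d == s:
                    d = rng.integers(0, i)
            sires.append(f"a{s}")
            dams.append(f"a{d}")
    frame = pd.DataFrame(
        {"animal": [f"a{i}" for i in range(n)], "sire": sires, "dam": dams}
    )
    return Pedigree.from_frame(frame)


@pytest.fixture
def random_pedigree_200():
    return random_pedigree(200, seed=7)
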