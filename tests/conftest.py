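import numpy as np
import pytest

import pwcda

#: Worked-example edge weights: (w1..w8) name the similarity/association
#: edges c1-c3, c1-c4, c1-c5, c3-d1, c4-d2, c5-d3, d1-d2, d3-d2.
WORKED_EXAMPLE_WEIGHTS = {
    ("c1", "c3"): 0.9,
    ("c1", "c4"): 0.8,
    ("c1", "c5"): 0.7,
    ("c3", "d1"): 0.9,
    ("c4", "d2"): 0.6,
    ("c5", "d3"): 0.8,
    ("d1", "d2"): 0.9,
    ("d3", "d2"): 0.7,
    ("c1", "c2"): 0.9,
    ("c2", "c5"): 0.9,
}


@pytest.fixture
def example_net() -> pwcda.HetNet:
    """The 5-circRNA / 3-disease worked-example topology (10 edges)."""
    circ = ["c1", "c2", "c3", "c4", "c5"]
    dis = ["d1", "d2", "d3"]
    cc = np.zeros((5, 5))
    dd = np.zeros((3, 3))
    cd = np.zeros((3, 5))
    for (a, b), w in WORKED_EXAMPLE_WEIGHTS.items():
        if a in circ and b in circ:
            i, j = circ.index(a), circ.index(b)
            cc[i, j] = cc[j, i] = w
        elif a in dis and b in dis:
            i, j = dis.index(a), dis.index(b)
            dd[i, j] = dd[j, i] = w
        else:
            cd[dis.index(b), circ.index(a)] = w
    return pwcda.HetNet(circ, dis, cc, dd, cd, stage="final")


@pytest.fixture(scope="session")
def default_dataset() -> pwcda.SyntheticDataset:
    """The default planted-block synthetic dataset (seed 7)."""
    return pwcda.generate()
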