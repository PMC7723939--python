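import numpy as np
import pandas as pd
import pytest

from reaxpot.network import (
    Compound,
    EnzymeDefinition,
    Pathway,
    Reaction,
    ReactionNetwork,
)
from reaxpot.preprocess import AbundanceMatrix


@pytest.fixture()
def toy_network() -> ReactionNetwork:
    """Hand-built five-reaction network with enzyme structure and pathways."""
    net = ReactionNetwork()
    for cid in ["C00001", "C00002", "C00003", "C00004", "C00005", "C00006", "C00007"]:
        net.compounds[cid] = Compound(cid)
    net.enzymes["E1"] = EnzymeDefinition("E1", (("G1", "G2"),))
    net.enzymes["E2"] = EnzymeDefinition("E2", (("G3",), ("G4", "G5")))
    net.enzymes["E3"] = EnzymeDefinition("E3", (("G6",),))
    net.reactions["R1"] = Reaction(
        "R1", (("C00001", 1), ("C00002", 1)), (("C00003", 1),), ("E1",), True
    )
    net.reactions["R2"] = Reaction(
        "R2", (("C00003", 2),), (("C00004", 1), ("C00005", 1)), ("E2",), True
    )
    net.reactions["R3"] = Reaction("R3", (("C00005", 1),), (("C00006", 2),), ("E3",), False)
    net.reactions["R4"] = Reaction("R4", (("C00006", 1),), (("C00007", 1),), (), True)
    net.reactions["R5"] = Reaction(
        "R5", (("C00001", 1),), (("C00007", 1),), ("E1", "E2"), True
    )
    net.pathways["P1"] = Pathway(
        "P1", "upper", frozenset({"C00001", "C00002", "C00003"}), frozenset({"R1", "R2"})
    )
    net.pathways["P2"] = Pathway(
        "P2", "lower", frozenset({"C00005", "C00006", "C00007"}), frozenset({"R3", "R4", "R5"})
    )
    return net


def make_matrix(values, features, samples=None, groups=None, state="raw"):
    values = np.asarray(values, dtype=float)
    if samples is None:
        samples = [f"ref_{i}" for i in range(1, values.shape[1] // 2 + 1)] + [
            f"test_{i}" for i in range(1, values.shape[1] - values.shape[1] // 2 + 1)
        ]
    if groups is None:
        groups = {s: ("reference" if s.startswith("ref") else "test") for s in samples}
    data = pd.DataFrame(values, index=features, columns=samples)
    return AbundanceMatrix(data=data, groups=groups, state=state)


@pytest.fixture()
def small_matrix():
    return make_matrix(
        [[2.0, 4.0, np.nan, 8.0], [1.0, 1.0, 1.0, 1.0], [0.0, np.nan, 5.0, 5.0]],
        ["M1", "M2", "M3"],
    )
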