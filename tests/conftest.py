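import numpy as np
import pytest

from hbnet import Config, FixtureSpec, make_fixture, protonate
from hbnet.fixtures import LIGANDS

#: every catalog scenario with its reference-ligand selector
SCENARIOS = [
    ("water_bridge", None, {"n": 2}),
    ("imidazole_carboxylate", "IMZ:L:1", {}),
    ("serine_rotor", None, {}),
    ("amine_transfer", "PIP:L:1", {}),
    ("donor_face", "PYR:L:1", {}),
    ("asn_flip", None, {}),
    ("histidine", None, {}),
    ("chain_break", None, {}),
]


@pytest.fixture(scope="session")
def config():
    return Config()


@pytest.fixture(scope="session")
def protonated_fixtures():
    """Protonation results for every pipeline scenario (computed once)."""
    out = {}
    for scen, lig, params in SCENARIOS:
        text = make_fixture(FixtureSpec(scen, params))
        out[scen] = protonate(text, ligand=lig)
    return out


def cys_pair_text():
    """Two cysteines whose SG atoms sit ~2.07 A apart (disulfide range)."""
    from hbnet.fixtures import pdb_text

    def cys(chain, resseq, transform):
        rows = [("N", "N", [0, 0, 0]), ("CA", "C", [1.46, 0, 0]),
                ("C", "C", [2.0, -1.4, 0]), ("O", "O", [3.2, -1.6, 0]),
                ("CB", "C", [2.0, 0.8, 1.2]), ("SG", "S", [1.6, 2.5, 1.2])]
        return [(n, "CYS", chain, resseq, e, transform(np.asarray(x, float)))
                for n, e, x in rows]

    rows = cys("A", 1, lambda x: x)
    mirror = np.array([1, -1, 1])
    shift = np.array([0.3, 7.05, 0.0])
    rows += cys("A", 5, lambda x: x * mirror + shift)
    return pdb_text(rows)
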