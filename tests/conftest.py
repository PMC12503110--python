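import pandas as pd
import pytest

from pleiolink.simulate import SimScenario, default_scenario, gen_counts
from pleiolink.structures import MutationSite, StructureModel


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=101)


@pytest.fixture(scope="session")
def counts_bundle(scenario):
    return gen_counts(scenario)


@pytest.fixture(scope="session")
def null_scenario():
    """Same design, no planted expression effects."""
    base = default_scenario(seed=202)
    return SimScenario(**{**vars(base), "planted_degs": {}})


def make_structure(points, structure_id="toy"):
    """Build an in-memory structure from (chain, resseq, resname, atom, xyz)."""
    rows = [(c, r, "", rn, an, "", float(p[0]), float(p[1]), float(p[2]))
            for c, r, rn, an, p in points]
    atoms = pd.DataFrame(rows, columns=["chain_id", "residue_seq", "icode",
                                        "residue_name", "atom_name", "altloc",
                                        "x", "y", "z"])
    return StructureModel(structure_id=structure_id, atoms=atoms)


@pytest.fixture
def toy_structure():
    """Site Cα at origin; partner Cα points at distances 5 and 10."""
    pts = [("B", 146, "VAL", "CA", (0, 0, 0)),
           ("C", 1, "ALA", "CA", (3, 4, 0)),
           ("C", 2, "ALA", "CA", (6, 8, 0))]
    return make_structure(pts)


@pytest.fixture
def toy_role_map():
    return {"toy": {"B": "beta", "C": "sigma"}}


@pytest.fixture
def toy_site():
    return MutationSite("V146F", 146, "V", "F")


def random_structure(rng, n_partner_atoms=100, roles=("sigma", "dna_nontemplate")):
    """Random multi-chain structure plus its role map, for oracle tests."""
    pts = [("B", 10, "VAL", "CA", rng.normal(0, 20, 3))]
    role_map = {"rand": {"B": "beta"}}
    for chain, role in zip("CD", roles):
        role_map["rand"][chain] = role
        resname = "ALA" if role == "sigma" else "DA"
        atom = "CA" if role == "sigma" else "C1'"
        for i in range(n_partner_atoms // len(roles)):
            pts.append((chain, i + 1, resname, atom, rng.normal(0, 20, 3)))
    return make_structure(pts, "rand"), role_map
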