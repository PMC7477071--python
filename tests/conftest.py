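import numpy as np
import pytest

from prscan.structure_io import CoarseStructure, ResidueNode
from prscan.synthetic import FixtureSpec, make_complex, make_unbound


def make_chain(coords, chain_id="A", res_name="ALA", start=1):
    """CoarseStructure from an (N, 3) array, one chain, contiguous numbering."""
    nodes = [
        ResidueNode(
            chain_id=chain_id,
            res_seq=start + k,
            res_name=res_name,
            coord=tuple(float(x) for x in xyz),
        )
        for k, xyz in enumerate(np.asarray(coords, dtype=float))
    ]
    return CoarseStructure(nodes, label=f"chain {chain_id}")


def compact_cloud(n, seed=0, scale=4.0):
    """Random compact 3-D point cloud with no near-coincident points."""
    rng = np.random.default_rng(seed)
    while True:
        coords = rng.normal(scale=scale, size=(n, 3))
        from scipy.spatial.distance import pdist

        if pdist(coords).min() > 1.0:
            return coords


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.100   0.200  -0.300  1.00  0.00           C
ATOM      3  CA  GLY A   2       4.500   1.000   0.700  1.00  0.00           C
ATOM      4  CA  SER A   3       7.900   0.500   0.100  1.00  0.00           C
ATOM      5  CA  LEU B   1       3.000   9.000   2.000  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture(scope="session")
def fixture_complex():
    """Deterministic 60-residue two-chain synthetic complex."""
    return make_complex(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def planted_pair(fixture_complex):
    """Complex, unbound chain A, and the planted ground truth (seed 1)."""
    spec = FixtureSpec(seed=1)
    unbound, truth = make_unbound(fixture_complex, "A", spec)
    return fixture_complex, unbound, truth
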