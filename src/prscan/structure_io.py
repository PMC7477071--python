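"""Read and write Cα-level coordinate data from PDB files.

Each residue is reduced to the position of its Cα atom.  A
:class:`CoarseStructure` is an ordered list of such nodes, selected by chain
(and optionally a residue range), and is the input to every downstream stage:
superposition, elastic-network construction and perturbation scanning.

Residues are indexed throughout by their author numbering (chain id,
residue number, insertion code), so results can be compared directly with
numbering used in structural databases and the literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

logger = logging.getLogger(__name__)

#: Three-letter codes of the 20 standard amino acids.
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass(frozen=True)
class ResidueNode:
    """One coarse-grained node: a residue represented by its Cα atom."""

    chain_id: str
    res_seq: int
    res_name: str
    coord: tuple[float, float, float]
    ins_code: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        """Author-numbering identity of the residue."""
        return (self.chain_id, self.res_seq, self.ins_code)

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AA

    def __str__(self) -> str:  # e.g. "G292:A"
        one = _THREE_TO_ONE.get(self.res_name, "X")
        return f"{one}{self.res_seq}{self.ins_code}:{self.chain_id}"


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def three_to_one(res_name: str) -> str:
    """Map a three-letter residue code to its one-letter code ('X' if unknown)."""
    return _THREE_TO_ONE.get(res_name.upper(), "X")


def one_to_three(code: str) -> str:
    return _ONE_TO_THREE[code.upper()]


@dataclass
class CoarseStructure:
    """Ordered Cα node list for a complex or a single protein."""

    nodes: list[ResidueNode]
    label: str = ""

    def __post_init__(self) -> None:
        keys = [n.key for n in self.nodes]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate residue keys in {self.label!r}")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of Cα coordinates in Å."""
        return np.array([n.coord for n in self.nodes], dtype=float)

    @property
    def chain_ids(self) -> np.ndarray:
        return np.array([n.chain_id for n in self.nodes])

    @property
    def keys(self) -> list[tuple[str, int, str]]:
        return [n.key for n in self.nodes]

    def index_of(self, key: tuple[str, int, str]) -> int:
        return self.keys.index(key)

    def subset(self, indices) -> "CoarseStructure":
        """New structure keeping ``indices`` (order preserved)."""
        return CoarseStructure(
            [self.nodes[i] for i in indices], label=self.label
        )

    def chain_indices(self, chains) -> np.ndarray:
        """Indices of all nodes whose chain id is in ``chains``."""
        chains = set(chains)
        return np.array(
            [i for i, node in enumerate(self.nodes) if node.chain_id in chains],
            dtype=int,
        )


@dataclass
class ResidueMatch:
    """One-to-one pairing of common residues between two structures.

    ``pairs[k] = (i, j)`` pairs node *i* of the first (bound) structure with
    node *j* of the second (unbound) one; only paired residues take part in
    superposition and scoring.
    """

    pairs: list[tuple[int, int]]
    coverage: float
    name_mismatches: list[tuple[tuple[str, int, str], str, str]] = field(
        default_factory=list
    )

    @property
    def bound_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.pairs], dtype=int)

    @property
    def unbound_indices(self) -> np.ndarray:
        return np.array([j for _, j in self.pairs], dtype=int)


def parse_chain_spec(spec: str):
    """Parse a chain selection such as ``"A"``, ``"AB"`` or ``"A:16-245"``.

    Comma-separated items; each item is one chain id optionally followed by
    ``:start-end`` (inclusive author numbering).  Returns a list of
    ``(chain_id, (start, end) | None)``.
    """
    out = []
    for item in spec.split(","):
        item = item.strip()
        if not item:
            continue
        if ":" in item:
            chain, rng = item.split(":", 1)
            start_s, end_s = rng.split("-", 1)
            out.append((chain, (int(start_s), int(end_s))))
        elif len(item) > 1:
            # bare multi-letter item: several single-letter chains
            out.extend((c, None) for c in item)
        else:
            out.append((item, None))
    if not out:
        raise ValueError(f"empty chain spec: {spec!r}")
    return out


def read_calpha(
    path,
    chain_spec: str,
    include_hetero: bool = False,
    label: str | None = None,
) -> CoarseStructure:
    """Read the Cα nodes of the selected chains from a PDB file.

    Only the first model of multi-model (e.g. NMR) files is used.  Alternate
    locations are resolved to the highest-occupancy conformer.  Residues
    without a Cα atom are skipped with a warning.  By default only ATOM
    records are considered; ``include_hetero`` admits HETATM residues (such
    as selenomethionine) that carry a Cα.
    """
    selections = parse_chain_spec(chain_spec)
    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1, altloc="occupancy")

    nodes: list[ResidueNode] = []
    for chain, rng in selections:
        chain_mask = atoms.chain_id == chain
        if not include_hetero:
            chain_mask &= ~atoms.hetero
        if rng is not None:
            chain_mask &= (atoms.res_id >= rng[0]) & (atoms.res_id <= rng[1])
        sub = atoms[chain_mask]
        if sub.array_length() == 0:
            continue
        ca = sub[(sub.atom_name == "CA") & (sub.element == "C")]
        # report residues present in the selection but lacking a Cα
        all_res = set(zip(sub.res_id.tolist(), sub.ins_code.tolist()))
        ca_res = set(zip(ca.res_id.tolist(), ca.ins_code.tolist()))
        for res_id, ins in sorted(all_res - ca_res):
            name = sub.res_name[(sub.res_id == res_id) & (sub.ins_code == ins)][0]
            if name in STANDARD_AA or include_hetero:
                logger.warning(
                    "residue %s%s%s:%s has no Calpha atom; skipped",
                    name, res_id, ins, chain,
                )
        chain_nodes = [
            ResidueNode(
                chain_id=chain,
                res_seq=int(ca.res_id[k]),
                res_name=str(ca.res_name[k]),
                coord=tuple(float(x) for x in ca.coord[k]),
                ins_code=str(ca.ins_code[k]),
            )
            for k in range(ca.array_length())
        ]
        # author ordering: residue number ascending, insertion codes after
        # their base number
        chain_nodes.sort(key=lambda node: (node.res_seq, node.ins_code))
        nodes.extend(chain_nodes)

    if not nodes:
        raise ValueError(
            f"no Calpha atoms found in {path} for chain spec {chain_spec!r}"
        )
    for node in nodes:
        if not all(np.isfinite(node.coord)):
            raise ValueError(f"non-finite coordinates at {node}")
        if not node.is_standard:
            logger.info("nonstandard residue retained: %s (%s)", node, node.res_name)
    if label is None:
        label = f"{path}:{chain_spec}"
    return CoarseStructure(nodes, label=label)


def write_calpha_pdb(structure: CoarseStructure, path) -> None:
    """Write a CoarseStructure as a Cα-only PDB file."""
    n = structure.n
    atoms = struc.AtomArray(n)
    atoms.coord = structure.coords
    atoms.chain_id = np.array([node.chain_id for node in structure.nodes])
    atoms.res_id = np.array([node.res_seq for node in structure.nodes])
    atoms.ins_code = np.array([node.ins_code for node in structure.nodes])
    atoms.res_name = np.array([node.res_name for node in structure.nodes])
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(str(path))


def match_common(
    bound: CoarseStructure,
    unbound: CoarseStructure,
    chain_map: dict[str, str] | None = None,
) -> ResidueMatch:
    """Pair the residues common to a bound constituent and its unbound form.

    Matching is by author residue number (and insertion code) within a
    chain mapping.  When ``chain_map`` is not given, the distinct chains of
    each structure are paired in order of appearance.  Residues present on
    only one side are excluded from all downstream computation.  A residue
    name disagreement at equal numbering is recorded, not fatal.
    """
    if bound.n == 0 or unbound.n == 0:
        raise ValueError("cannot match empty structures")
    if chain_map is None:
        bound_chains = list(dict.fromkeys(n.chain_id for n in bound.nodes))
        unbound_chains = list(dict.fromkeys(n.chain_id for n in unbound.nodes))
        if len(bound_chains) != len(unbound_chains):
            raise ValueError(
                "chain counts differ; supply an explicit chain_map"
            )
        chain_map = dict(zip(bound_chains, unbound_chains))

    unbound_lookup = {node.key: j for j, node in enumerate(unbound.nodes)}
    pairs: list[tuple[int, int]] = []
    mismatches = []
    for i, node in enumerate(bound.nodes):
        mapped = chain_map.get(node.chain_id)
        if mapped is None:
            continue
        j = unbound_lookup.get((mapped, node.res_seq, node.ins_code))
        if j is None:
            continue
        other = unbound.nodes[j]
        if other.res_name != node.res_name:
            logger.warning(
                "residue name mismatch at %s: %s vs %s",
                node.key, node.res_name, other.res_name,
            )
            mismatches.append((node.key, node.res_name, other.res_name))
        pairs.append((i, j))

    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} matched residues; need at least 3"
        )
    coverage = len(pairs) / bound.n
    return ResidueMatch(pairs=pairs, coverage=coverage, name_mismatches=mismatches)
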