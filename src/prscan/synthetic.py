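"""Self-contained synthetic fixtures for the scanning pipeline.

Real inputs to the method are crystal structures of a two-protein complex
and of its constituents free in solution.  For testing we emulate exactly
the statistical situation the method assumes: a compact, connected pair of
Cα bead chains in contact across an interface, whose "unbound" form
differs from the bound one by the network's *own* linear response to a
force planted at a known effector residue (plus an arbitrary rigid-body
move, so the superposition stage has real work to do).  Because the
displacement field is generated by the same physics the scan inverts, the
planted residue is recoverable and ranks at the top — which is what the
end-to-end tests assert.

Chains are perturbed helix-like spirals by default (compact, connected at
a 10 Å cutoff, no steric clashes); a cubic-lattice walk is available as a
stress-test alternative.  Residue names are assigned round-robin over the
20 standard types so composition reports have full category coverage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from .enm import FloppyNetworkError, build_network
from .prs import lrt_response
from .structure_io import CoarseStructure, ResidueNode, one_to_three
from .superpose import kabsch_superpose

#: Round-robin residue-name alphabet (one-letter, standard 20).
_AA_CYCLE = "AVLIMFGWPDERKNQTYSHC"

#: Cα–Cα virtual bond length, Å.
_BOND = 3.8

#: Minimum allowed inter-bead distance, Å (steric exclusion).
_MIN_DIST = 3.5


@dataclass
class FixtureSpec:
    """Parameters of one synthetic bound/unbound fixture."""

    n_a: int = 30
    n_b: int = 30
    geometry: str = "spiral"             # "spiral" | "lattice"
    interface_contacts_target: int = 5   # min cross-chain Cα pairs within 7 Å
    planted_residue: int | None = None   # complex node index; default set per call
    plant_on: str | None = None          # chain hosting the effector (default: the constituent)
    planted_direction: np.ndarray | None = None
    displacement_scale: float = 2.0      # Å, max |ΔS| of the planted field
    seed: int = 0
    generate_cutoff: float = 12.0        # Å, cutoff used to build the planted response
    noise: float = 0.1                   # Å, positional jitter
    rigid_move: bool = True              # apply a random rigid move to the unbound form
    max_attempts: int = 100


def _spiral_chain(n: int, rng: np.random.Generator, noise: float) -> np.ndarray:
    """Helix-like spiral: ~3.8 Å rise+turn per residue, compact rod."""
    radius, rise, turn = 2.3, 1.5, math.radians(100.0)
    t = np.arange(n)
    coords = np.stack(
        [
            radius * np.cos(turn * t),
            radius * np.sin(turn * t),
            rise * t,
        ],
        axis=1,
    )
    coords -= coords.mean(axis=0)
    return coords + rng.normal(scale=noise, size=coords.shape)


def _lattice_chain(n: int, rng: np.random.Generator, noise: float) -> np.ndarray:
    """Self-avoiding cubic-lattice walk with 3.8 Å steps, biased inward."""
    steps = _BOND * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    for _ in range(200):
        pos = [np.zeros(3)]
        visited = {(0, 0, 0)}
        ok = True
        for _ in range(n - 1):
            order = rng.permutation(6)
            # prefer steps that keep the walk compact
            order = sorted(
                order, key=lambda s: np.linalg.norm(pos[-1] + steps[s])
                + rng.uniform(0, 2 * _BOND)
            )
            for s in order:
                nxt = pos[-1] + steps[s]
                key = tuple(np.round(nxt / _BOND).astype(int))
                if key not in visited:
                    pos.append(nxt)
                    visited.add(key)
                    break
            else:
                ok = False
                break
        if ok:
            coords = np.array(pos)
            coords -= coords.mean(axis=0)
            return coords + rng.normal(scale=noise, size=coords.shape)
    raise RuntimeError("lattice walk failed to avoid itself")


def _build_nodes(coords_a, coords_b) -> CoarseStructure:
    nodes = []
    for chain, coords in (("A", coords_a), ("B", coords_b)):
        for k, xyz in enumerate(coords):
            aa = _AA_CYCLE[k % len(_AA_CYCLE)]
            nodes.append(
                ResidueNode(
                    chain_id=chain,
                    res_seq=k + 1,
                    res_name=one_to_three(aa),
                    coord=tuple(float(x) for x in xyz),
                )
            )
    return CoarseStructure(nodes, label="synthetic complex")


def make_complex(spec: FixtureSpec) -> CoarseStructure:
    """Generate a two-chain complex satisfying the fixture invariants.

    The result is deterministic for a given spec, connected at a 10 Å
    cutoff with exactly six zero modes, has at least
    ``interface_contacts_target`` cross-chain Cα pairs within 7 Å, and no
    two beads closer than 3.5 Å.  Placement is retried with fresh jitter
    (up to ``max_attempts``) until every constraint holds.
    """
    if spec.n_a < 10 or spec.n_b < 10:
        raise ValueError("each chain needs at least 10 residues")
    chain_fn = {"spiral": _spiral_chain, "lattice": _lattice_chain}.get(spec.geometry)
    if chain_fn is None:
        raise ValueError(f"unknown geometry {spec.geometry!r}")

    rng = np.random.default_rng(spec.seed)
    for attempt in range(spec.max_attempts):
        coords_a = chain_fn(spec.n_a, rng, spec.noise)
        coords_b = chain_fn(spec.n_b, rng, spec.noise)
        # slide chain B sideways until the interface is tight but clash-free
        for gap in (9.2, 9.8, 10.4, 11.0):
            cb = coords_b + np.array([gap, 0.0, 0.0])
            cross = cdist(coords_a, cb)
            if cross.min() <= _MIN_DIST:
                continue
            if (cross <= 7.0).sum() < spec.interface_contacts_target:
                continue
            structure = _build_nodes(coords_a, cb)
            if pdist(structure.coords).min() <= _MIN_DIST:
                continue
            try:
                network = build_network(structure, 10.0)
                if network.spectrum.n_zero == 6:
                    return structure
            except (ValueError, RuntimeError):
                pass
    raise RuntimeError(
        f"could not satisfy fixture constraints in {spec.max_attempts} attempts"
    )


def _rigid_mode_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the six rigid-body fields of a point set."""
    n = coords.shape[0]
    centered = coords - coords.mean(axis=0)
    basis = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        basis.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(np.tile(e, (n, 1)), centered).ravel())
    q, _ = np.linalg.qr(np.array(basis).T)
    return q


def _choose_planting(
    network, rows: np.ndarray, candidates: np.ndarray, planted: int | None
):
    """Pick an effector site and force direction that are recoverable.

    A planted field is recoverable only insofar as it (a) survives the
    rigid-body projection implied by superposition and (b) changes little
    under small direction offsets, since the scan samples directions at
    random.  Both are read off the SVD of the rigid-projected 3R × 3
    response block of a candidate site: (a) is its retained energy
    fraction, (b) the dominance of its leading singular value.  The default
    site maximizes the product of the two over ``candidates`` (the
    residues allowed to host the effector, which need not lie on the
    scanned constituent); the default direction is the leading right
    singular vector at the chosen site.
    """
    coords_sub = network.structure.coords[rows]
    q = _rigid_mode_basis(coords_sub)
    row3 = (3 * rows[:, None] + np.arange(3)[None, :]).ravel()
    cov_rows = network.covariance[row3]

    def svd_of(site: int):
        block = cov_rows[:, 3 * site : 3 * site + 3]
        projected = block - q @ (q.T @ block)
        _, s, vt = np.linalg.svd(projected, full_matrices=False)
        retained = (s ** 2).sum() / (block ** 2).sum()
        dominance = s[0] ** 2 / (s ** 2).sum()
        return retained * dominance, vt[0]

    if planted is not None:
        _, direction = svd_of(planted)
        return planted, direction
    scored = [(svd_of(int(p))[0], int(p)) for p in candidates]
    best_p = max(scored)[1]
    return best_p, svd_of(best_p)[1]


def make_unbound(
    complex_structure: CoarseStructure,
    constituent: str,
    spec: FixtureSpec,
):
    """Construct the unbound form of one constituent plus its ground truth.

    The bound→unbound deformation is the complex network's linear response
    (at ``generate_cutoff``) to a unit force planted at
    ``spec.planted_residue`` along ``spec.planted_direction``, restricted
    to the constituent, scaled so its largest displacement is
    ``displacement_scale`` Å, and projected free of any net rigid-body
    component (a rigid component would be unobservable after
    superposition).  When site or direction are left unset they default to
    the most recoverable choice (see :func:`_choose_planting`).  A random
    rigid move is then applied so the superposition stage is genuinely
    exercised.

    Returns ``(unbound_structure, ground_truth)`` where ``ground_truth``
    holds the planted residue (complex index and key), direction, and the
    exact per-residue displacement field the pipeline should recover.
    """
    rng = np.random.default_rng(spec.seed + 7919)
    rows = complex_structure.chain_indices([constituent])
    if rows.size == 0:
        raise ValueError(f"no residues on chain {constituent!r}")

    network = build_network(complex_structure, spec.generate_cutoff)

    planted = spec.planted_residue
    if planted is not None and not 0 <= planted < complex_structure.n:
        raise ValueError("planted residue outside the complex")
    if planted is None or spec.planted_direction is None:
        candidates = complex_structure.chain_indices(
            [spec.plant_on or constituent]
        )
        if candidates.size == 0:
            raise ValueError(f"no residues on host chain {spec.plant_on!r}")
        planted, auto_direction = _choose_planting(
            network, rows, candidates, planted
        )
    direction = spec.planted_direction
    if direction is None:
        direction = auto_direction
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    response = lrt_response(network, planted, direction)

    bound_sub = complex_structure.coords[rows]
    sub = response[rows]
    if spec.displacement_scale > 0:
        scale = spec.displacement_scale / np.abs(np.linalg.norm(sub, axis=1)).max()
        target = bound_sub + scale * sub
        # project out the net rigid component of the planted field
        rot, trans, _ = kabsch_superpose(target, bound_sub)
        deformation = (target @ rot.T + trans) - bound_sub
    else:
        deformation = np.zeros_like(bound_sub)
    unbound_coords = bound_sub + deformation

    if spec.rigid_move:
        q = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-20.0, 20.0, size=3)
        unbound_coords = unbound_coords @ q.T + shift

    nodes = [
        replace(complex_structure.nodes[i], coord=tuple(map(float, xyz)))
        for i, xyz in zip(rows, unbound_coords)
    ]
    unbound = CoarseStructure(nodes, label=f"synthetic unbound {constituent}")
    ground_truth = {
        "planted_index": int(planted),
        "planted_key": list(complex_structure.nodes[planted].key),
        "direction": direction.tolist(),
        "constituent": constituent,
        "displacement_scale": spec.displacement_scale,
        "generate_cutoff": spec.generate_cutoff,
        "seed": spec.seed,
        "delta_s": deformation.tolist(),
    }
    return unbound, ground_truth


def write_ground_truth(ground_truth: dict, path) -> None:
    """Serialize a fixture's ground truth as a JSON sidecar."""
    Path(path).write_text(json.dumps(ground_truth, indent=2))
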