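"""Interface zoning and dissociation-control typing of a two-chain complex.

Residues are split into three mutually exclusive zones by Cα–Cα distance:

* **interface** — has a Cα of the partner chain group within the interface
  cutoff (7 Å by default);
* **first_shell** — not interface, but within the same cutoff of some
  interface residue (first coordination shell);
* **remote** — everything beyond the first coordination shell.

A complex is then typed by where the PRS-selected effector residues live.
With constituents A and B and the residues selected for each constituent's
bound→unbound change:

* **Type I** — all selected residues (for both fields) sit on one single
  chain group: one protein centrally controls both dissociation events;
* **Type II** — cross control: A's effectors all on B and B's all on A;
* **Type III** — auto control: each constituent's effectors on itself;
* **Type IV** — effectors scattered over both partners (residual class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import CoarseStructure

logger = logging.getLogger(__name__)

DEFAULT_INTERFACE_CUTOFF = 7.0

ZONE_INTERFACE = "interface"
ZONE_FIRST_SHELL = "first_shell"
ZONE_REMOTE = "remote"


@dataclass
class ZoneAssignment:
    """Per-residue zone labels for one complex partition."""

    labels: list[str]            # one of the three zone constants, per node
    interface_cutoff: float
    group_of: list[str]          # "A" or "B" per node

    def zone_indices(self, zone: str) -> list[int]:
        return [i for i, z in enumerate(self.labels) if z == zone]


def classify_zones(
    complex_structure: CoarseStructure,
    group_a_chains,
    group_b_chains,
    interface_cutoff: float = DEFAULT_INTERFACE_CUTOFF,
) -> ZoneAssignment:
    """Assign every residue to interface / first shell / remote.

    The two chain groups partition the complex; interface membership is
    decided by cross-group Cα distances ≤ ``interface_cutoff``, the first
    coordination shell by distance ≤ the same cutoff from any interface
    residue.  If the groups never come within the cutoff, everything is
    remote and a warning is emitted.
    """
    idx_a = complex_structure.chain_indices(group_a_chains)
    idx_b = complex_structure.chain_indices(group_b_chains)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("both chain groups must be non-empty")
    overlap = set(idx_a.tolist()) & set(idx_b.tolist())
    if overlap:
        raise ValueError("chain groups overlap")

    coords = complex_structure.coords
    n = complex_structure.n
    group_of = [""] * n
    for i in idx_a:
        group_of[i] = "A"
    for i in idx_b:
        group_of[i] = "B"

    cross = cdist(coords[idx_a], coords[idx_b])
    iface_a = idx_a[np.any(cross <= interface_cutoff, axis=1)]
    iface_b = idx_b[np.any(cross <= interface_cutoff, axis=0)]
    interface = np.concatenate([iface_a, iface_b])

    labels = [ZONE_REMOTE] * n
    if interface.size == 0:
        logger.warning(
            "no interface residues at %.1f Å: the chain groups do not touch",
            interface_cutoff,
        )
        return ZoneAssignment(labels, interface_cutoff, group_of)

    for i in interface:
        labels[i] = ZONE_INTERFACE
    dist_to_iface = cdist(coords, coords[interface])
    near = np.any(dist_to_iface <= interface_cutoff, axis=1)
    for i in range(n):
        if labels[i] == ZONE_REMOTE and near[i]:
            labels[i] = ZONE_FIRST_SHELL
    return ZoneAssignment(labels, interface_cutoff, group_of)


@dataclass
class ComplexType:
    """Dissociation-control class with the per-constituent evidence."""

    type_label: str  # "I" | "II" | "III" | "IV"
    evidence: dict   # field name -> list of (residue key, host group)


def classify_complex_type(
    selected_a_hosts: list[str],
    selected_b_hosts: list[str],
    evidence: dict | None = None,
) -> ComplexType:
    """Type the complex from the host chain groups of selected residues.

    ``selected_a_hosts`` lists, for each residue selected against
    constituent A's displacement field, the chain group ("A" or "B") that
    residue sits on; likewise for B.  Precedence is I → II → III → IV:
    centralized control (all effectors on one single group) is tested
    before cross and auto control; anything mixed is Type IV.
    """
    if not selected_a_hosts or not selected_b_hosts:
        raise ValueError("both selection sets must be non-empty")
    hosts_a = set(selected_a_hosts)
    hosts_b = set(selected_b_hosts)
    if not hosts_a <= {"A", "B"} or not hosts_b <= {"A", "B"}:
        raise ValueError("host labels must be 'A' or 'B'")

    if len(hosts_a | hosts_b) == 1:
        label = "I"
    elif hosts_a == {"B"} and hosts_b == {"A"}:
        label = "II"
    elif hosts_a == {"A"} and hosts_b == {"B"}:
        label = "III"
    else:
        label = "IV"
    return ComplexType(type_label=label, evidence=evidence or {})
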