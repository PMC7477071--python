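"""Rigid-body superposition and bound→unbound displacement fields.

The experimental signal that perturbation scanning is scored against is the
per-residue displacement ΔS between a constituent protein in its bound
(complexed) conformation and its unbound conformation, after the unbound
form has been least-squares superposed onto the bound one over the common
residues.  Superposition is the Kabsch fit (proper rotation + translation)
over all matched Cα pairs, with no outlier trimming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import CoarseStructure, ResidueMatch, ResidueNode

logger = logging.getLogger(__name__)


@dataclass
class DisplacementField:
    """Per-residue displacement vectors ΔS for one constituent.

    ``delta_s[k]`` is (superposed unbound − bound) at matched residue
    ``residues[k]``, in Å, expressed in the bound frame.
    """

    residues: list[ResidueNode]
    delta_s: np.ndarray  # (R, 3)
    rmsd_global: float
    label: str = ""
    local_rmsd: list[tuple[tuple[str, int, int], float]] = field(
        default_factory=list
    )

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.delta_s, axis=1)

    @property
    def keys(self) -> list[tuple[str, int, str]]:
        return [r.key for r in self.residues]


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps mobile points onto the reference
    frame.  The rotation is proper (no reflection).  Degenerate (collinear
    or coincident) point sets are rejected.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 point pairs")

    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    mob_c = mobile - cm
    ref_c = reference - cr

    # collinear point sets leave a free rotation about the common axis
    sv = np.linalg.svd(mob_c, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) point set; fit is not unique")

    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    matrix = rot.as_matrix()
    translation = cr - matrix @ cm
    diff = ref_c - mob_c @ matrix.T
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return matrix, translation, rmsd


def displacement_field(
    bound: CoarseStructure,
    unbound: CoarseStructure,
    match: ResidueMatch,
    label: str = "",
) -> DisplacementField:
    """Superpose the unbound form onto the bound one and take ΔS.

    Only matched residues enter the fit and the field.  The global RMSD is
    the root-mean-square of |ΔS| over matched residues and equals the fit
    RMSD.
    """
    b_idx = match.bound_indices
    u_idx = match.unbound_indices
    ref = bound.coords[b_idx]
    mob = unbound.coords[u_idx]
    rotation, translation, rmsd = kabsch_superpose(mob, ref)
    aligned = mob @ rotation.T + translation
    delta = aligned - ref
    residues = [bound.nodes[i] for i in b_idx]
    fld = DisplacementField(
        residues=residues,
        delta_s=delta,
        rmsd_global=rmsd,
        label=label or f"{bound.label} -> {unbound.label}",
    )
    fld.local_rmsd = local_rmsd(fld)
    return fld


def local_rmsd(
    field: DisplacementField,
    window_ranges=None,
    min_run: int = 3,
    floor: float = 1.0,
) -> list[tuple[tuple[str, int, int], float]]:
    """Per-range RMS displacement, for given or auto-detected ranges.

    ``window_ranges`` is a list of ``(chain_id, start, end)`` in author
    numbering (inclusive).  Without it, "regions of motion" are detected as
    maximal runs of at least ``min_run`` consecutive matched residues whose
    |ΔS| exceeds ``max(floor, 2 × median |ΔS|)``.
    """
    mags = field.magnitudes
    out: list[tuple[tuple[str, int, int], float]] = []
    if window_ranges is not None:
        for chain, start, end in window_ranges:
            sel = [
                k for k, r in enumerate(field.residues)
                if r.chain_id == chain and start <= r.res_seq <= end
            ]
            if not sel:
                raise ValueError(f"empty local-RMSD range {chain}:{start}-{end}")
            rms = float(np.sqrt(np.mean(mags[sel] ** 2)))
            out.append(((chain, start, end), rms))
        return out

    threshold = max(floor, 2.0 * float(np.median(mags)))
    above = mags > threshold
    k = 0
    n = len(mags)
    while k < n:
        if not above[k]:
            k += 1
            continue
        j = k
        while (
            j + 1 < n
            and above[j + 1]
            and field.residues[j + 1].chain_id == field.residues[j].chain_id
        ):
            j += 1
        if j - k + 1 >= min_run:
            chain = field.residues[k].chain_id
            rng = (chain, field.residues[k].res_seq, field.residues[j].res_seq)
            rms = float(np.sqrt(np.mean(mags[k : j + 1] ** 2)))
            out.append((rng, rms))
        k = j + 1
    return out
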