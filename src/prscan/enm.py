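"""Anisotropic elastic network model on Cα nodes.

Every pair of Cα nodes closer than a cutoff r_c is connected by a harmonic
spring whose rest length is the distance in the input structure, so the
network is at its energy minimum by construction.  With uniform force
constants, stacking the bond direction cosines into the 3N × M matrix B
gives the Hessian of the harmonic potential as H = B Bᵀ.  Any connected
network has exactly six zero eigenvalues (rigid translations and
rotations); the Moore–Penrose pseudo-inverse of H on the complement of
that null space is the covariance matrix used by linear response theory
and, through its diagonal 3 × 3 blocks, the per-residue fluctuation (RMSF)
profile.

The spring constant and the thermal prefactor 1/(3 k_B T) only rescale the
covariance by a positive constant.  All downstream scores are Pearson
correlations, which are invariant to positive scaling, so both are folded
into an arbitrary overall unit (``spring_scale``, default 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial import cKDTree

from .structure_io import CoarseStructure

#: Eigenvalues below this fraction of the largest one count as zero modes.
ZERO_MODE_RTOL = 1e-8


class FloppyNetworkError(RuntimeError):
    """The network has internal zero modes (disconnected or under-constrained)."""


@dataclass
class ModeSpectrum:
    """Full eigendecomposition of the network Hessian."""

    eigenvalues: np.ndarray   # ascending, length 3N
    eigenvectors: np.ndarray  # orthonormal columns, (3N, 3N)
    n_zero: int
    tol: float


@dataclass
class ElasticNetwork:
    """Cα elastic network: contacts, Hessian and covariance."""

    structure: CoarseStructure
    cutoff_rc: float
    contacts: np.ndarray        # (M, 2) node index pairs, i < j
    rest_lengths: np.ndarray    # (M,) Å
    b_matrix: np.ndarray        # (3N, M) direction cosines
    hessian: np.ndarray         # (3N, 3N)
    spring_scale: float = 1.0
    _spectrum: ModeSpectrum | None = field(default=None, repr=False)
    _covariance: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.structure.n

    @property
    def n_contacts(self) -> int:
        return self.contacts.shape[0]

    @property
    def spectrum(self) -> ModeSpectrum:
        if self._spectrum is None:
            self._spectrum = count_zero_modes(self)
        return self._spectrum

    @property
    def covariance(self) -> np.ndarray:
        if self._covariance is None:
            self._covariance = pseudo_inverse(self)
        return self._covariance


def build_network(
    structure: CoarseStructure,
    cutoff_rc: float,
    spring_scale: float = 1.0,
) -> ElasticNetwork:
    """Build the elastic network at contact cutoff ``cutoff_rc`` (Å).

    Contacts are exactly the unordered node pairs at Euclidean distance
    ≤ r_c (closed ball, deterministic on ties).  Coincident nodes
    (distance < 1e-6 Å) are rejected outright.
    """
    if structure.n < 2:
        raise ValueError("need at least 2 nodes to build a network")
    if cutoff_rc <= 0:
        raise ValueError("cutoff must be positive")
    coords = structure.coords
    tree = cKDTree(coords)
    pairs = sorted(tree.query_pairs(r=cutoff_rc))
    if not pairs:
        raise ValueError(f"no contacts at cutoff {cutoff_rc} Å")
    contacts = np.array(pairs, dtype=int)
    diff = coords[contacts[:, 0]] - coords[contacts[:, 1]]
    lengths = np.linalg.norm(diff, axis=1)
    if np.any(lengths < 1e-6):
        bad = contacts[lengths < 1e-6][0]
        raise ValueError(f"coincident nodes {bad[0]} and {bad[1]}")

    n = structure.n
    m = contacts.shape[0]
    b = np.zeros((3 * n, m))
    cosines = diff / lengths[:, None]
    for col, ((i, j), e) in enumerate(zip(contacts, cosines)):
        b[3 * i : 3 * i + 3, col] = e
        b[3 * j : 3 * j + 3, col] = -e
    hessian = spring_scale * (b @ b.T)
    return ElasticNetwork(
        structure=structure,
        cutoff_rc=float(cutoff_rc),
        contacts=contacts,
        rest_lengths=lengths,
        b_matrix=b,
        hessian=hessian,
        spring_scale=float(spring_scale),
    )


def count_zero_modes(
    network: ElasticNetwork, rtol: float = ZERO_MODE_RTOL
) -> ModeSpectrum:
    """Diagonalize the Hessian and count its near-zero eigenvalues.

    A valid 3-D network has at least six (rigid-body translations and
    rotations); more than six flags a floppy or disconnected network at
    this cutoff, which the caller must reject.
    """
    evals, evecs = scipy.linalg.eigh(network.hessian)
    tol = rtol * float(evals[-1])
    n_zero = int(np.count_nonzero(evals < tol))
    if n_zero < 6:
        raise RuntimeError(
            f"only {n_zero} zero modes found; Hessian is inconsistent"
        )
    return ModeSpectrum(eigenvalues=evals, eigenvectors=evecs, n_zero=n_zero, tol=tol)


def pseudo_inverse(network: ElasticNetwork) -> np.ndarray:
    """Covariance matrix H⁻¹: Moore–Penrose inverse on the non-zero modes.

    Requires exactly six zero modes; a floppy network raises
    :class:`FloppyNetworkError` so the caller can drop the cutoff.
    """
    spec = network.spectrum
    if spec.n_zero != 6:
        raise FloppyNetworkError(
            f"{spec.n_zero} zero modes at cutoff {network.cutoff_rc} Å "
            "(expected 6); network is floppy or disconnected"
        )
    inv = np.zeros_like(spec.eigenvalues)
    inv[6:] = 1.0 / spec.eigenvalues[6:]
    v = spec.eigenvectors
    cov = (v * inv[None, :]) @ v.T
    return (cov + cov.T) / 2.0


def rmsf(network: ElasticNetwork) -> np.ndarray:
    """Per-residue RMSF profile from the covariance diagonal blocks.

    RMSF_i = sqrt(trace of the i-th 3×3 diagonal super-block of H⁻¹), in
    the arbitrary uniform-spring units.
    """
    diag = np.diag(network.covariance)
    return np.sqrt(diag.reshape(-1, 3).sum(axis=1))


def rmsf_correlation(
    bound_profile: np.ndarray,
    unbound_profile: np.ndarray,
    match=None,
) -> float:
    """Pearson correlation between bound and unbound RMSF profiles.

    ``bound_profile`` is the full-complex profile already restricted to one
    constituent; ``match`` (a :class:`~prscan.structure_io.ResidueMatch`
    between that constituent and its unbound form) selects the residues to
    correlate.  Zero variance on either side makes the correlation
    undefined (NaN).
    """
    bound_profile = np.asarray(bound_profile, dtype=float)
    unbound_profile = np.asarray(unbound_profile, dtype=float)
    if match is not None:
        bound_profile = bound_profile[match.bound_indices]
        unbound_profile = unbound_profile[match.unbound_indices]
    if bound_profile.shape != unbound_profile.shape:
        raise ValueError("profiles must cover the same residues")
    if np.std(bound_profile) == 0 or np.std(unbound_profile) == 0:
        return float("nan")
    return float(np.corrcoef(bound_profile, unbound_profile)[0, 1])
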