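"""Perturbation response scanning (PRS) against a dissociation field.

Linear response theory relates an external force ΔF applied to the network
to the resulting displacement of every residue,

    ΔR ∝ H⁻¹ ΔF,

where H⁻¹ is the elastic-network covariance.  PRS applies a fictitious
force to each residue of the bound complex in turn, in many random
directions, and asks which (residue, direction) pairs produce a response
that best reproduces the experimentally observed bound→unbound
displacement field ΔS of one constituent.  Agreement for one perturbation
is scored by the Pearson correlation C_i between the per-residue
displacement magnitudes |ΔR_k| and |ΔS_k| over the constituent's matched
residues; C_i^max is the best score over sampled directions at residue i.

Because C_i is a correlation it is invariant to the overall positive scale
of the covariance, so the spring constant and thermal prefactor never
matter.  The contact cutoff r_c does: the scan is repeated over a grid
(10–14 Å by default) and the cutoff whose best response agrees most
closely with ΔS for at least one residue is selected as r_opt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .enm import ElasticNetwork, FloppyNetworkError, build_network
from .structure_io import CoarseStructure
from .superpose import DisplacementField

logger = logging.getLogger(__name__)

DEFAULT_N_DIRECTIONS = 500
DEFAULT_CUTOFF_GRID = (10.0, 11.0, 12.0, 13.0, 14.0)
DEFAULT_GAP_THRESHOLD = 0.05
DEFAULT_GAP_WINDOW = 20
DEFAULT_TOP_K = 10


@dataclass
class PerturbationSet:
    """Random unit force directions shared by every scanned residue."""

    directions: np.ndarray  # (K, 3) unit vectors
    seed: int | None = None

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]


def random_directions(
    n_directions: int = DEFAULT_N_DIRECTIONS, seed: int | None = None
) -> PerturbationSet:
    """Sample ``n_directions`` unit vectors uniformly on the sphere.

    Normalized 3-D Gaussian draws; deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_directions, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # resample the (measure-zero) chance of a null draw
    while np.any(norms < 1e-12):
        bad = norms[:, 0] < 1e-12
        v[bad] = rng.normal(size=(int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1, keepdims=True)
    return PerturbationSet(directions=v / norms, seed=seed)


@dataclass
class PRSResult:
    """Scan outcome for one cutoff and one target displacement field."""

    target_label: str
    cutoff_rc: float
    ci_max: np.ndarray          # (N,) best C_i per scanned residue (NaN if undefined)
    best_direction: np.ndarray  # (N, 3) direction achieving ci_max
    residue_keys: list          # (chain, res_seq, ins_code) per scanned residue
    ci_all: np.ndarray | None = None  # optional (N, K) full matrix

    def ranking(self) -> np.ndarray:
        """Residue indices sorted by descending ci_max (NaN last, ties by index)."""
        ci = np.where(np.isnan(self.ci_max), -np.inf, self.ci_max)
        return np.argsort(-ci, kind="stable")


def lrt_response(
    network: ElasticNetwork, residue: int, direction: np.ndarray
) -> np.ndarray:
    """Displacement of all residues in response to a force at one residue.

    Returns the (N, 3) field H⁻¹ ΔF where ΔF is zero except the three
    components of ``residue`` set to ``direction``.  The overall scale is
    arbitrary (uniform-spring units).
    """
    n = network.n_nodes
    if not 0 <= residue < n:
        raise IndexError(f"residue index {residue} outside network of {n} nodes")
    direction = np.asarray(direction, dtype=float)
    block = network.covariance[:, 3 * residue : 3 * residue + 3]
    return (block @ direction).reshape(n, 3)


def pearson_overlap(
    predicted: np.ndarray,
    experimental: DisplacementField,
    restrict_to: np.ndarray,
    variant: str = "magnitude",
) -> float:
    """Score one predicted response field against the experimental ΔS.

    ``predicted`` is the (N, 3) response over the whole complex;
    ``restrict_to`` gives the complex node indices of the field's residues
    (same order as the field).  ``variant="magnitude"`` (default)
    correlates per-residue displacement magnitudes |ΔR_k| vs |ΔS_k|;
    ``variant="components"`` correlates the stacked 3R Cartesian
    components instead.  Returns NaN when either side has zero variance.
    """
    restrict_to = np.asarray(restrict_to, dtype=int)
    if restrict_to.size < 3:
        raise ValueError("restriction set must contain at least 3 residues")
    pred = np.asarray(predicted, dtype=float)[restrict_to]
    if variant == "magnitude":
        x = np.linalg.norm(pred, axis=1)
        y = experimental.magnitudes
    elif variant == "components":
        x = pred.ravel()
        y = experimental.delta_s.ravel()
    else:
        raise ValueError(f"unknown overlap variant {variant!r}")
    if x.shape != y.shape:
        raise ValueError("predicted and experimental fields differ in size")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def field_indices(structure: CoarseStructure, fld: DisplacementField) -> np.ndarray:
    """Complex node indices of a field's residues, in field order."""
    lookup = {key: i for i, key in enumerate(structure.keys)}
    try:
        return np.array([lookup[key] for key in fld.keys], dtype=int)
    except KeyError as err:
        raise KeyError(f"field residue {err.args[0]} not in the complex") from None


def _pearson_columns(mat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of ``mat`` with vector ``y``."""
    xm = mat - mat.mean(axis=0, keepdims=True)
    ym = y - y.mean()
    sx = np.sqrt((xm ** 2).sum(axis=0))
    sy = np.sqrt((ym ** 2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm * ym[:, None]).sum(axis=0) / denom
    r[denom == 0] = np.nan
    return r


def prs_scan(
    network: ElasticNetwork,
    fld: DisplacementField,
    perturbations: PerturbationSet,
    variant: str = "magnitude",
    keep_all: bool = False,
) -> PRSResult:
    """Scan every residue of the complex against one constituent's ΔS.

    Each residue of the bound complex (both chains) is perturbed along every
    direction in ``perturbations``; the Pearson overlap of the response with
    ΔS — restricted to the field's matched residues — is recorded, and the
    best direction per residue retained.  Deterministic given the
    perturbation set.
    """
    rows = field_indices(network.structure, fld)
    cov = network.covariance
    n = network.n_nodes
    dirs = perturbations.directions  # (K, 3)
    k = dirs.shape[0]

    if variant == "magnitude":
        target = fld.magnitudes
    elif variant == "components":
        target = fld.delta_s.ravel()
    else:
        raise ValueError(f"unknown overlap variant {variant!r}")
    row3 = (3 * rows[:, None] + np.arange(3)[None, :]).ravel()
    cov_rows = cov[row3]  # (3R, 3N)

    ci_max = np.full(n, np.nan)
    best_direction = np.zeros((n, 3))
    ci_all = np.full((n, k), np.nan) if keep_all else None
    for i in range(n):
        block = cov_rows[:, 3 * i : 3 * i + 3]      # (3R, 3)
        resp = block @ dirs.T                        # (3R, K)
        if variant == "magnitude":
            resp = resp.reshape(-1, 3, k)
            x = np.sqrt((resp ** 2).sum(axis=1))     # (R, K)
        else:
            x = resp                                 # (3R, K)
        ci = _pearson_columns(x, target)
        if ci_all is not None:
            ci_all[i] = ci
        if np.all(np.isnan(ci)):
            continue
        best = int(np.nanargmax(ci))
        ci_max[i] = ci[best]
        best_direction[i] = dirs[best]

    return PRSResult(
        target_label=fld.label,
        cutoff_rc=network.cutoff_rc,
        ci_max=ci_max,
        best_direction=best_direction,
        residue_keys=network.structure.keys,
        ci_all=ci_all,
    )


@dataclass
class CutoffScan:
    """PRS results over the cutoff grid, with the optimum identified."""

    r_opt: float
    results: dict[float, dict[str, PRSResult]]  # cutoff -> field label -> result
    dropped_cutoffs: list[float] = field(default_factory=list)
    stability: dict[float, float] = field(default_factory=dict)  # cutoff -> global max

    def at_optimum(self) -> dict[str, PRSResult]:
        return self.results[self.r_opt]


def _global_max(per_field: dict[str, PRSResult]) -> float:
    best = -np.inf
    for res in per_field.values():
        ci = res.ci_max
        if np.any(~np.isnan(ci)):
            best = max(best, float(np.nanmax(ci)))
    return best


def optimize_cutoff(
    complex_structure: CoarseStructure,
    fields: list[DisplacementField],
    perturbations: PerturbationSet,
    cutoff_grid=DEFAULT_CUTOFF_GRID,
    variant: str = "magnitude",
    spring_scale: float = 1.0,
) -> CutoffScan:
    """Scan a grid of cutoffs and pick r_opt.

    For each grid cutoff with a valid (exactly six zero modes) network, PRS
    is run against every supplied field; r_opt is the cutoff maximizing the
    best C_i^max over all residues and fields jointly.  Floppy cutoffs are
    dropped with a warning; if all are floppy a hard error advises a larger
    cutoff.  A stability report (global best score per cutoff) is retained.
    """
    cutoff_grid = list(cutoff_grid)
    if not cutoff_grid:
        raise ValueError("empty cutoff grid")
    if not fields:
        raise ValueError("need at least one displacement field")

    results: dict[float, dict[str, PRSResult]] = {}
    dropped: list[float] = []
    stability: dict[float, float] = {}
    for rc in cutoff_grid:
        try:
            network = build_network(complex_structure, rc, spring_scale=spring_scale)
            network.covariance  # triggers the six-zero-mode check
        except (FloppyNetworkError, ValueError) as err:
            logger.warning("cutoff %.1f Å dropped: %s", rc, err)
            dropped.append(rc)
            continue
        per_field = {
            fld.label: prs_scan(network, fld, perturbations, variant=variant)
            for fld in fields
        }
        results[rc] = per_field
        stability[rc] = _global_max(per_field)

    if not results:
        raise FloppyNetworkError(
            "every grid cutoff yields a floppy network; increase the cutoff"
        )
    r_opt = max(results, key=lambda rc: stability[rc])
    for rc in (r_opt - 1.0, r_opt + 1.0):
        if rc in stability:
            logger.info(
                "stability: best score %.3f at %.1f Å vs %.3f at r_opt %.1f Å",
                stability[rc], rc, stability[r_opt], r_opt,
            )
    return CutoffScan(
        r_opt=r_opt, results=results, dropped_cutoffs=dropped, stability=stability
    )


@dataclass
class Selection:
    """Residues selected as candidate dissociation effectors."""

    indices: list[int]           # into the complex node list
    residue_keys: list
    rule: str                    # "gap" | "consensus" | "fallback"
    ci_threshold: float          # ci_max of the last selected residue


def select_top_residues(
    result: PRSResult,
    results_all_cutoffs: list[PRSResult],
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    window: int = DEFAULT_GAP_WINDOW,
    top_k: int = DEFAULT_TOP_K,
) -> Selection:
    """Select effector residues from the C_i^max distribution.

    Rule 1 (sharp decrease): within the top-``window`` residues ranked by
    descending C_i^max, if some consecutive gap exceeds ``gap_threshold``,
    select everything above the largest such gap.  Rule 2 (smooth
    decrease): otherwise intersect the top-``top_k`` residue sets across
    all grid cutoffs.  An empty intersection falls back to the
    top-``top_k`` at the optimal cutoff with a warning.  Ties in C_i^max
    break by residue order; the selection is deterministic.
    """
    order = result.ranking()
    ci_sorted = result.ci_max[order]
    valid = ~np.isnan(ci_sorted)
    order = order[valid]
    ci_sorted = ci_sorted[valid]
    if order.size == 0:
        raise ValueError("no defined C_i^max values to select from")

    w = min(window, order.size)
    gaps = ci_sorted[: w - 1] - ci_sorted[1:w]
    if gaps.size and np.max(gaps) > gap_threshold:
        cut = int(np.argmax(gaps))  # largest gap wins; earliest on ties
        chosen = order[: cut + 1].tolist()
        rule = "gap"
    else:
        top_sets = []
        for res in results_all_cutoffs:
            r_order = res.ranking()
            r_ci = res.ci_max[r_order]
            r_order = r_order[~np.isnan(r_ci)]
            top_sets.append(set(r_order[:top_k].tolist()))
        common = set.intersection(*top_sets) if top_sets else set()
        if common:
            chosen = [int(i) for i in order if int(i) in common]
            rule = "consensus"
        else:
            logger.warning(
                "empty consensus across cutoffs; falling back to top-%d at r_opt",
                top_k,
            )
            chosen = order[:top_k].tolist()
            rule = "fallback"

    chosen = [int(i) for i in chosen]
    return Selection(
        indices=chosen,
        residue_keys=[result.residue_keys[i] for i in chosen],
        rule=rule,
        ci_threshold=float(result.ci_max[chosen[-1]]),
    )
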