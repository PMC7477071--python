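# Methods

## The procedure

`prscan` treats dissociation of a two-protein complex as a linear-response
problem on a coarse-grained harmonic model of the bound state.

1. **Coarse-graining.** Each residue of the bound complex and of each
   unbound constituent is represented by its Cα atom (author numbering;
   first model only for multi-model files; alternate locations resolved by
   occupancy).  Only residues present in *both* the bound and unbound form
   of a constituent take part in any computation; matching is by author
   residue number and insertion code within a chain mapping, with no
   sequence alignment.  Residue-name disagreements at equal numbers are
   logged, not fatal, so point mutants can still be compared.
2. **Displacement field.** The unbound constituent is superposed on its
   bound counterpart with a Kabsch fit (proper rotation, all matched
   residues, no outlier trimming), and ΔS is the per-residue coordinate
   difference in the bound frame.  The global RMSD is the RMS of |ΔS|;
   "regions of motion" are reported as maximal runs of ≥3 consecutive
   residues with |ΔS| > max(1 Å, 2 × median), computed after the global
   fit only.
3. **Elastic network.** Nodes within r_c of each other (closed ball, ≤)
   are joined by unit-stiffness springs at their native lengths.  The
   Hessian is assembled as **BB**ᵀ from the 3N × M direction-cosine matrix;
   its pseudo-inverse, taken over all but the six rigid-body modes, is the
   covariance used both for scanning and for per-residue RMSF profiles
   (square root of the trace of each diagonal 3 × 3 block).
4. **Scanning.** Every residue of the complex — both chains, since
   effectors for one constituent's motion may sit on the partner — is
   perturbed along 500 unit force directions drawn uniformly on the sphere
   (normalized Gaussian triples, seeded).  Each response H⁻¹ΔF is scored
   against ΔS by the Pearson correlation of per-residue displacement
   magnitudes over the constituent's matched residues; C_i^max and the
   best direction are kept per residue.
5. **Cutoff optimization.** The scan repeats for r_c ∈ {10, 11, 12, 13,
   14} Å.  Cutoffs with more than six near-zero modes (floppy or
   disconnected networks) are dropped with a warning.  r_opt maximizes the
   global best score over residues and both constituents' fields jointly;
   the scores at r_opt ± 1 Å are reported as a stability check.
6. **Selection, zoning, typing.** Residues are selected above the largest
   gap (> 0.05) among the top-20 ranked C_i^max values, or — when the
   decay is smooth — as the intersection of the top-10 sets across all
   cutoffs (falling back, with a warning, to the top-10 at r_opt if the
   intersection is empty).  Zones use 7 Å Cα rules: interface residues
   have a cross-partner Cα within 7 Å, first-shell residues are within 7 Å
   of an interface residue, the rest are remote.  The complex is typed
   I/II/III/IV from the host chains of the selected residues, with
   precedence I → II → III → IV (centralized control is strictly stronger
   than cross or auto control; anything mixed is IV).

## Assumptions

- Fluctuations about the bound conformation are harmonic, isotropic in
  spring stiffness, and fully determined by Cα contact topology.
- The binding partners behave as near-rigid bodies: ΔS is meaningful as a
  small displacement field after a single global superposition.
- The perturbation is a static point force at one residue; responses add
  linearly and their overall amplitude is not interpreted.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| cutoff grid | 10–14 step 1 | Å | lower bound matches the ~7 Å first coordination shell plus slack; networks below ~9 Å are frequently floppy |
| n_directions | 500 | — | per-residue force directions |
| interface cutoff | 7 | Å | Cα–Cα, used for both interface and first shell |
| gap_threshold | 0.05 | — | "sharp decrease" rule; qualitative in origin, exposed in config |
| selection window / top-k | 20 / 10 | — | ranked window for the gap rule; per-cutoff set size for the consensus rule |
| spring constant, 1/(3k_BT) | folded into 1 | — | every reported score is a Pearson correlation, invariant to positive rescaling; absolute units are deliberately dropped |
| zero-mode tolerance | 1e-8 × λ_max | — | separates rigid from soft internal modes at the sizes handled here |

The eigendecomposition path is dense: target systems are at most ~1000
residues (3000 coordinates), where `scipy.linalg.eigh` is both faster and
more predictable than iterative sparse solvers.

## The synthetic generator

Real validation data for this method are pairs of crystal structures.  The
generator emulates the *statistical* situation instead: two compact,
connected Cα bead chains (perturbed helix-like spirals; a cubic-lattice
walk variant exists for stress tests) in contact across an interface, with
an "unbound" form displaced by the complex network's own linear response
to a force planted at a known residue, made rigid-free (a net rigid
component would be unobservable after superposition), scaled to a 2 Å
maximum, and finally subjected to a random rigid move so the superposition
stage does real work.  Every fixture is validated before use: exactly six
zero modes at 10 Å, at least five cross-chain contacts within 7 Å, no two
beads closer than 3.5 Å; placement retries with fresh jitter until the
constraints hold.

Two generator choices matter for interpretation:

- **Recoverable planting.** The response to a force, restricted to one
  constituent, generally contains a large rigid-body part — especially for
  forces on the partner chain, which drag the constituent as a quasi-rigid
  body.  Superposition removes that part from ΔS but not from the
  predicted ΔR, so an arbitrary planted site/direction caps the
  self-consistency score well below 1.  When site or direction are left
  unset, the generator therefore picks them from the SVD of the
  rigid-projected response block: the direction is the leading right
  singular vector, and candidate sites are scored by retained energy after
  projection times the dominance of the leading singular value (direction
  insensitivity, which matters because the scan samples directions at
  random).  A `plant_on` field hosts the effector on the partner chain to
  construct cross-control scenarios.
- **Jitter of 0.1 Å** keeps ideal ~3.8 Å Cα spacing above the 3.5 Å
  steric floor while still breaking exact symmetry.

What passing tests on these fixtures show: the pipeline inverts its own
forward model — field construction, superposition, network build, scan,
selection and typing are mutually consistent, deterministic under a seed,
and invariant to the arbitrary overall scale.  What they do not show:
performance on real conformational changes, which include anharmonic and
side-chain motions, disorder, and displacement fields that are *not* a
single-residue linear response; nor anything about the electrostatic
interpretation of remote control, which is outside this package's scope.
Analyses of real complexes should treat the synthetic recovery rates as an
internal-consistency bound, not an accuracy estimate.

## Numerical choices and degenerate inputs

- Contacts use a closed ball (distance ≤ r_c) so boundary ties are
  deterministic; coincident nodes (< 1e-6 Å) are rejected.
- The covariance is symmetrized after reconstruction from eigenpairs.
- Pearson scores with zero variance on either side are undefined and
  propagate as NaN; NaN scores rank last and are never selected.
- Ties in C_i^max break by residue order; the direction achieving the
  maximum is the first one encountered.
- Kabsch fits require ≥3 non-collinear pairs; collinear sets are rejected
  (the rotation about the common axis would be arbitrary).
- Superposition and matching errors abort the pipeline with the stage
  named; floppy-cutoff warnings are collected in the run manifest.
- With fewer than six zero modes the Hessian is internally inconsistent
  and the run aborts; with more than six the cutoff is rejected rather
  than silently pseudo-inverted.

## Problem sizes

Tests and the acceptance script use 60-residue complexes (30 + 30), 500
directions and the full five-point cutoff grid; recovery statistics run
over 20 independently generated fixtures, cutoff recovery over 8 and type
classification over 8 scenario instances.  These sizes exercise every code
path at full method fidelity — the scan cost is O(N² · K) in residues and
directions and the eigendecomposition O(N³), so behaviour at 60 residues
is structurally identical to the several-hundred-residue complexes the
method targets.

## Known limitations

- Residue matching is purely number-based; renumbered depositions need an
  explicit chain mapping and consistent author numbering.
- Local RMSD regions are computed after the global fit only; a local
  re-fit per region would report different values.
- The magnitude form of the overlap score discards directional
  anticorrelation within a residue; the stacked-component variant is
  available (`variant="components"`) for sensitivity analysis.
- Single-constituent runs (one unbound structure missing) produce
  selections but no type call.
- No mmCIF input, no heavy-atom or ΔSASA interface definition, no
  distance-dependent springs, no MD-derived covariance input.
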