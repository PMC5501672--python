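# Methods

This note documents the models and numerical procedures implemented in
`porexlink`, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the design choices made where the design was
genuinely open.

## Pore-radius profiling

**Model.** The pore radius at axial position z is the radius of the largest
probe sphere centred in the plane through z perpendicular to the channel
axis:

    R_pore(z) = max_p min_i ( |p − x_i| − r_i ),   p in the plane at z.

Distances to atoms are three-dimensional, so atoms above and below the plane
constrain the probe, as in HOLE-style profiling.  Hydrogens are excluded by
default; the united-atom van der Waals radii (C 1.85, N 1.75, O 1.65,
S 2.00, P 1.90, H 1.00 Å) absorb them and are overridable via
`RadiusTable`.

**Search.** The in-plane maximisation runs simulated annealing (default
3 restarts × 120 iterations, initial temperature 1.0, proposal σ 0.6 Å ×
temperature, cooling 0.96) followed by a Nelder–Mead polish run twice with
tight tolerances (xatol 1e-10).  Two guards keep the search physical:
proposals never leave a disk of radius `r_max_cap` around the slice seed,
and a move from open space (f ≥ 0) into atom overlap (f < 0) is always
rejected — the latter is what prevents the walker from tunnelling through
the discrete-atom wall into the bulk solvent outside the protein, where the
objective grows again.  The objective is clamped at `r_max_cap` (default
15 Å), which doubles as the "pore exit" sentinel: capped slices delimit the
profile, and the reported profile is the maximal contiguous uncapped run
containing the membrane window.

**Axis and walk.** The axis is either supplied or auto-detected as the
principal inertial axis of the Cα atoms inside the `membrane` segment; the
walk proceeds in `z_step` (default 0.5 Å) increments, seeding each slice
from the previous optimised centre so the centre path can follow a tilted
or curved pore.  All randomness derives from a single integer seed
(per-slice generators are spawned from `(seed, frame, slice)`), so profiles
are bit-reproducible, and numerical experiments in the test suite confirm
rigid-motion invariance at machine precision and the exact +δ shift of all
uncapped radii when every vdW radius is shrunk by δ.

**Ensemble averaging.** Per-frame profiles are linearly interpolated onto
the first frame's z grid; capped or out-of-range slices are dropped from
the statistics (contribution counts are reported, never imputed).  The SD
is the population SD.  The narrowest point of the mean profile is compared
with the hydrated Cl⁻ radius window (1.6–1.9 Å): `open` at or above the
upper bound, `closed` below the lower, `marginal` between.  Whether the
filter radius of a real system should be read from the ensemble mean or
from per-frame minima is genuinely ambiguous; both are available
(`EnsembleProfile.profiles` keeps every per-frame curve).

## Cβ distances

Cross-linker geometry references side-chain take-off points, so distances
are Cβ–Cβ throughout.  Glycine (or any Cβ-stripped residue with a complete
backbone) gets a virtual Cβ built from N/Cα/C with exact tetrahedral
geometry and a 1.53 Å bond on the L-amino-acid side; residues with only a
Cα fall back to Cα and the point is flagged, never silent.  Summary
statistics use the population SD — immaterial against the sample SD at the
100–200-frame ensembles this targets.  Interface stability flags a pair
stable when its distance SD over the trajectory is ≤ 1.5 Å (default),
encoding "small SD ⇒ the interface did not dissociate during the run".

## Cross-linker span model

`span_max(n) = 2.6 + 1.3·n` Å is the unique line through the two shortest
published reagent anchors (M3M 6.5 Å, M8M 13 Å) and reproduces the third
(M17M 24.7 Å) exactly; intermediate spans (M1M 3.9, M2M 5.2, M5M 9.1 Å) are
derived from it and overridable.  `span_min = span_max/2` encodes fold-back
of the flexible methylene chain: pairs much closer than the extended length
still bridge, at reduced efficiency (partial).

Classification of a distance series against a reagent, on the mean distance
d (a `--use-min` mode classifies on the per-frame minimum instead):

* d ≤ 2.1 Å → spontaneous disulfide (no reagent needed);
* span_min ≤ d ≤ span_max + slack_full → full bridging;
* d < span_min, or d ≤ span_max + slack_partial → partial;
* otherwise → not bridgeable.

The above-span slacks are **fluctuation-limited**: `slack = min(tol,
k_sd·SD)` with tol_full 1.0 Å, tol_partial 3.0 Å, k_sd 2.  The rationale: a
pair whose *mean* separation exceeds the fully extended reagent can only be
caught during transient approaches, so the allowance must be earned by the
observed thermal fluctuation.  A static (zero-variance) 25 Å pair is
therefore beyond even the 24.7 Å reagent, while a 13.5 Å pair fluctuating
by ±0.8 Å is fully bridged by the 13 Å reagent.  The calibration constants
are design choices, not ground truth; the contract asserted in tests is the
bridgeable-vs-not level.  Monofunctional reagents are representable in
observation tables but excluded from distance-based prediction — their
inhibitory action is pore blockage, not bridging.

Aggregation across conformational states takes the strongest call per
reagent (full > spontaneous > partial > none) and records the supporting
states, so a reagent can be predicted to trap specifically the open or the
closed conformation.  Concordance against an observation table is scored
per pair at the any-crosslinking vs none level, with a per-reagent
confusion table; unmatched rows are reported, never dropped.

## Superposition, equilibration, clustering

Superposition is Kabsch (SVD of the cross-covariance with a determinant
sign fix; reflections forbidden), on unweighted coordinates of the chosen
selection; the RMSD is evaluated from the transformed residuals rather than
the trace identity to avoid cancellation near zero.  The all-pairs frame
matrix uses batched 3×3 SVDs with per-pair refitting (a fit-to-reference
alternative is available, since published protocols rarely say which was
used).

Cross-structure comparison builds a residue correspondence by global
pairwise sequence alignment per chain (BLOSUM62, gap open −10, extend
−0.5), so numbering offsets and orthologue comparisons need no manual
mapping.  Segment RMSD is reported in both modes: `fit-global` (one overall
superposition, then per-segment deviation — sensitive to rigid-body segment
displacement) and `fit-local` (per-segment refit — internal deformation
only, never larger than fit-global).

Equilibration detection makes the usual plateau-by-eye criterion explicit:
a window (default 20 frames) is flat when its linear RMSD slope is within
±0.02 Å/frame and its range within 2 Å; the onset is the start of the first
flat window from which every later window is also flat.

Clustering is quality-threshold style on the pairwise superposed-RMSD
matrix (default 2 Å, backbone atoms): repeatedly extract the frame with the
most unassigned neighbours within the threshold together with those
neighbours; ties break to the lowest frame index; the centroid is the
member minimising total within-cluster RMSD.  This is the simplest
algorithm matching a "structures within ~2 Å of one another, centroid
representatives" description.

## Synthetic data: what it emulates, and what it does not

The generator produces three families of inputs with exact ground truth:

* **Ring-stack channels** — stacked 16-atom carbon rings tracing a bundle
  radius ρ(z); the on-axis pore radius is analytic
  (`min_j sqrt(ρ_j² + (z−z_j)²) − r_C`), used for oracle tests at every z.
* **Helix-bundle channels** — idealised α-helices (Cα lattice radius 2.3 Å,
  rise 1.5 Å/residue, twist 100°/residue; N/C/O on companion lattices, Cβ
  by the same tetrahedral construction used for virtual Cβ points).  Six
  pore-lining inner helices plus six outer helices surround the axis; a
  single ring of twelve at pore-forming radius would sterically overlap,
  and in real channels only a subset of helices lines the filter.  Each
  inner helix is phased so one Cα points exactly at the axis in the filter
  plane, and a glycine band (±2 residues) around it keeps Cβ atoms clear of
  the constriction, making the minimal pore radius exactly
  ρ(z_f) − 2.3 − 1.85 by construction: the reference open state is built to
  2.50 Å and the closed state to 0.80 Å.  The closed state additionally
  spins designated "gating" helices about their own axes, changing reporter
  Cβ–Cβ distances between states.  Radial placement follows ρ(z) rigidly
  per residue, preserving residue geometry exactly.
* **Ensembles and observations** — seeded iid atomic noise or rigid
  per-helix jitter stands in for MD snapshots; simulated cross-linking
  outcome tables apply the package's own span classification to the
  ground-truth state distances (best across states, majority-state
  downgrade for full calls) with optional symmetric label noise across the
  crosslinked/none boundary.

What passing these tests shows: the probe search finds true in-plane
optima, the distance/ span/ concordance chain is self-consistent, and the
comparison stack recovers planted structure.  What it does not show:
anything about force fields, membrane physics, side-chain packing beyond
Cβ, or the realism of any particular channel model — the synthetic helices
are lattice idealisations (peptide-bond lengths are approximate), and real
ensembles have correlated, anisotropic fluctuations that iid or rigid-jitter
noise does not reproduce.

## Problem sizes and numerical defaults

The shipped tests and the acceptance script run the reference channel
(12 helices × 31 residues, ~1 830 atoms) with single-frame profiles at
0.5–1.0 Å slice spacing, 100-frame clustering problems and 150-frame
equilibration series, totalling a few minutes on one CPU; all sizes are
configurable upward for production use.  Degenerate inputs are errors, not
silent defaults: coplanar atom sets have no principal axis, segments
resolving to fewer than 3 mapped atoms are skipped with a warning,
duplicate observation rows and non-matching multi-model files raise
immediately with the offending item named.

## Known limitations

* The probe search is a stochastic optimiser; its guarantees are empirical
  (grid-oracle agreement within 0.05 Å on every tested channel), not
  worst-case.  Pathological pore shapes with disconnected voids inside the
  wall may be reported as part of the pore if a non-overlapping path
  reaches them.
* The span model is linear in spacer length and symmetric between reagents;
  real reagent chemistry (S–S geometry, side-chain rotamers) is absorbed
  into the calibration constants.
* Sequence-alignment-guided correspondence assumes chains align globally;
  rearranged topologies would need an explicit correspondence TSV.
* No mmCIF or compressed-trajectory input; multi-model PDB is the single
  ensemble format.
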