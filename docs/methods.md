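# Methods

## Contact model

Two contact kinds are evaluated independently per frame, so the same
residue pair can carry both a vdW and an H-bond fingerprint row.

**van der Waals contact.** Present in a frame iff any atom pair (i, j)
across the two sides satisfies ‖x_i − x_j‖ ≤ r_i + r_j, inclusive at
equality. Radii are per element; the bundled default is the Bondi (1964)
table (`dynifp/data/bondi_radii.tsv`), overridable by any two-column TSV.
Hydrogens participate when present; united-atom topologies (no nonpolar
hydrogens) are accepted because the rule quantifies over existing atoms
only. Detection uses a k-d tree pruned at the largest possible radius sum
and then checks exact per-pair sums, so results are identical to the
brute-force O(N²) rule; qualifying pairs are returned sorted ascending by
(i, j), which fixes the output order.

**Hydrogen bond.** D–H···A with D, A ∈ {N, O}. Present iff
2.5 Å ≤ ‖D − A‖ ≤ 3.5 Å (inclusive at both ends) and the off-axis angle is
strictly below 30°. The off-axis angle is the deviation of the arrangement
from linearity, measured at the donor by default: angle(D→H, D→A). A
hydrogen-vertex convention (deviation of the D–H–A angle from 180°) is
available via `HBondCriteria(vertex="hydrogen")`. Boundary evaluation uses
a 1e-9 guard so geometries constructed exactly on a bound land on the
documented side. Sulfur donors/acceptors are excluded. Donor hydrogens are
assigned by ≤ 1.2 Å proximity to an N/O in the reference frame (frame 0 of
the trajectory) and re-used for all frames; this covers topologies without
bond records.

**Salt bridges** are annotated on residue pairs with opposite side-chain
charges (Lys/Arg/His⁺ vs Asp/Glu). Annotation is metadata only: detection
geometry remains the H-bond criterion, matching how charged pairs are
tabulated alongside hydrogen bonds.

## Fingerprint statistics

The occurrence fraction of a contact in one replica is the exact rational
(presence frames)/(total frames), computed on the assessment window. The
default window is the last 10 ns of each run, selected as the half-open
interval (t_end − w, t_end]; a window equal to the full duration returns
the trajectory unchanged, and re-slicing with the same window is a no-op
(one frame-step of slack in the duration check makes the operation
idempotent).

Occupancy classes: white [0, 0.30), blue [0.30, 0.60), yellow
[0.60, 0.90], red (0.90, 1]. The boundary placement (half-open bins, 90 %
exactly falling in yellow) is a convention fixed here and configurable via
`OccupancyBins`; only the verbal class descriptions are externally given,
not the boundary side.

Consensus significance: a contact is significant in a condition iff its
fraction strictly exceeds 0.60 in at least 2 replicas. Both the threshold
and the replica minimum are parameters (`frac_threshold`, `min_replicas`)
for designs with other replica counts. Strictness matters: per-replica
fractions (0.60, 0.60, 0.90) are not significant. No uncertainty is
attached to fractions (no block averaging or bootstrap); the hard consensus
rule is the intended filter.

Differential labels between two conditions use only the two significance
booleans: formed (significant only in the target condition), broken
(reverse), present-both, absent-both. The activation report restricts to
protein/protein contacts and additionally extracts compensating
salt-bridge shifts: a broken charged pair and a formed charged pair sharing
exactly one residue are reported as one shift (shared residue, old partner,
new partner), and the new pair is listed under shifts rather than formed.

## Geometry

Superposition is least-squares rigid (Kabsch), implemented with
`scipy.spatial.transform.Rotation.align_vectors`; inputs with fewer than 3
points or a collinear point set (second singular value < 1e-10) are
rejected. RMSD traces superpose each frame on the reference over the given
selection and report the post-fit RMSD over the same selection.

Residence volumes: frames are sampled every 0.1 ns (configurable stride),
rigidly superposed on a common reference over the fit selection (default
intent: transmembrane Cα, so volumes from different runs overlay in one
frame of reference), and each ligand atom increments the voxel containing
it; counts pool across replicas. Default spacing 1.0 Å. The box is
auto-sized to the pooled ligand extent plus 3 Å padding, snapped to the
spacing — or fixed explicitly when two grids must be comparable. Positions
outside the box are counted in `n_outside`, never dropped, so
Σcounts + n_outside = frames × ligand atoms always holds.

Volume overlap is the Jaccard index of voxel sets occupied in at least a
threshold fraction of sampled frames (default 0.05). Any quantitative
overlap is threshold-dependent; the threshold is therefore a prominent
parameter and carried in grid metadata. Grids export as OpenDX regular
scalar fields with integer data values (z index fastest, the OpenDX
convention), so export → import is lossless; the files load in common
molecular viewers and in `gridData`.

## Assay mathematics

Normalization: (Luc/Ren − lowest)/(highest − lowest) per plate, where the
lowest/highest ratios come from the negative (DMSO) and positive (10 µM
forskolin) controls. Out-of-range wells may fall outside [0, 1] and are
reported unclipped. Responses are fractions internally; percentages only at
I/O.

Hill fit: y = baseline + amplitude·cⁿ/(EC50ⁿ + cⁿ). An explicit baseline is
included because plate normalization does not guarantee a zero floor.
Fitting is bounded trust-region least squares with n ∈ [0.3, 10], EC50
within a 100-fold margin of the tested range, and three documented starts
(EC50 at the geometric mean of positive concentrations with n = 1 and
n = 2, and at the half-rise concentration with n = 1); the converged start
with the smallest residual norm wins, making the fit deterministic.
All-equal responses return a zero-amplitude fit rather than an error.
Measured recovery (scripts/acceptance.py): EC50 exact to machine precision
on noiseless curves, mean |error| ≈ 7 % at 2 % Gaussian response noise over
100 seeds on an 8-point design spanning 10–400 µM.

Threshold concentration: analytic inverse of the fitted curve at 10 % of
the forskolin response; an error is raised when that target lies outside
the curve's range ("threshold beyond tested concentrations"). E_max is the
mutant response at 250 µM as a percentage of wild type.

Mutant classes (threshold µM, E_max % of WT): hyperactive E_max > 110;
unaffected threshold ∈ [140, 170] and E_max ∈ [80, 110]; affected
threshold ∈ (170, 210] and E_max ∈ [40, 80); inactive threshold > 210 and
E_max < 40. The published bins share boundary values without stating
inclusivity; the convention above makes the regions mutually exclusive,
and anything outside them returns "unclassified" with both margins
preserved. A threshold of "not reached" is treated as > 210 µM.

Competition curves: the IC50 is the antagonist concentration at 50 %
relative response — an exact data point is preferred; otherwise the
bracketing points are interpolated log-linearly in concentration (standard
for ranges spanning decades). All-above-0.5 inputs raise "IC50 not
reached". Rising segments are flagged rather than smoothed. No affinity-
ratio estimator beyond the interpolated IC50 is provided; converting IC50
to a binding constant requires a competition model and is left to the user.

## Synthetic generator

The generator emulates the statistical structure of replicated MD output
— per-contact occupancy fractions, H-bond/vdW geometries, diffusing-ligand
point clouds — not physics. Residues are minimal side-chain templates
(Cα, Cβ probe, and a polar group where the residue type has one) spaced
20 Å apart with a slight helical wobble (so Cα sets are never collinear
and superposition is well-posed); the ligand is a HETATM carbon chain
50 Å off the protein axis, anchored off-lattice so base positions never
sit exactly on 1 Å voxel boundaries.

Each contact schedule moves one residue between a present geometry
(collinear D–H···A at 3.0 Å, or vdW probes at the radius sum minus 0.2 Å)
and an absent geometry placing the primary pair at least the schedule
margin (default 1.0 Å, minimum 0.5 Å) outside the criterion; an extra 1 Å
guard on vdW absences covers the ≤ 1 Å local offsets of hydrogens. The
ligand is always the static side. Presence frames are a seeded shuffle of
frame indices, so round(fraction × n_frames) frames match exactly —
non-integral products are rejected rather than rounded silently. Atoms of
unscheduled residues receive σ = 0.05 Å Gaussian jitter, small enough
never to cross a criterion boundary given the margins. A residue may be
moved by at most one schedule, and a pair may be scheduled at most once;
conflicting specs are errors. All outputs are pure functions of
(spec, seed); per-replica and per-schedule streams derive from the master
seed via `numpy.random.SeedSequence` spawn keys.

What passing on these fixtures shows: the detectors implement the stated
geometric criteria exactly and the statistics aggregate them correctly.
What it does not show: behaviour on force-field-realistic conformations,
solvent-mediated interactions, or contacts near criterion boundaries with
thermal noise — real trajectories put many pairs in the ambiguous region
that the generator deliberately avoids.

## Problem sizes

The test suite and the acceptance script run on deliberately small
problems: 50 random frames of ≤ 200 atoms for oracle equivalence,
100-frame replicas for fingerprint recovery, 100 × 6 positions for grid
conservation, 100 seeds for noisy Hill recovery. These sizes already
exercise every code path and keep the whole suite in seconds; the
algorithms themselves stream per frame and scale to real trajectory
lengths.

## Known limitations

- No π-stacking, cation–π, halogen-bond or water-mediated contact types,
  and no energy-based contact scoring.
- Binary MD formats (XTC/DCD) are not parsed; convert to multi-model PDB
  or the internal text format upstream, or adapt via MDAnalysis.
- Element inference from legacy PDBs uses the first alphabetic character
  of the atom name with a two-letter exception list (Cl, Br, Fe, Zn, Mg,
  Se, Si); CA/NA/HG-style metal ambiguities resolve to C/N/H, the right
  call inside proteins and the wrong one for bare ions.
- The consensus rule is a hard filter; near-threshold contacts flip with
  single-frame changes, which is inherent to the rule, not smoothed here.
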