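# Methods

## Scope and model system

The package analyses the intracellular fragment of the photoreceptor
membrane guanylate cyclase GC-E (ROS-GC1/retGC1), a homodimer whose
cytoplasmic part comprises, per chain, a kinase homology domain (KHD),
an alpha-helical dimerization domain (DD) and a catalytic domain (CCD).
Residue numbering follows the bovine orthologue used for structural
modelling; human positions are five lower (human V902L is bovine
V907L), and a configurable integer offset in the run configuration maps
between the two schemes. Two families of analyses are implemented:

1. **Conformational dynamics** of trajectories of the dimer — iterative
   Kabsch superposition, hinge-centered projection of the
   catalytic-domain center, and binding-site difference distance
   matrices (DDMs).
2. **Enzyme kinetics** of cyclase activity versus Mg-GTP — Hill-model
   fitting, Hill-weighted Lineweaver–Burk linearization, immunoblot
   calibration, and catalytic-parameter derivation (kcat, kcat/KM).

No molecular dynamics is run here; a kinematic synthetic-data generator
provides trajectories and assay tables with planted, known ground truth
so every analysis stage is testable at desk scale.

## Iterative trajectory superposition

`kabsch_superpose` solves the orthogonal Procrustes problem by SVD of
the weighted cross-covariance of the centered point sets. The sign of
the smallest singular value is flipped when the raw solution has
negative determinant, so the returned rotation is always proper
(det = +1); reflections are never produced, including for near-planar
inputs. Fewer than three points, or a collinear set (rank of the
centered coordinates < 2 at tolerance 1e-9), raises a conditioning
error rather than returning an under-determined transform.

`align_trajectory` implements the iterative scheme: all frames are
first superposed onto frame 0 over a chosen atom selection; each
subsequent iteration recomputes the arithmetic mean of the aligned
selection coordinates and re-aligns every frame to that average. The
loop stops when the plain (un-refitted) RMSD between successive average
structures drops below a tolerance. The tolerance is not dictated by
the underlying procedure being emulated, so the default is a package
choice: **0.01 Å** between successive averages, with `max_iter = 100`.
This is far below thermal jitter and cheap to reach; exhausting
`max_iter` flags `converged = False` in the result instead of raising.
The average is used only as a reference, so no re-orthogonalization is
needed. The selection's transform is applied to the whole frame:
aligning on the KHD transports DD and CCD rigidly, which is what makes
the hinge projection meaningful.

Two distinct selections are used in the pipelines: KHD backbone carbons
only (projection analysis, so catalytic-domain motion is measured
*relative to* the KHD) and all residues (before the DDM, for parity
with the projection workflow — mathematically redundant, see below).

## Hinge-centered projection of the catalytic domain

Residue 818 sits at the end of the KHD, just before the dimerization
helix, one copy per chain. After alignment, every frame is translated
(never rotated) so the midpoint of the two residue-818 backbone
carbons is exactly the origin. Per frame, the geometric center of the
catalytic-domain selection — the unweighted mean of its backbone-carbon
coordinates; mass weighting is deliberately not applied — defines the
endpoint of a segment from the origin. Projecting the endpoints onto
the x–y plane traces the area in which the catalytic domain moves.

The projection plane is the x–y plane of the post-alignment frame
(the frame-0/average-structure frame); no additional principal-axis
reorientation is applied, and the synthetic template is built so the
KHD→CCD axis runs roughly along z. Consequence worth stating
explicitly: the trace is exactly invariant under a global *translation*
of the input, but a global *rotation* rotates the alignment reference
and therefore the plane — the 3D center trace is equivariant
(it rotates with the input), not invariant. Both properties are tested.

`summarize_trace` reports the centroid, the maximum displacement from
the first point, the net drift (last minus first point) and the convex
hull area of the trace (SciPy Qhull; zero for fewer than three distinct
or collinear points). An optional stride thins dense trajectories
before the hull computation.

### Representative backbone atom

Every residue is represented by its "first backbone carbon",
interpreted as the α-carbon: CA is the first carbon in N→CA→C backbone
order and the conventional residue representative. The choice is
switchable to the carbonyl C (`atom_name="C"`) throughout, since the
wording admits either reading.

### Helix-rotation arithmetic

An ideal α-helix has 3.6 residues per turn, so each residue inserted
into a helical segment rotates the downstream part by 360/3.6 = 100°.
`helix_rotation_angle` returns both the cumulative angle (n × 100°) and
its value modulo 360°. Note the arithmetic tension the function makes
visible: four insertions give a cumulative 400°, i.e. a net 40° offset,
even though four residues are often described as restoring "a full
turn"; both numbers are reported rather than reconciled.

## Difference distance matrices

The GTP binding site comprises Asp890, Arg981, Ala1013 and Lys1051 on
each subunit — eight residues. For one trajectory, the pairwise
Euclidean distances between the eight backbone carbons are averaged
over all frames (a stride is configurable; the default uses every
frame) and reported in nanometres, giving a symmetric 8 × 8 matrix with
an exactly zero diagonal. Label order is fixed as subunit 1's four
residues then subunit 2's, so intra-subunit blocks are contiguous. The
element-wise difference of two such matrices (e.g. wild type minus
mutant) is the DDM: signed, symmetric, antisymmetric under argument
swap.

Distances are invariant under rigid motions, so prior superposition
cannot change the DDM; the pipeline nevertheless aligns first for
workflow parity, and a regression test asserts bit-level agreement
(1e-9 nm) with and without the alignment stage.

Residues are ranked by `score(i) = mean over j≠i of |DDM(i, j)|`,
descending, ties broken by matrix order. The score definition is a
package convention (any monotone aggregate of a row's absolute entries
would do); it recovers a planted single-residue displacement as the
top-ranked residue while the unperturbed subunit's intra-block entries
stay near zero — the asymmetric-subunit signature.

## Synthetic homodimer generator

The template is a coarse, backbone-only (N, CA, C, O) C2-symmetric
dimer: chain A is laid out as a helical path (1.8 Å radius, 100° twist
and 1.5 Å rise per *sequence position*) descending from the KHD through
the hinge at z = 0 and along the DD, ending in a compact
catalytic-domain blob (8 Å Fibonacci sphere) below the helix; chain B
is chain A rotated 180° about z. Key geometric decisions:

* **Sparse residues, real extents.** Only a handful of residues per
  domain are materialised (defaults 10/8/12), but their z positions are
  proportional to residue *number*, so the template has the lever-arm
  proportions of the real construct (the dimerization helix spans
  residues 819–880 ≈ 93 Å). This matters: both the projected swing
  signal and the alignment-noise amplification scale with arm lengths,
  so a foreshortened template would distort their ratio.
* The binding-site residues 890, 981, 1013 and 1051 are always
  materialised (snapped onto the evenly spaced CCD residue grid) and
  carry their real identities (ASP/ARG/ALA/LYS); all other residues are
  GLY.
* The hinge midpoint of the template is exactly the origin by
  construction.

Motions are kinematic, not physical — no force field, solvent or
thermodynamics. Per frame, in order: (1) a rigid **swing** of DD+CCD of
one chain (default B, mirroring the observed one-subunit asymmetry)
about that chain's hinge CA, around a configurable unit axis, with a
linear ramp from 0 to the amplitude (or one sinusoidal cycle); (2) a
single-residue **displacement** by a fixed vector, ramped linearly over
the frames; (3) isotropic Gaussian **jitter** per atom; (4) an optional
random whole-frame rigid motion (for testing that alignment removes
it). All randomness flows through one `numpy.random.Generator` seeded
per simulation; seeds are mandatory, and identical specs reproduce
byte-identical coordinates.

Default study conditions used by the analysis drivers and fixtures:
30 frames, jitter 0.3 Å (a conservative stand-in for post-alignment
backbone fluctuation), swing amplitude 20° for the mutant-like
trajectory, and a 7.8 Å displacement of Lys1051 in the moving chain
(comparable to the ~8.6 Å distance changes the DDM is meant to
resolve). What passing tests show — and what they do not: the planted
swing is detected at a 9–15× margin over the jitter-only baseline and
the displaced residue ranks first, demonstrating that the analysis
chain recovers planted kinematic truth; this says nothing about force
fields, sampling convergence, or whether the real mutant moves this
way.

## Enzyme kinetics

Activity versus substrate follows the Hill model
`v(S) = Vmax·S^h / (EC50^h + S^h)` with Vmax in pmol cGMP/(µg total
protein·min), EC50 in mM and dimensionless cooperativity h; `v(0) = 0`.

**Fitting.** `fit_hill` minimises the residual sum of squares with
bounded trust-region least squares (SciPy `least_squares`, tolerances
1e-14). Initialisation is a fixed, deterministic multi-start:
a₀ = max activity, c₀ = the linearly interpolated substrate at half
maximum, h₀ ∈ {1, 2}; bounds a ∈ (0, 10·a₀], c ∈ (0, 2·max S],
h ∈ [0.5, 5]. The start with the lowest RSS wins, so the fit is a pure
function of the data. Points at S = 0 participate with model value 0.
Degenerate input (all-zero activities) raises; non-convergence from all
starts is reported in the result, not raised.

**Linearization.** Because of cooperativity the classical
Lineweaver–Burk plot (1/v vs 1/S) is curved; weighting the abscissa as
1/S^h restores a straight line with intercept 1/Vmax and slope
EC50^h/Vmax. `hill_linearization` takes h as an explicit argument
(mirroring the workflow of linearizing with the per-condition apparent
Hill coefficient rather than re-fitting) and performs ordinary least
squares, excluding S = 0 (undefined abscissa) and dropping v ≤ 0 points
with a warning. On noiseless Hill data with matching h the identity is
exact: `km_app = (slope/intercept)^(1/h) = EC50`, `vmax_lb = Vmax`,
r² = 1 — the "apparent KM equals EC50" observation as an algebraic
limit, which the tests assert to 1e-6 mM.

**Catalytic parameters.** `catalytic_efficiency(kcat, km)` returns
kcat/KM in M⁻¹ s⁻¹ (KM given in mM, hence the 10⁻³ factor).
`kcat_from_vmax` converts specific activity to a turnover number,
`kcat = Vmax·10⁻¹²·M / (f·10⁻⁶·60)` s⁻¹, where M is the monomer mass
(g/mol) and f the enzyme fraction of total membrane protein (µg/µg)
obtained from the immunoblot calibration; the formula is exposed for
forward use, while the pipeline also accepts externally determined kcat
values per condition. One published inconsistency is documented rather
than reconciled: the V902L+GCAP2 row prints an efficiency of 2.2×10³
whereas 0.7 s⁻¹ / 0.31 mM = 2.26×10³, presumably computed from
unrounded fit values; no check asserts that entry.

**Calibration.** `fit_calibration` is OLS of band intensity on protein
amount over the 20–400 ng standard range; `quantify_from_calibration`
inverts the line and flags amounts outside the standard range as
extrapolated.

**Synthetic assays.** The kinetics generator inverts the fit: it
evaluates the Hill model on a substrate grid within the assayed 0–4 mM
range (default: 0 plus a 20-point geometric grid from 0.05 to 4 mM in
the drivers) and applies multiplicative Gaussian noise
`v·(1 + ε), ε ~ N(0, noise_sd)`; activity at S = 0 is exactly zero.
Noiseless generation followed by refitting recovers the generator
parameters to 1e-3 relative — the loop-closure property the headline
checks rely on. The 2%-noise fixtures show realistic estimator scatter
(median EC50 error < 5% over 50 seeds).

## File formats and numerical conventions

* Internal coordinates are Å throughout; only DDMs are reported in nm
  (two-decimal display, full precision in files).
* Multi-model PDB I/O goes through biotite: first altloc kept, HETATM
  dropped, occupancy/B-factor written 1.00/0.00, coordinates rendered
  to three decimals; a coordinate outside the fixed-width field
  (±9999.999/−999.999 Å) is rejected, never truncated. A one-frame
  trajectory is written as a conventional single-model PDB.
* A minimal XYZ block format is supported for trajectories; it carries
  no residue metadata, so reading it without a topology synthesises a
  placeholder (single chain, one residue per atom).
* Every pipeline run writes a provenance block (config SHA-256, seed,
  package and NumPy versions) so deterministic stages reproduce
  byte-for-byte.

## Problem sizes

The analysis drivers and the test suite run on 240-atom dimer templates
(60 residues), 30-frame trajectories, and 20-point saturation grids;
Monte-Carlo checks use 50–1000 replicates. These sizes were chosen so
that every statistical property they probe (fit recovery, noise
scaling, detection margins) is already stable at desk scale.

## Known limitations

* The generator is kinematic; it cannot emulate correlated thermal
  motion, anharmonicity, or solvent effects, and jitter is isotropic
  and uncorrelated between atoms and frames.
* The projection plane is inherited from the alignment reference; two
  trajectories are comparable in the same plane only if aligned to a
  common reference (the drivers compare summary statistics, which are
  insensitive to an in-plane rotation of the trace).
* The Hill fit assumes homoscedastic absolute error; the generator's
  multiplicative noise is mildly heteroscedastic, which the tests
  absorb at the 5% median-error level rather than modelling weights.
* DCD/XTC binary trajectory formats, PDBx/mmCIF, PCA/essential-dynamics
  decomposition, Ca²⁺-dependence (IC50) analysis and global
  multi-condition fitting are out of scope.
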