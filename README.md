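# gce-dynamics

Conformational-dynamics and enzyme-kinetics analysis of the
photoreceptor membrane guanylate cyclase **GC-E** (ROS-GC1/retGC1), the
homodimeric enzyme that resynthesises cGMP in rod and cone
photoreceptors. GC-E is switched on by Ca²⁺-sensor proteins (GCAPs),
and the point mutation V902L (bovine numbering V907L) locks it in a
constitutively active state associated with cone–rod dystrophy. This
package provides the analysis machinery for asking two questions about
that switch:

* **How does the catalytic domain move?** Iterative Kabsch
  superposition of dimer trajectories, projection of the
  catalytic-domain center in a hinge-centered frame (hinge residue 818,
  just before the dimerization helix), and difference distance matrices
  (DDMs) over the eight GTP-binding-site residues (Asp890, Arg981,
  Ala1013, Lys1051 × two subunits).
* **How efficient is the enzyme?** Hill fits of activity vs. Mg-GTP,
  `v(S) = Vmax·S^h/(EC50^h + S^h)`, Hill-weighted Lineweaver–Burk
  linearization (1/v vs 1/S^h), immunoblot calibration, and catalytic
  parameters kcat and kcat/KM.

Because no trajectories or raw assay points are available for the
original study system, a first-class synthetic-data module generates
coarse C2-symmetric homodimer trajectories with controllable domain
swing, residue displacement and thermal jitter, plus noisy saturation
datasets — all seeded and reproducible — so every analysis stage is
validated against planted ground truth. See `docs/methods.md` for the
models, conventions and their limitations.

## Worked example

Simulate a jitter-only control and a mutant-like trajectory whose
catalytic domain swings 20° about the hinge while Lys1051 of one
subunit is displaced, then run the projection analysis:

```sh
gcedyn simulate --out wt.pdb  --seed 1 --n-frames 30 --jitter 0.3
gcedyn simulate --out mut.pdb --seed 2 --n-frames 30 --jitter 0.3 \
       --swing 20 --displace B:1051:6,4,3
gcedyn project --traj wt.pdb  --ccd 881-1060 --out wt_trace.csv
gcedyn project --traj mut.pdb --ccd 881-1060 --out mut_trace.csv
```

which prints (deterministic given the seeds):

```
trace of 30 frames; max displacement 1.175 A, hull area 2.401 A^2
trace of 30 frames; max displacement 19.027 A, hull area 29.421 A^2
```

The control's catalytic-domain center wanders ~1.2 Å (alignment noise
from thermal jitter, amplified by the ~100 Å dimerization-helix lever
arm), while the planted swing carries the mutant's center ~19 Å away —
the conformational contrast the projection is designed to expose. The
same pair of trajectories feeds the DDM:

```sh
gcedyn ddm --traj-a mut.pdb --traj-b wt.pdb --out ddm.csv --ranking rank.csv
# 8x8 difference distance matrix; largest mean |change| 0.948 nm at B:981 ARG
```

Here the whole-domain swing dominates, so the largest average distance
changes sit in the swinging subunit B; run the displacement without the
swing (drop `--swing 20`) and the planted Lys1051 tops the ranking
instead.

The equivalent library calls live in the numbered drivers under
`analysis/` (`01_simulate_fixtures.py` … `05_kinetics_table.py`), which
regenerate all tables under `results/` (bulky trajectory files go to
`scratch/`). The kinetics driver fits the four published catalytic
conditions from noiseless synthetic curves and reproduces the
generator truth to rounding, e.g. Vmax 11.33 pmol/(µg·min) and
EC50 0.37 mM for the GCAP1-activated wild type with Hill coefficient
2.07, and kcat/KM = 4.0 × 10³ M⁻¹s⁻¹ for V902L + GCAP1.

## Layout

```
src/gce_dynamics/     structure_io, synthetic_data, alignment,
                      domain_geometry, ddm, kinetics, pipeline, cli
analysis/             numbered narrative drivers (simulate → kinetics table)
tests/                pytest suite incl. planted-truth recovery checks
scripts/acceptance.py headline-number recomputation
docs/methods.md       models, conventions, limitations
```
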