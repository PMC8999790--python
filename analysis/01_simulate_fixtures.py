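"""Generate the synthetic study inputs.

Builds the coarse C2-symmetric homodimer template (kinase homology,
dimerization-helix and catalytic domains; hinge residue 818) and writes
three 30-frame trajectories:

  * wt.pdb        - thermal jitter only (wild-type-like control)
  * mutant.pdb    - jitter + a 20-degree catalytic-domain swing of one
                    subunit + a displaced Lys1051 (mutant-like)
  * displaced.pdb - jitter + the Lys1051 displacement alone (the planted
                    binding-site signal for the difference-distance run)

plus noiseless and 2%-noise saturation datasets for the four published
catalytic conditions.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gce_dynamics.kinetics import hill_activity
from gce_dynamics.structure_io import write_trajectory
from gce_dynamics.synthetic_data import (
    DomainDefinition,
    KineticsParams,
    MotionSpec,
    build_dimer_template,
    simulate_kinetics,
    simulate_trajectory,
)

SEED = 2026
N_FRAMES = 30
JITTER_SD = 0.3  # A
SWING_DEG = 20.0
DISPLACEMENT = ("B", 1051, (6.0, 4.0, 3.0))  # |v| = 7.8 A

CONDITIONS = {
    "WT GC-E + GCAP1": (11.33, 0.37, 2.07),
    "V902L + GCAP1": (9.0, 0.20, 1.75),
    "V902L + GCAP2": (7.32, 0.36, 1.76),
    "V902L no GCAPs": (7.36, 0.37, 1.58),
}
S_GRID = tuple([0.0] + list(np.geomspace(0.05, 4.0, 20)))

BASE = Path(__file__).resolve().parent.parent
TRAJ_OUT = BASE / "scratch" / "fixtures"  # multi-model PDBs are bulky; regenerable
OUT = BASE / "results" / "fixtures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    TRAJ_OUT.mkdir(parents=True, exist_ok=True)
    domains = DomainDefinition()
    template = build_dimer_template(domains)
    print(f"template: {template.n_atoms} atoms, chains {template.chains}, "
          f"{len(template.residues())} residues")

    motions = {
        "wt": MotionSpec(seed=SEED, jitter_sd=JITTER_SD),
        "mutant": MotionSpec(
            seed=SEED + 1, jitter_sd=JITTER_SD, swing_amplitude=SWING_DEG,
            displaced_residue=DISPLACEMENT,
        ),
        "displaced": MotionSpec(
            seed=SEED + 2, jitter_sd=JITTER_SD, displaced_residue=DISPLACEMENT
        ),
    }
    for name, motion in motions.items():
        traj = simulate_trajectory(template, domains, motion, N_FRAMES)
        path = TRAJ_OUT / f"{name}.pdb"
        write_trajectory(traj, path)
        print(f"wrote {path.name}: {traj.frame_count} frames "
              f"(jitter {motion.jitter_sd} A, swing {motion.swing_amplitude} deg)")

    rows = []
    for noise, tag in ((0.0, "noiseless"), (0.02, "noisy")):
        for i, (condition, (vmax, ec50, h)) in enumerate(CONDITIONS.items()):
            params = KineticsParams(
                a=vmax, c=ec50, h=h, seed=SEED + 10 + i, noise_sd=noise,
                s_grid=S_GRID,
            )
            data = simulate_kinetics(params, condition=condition)
            rows.append(
                pd.DataFrame(
                    {
                        "substrate_mM": data.substrate,
                        "activity_pmol_per_ug_min": data.activity,
                        "condition": data.condition,
                        "noise": tag,
                    }
                )
            )
    assay = pd.concat(rows, ignore_index=True)
    for tag, group in assay.groupby("noise"):
        path = OUT / f"assay_{tag}.csv"
        group.drop(columns="noise").to_csv(path, index=False)
        print(f"wrote {path.name}: {len(group)} points, "
              f"{group['condition'].nunique()} conditions")


if __name__ == "__main__":
    main()
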