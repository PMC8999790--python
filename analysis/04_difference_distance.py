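"""Binding-site difference distance matrix: control vs. planted displacement.

Averages the pairwise distances between the eight GTP-binding-site
backbone carbons (Asp890, Arg981, Ala1013, Lys1051 on each subunit)
over each trajectory, forms the element-wise difference, and ranks the
residues by mean absolute distance change.  The planted Lys1051
displacement in subunit B should top the ranking while subunit A's
intra-block entries stay near zero - the asymmetric-subunit signature.
"""

from pathlib import Path

from gce_dynamics.pipeline import RunConfig, run_ddm_analysis

BASE = Path(__file__).resolve().parent.parent
FIXTURES = BASE / "scratch" / "fixtures"
OUT = BASE / "results" / "ddm"


def main() -> None:
    config = RunConfig(
        seed=2026,
        out_dir=OUT,
        trajectory_a=FIXTURES / "displaced.pdb",
        trajectory_b=FIXTURES / "wt.pdb",
    )
    ddm, ranking, files = run_ddm_analysis(config)
    print(f"{ddm.n}x{ddm.n} difference distance matrix (nm) -> {files['ddm']}")
    print("residue ranking by mean |distance change| (nm):")
    for (chain, number, name), score in ranking:
        print(f"  {chain}:{number:>4} {name:<3}  {score:6.3f}")
    import numpy as np

    intra_a = float(np.abs(ddm.values[:4, :4]).max())
    print(f"largest intra-subunit-A entry: {intra_a:.4f} nm "
          f"({'quiet, as planted' if intra_a < 0.02 else 'unexpected signal'})")
    top = ranking[0][0]
    print(f"top residue: {top[0]}:{top[1]} {top[2]} "
          f"({'matches the planted displacement' if top[1] == 1051 else 'UNEXPECTED'})")


if __name__ == "__main__":
    main()
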