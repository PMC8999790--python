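"""End-to-end orchestration of the projection, DDM and kinetics analyses.

A single ``RunConfig`` (loadable from YAML) names the input
trajectories and assay tables, the residue selections (kinase homology
domain for alignment, catalytic domain for projection, binding-site
residues for the DDM), the alignment tolerance, a residue-numbering
offset (human positions are 5 below the bovine numbering used by the
modeled structure) and the seed.  Each run writes its outputs next to
a machine-readable provenance block (config hash, seed, package and
library versions) so deterministic stages reproduce byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from gce_dynamics import __version__
from gce_dynamics.alignment import AlignmentResult, align_trajectory
from gce_dynamics.ddm import (
    DifferenceDistanceMatrix,
    difference_distance_matrix,
    mean_distance_matrix,
    residue_displacement_ranking,
)
from gce_dynamics.domain_geometry import (
    ProjectionTrace,
    TraceSummary,
    center_on_hinge,
    project_catalytic_center,
    summarize_trace,
)
from gce_dynamics.errors import ConfigurationError, StructuralMismatchError
from gce_dynamics.kinetics import (
    KineticsDataset,
    catalytic_efficiency,
    fit_hill,
    hill_linearization,
    kcat_from_vmax,
)
from gce_dynamics.structure_io import (
    Selection,
    Structure,
    Trajectory,
    read_trajectory,
    select_backbone_carbon,
)

__all__ = [
    "RunConfig",
    "run_projection_analysis",
    "run_ddm_analysis",
    "run_kinetics_analysis",
    "parse_residue_spec",
    "resolve_dimer_selection",
]

logger = logging.getLogger("gce_dynamics")

#: Catalytic-parameter output columns for the kinetics stage.
KINETICS_COLUMNS = [
    "condition",
    "vmax_pmol_per_ug_min",
    "ec50_mM",
    "km_app_mM",
    "kcat_per_s",
    "kcat_over_km_e3",
    "hill_h",
    "r_squared_linearization",
    "fit_converged",
    "error",
]


def parse_residue_spec(spec: int | str | Sequence[int | str]) -> list[int]:
    """Expand residue specs like ``"770-818"`` or ``[890, "981-1013"]``."""
    if isinstance(spec, (int, np.integer)):
        return [int(spec)]
    if isinstance(spec, str):
        out: list[int] = []
        for token in spec.replace(" ", "").split(","):
            if not token:
                continue
            if "-" in token[1:]:
                lo, hi = token.split("-", 1)
                out.extend(range(int(lo), int(hi) + 1))
            else:
                out.append(int(token))
        return out
    out = []
    for item in spec:
        out.extend(parse_residue_spec(item))
    return out


@dataclass
class RunConfig:
    """Inputs, selections and parameters for one analysis run."""

    seed: int
    out_dir: Path = Path("results")
    trajectory_a: Path | None = None
    trajectory_b: Path | None = None
    khd_residues: list[int] = field(default_factory=lambda: list(range(770, 819)))
    ccd_residues: list[int] = field(default_factory=lambda: list(range(881, 1061)))
    binding_site_residues: list[int] = field(
        default_factory=lambda: [890, 981, 1013, 1051]
    )
    hinge_residue: int = 818
    chains: tuple[str, str] = ("A", "B")
    tolerance: float = 0.01
    max_iter: int = 100
    numbering_offset: int = 0
    align_for_ddm: bool = True
    kinetics_csv: Path | None = None
    kcat: dict[str, float] = field(default_factory=dict)
    gc_fraction: float | None = None
    monomer_mass: float | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        self.trajectory_a = Path(self.trajectory_a) if self.trajectory_a else None
        self.trajectory_b = Path(self.trajectory_b) if self.trajectory_b else None
        self.kinetics_csv = Path(self.kinetics_csv) if self.kinetics_csv else None
        self.khd_residues = parse_residue_spec(self.khd_residues)
        self.ccd_residues = parse_residue_spec(self.ccd_residues)
        self.binding_site_residues = parse_residue_spec(self.binding_site_residues)
        self.chains = tuple(self.chains)  # type: ignore[assignment]
        if self.tolerance <= 0:
            raise ConfigurationError("alignment tolerance must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "seed" not in raw:
            raise ConfigurationError("config must state a seed explicitly")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def offset_residue(self, residue: int) -> int:
        """Map a configured residue number into the structure's numbering."""
        return residue + self.numbering_offset

    def digest(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def resolve_dimer_selection(
    topology: Structure,
    residues: Sequence[int],
    chains: Sequence[str],
    offset: int = 0,
    atom_name: str = "CA",
    skip_missing: bool = False,
) -> Selection:
    """Backbone-carbon selection of the given residues on every chain.

    Residues are resolved chain-by-chain (first chain's residues first,
    matching the dimer block layout of the DDM).  ``offset`` shifts the
    configured numbers into the structure's numbering scheme.
    ``skip_missing`` drops residues a chain does not contain instead of
    raising, which lets coarse templates use range-style selections.
    """
    present = {(a.chain_id, a.residue_number) for a in topology.atoms}
    pairs: list[tuple[str, int]] = []
    for chain in chains:
        for residue in residues:
            key = (chain, residue + offset)
            if skip_missing and key not in present:
                continue
            pairs.append(key)
    if not pairs:
        raise ConfigurationError(
            "selection resolved to zero residues; check residue numbers and offset"
        )
    return select_backbone_carbon(topology, pairs, atom_name=atom_name)


def _write_provenance(config: RunConfig, stage: str, out_dir: Path) -> Path:
    payload = {
        "stage": stage,
        "config_sha256": config.digest(),
        "seed": config.seed,
        "versions": {
            "gce_dynamics": __version__,
            "numpy": np.__version__,
        },
        "config": {k: str(v) for k, v in asdict(config).items()},
    }
    path = out_dir / f"provenance_{stage}.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def _load_trajectory(path: Path) -> Trajectory:
    fmt = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    return read_trajectory(path, format=fmt)


def run_projection_analysis(
    config: RunConfig, traj: Trajectory | None = None
) -> tuple[ProjectionTrace, TraceSummary, dict[str, Path]]:
    """Alignment on the KHD, hinge centering, projection and trace summary.

    Composes ``align_trajectory`` (kinase-homology-domain selection) ->
    ``center_on_hinge`` -> ``project_catalytic_center`` ->
    ``summarize_trace`` and writes ``trace.csv``, ``summary.json`` and
    an alignment report.
    """
    t0 = time.perf_counter()
    if traj is None:
        if config.trajectory_a is None:
            raise ConfigurationError("projection analysis needs trajectory_a")
        traj = _load_trajectory(config.trajectory_a)

    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        khd_sel = resolve_dimer_selection(
            traj.topology,
            config.khd_residues,
            config.chains,
            config.numbering_offset,
            skip_missing=True,
        )
        aligned, align_result = align_trajectory(
            traj, khd_sel, tolerance=config.tolerance, max_iter=config.max_iter
        )
        hinge = (
            config.chains[0],
            config.chains[1],
            config.offset_residue(config.hinge_residue),
        )
        centered = center_on_hinge(aligned, hinge)
        ccd_sel = resolve_dimer_selection(
            centered.topology,
            config.ccd_residues,
            config.chains,
            config.numbering_offset,
            skip_missing=True,
        )
        trace = project_catalytic_center(centered, ccd_sel, hinge=hinge)
        summary = summarize_trace(trace)
    except Exception as exc:
        raise type(exc)(f"[projection] {exc}") from exc

    trace_df = pd.DataFrame(
        {
            "frame": trace.frame_ids,
            "x": trace.points[:, 0],
            "y": trace.points[:, 1],
            "z": trace.z_values,
        }
    )
    files = {
        "trace": out_dir / "trace.csv",
        "summary": out_dir / "summary.json",
        "alignment": out_dir / "align_report.json",
        "provenance": _write_provenance(config, "projection", out_dir),
    }
    trace_df.to_csv(files["trace"], index=False)
    files["summary"].write_text(
        json.dumps(
            {
                "centroid_x": summary.centroid[0],
                "centroid_y": summary.centroid[1],
                "max_displacement_from_start_A": summary.max_displacement_from_start,
                "convex_hull_area_A2": summary.convex_hull_area,
                "net_drift_A": summary.net_drift,
                "hinge_residue": trace.hinge_label,
            },
            indent=2,
        )
    )
    files["alignment"].write_text(json.dumps(_align_report(align_result), indent=2))
    logger.info(
        "projection analysis: %d frames, alignment %s in %d iteration(s), %.2f s",
        traj.frame_count,
        "converged" if align_result.converged else "NOT converged",
        align_result.iterations,
        time.perf_counter() - t0,
    )
    return trace, summary, files


def _align_report(result: AlignmentResult) -> dict[str, Any]:
    return {
        "iterations": result.iterations,
        "converged": result.converged,
        "rmsd_per_frame_A": [float(r) for r in result.rmsd_per_frame],
        "mean_rmsd_A": float(result.rmsd_per_frame.mean()),
    }


def run_ddm_analysis(
    config: RunConfig,
    traj_a: Trajectory | None = None,
    traj_b: Trajectory | None = None,
) -> tuple[
    DifferenceDistanceMatrix,
    list[tuple[tuple[str, int, str], float]],
    dict[str, Path],
]:
    """Binding-site difference distance matrix between two trajectories.

    Each trajectory is (optionally) aligned over all residues, averaged
    into a binding-site distance matrix, differenced A - B, and the
    residues are ranked by mean absolute distance change.
    """
    t0 = time.perf_counter()
    if traj_a is None:
        if config.trajectory_a is None:
            raise ConfigurationError("DDM analysis needs trajectory_a")
        traj_a = _load_trajectory(config.trajectory_a)
    if traj_b is None:
        if config.trajectory_b is None:
            raise ConfigurationError("DDM analysis needs trajectory_b")
        traj_b = _load_trajectory(config.trajectory_b)

    labels_a = [a.label + (a.atom_name,) for a in traj_a.topology.atoms]
    labels_b = [a.label + (a.atom_name,) for a in traj_b.topology.atoms]
    if labels_a != labels_b:
        raise StructuralMismatchError(
            "[ddm] the two trajectories have different topologies"
        )

    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    def _process(traj: Trajectory):
        if config.align_for_ddm:
            all_residues = sorted(
                {a.residue_number for a in traj.topology.atoms}
            )
            sel = resolve_dimer_selection(
                traj.topology, all_residues, config.chains, offset=0, skip_missing=True
            )
            traj, _ = align_trajectory(
                traj, sel, tolerance=config.tolerance, max_iter=config.max_iter
            )
        site = resolve_dimer_selection(
            traj.topology,
            config.binding_site_residues,
            config.chains,
            config.numbering_offset,
        )
        return mean_distance_matrix(traj, site)

    try:
        dm_a = _process(traj_a)
        dm_b = _process(traj_b)
        ddm = difference_distance_matrix(
            dm_a,
            dm_b,
            source_a=str(config.trajectory_a or "A"),
            source_b=str(config.trajectory_b or "B"),
        )
        ranking = residue_displacement_ranking(ddm)
    except Exception as exc:
        raise type(exc)(f"[ddm] {exc}") from exc

    label_strs = [f"{c}:{n}:{name}" for c, n, name in ddm.labels]
    ddm_df = pd.DataFrame(ddm.values, index=label_strs, columns=label_strs)
    rank_df = pd.DataFrame(
        {
            "chain": [lab[0] for lab, _ in ranking],
            "residue_number": [lab[1] for lab, _ in ranking],
            "residue_name": [lab[2] for lab, _ in ranking],
            "mean_abs_distance_change_nm": [score for _, score in ranking],
        }
    )
    files = {
        "ddm": out_dir / "ddm.csv",
        "ranking": out_dir / "ranking.csv",
        "provenance": _write_provenance(config, "ddm", out_dir),
    }
    ddm_df.to_csv(files["ddm"])
    rank_df.to_csv(files["ranking"], index=False)
    logger.info(
        "ddm analysis: %dx%d matrix, top residue %s (%.3f nm), %.2f s",
        ddm.n,
        ddm.n,
        ranking[0][0],
        ranking[0][1],
        time.perf_counter() - t0,
    )
    return ddm, ranking, files


def load_kinetics_csv(path: str | Path) -> list[KineticsDataset]:
    """Read saturation datasets from a CSV with one block per condition.

    Expected columns: ``substrate_mM``, ``activity_pmol_per_ug_min``,
    ``condition``.  Conditions are returned in sorted order.
    """
    df = pd.read_csv(path)
    required = {"substrate_mM", "activity_pmol_per_ug_min", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"kinetics CSV lacks columns: {sorted(missing)}")
    datasets = []
    for condition, group in sorted(df.groupby("condition"), key=lambda kv: str(kv[0])):
        datasets.append(
            KineticsDataset(
                substrate=group["substrate_mM"].to_numpy(float),
                activity=group["activity_pmol_per_ug_min"].to_numpy(float),
                condition=str(condition),
            )
        )
    return datasets


def run_kinetics_analysis(
    config: RunConfig, datasets: Sequence[KineticsDataset] | None = None
) -> pd.DataFrame:
    """Fit every condition and emit one catalytic-parameter row per condition.

    Per condition: nonlinear Hill fit, Hill-weighted linearization with
    the fitted h (apparent KM), kcat taken from the config (or derived
    from Vmax via the calibrated enzyme fraction and monomer mass when
    both are configured), and catalytic efficiency kcat/KM.  Fit
    failures are recorded in-row; the run continues.
    """
    if datasets is None:
        if config.kinetics_csv is None:
            raise ConfigurationError("kinetics analysis needs kinetics_csv")
        datasets = load_kinetics_csv(config.kinetics_csv)
    if not len(datasets):
        raise ConfigurationError("kinetics analysis needs at least one condition")

    rows: list[dict[str, Any]] = []
    for data in sorted(datasets, key=lambda d: d.condition):
        row: dict[str, Any] = {c: np.nan for c in KINETICS_COLUMNS}
        row["condition"] = data.condition
        row["error"] = ""
        try:
            fit = fit_hill(data)
            lin = hill_linearization(data, fit.h)
            kcat = config.kcat.get(data.condition)
            if kcat is None and config.gc_fraction and config.monomer_mass:
                kcat = kcat_from_vmax(
                    fit.vmax, config.gc_fraction, config.monomer_mass
                )
            row.update(
                vmax_pmol_per_ug_min=fit.vmax,
                ec50_mM=fit.ec50,
                km_app_mM=lin.km_app,
                hill_h=fit.h,
                r_squared_linearization=lin.r_squared,
                fit_converged=fit.converged,
            )
            if kcat is not None:
                row["kcat_per_s"] = kcat
                row["kcat_over_km_e3"] = catalytic_efficiency(kcat, lin.km_app) / 1e3
        except Exception as exc:  # recorded per condition, run continues
            row["error"] = f"{type(exc).__name__}: {exc}"
            row["fit_converged"] = False
            logger.warning("kinetics condition %r failed: %s", data.condition, exc)
        rows.append(row)

    table = pd.DataFrame(rows, columns=KINETICS_COLUMNS)
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / "kinetics_table.csv", index=False)
    _write_provenance(config, "kinetics", out_dir)
    return table
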