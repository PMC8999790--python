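"""Hinge-centered framing and catalytic-domain motion projection.

The homodimer is translated so the midpoint of the two hinge-residue
alpha-carbons (residue 818 in bovine numbering, one per chain, sitting
just before the dimerization helix) is the coordinate origin.  For each
frame the geometric center of the catalytic-domain selection defines the
endpoint of a line segment from the origin; projecting those endpoints
onto the x-y plane traces the area in which the catalytic domain moves
relative to the kinase homology domain.  No additional reorientation is
applied: the projection plane is the x-y plane of the post-alignment
coordinate frame.

``helix_rotation_angle`` covers the alpha-helix arithmetic used for
alanine-insertion constructs: an ideal helix has 3.6 residues per turn,
so each inserted residue rotates the downstream helix by 360/3.6 = 100
degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from gce_dynamics.errors import EmptyInputError
from gce_dynamics.structure_io import Selection, Trajectory, select_backbone_carbon

__all__ = [
    "ProjectionTrace",
    "TraceSummary",
    "center_on_hinge",
    "project_catalytic_center",
    "summarize_trace",
    "helix_rotation_angle",
]

#: Residues per turn of an ideal alpha-helix.
_HELIX_RESIDUES_PER_TURN = 3.6


@dataclass
class ProjectionTrace:
    """Per-frame (x, y) position of the catalytic-domain center, hinge at origin."""

    points: np.ndarray  # (n_frames, 2), A
    z_values: np.ndarray  # (n_frames,), A
    hinge_label: int
    frame_ids: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.frame_ids = np.asarray(self.frame_ids, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (n_frames, 2)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("trace points must be finite")
        if len(self.points) != len(self.z_values) or len(self.points) != len(
            self.frame_ids
        ):
            raise ValueError("points, z_values and frame_ids must be parallel")


@dataclass
class TraceSummary:
    centroid: tuple[float, float]
    max_displacement_from_start: float  # A
    convex_hull_area: float  # A^2
    net_drift: float  # A


def center_on_hinge(
    traj: Trajectory,
    hinge: tuple[str, str, int],
    atom_name: str = "CA",
) -> Trajectory:
    """Translate every frame so the two-chain hinge midpoint is the origin.

    ``hinge`` names the two chains and the shared residue number whose
    backbone-carbon midpoint defines the origin.  Only a translation is
    applied, independently per frame.
    """
    chain_a, chain_b, resnum = hinge
    sel = select_backbone_carbon(
        traj.topology, [(chain_a, resnum), (chain_b, resnum)], atom_name=atom_name
    )
    midpoints = traj.frames[:, sel.atom_indices, :].mean(axis=1)
    return traj.with_frames(traj.frames - midpoints[:, None, :])


def project_catalytic_center(
    traj: Trajectory,
    ccd_selection: Selection,
    hinge: tuple[str, str, int] | None = ("A", "B", 818),
    hinge_atom_name: str = "CA",
) -> ProjectionTrace:
    """Trace the catalytic-domain geometric center in the hinge frame.

    The trajectory must already be hinge-centered; when ``hinge`` is
    given this is asserted (midpoint within 1e-6 A of the origin).  The
    geometric center is the unweighted mean of the selection's atom
    coordinates; its (x, y) components form the trace and z is retained
    separately.
    """
    hinge_label = 0
    if hinge is not None:
        chain_a, chain_b, resnum = hinge
        hinge_label = int(resnum)
        sel = select_backbone_carbon(
            traj.topology, [(chain_a, resnum), (chain_b, resnum)], atom_name=hinge_atom_name
        )
        midpoints = traj.frames[:, sel.atom_indices, :].mean(axis=1)
        worst = float(np.abs(midpoints).max())
        if worst > 1e-6:
            raise ValueError(
                f"trajectory is not hinge-centered (hinge midpoint up to "
                f"{worst:.3e} A from origin); run center_on_hinge first"
            )
    centers = traj.frames[:, ccd_selection.atom_indices, :].mean(axis=1)
    return ProjectionTrace(
        points=centers[:, :2],
        z_values=centers[:, 2],
        hinge_label=hinge_label,
        frame_ids=np.arange(traj.frame_count),
    )


def summarize_trace(trace: ProjectionTrace, stride: int = 1) -> TraceSummary:
    """Summary statistics of a 2D projection trace.

    ``max_displacement_from_start`` is the largest distance of any point
    from the first point, ``net_drift`` the distance between last and
    first point, and ``convex_hull_area`` the area swept by the trace
    (zero for fewer than three distinct points).  ``stride`` thins dense
    trajectories before the hull computation.
    """
    pts = trace.points[::stride]
    if len(pts) == 0:
        raise EmptyInputError("trace contains no points")
    centroid = pts.mean(axis=0)
    displacements = np.linalg.norm(pts - pts[0], axis=1)
    area = _hull_area(pts)
    return TraceSummary(
        centroid=(float(centroid[0]), float(centroid[1])),
        max_displacement_from_start=float(displacements.max()),
        convex_hull_area=area,
        net_drift=float(displacements[-1]),
    )


def _hull_area(points: np.ndarray) -> float:
    distinct = np.unique(points, axis=0)
    if len(distinct) < 3:
        return 0.0
    try:
        hull = ConvexHull(distinct)
    except QhullError:
        return 0.0  # collinear points enclose no area
    # for 2D inputs ConvexHull.volume is the enclosed area
    return float(hull.volume)


def helix_rotation_angle(n_inserted: int) -> tuple[float, float]:
    """Cumulative and net helix rotation caused by inserted residues.

    Each residue inserted into an ideal alpha-helix (3.6 residues/turn)
    rotates the downstream part by 360/3.6 = 100 degrees.  Returns the
    cumulative rotation ``n * 100`` and its value modulo 360.  Note that
    four insertions give a cumulative 400 degrees, i.e. a net 40-degree
    offset rather than an exact full turn.
    """
    if n_inserted < 0:
        raise ValueError("number of inserted residues must be >= 0")
    per_residue = 360.0 / _HELIX_RESIDUES_PER_TURN
    cumulative = n_inserted * per_residue
    return cumulative, cumulative % 360.0
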