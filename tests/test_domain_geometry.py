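"""Hinge centering, catalytic-center projection, trace summaries, helix arithmetic."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gce_dynamics.alignment import align_trajectory
from gce_dynamics.domain_geometry import (
    ProjectionTrace,
    center_on_hinge,
    helix_rotation_angle,
    project_catalytic_center,
    summarize_trace,
)
from gce_dynamics.errors import EmptyInputError, SelectionError
from gce_dynamics.structure_io import (
    AtomRecord,
    Structure,
    Trajectory,
    select_backbone_carbon,
)
from gce_dynamics.synthetic_data import MotionSpec, simulate_trajectory


def _toy_dimer(length=5.0):
    """Minimal dimer: hinge CAs at +-x, one catalytic atom straight below."""
    atoms = [
        AtomRecord("A", 818, "GLY", "CA", np.array([1.0, 0.0, 0.0])),
        AtomRecord("B", 818, "GLY", "CA", np.array([-1.0, 0.0, 0.0])),
        AtomRecord("A", 1013, "ALA", "CA", np.array([0.0, 0.0, -length])),
    ]
    return Structure(atoms)


class TestCenterOnHinge:
    def test_midpoint_lands_exactly_at_origin(self, wt_like_trajectory):
        centered = center_on_hinge(wt_like_trajectory, ("A", "B", 818))
        sel = select_backbone_carbon(centered.topology, [("A", 818), ("B", 818)])
        midpoints = centered.frames[:, sel.atom_indices, :].mean(axis=1)
        assert np.abs(midpoints).max() < 1e-12

    def test_translation_invariance(self, wt_like_trajectory):
        shifted = wt_like_trajectory.with_frames(
            wt_like_trajectory.frames + np.array([7.0, -3.0, 2.0])
        )
        a = center_on_hinge(wt_like_trajectory, ("A", "B", 818))
        b = center_on_hinge(shifted, ("A", "B", 818))
        np.testing.assert_allclose(a.frames, b.frames, atol=1e-12)

    def test_missing_hinge_residue_is_lookup_error(self, wt_like_trajectory):
        with pytest.raises(SelectionError):
            center_on_hinge(wt_like_trajectory, ("A", "B", 4242))


class TestProjectCatalyticCenter:
    def test_static_trajectory_gives_constant_trace(self, template, domains):
        traj = simulate_trajectory(template, domains, MotionSpec(seed=1), 4)
        centered = center_on_hinge(traj, ("A", "B", 818))
        ccd = sorted(
            r for r in {a.residue_number for a in template.atoms}
            if domains.domain_of(r) == "CCD"
        )
        sel = select_backbone_carbon(centered.topology, [(c, r) for c in "AB" for r in ccd])
        trace = project_catalytic_center(centered, sel)
        assert np.abs(trace.points - trace.points[0]).max() < 1e-12

    def test_analytic_rotation_of_center(self):
        """A center at (0,0,-L) swung by theta about x lands at (0, L sinth)."""
        length, theta = 5.0, np.deg2rad(25.0)
        topo = _toy_dimer(length)
        rot = Rotation.from_euler("x", theta).as_matrix()  # takes -z toward +y
        frames = np.stack([topo.coords, topo.coords])
        frames[1, 2] = rot @ frames[1, 2]
        frames[1, :2] = frames[0, :2]  # hinge stays put
        traj = Trajectory(topo, frames)
        sel = select_backbone_carbon(topo, [("A", 1013)])
        trace = project_catalytic_center(traj, sel)
        np.testing.assert_allclose(trace.points[0], [0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(
            trace.points[1], [0.0, length * np.sin(theta)], atol=1e-9
        )
        assert trace.z_values[1] == pytest.approx(-length * np.cos(theta), abs=1e-9)

    def test_non_centered_input_rejected(self, wt_like_trajectory, domains):
        ccd = sorted(
            r
            for r in {a.residue_number for a in wt_like_trajectory.topology.atoms}
            if domains.domain_of(r) == "CCD"
        )
        sel = select_backbone_carbon(
            wt_like_trajectory.topology, [(c, r) for c in "AB" for r in ccd]
        )
        shifted = wt_like_trajectory.with_frames(wt_like_trajectory.frames + 5.0)
        with pytest.raises(ValueError, match="hinge-centered"):
            project_catalytic_center(shifted, sel)

    def _run_pipeline(self, t, domains):
        residues = sorted({a.residue_number for a in t.topology.atoms})
        khd = [r for r in residues if domains.domain_of(r) == "KHD"]
        ccd = [r for r in residues if domains.domain_of(r) == "CCD"]
        sel = select_backbone_carbon(t.topology, [(c, r) for c in "AB" for r in khd])
        aligned, _ = align_trajectory(t, sel, tolerance=1e-8)
        centered = center_on_hinge(aligned, ("A", "B", 818))
        csel = select_backbone_carbon(
            centered.topology, [(c, r) for c in "AB" for r in ccd]
        )
        return project_catalytic_center(centered, csel)

    def test_pipeline_invariant_under_global_translation(self, template, domains):
        """align -> center -> project is unchanged by a fixed translation."""
        motion = MotionSpec(seed=31, jitter_sd=0.3, swing_amplitude=15.0)
        traj = simulate_trajectory(template, domains, motion, 10)
        moved = traj.with_frames(traj.frames + np.array([12.0, -8.0, 3.0]))
        base = self._run_pipeline(traj, domains)
        shifted = self._run_pipeline(moved, domains)
        np.testing.assert_allclose(shifted.points, base.points, atol=1e-6)
        np.testing.assert_allclose(shifted.z_values, base.z_values, atol=1e-6)

    def test_pipeline_equivariant_under_global_rotation(self, template, domains):
        """A fixed rotation of every frame rotates the projected trace with it.

        The projection plane is the x-y plane of the alignment reference
        (frame 0), so rotating the whole input rotates that reference and
        the 3D catalytic-center trace equivariantly.
        """
        motion = MotionSpec(seed=31, jitter_sd=0.3, swing_amplitude=15.0)
        traj = simulate_trajectory(template, domains, motion, 10)
        rot = Rotation.from_euler("zyx", [40, -25, 65], degrees=True).as_matrix()
        moved = traj.with_frames(traj.frames @ rot.T + np.array([12.0, -8.0, 3.0]))
        base = self._run_pipeline(traj, domains)
        rotated = self._run_pipeline(moved, domains)
        centers_base = np.column_stack([base.points, base.z_values])
        centers_rot = np.column_stack([rotated.points, rotated.z_values])
        np.testing.assert_allclose(centers_rot, centers_base @ rot.T, atol=1e-6)


class TestSummarizeTrace:
    def _trace(self, points):
        points = np.asarray(points, dtype=float)
        return ProjectionTrace(
            points=points,
            z_values=np.zeros(len(points)),
            hinge_label=818,
            frame_ids=np.arange(len(points)),
        )

    def test_repeated_point_has_zero_extent(self):
        summary = summarize_trace(self._trace([[1.0, 2.0]] * 4))
        assert summary.convex_hull_area == 0.0
        assert summary.max_displacement_from_start == 0.0
        assert summary.net_drift == 0.0
        assert summary.centroid == (1.0, 2.0)

    def test_unit_square_hull_area(self):
        summary = summarize_trace(self._trace([[0, 0], [1, 0], [1, 1], [0, 1]]))
        assert summary.convex_hull_area == pytest.approx(1.0, abs=1e-12)

    def test_collinear_points_enclose_no_area(self):
        summary = summarize_trace(self._trace([[0, 0], [1, 1], [2, 2], [3, 3]]))
        assert summary.convex_hull_area == 0.0

    def test_planted_swing_net_drift_equals_chord(self):
        # points on an arc of radius L: drift = chord length 2 L sin(theta/2)
        length, theta = 6.0, np.deg2rad(30.0)
        angles = np.linspace(0.0, theta, 12)
        pts = np.column_stack([length * np.sin(angles), np.zeros(12)])
        pts[:, 1] = length * (1 - np.cos(angles))
        summary = summarize_trace(self._trace(pts))
        chord = 2 * length * np.sin(theta / 2)
        assert summary.net_drift == pytest.approx(chord, rel=1e-9)

    def test_empty_trace_rejected(self):
        trace = self._trace([[0.0, 0.0]])
        trace.points = trace.points[:0]
        trace.z_values = trace.z_values[:0]
        trace.frame_ids = trace.frame_ids[:0]
        with pytest.raises(EmptyInputError):
            summarize_trace(trace)


class TestSwingDetection:
    def test_planted_swing_exceeds_jitter_baseline(
        self, template, domains, wt_like_trajectory, mutant_like_trajectory
    ):
        """A 20-degree catalytic swing stands out against jitter-only motion."""
        residues = sorted({a.residue_number for a in template.atoms})
        khd = [r for r in residues if domains.domain_of(r) == "KHD"]
        ccd = [r for r in residues if domains.domain_of(r) == "CCD"]

        def max_disp(traj):
            sel = select_backbone_carbon(
                traj.topology, [(c, r) for c in "AB" for r in khd]
            )
            aligned, _ = align_trajectory(traj, sel)
            centered = center_on_hinge(aligned, ("A", "B", 818))
            csel = select_backbone_carbon(
                centered.topology, [(c, r) for c in "AB" for r in ccd]
            )
            trace = project_catalytic_center(centered, csel)
            return summarize_trace(trace).max_displacement_from_start

        baseline = max_disp(wt_like_trajectory)
        threshold = 3.0 * baseline
        swung = max_disp(mutant_like_trajectory)
        assert baseline < threshold  # jitter-only control sits below threshold
        assert swung > threshold  # the planted swing stands clear of it


@pytest.mark.parametrize(
    "n_inserted, expected",
    [(0, (0.0, 0.0)), (1, (100.0, 100.0)), (2, (200.0, 200.0)),
     (4, (400.0, 40.0)), (9, (900.0, 180.0))],
)
def test_helix_rotation_arithmetic(n_inserted, expected):
    cumulative, net = helix_rotation_angle(n_inserted)
    assert cumulative == pytest.approx(expected[0], abs=1e-12)
    assert net == pytest.approx(expected[1], abs=1e-12)


def test_helix_rotation_rejects_negative_insertions():
    with pytest.raises(ValueError):
        helix_rotation_angle(-1)
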