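"""Averaged distance matrices and difference distance matrices."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gce_dynamics.alignment import align_trajectory
from gce_dynamics.ddm import (
    DistanceMatrix,
    difference_distance_matrix,
    mean_distance_matrix,
    residue_displacement_ranking,
)
from gce_dynamics.errors import ConfigurationError, StructuralMismatchError
from gce_dynamics.structure_io import (
    AtomRecord,
    Structure,
    Trajectory,
    select_backbone_carbon,
)
from gce_dynamics.synthetic_data import MotionSpec, simulate_trajectory

BINDING_SITE = (890, 981, 1013, 1051)


def _site_selection(structure):
    return select_backbone_carbon(
        structure, [(c, r) for c in "AB" for r in BINDING_SITE]
    )


def _ca_structure(positions, numbers, chain="A"):
    atoms = [
        AtomRecord(chain, num, "GLY", "CA", np.asarray(pos, dtype=float))
        for num, pos in zip(numbers, positions)
    ]
    return Structure(atoms)


class TestMeanDistanceMatrix:
    def test_single_frame_two_atoms(self):
        topo = _ca_structure([[0, 0, 0], [5, 0, 0]], [1, 2])
        traj = Trajectory(topo, topo.coords[None])
        sel = select_backbone_carbon(topo, [("A", 1), ("A", 2)])
        dm = mean_distance_matrix(traj, sel)
        np.testing.assert_allclose(dm.values, [[0.0, 0.5], [0.5, 0.0]], atol=1e-12)

    def test_two_frame_average(self):
        topo = _ca_structure([[0, 0, 0], [4, 0, 0]], [1, 2])
        frames = np.stack([topo.coords, topo.coords])
        frames[1, 1, 0] = 6.0
        traj = Trajectory(topo, frames)
        sel = select_backbone_carbon(topo, [("A", 1), ("A", 2)])
        dm = mean_distance_matrix(traj, sel)
        assert dm.values[0, 1] == pytest.approx(0.5, abs=1e-12)  # (0.4+0.6)/2 nm

    def test_binding_site_matrix_is_8x8_zero_diagonal(self, wt_like_trajectory):
        dm = mean_distance_matrix(
            wt_like_trajectory, _site_selection(wt_like_trajectory.topology)
        )
        assert dm.values.shape == (8, 8)
        np.testing.assert_array_equal(np.diag(dm.values), 0.0)
        np.testing.assert_allclose(dm.values, dm.values.T, atol=1e-12)
        assert [(c, n) for c, n, _ in dm.labels] == [
            (c, r) for c in "AB" for r in BINDING_SITE
        ]

    def test_single_residue_selection_rejected(self, template):
        sel = select_backbone_carbon(template, [("A", 890)])
        traj = Trajectory(template, template.coords[None])
        with pytest.raises(ConfigurationError):
            mean_distance_matrix(traj, sel)

    def test_invariant_under_per_frame_rigid_motions(self, template, domains):
        """Distances survive arbitrary per-frame rotations+translations."""
        motion = MotionSpec(seed=41, swing_amplitude=18.0)
        base = simulate_trajectory(template, domains, motion, 12)
        rng = np.random.default_rng(8)
        frames = base.frames.copy()
        for k in range(frames.shape[0]):
            quat = rng.normal(size=4)
            rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
            frames[k] = frames[k] @ rot.T + rng.uniform(-30, 30, 3)
        moved = base.with_frames(frames)
        sel = _site_selection(template)
        dm_base = mean_distance_matrix(base, sel)
        dm_moved = mean_distance_matrix(moved, sel)
        assert np.abs(dm_base.values - dm_moved.values).max() < 1e-9


class TestDifferenceDistanceMatrix:
    def test_identical_inputs_give_zero_matrix(self, wt_like_trajectory):
        sel = _site_selection(wt_like_trajectory.topology)
        dm = mean_distance_matrix(wt_like_trajectory, sel)
        ddm = difference_distance_matrix(dm, dm)
        np.testing.assert_array_equal(ddm.values, 0.0)

    def test_antisymmetry_under_argument_swap(self, wt_like_trajectory, mutant_like_trajectory):
        sel = _site_selection(wt_like_trajectory.topology)
        a = mean_distance_matrix(wt_like_trajectory, sel)
        b = mean_distance_matrix(mutant_like_trajectory, sel)
        np.testing.assert_allclose(
            difference_distance_matrix(a, b).values,
            -difference_distance_matrix(b, a).values,
            atol=1e-15,
        )

    def test_label_mismatch_lists_differing_labels(self):
        topo = _ca_structure([[0, 0, 0], [3, 0, 0], [0, 4, 0]], [1, 2, 3])
        traj = Trajectory(topo, topo.coords[None])
        sel_a = select_backbone_carbon(topo, [("A", 1), ("A", 2)])
        sel_b = select_backbone_carbon(topo, [("A", 1), ("A", 3)])
        dm_a = mean_distance_matrix(traj, sel_a)
        dm_b = mean_distance_matrix(traj, sel_b)
        with pytest.raises(StructuralMismatchError, match="3"):
            difference_distance_matrix(dm_a, dm_b)

    def test_hand_computed_three_residue_displacement(self):
        """One residue shifted 8.6 A changes its rows by hand-computed amounts."""
        numbers = [1, 2, 3]
        pos_a = [[0, 0, 0], [3, 0, 0], [0, 4, 0]]  # d12=3, d13=4, d23=5 A
        pos_b = [[0, 0, 0], [3, 0, 0], [0, 12.6, 0]]  # residue 3 moved +8.6 in y
        topo_a = _ca_structure(pos_a, numbers)
        topo_b = _ca_structure(pos_b, numbers)
        sel = select_backbone_carbon(topo_a, [("A", n) for n in numbers])
        dm_a = mean_distance_matrix(Trajectory(topo_a, topo_a.coords[None]), sel)
        dm_b = mean_distance_matrix(Trajectory(topo_b, topo_b.coords[None]), sel)
        ddm = difference_distance_matrix(dm_a, dm_b)
        assert ddm.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert ddm.values[0, 2] == pytest.approx((4 - 12.6) / 10, abs=1e-12)
        d23_b = np.hypot(3.0, 12.6)
        assert ddm.values[1, 2] == pytest.approx((5 - d23_b) / 10, abs=1e-12)


class TestDisplacementRanking:
    def test_zero_matrix_all_scores_zero(self, wt_like_trajectory):
        sel = _site_selection(wt_like_trajectory.topology)
        dm = mean_distance_matrix(wt_like_trajectory, sel)
        ranking = residue_displacement_ranking(difference_distance_matrix(dm, dm))
        assert all(score == 0.0 for _, score in ranking)
        # ties broken by label order in the matrix
        assert [lab for lab, _ in ranking] == dm.labels

    def test_planted_displacement_ranks_first_with_quiet_other_chain(
        self, template, domains
    ):
        """A displaced Lys1051 dominates; the untouched subunit stays quiet."""
        still = simulate_trajectory(template, domains, MotionSpec(seed=1), 10)
        moved = simulate_trajectory(
            template,
            domains,
            MotionSpec(seed=2, displaced_residue=("B", 1051, (6.0, 4.0, 3.0))),
            10,
        )
        sel = _site_selection(template)
        ddm = difference_distance_matrix(
            mean_distance_matrix(still, sel), mean_distance_matrix(moved, sel)
        )
        ranking = residue_displacement_ranking(ddm)
        assert ranking[0][0] == ("B", 1051, "LYS")
        # intra-block entries of the unperturbed chain A are exactly quiet
        assert np.abs(ddm.values[:4, :4]).max() < 1e-9
        # while the displaced residue's entries are large
        assert np.abs(ddm.values[7, :]).max() > 0.1

    def test_two_displacements_rank_by_magnitude(self, template, domains):
        still = simulate_trajectory(template, domains, MotionSpec(seed=1), 5)
        big = simulate_trajectory(
            template, domains,
            MotionSpec(seed=2, displaced_residue=("B", 1051, (10.0, 0.0, 0.0))),
            5,
        )
        # apply the second, smaller displacement on top of the first result
        frames = big.frames.copy()
        mask = np.array(
            [a.chain_id == "A" and a.residue_number == 890 for a in template.atoms]
        )
        ramp = np.linspace(0, 1, 5)
        for k in range(5):
            frames[k][mask] += ramp[k] * np.array([0.0, 3.0, 0.0])
        both = big.with_frames(frames)
        sel = _site_selection(template)
        ddm = difference_distance_matrix(
            mean_distance_matrix(still, sel), mean_distance_matrix(both, sel)
        )
        ranking = residue_displacement_ranking(ddm)
        assert ranking[0][0] == ("B", 1051, "LYS")
        assert ranking[1][0] == ("A", 890, "ASP")

    def test_jitter_only_pair_has_no_false_signal(self, template, domains):
        a = simulate_trajectory(template, domains, MotionSpec(seed=51, jitter_sd=0.2), 50)
        b = simulate_trajectory(template, domains, MotionSpec(seed=52, jitter_sd=0.2), 50)
        sel = _site_selection(template)
        ddm = difference_distance_matrix(
            mean_distance_matrix(a, sel), mean_distance_matrix(b, sel)
        )
        # distance fluctuation sd ~ sqrt(2)*0.2 A; the mean over 50 frames
        # leaves entries of order 0.04 A = 0.004 nm; 0.02 nm is a 5-sigma cap
        assert np.abs(ddm.values).max() < 0.02

    def test_ddm_identical_with_and_without_prior_alignment(
        self, wt_like_trajectory, mutant_like_trajectory
    ):
        """Superposition cannot change distances: DDM parity to 1e-9 nm."""
        sel = _site_selection(wt_like_trajectory.topology)
        residues = sorted(
            {a.residue_number for a in wt_like_trajectory.topology.atoms}
        )
        all_sel = select_backbone_carbon(
            wt_like_trajectory.topology, [(c, r) for c in "AB" for r in residues]
        )

        def ddm_of(align):
            ta, tb = wt_like_trajectory, mutant_like_trajectory
            if align:
                ta, _ = align_trajectory(ta, all_sel)
                tb, _ = align_trajectory(tb, all_sel)
            return difference_distance_matrix(
                mean_distance_matrix(ta, sel), mean_distance_matrix(tb, sel)
            )

        np.testing.assert_allclose(
            ddm_of(True).values, ddm_of(False).values, atol=1e-9
        )


def test_distance_matrix_validates_symmetry():
    values = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(values, [("A", 1, "GLY"), ("A", 2, "GLY")])
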