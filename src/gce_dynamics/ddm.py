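"""Trajectory-averaged distance matrices and difference distance matrices.

Each residue of the binding-site selection is represented by one
backbone carbon; the pairwise Euclidean distances are averaged over all
trajectory frames and reported in nanometres.  The element-wise
difference of two such matrices — e.g. wild type minus mutant — is a
superposition-invariant measure of conformational change: an entry
(i, j) says how much the average separation of residues i and j
differs between the two simulations.  Because distances are invariant
under rigid motions, prior superposition does not change the result;
the pipeline aligns anyway for parity with the projection analysis.

The conventional layout puts the first subunit's residues first
(chain A: 890, 981, 1013, 1051, then chain B likewise for the cyclase
binding site), so intra-subunit blocks sit on the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from gce_dynamics.errors import ConfigurationError, StructuralMismatchError
from gce_dynamics.structure_io import Selection, Trajectory

__all__ = [
    "DistanceMatrix",
    "DifferenceDistanceMatrix",
    "mean_distance_matrix",
    "difference_distance_matrix",
    "residue_displacement_ranking",
]

_A_PER_NM = 10.0


@dataclass
class DistanceMatrix:
    """Symmetric matrix of trajectory-averaged residue distances (nm)."""

    values: np.ndarray
    labels: list[tuple[str, int, str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class DifferenceDistanceMatrix:
    """Signed element-wise difference of two averaged distance matrices (nm)."""

    values: np.ndarray
    labels: list[tuple[str, int, str]]
    source_a: str = "A"
    source_b: str = "B"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("difference distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)


def mean_distance_matrix(
    traj: Trajectory, residues: Selection, stride: int = 1
) -> DistanceMatrix:
    """Average pairwise backbone-carbon distances over all frames, in nm.

    Label order follows the request order of ``residues`` (subunit 1
    first, then subunit 2 in the dimer layout).  ``stride`` subsamples
    frames; by default every frame enters the average.
    """
    if len(residues) < 2:
        raise ConfigurationError(
            f"distance matrix needs >= 2 residues, got {len(residues)}"
        )
    frames = traj.frames[::stride, residues.atom_indices, :]
    n = len(residues)
    acc = np.zeros(n * (n - 1) // 2)
    for frame in frames:
        acc += pdist(frame)
    mean_ang = acc / frames.shape[0]
    values = squareform(mean_ang) / _A_PER_NM
    return DistanceMatrix(values=values, labels=list(residues.labels))


def difference_distance_matrix(
    a: DistanceMatrix, b: DistanceMatrix, source_a: str = "A", source_b: str = "B"
) -> DifferenceDistanceMatrix:
    """Element-wise difference ``a - b`` of two averaged distance matrices."""
    if a.labels != b.labels:
        differing = [
            (la, lb) for la, lb in zip(a.labels, b.labels) if la != lb
        ] or [(la, None) for la in a.labels[len(b.labels):]]
        raise StructuralMismatchError(
            f"distance matrices have incompatible labels: {differing}"
        )
    return DifferenceDistanceMatrix(
        values=a.values - b.values,
        labels=list(a.labels),
        source_a=source_a,
        source_b=source_b,
    )


def residue_displacement_ranking(
    ddm: DifferenceDistanceMatrix,
) -> list[tuple[tuple[str, int, str], float]]:
    """Rank residues by mean absolute distance change to all other residues.

    The score of residue i is ``mean_{j != i} |ddm[i, j]|``; residues are
    returned in descending score order, ties broken by label order in
    the matrix.
    """
    n = ddm.n
    if n < 2:
        return [(label, 0.0) for label in ddm.labels]
    abs_vals = np.abs(ddm.values)
    scores = (abs_vals.sum(axis=1) - np.diag(abs_vals)) / (n - 1)
    order = sorted(range(n), key=lambda i: (-scores[i], i))
    return [(ddm.labels[i], float(scores[i])) for i in order]
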