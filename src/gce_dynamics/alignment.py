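"""Rigid-body superposition and iterative trajectory alignment.

``kabsch_superpose`` computes the proper rotation and translation that
minimise the (weighted) RMSD of a mobile point set onto a reference,
via SVD of the cross-covariance with the reflection sign corrected on
the smallest singular value.  ``align_trajectory`` implements the
iterative scheme used for the cyclase trajectories: all frames are
first superposed onto frame 0 over a selection, then repeatedly onto
the running average of the aligned selection coordinates until the
average structure stops moving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gce_dynamics.errors import ConditioningError
from gce_dynamics.structure_io import Selection, Trajectory

__all__ = ["RigidTransform", "AlignmentResult", "kabsch_superpose", "align_trajectory"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation (A)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tra = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or tra.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(rot) < 0:
            raise ValueError("improper rotation (reflection) is not allowed")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``inner`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ inner.rotation,
            self.rotation @ inner.translation + self.translation,
        )


@dataclass
class AlignmentResult:
    """Per-frame transforms and convergence diagnostics of the iteration."""

    transforms: list[RigidTransform]
    rmsd_per_frame: np.ndarray  # A, selection RMSD to the final average
    iterations: int
    converged: bool
    final_average: np.ndarray  # (n_selected, 3) average selection coordinates
    mean_rmsd_history: list[float] = field(default_factory=list)  # per iteration


def _weighted_rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray) -> float:
    d2 = np.sum((a - b) ** 2, axis=1)
    return float(np.sqrt(np.sum(weights * d2) / np.sum(weights)))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal proper rigid superposition of ``mobile`` onto ``reference``.

    Returns the minimising transform and the RMSD at the minimum.  At
    least three non-collinear points are required; reflections are
    excluded by flipping the sign of the smallest singular value when
    the raw solution has negative determinant.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(
            f"point sets must share shape (n, 3); got {mobile.shape} vs "
            f"{reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise ConditioningError(f"superposition needs >= 3 points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")

    wsum = w.sum()
    cm = (w[:, None] * mobile).sum(axis=0) / wsum
    cr = (w[:, None] * reference).sum(axis=0) / wsum
    x = mobile - cm
    y = reference - cr
    # collinear sets leave the rotation about the common axis undetermined
    for pts in (x, y):
        if np.linalg.matrix_rank(pts * np.sqrt(w)[:, None], tol=1e-9) < 2:
            raise ConditioningError("point set is collinear; superposition is degenerate")

    cov = x.T @ (w[:, None] * y)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    transform = RigidTransform(rotation, cr - rotation @ cm)
    rmsd = _weighted_rmsd(transform.apply(mobile), reference, w)
    return transform, rmsd


def align_trajectory(
    traj: Trajectory,
    selection: Selection,
    tolerance: float = 0.01,
    max_iter: int = 100,
    weights: np.ndarray | None = None,
) -> tuple[Trajectory, AlignmentResult]:
    """Iteratively superpose all frames onto the running average selection.

    Iteration 1 aligns every frame to frame 0 over ``selection``; each
    subsequent iteration recomputes the arithmetic mean of the aligned
    selection coordinates and re-aligns all frames to it.  The loop
    stops when the plain RMSD between successive average structures
    drops below ``tolerance`` (A) or after ``max_iter`` iterations, in
    which case the result is flagged ``converged=False``.  The
    selection's transform is applied to the whole frame, so alignment
    on one domain moves the entire structure rigidly.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    frames = traj.frames.copy()
    n_frames = frames.shape[0]
    transforms = [RigidTransform.identity() for _ in range(n_frames)]
    uniform = np.ones(len(selection))
    w = uniform if weights is None else np.asarray(weights, dtype=float)

    reference = selection.coords(frames[0])
    iterations = 0
    converged = False
    history: list[float] = []
    while iterations < max_iter:
        iterations += 1
        for k in range(n_frames):
            transform, _ = kabsch_superpose(selection.coords(frames[k]), reference, w)
            frames[k] = transform.apply(frames[k])
            transforms[k] = transform.compose(transforms[k])
        average = np.mean([selection.coords(frames[k]) for k in range(n_frames)], axis=0)
        history.append(
            float(
                np.mean(
                    [
                        _weighted_rmsd(selection.coords(frames[k]), average, w)
                        for k in range(n_frames)
                    ]
                )
            )
        )
        shift = _weighted_rmsd(average, reference, w)
        reference = average
        if shift < tolerance:
            converged = True
            break

    rmsd_per_frame = np.array(
        [_weighted_rmsd(selection.coords(frames[k]), reference, w) for k in range(n_frames)]
    )
    aligned = traj.with_frames(frames)
    result = AlignmentResult(
        transforms=transforms,
        rmsd_per_frame=rmsd_per_frame,
        iterations=iterations,
        converged=converged,
        final_average=reference,
        mean_rmsd_history=history,
    )
    return aligned, result
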