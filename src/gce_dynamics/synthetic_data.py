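"""Kinematic synthetic data: coarse homodimer trajectories and assay curves.

The generator emulates the modeled intracellular fragment of the
bovine cyclase homodimer — a kinase homology domain (KHD), the
alpha-helical dimerization domain (DD) and the catalytic domain (CCD)
per chain, with the hinge residue 818 at the KHD/DD boundary — as a
coarse backbone-only structure (N, CA, C, O per residue).  The two
chains are exact C2 copies related by a 180-degree rotation about the
z-axis, the KHD extends toward +z, the DD runs through the hinge and
the CCD sits toward -z, so the hinge-centered projection of the
catalytic-domain center is well defined by construction.

Motions are kinematic, not physical: isotropic Gaussian jitter stands
in for thermal fluctuation, a rigid swing of DD+CCD of one chain about
its hinge emulates the mutant's domain motion (the asymmetry — one
subunit moves, the other does not — mirrors the experimental finding),
and a single ramped residue displacement plants a binding-site signal
for the difference-distance analysis.  The kinetics generator inverts
the Hill fit: it evaluates v = a*S^h/(c^h+S^h) on a substrate grid
within the assayed 0-4 mM range and applies relative Gaussian noise.

All randomness flows through one ``numpy.random.Generator`` seeded per
simulation; identical specs and seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from gce_dynamics.errors import ConfigurationError
from gce_dynamics.kinetics import KineticsDataset, hill_activity
from gce_dynamics.structure_io import AtomRecord, Structure, Trajectory

__all__ = [
    "DomainDefinition",
    "MotionSpec",
    "KineticsParams",
    "build_dimer_template",
    "simulate_trajectory",
    "simulate_kinetics",
]

#: Backbone atom offsets (A) relative to the residue center, chosen
#: non-coplanar so per-residue frames are never degenerate.
_BACKBONE_OFFSETS = {
    "N": np.array([-1.2, 0.4, -0.6]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.1, -0.3, 0.5]),
    "O": np.array([1.9, 0.6, 1.0]),
}
_RISE_PER_RESIDUE = 1.5  # A, ideal alpha-helix rise
_TWIST_PER_RESIDUE = np.deg2rad(100.0)  # ideal alpha-helix twist
_HELIX_RADIUS = 1.8  # A
_CHAIN_OFFSET = 6.0  # A, half-distance between the two chains' axes
_CCD_RADIUS = 8.0  # A, radius of the catalytic-domain blob
_CCD_GAP = 8.0  # A, gap between DD end and CCD-blob center


@dataclass
class DomainDefinition:
    """Residue-number intervals of the three domains (bovine numbering).

    Ranges are inclusive, disjoint and ordered KHD < DD < CCD along the
    sequence; the hinge residue is the last KHD residue, sitting just
    before the dimerization helix.  The catalytic-domain key residues
    (the GTP binding site: 890, 981, 1013, 1051) are always materialised
    in generated templates so binding-site analyses can resolve them.
    """

    khd_range: tuple[int, int] = (770, 818)
    dd_range: tuple[int, int] = (819, 880)
    ccd_range: tuple[int, int] = (881, 1060)
    hinge_residue: int = 818
    ccd_key_residues: tuple[int, ...] = (890, 981, 1013, 1051)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("khd_range", self.khd_range),
            ("dd_range", self.dd_range),
            ("ccd_range", self.ccd_range),
        ):
            if lo > hi:
                raise ConfigurationError(f"{name} is empty: {(lo, hi)}")
        if not (self.khd_range[1] < self.dd_range[0] <= self.dd_range[1] < self.ccd_range[0]):
            raise ConfigurationError(
                "domain ranges must be disjoint and ordered KHD < DD < CCD"
            )
        if self.hinge_residue != self.khd_range[1]:
            raise ConfigurationError(
                f"hinge residue {self.hinge_residue} must close the KHD "
                f"(expected {self.khd_range[1]})"
            )
        for res in self.ccd_key_residues:
            if not self.ccd_range[0] <= res <= self.ccd_range[1]:
                raise ConfigurationError(
                    f"key residue {res} outside the CCD range {self.ccd_range}"
                )

    def domain_of(self, residue_number: int) -> str | None:
        if self.khd_range[0] <= residue_number <= self.khd_range[1]:
            return "KHD"
        if self.dd_range[0] <= residue_number <= self.dd_range[1]:
            return "DD"
        if self.ccd_range[0] <= residue_number <= self.ccd_range[1]:
            return "CCD"
        return None


@dataclass
class MotionSpec:
    """Kinematic motion parameters for one simulated trajectory.

    ``swing_amplitude`` (degrees) rotates DD+CCD of the moving chain
    rigidly about its hinge CA around ``swing_axis``; the angle follows
    a linear ramp from 0 to the amplitude, or one sinusoidal cycle.
    ``displaced_residue`` shifts one residue by the given vector (A),
    ramped linearly over the frames.  ``global_rigid`` applies a random
    whole-frame rotation+translation per frame (useful for testing that
    alignment removes it); ``jitter_sd`` adds isotropic Gaussian noise.
    """

    seed: int
    jitter_sd: float = 0.0
    global_rigid: bool = False
    swing_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    swing_amplitude: float = 0.0
    swing_profile: str = "linear"
    displaced_residue: tuple[str, int, tuple[float, float, float]] | None = None
    moving_chain: str = "B"

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be >= 0")
        if self.swing_profile not in ("linear", "sinusoid"):
            raise ConfigurationError(
                f"unknown swing profile {self.swing_profile!r}"
            )
        axis = np.asarray(self.swing_axis, dtype=float)
        if self.swing_amplitude != 0.0 and not np.isclose(
            np.linalg.norm(axis), 1.0, atol=1e-9
        ):
            raise ConfigurationError("swing_axis must be a unit vector")


@dataclass
class KineticsParams:
    """True Hill parameters and noise model for a simulated assay.

    ``a`` is Vmax in pmol/(ug*min), ``c`` the EC50 in mM, ``h`` the
    Hill coefficient; ``noise_sd`` is the relative standard deviation
    of the multiplicative Gaussian noise.  The default substrate grid
    spans the assayed 0-4 mM Mg-GTP range.
    """

    a: float
    c: float
    h: float
    seed: int
    noise_sd: float = 0.0
    s_grid: tuple[float, ...] = (
        0.0, 0.05, 0.1, 0.15, 0.25, 0.4, 0.6, 0.8,
        1.0, 1.25, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0,
    )

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0 or self.h <= 0:
            raise ConfigurationError("a, c and h must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if any(s < 0 for s in self.s_grid):
            raise ConfigurationError("substrate concentrations must be >= 0")


def _spaced_residue_numbers(lo: int, hi: int, n: int) -> np.ndarray:
    if n < 1:
        raise ConfigurationError("residue count must be positive")
    if n > hi - lo + 1:
        raise ConfigurationError(
            f"cannot place {n} residues in range [{lo}, {hi}]"
        )
    vals = np.round(np.linspace(lo, hi, n)).astype(int)
    # rounding can collide on narrow ranges; push duplicates up
    for i in range(1, n):
        if vals[i] <= vals[i - 1]:
            vals[i] = vals[i - 1] + 1
    assert vals[-1] <= hi
    return vals


def _ccd_residue_numbers(domains: DomainDefinition, n: int) -> np.ndarray:
    lo, hi = domains.ccd_range
    vals = _spaced_residue_numbers(lo, hi, n)
    if n < len(domains.ccd_key_residues):
        raise ConfigurationError(
            "catalytic domain needs at least as many residues as key residues"
        )
    vals = vals.tolist()
    for key in domains.ccd_key_residues:
        if key in vals:
            continue
        free = [i for i, v in enumerate(vals) if v not in domains.ccd_key_residues]
        nearest = min(free, key=lambda i: abs(vals[i] - key))
        vals[nearest] = key
    out = np.array(sorted(vals))
    if len(np.unique(out)) != len(out):
        raise ConfigurationError("could not place key residues without collision")
    return out


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Deterministic quasi-uniform points on a sphere."""
    k = np.arange(n, dtype=float)
    phi = np.arccos(1 - 2 * (k + 0.5) / n)
    theta = np.pi * (1 + 5**0.5) * k
    return radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def build_dimer_template(
    domains: DomainDefinition | None = None,
    residues_per_domain: tuple[int, int, int] = (10, 8, 12),
) -> Structure:
    """Coarse C2-symmetric homodimer template.

    Chain A is laid out with the KHD as a helical path toward +z ending
    at the hinge (z = 0), the DD continuing the helix toward -z, and
    the CCD as a compact blob below the DD; each residue carries four
    backbone atoms.  Chain B is chain A rotated 180 degrees about the
    z-axis, so the hinge midpoint of the template is exactly the origin
    and the two chains share residue numbering.
    """
    domains = domains or DomainDefinition()
    n_khd, n_dd, n_ccd = residues_per_domain

    khd_nums = _spaced_residue_numbers(*domains.khd_range, n_khd)
    if khd_nums[-1] != domains.hinge_residue:
        khd_nums[-1] = domains.hinge_residue
    dd_nums = _spaced_residue_numbers(*domains.dd_range, n_dd)
    ccd_nums = _ccd_residue_numbers(domains, n_ccd)

    centers: list[np.ndarray] = []
    numbers: list[int] = []

    # Sparse residues mark a path whose spatial extent reflects the real
    # domain spans: position along z is proportional to residue number
    # (1.5 A helical rise per sequence position), so the template has the
    # lever-arm proportions of the actual construct even though only a
    # handful of residues are materialised per domain.
    hinge = domains.hinge_residue

    def _helix_point(num: int) -> np.ndarray:
        twist = num * _TWIST_PER_RESIDUE
        z = (hinge - num) * _RISE_PER_RESIDUE  # hinge at z = 0, KHD above
        return np.array(
            [
                _CHAIN_OFFSET + _HELIX_RADIUS * np.cos(twist),
                _HELIX_RADIUS * np.sin(twist),
                z,
            ]
        )

    for num in khd_nums:
        centers.append(_helix_point(int(num)))
        numbers.append(int(num))
    for num in dd_nums:
        centers.append(_helix_point(int(num)))
        numbers.append(int(num))

    # CCD: compact blob below the end of the dimerization helix
    dd_end_z = (hinge - domains.dd_range[1]) * _RISE_PER_RESIDUE
    ccd_center = np.array(
        [_CHAIN_OFFSET, 0.0, dd_end_z - _CCD_GAP - _CCD_RADIUS]
    )
    for point, num in zip(_fibonacci_sphere(len(ccd_nums), _CCD_RADIUS), ccd_nums):
        centers.append(ccd_center + point)
        numbers.append(int(num))

    atoms: list[AtomRecord] = []
    flip = Rotation.from_euler("z", 180, degrees=True).as_matrix()
    for chain_id, transform in (("A", np.eye(3)), ("B", flip)):
        for center, num in zip(centers, numbers):
            res_name = _residue_name(num, domains)
            for atom_name, offset in _BACKBONE_OFFSETS.items():
                atoms_xyz = transform @ (center + offset)
                atoms.append(
                    AtomRecord(chain_id, num, res_name, atom_name, atoms_xyz)
                )
    return Structure(atoms)


#: Binding-site residues carry their real identities; everything else is GLY.
_KEY_RESIDUE_NAMES = {890: "ASP", 981: "ARG", 1013: "ALA", 1051: "LYS"}


def _residue_name(number: int, domains: DomainDefinition) -> str:
    return _KEY_RESIDUE_NAMES.get(number, "GLY")


def _swing_angles(motion: MotionSpec, n_frames: int) -> np.ndarray:
    t = np.zeros(n_frames) if n_frames == 1 else np.arange(n_frames) / (n_frames - 1)
    if motion.swing_profile == "linear":
        return np.deg2rad(motion.swing_amplitude) * t
    return np.deg2rad(motion.swing_amplitude) * np.sin(2 * np.pi * t)


def simulate_trajectory(
    template: Structure,
    domains: DomainDefinition,
    motion: MotionSpec,
    n_frames: int,
) -> Trajectory:
    """Generate a trajectory from the template under a kinematic motion.

    Per frame, in order: the DD+CCD atoms of the moving chain are
    rotated about that chain's hinge CA (swing), the displaced residue
    is shifted by its ramped vector, Gaussian jitter is added, and an
    optional random whole-frame rigid motion is applied.  With zero
    jitter, zero amplitude and no displacement, every frame equals the
    template.
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    rng = np.random.default_rng(motion.seed)
    base = template.coords
    n_atoms = template.n_atoms

    res_numbers = np.array([a.residue_number for a in template.atoms])
    chain_ids = np.array([a.chain_id for a in template.atoms])
    atom_names = np.array([a.atom_name for a in template.atoms])

    swing_mask = (chain_ids == motion.moving_chain) & (
        res_numbers >= domains.dd_range[0]
    )
    hinge_ca = (
        (chain_ids == motion.moving_chain)
        & (res_numbers == domains.hinge_residue)
        & (atom_names == "CA")
    )
    if motion.swing_amplitude != 0.0:
        if not hinge_ca.any():
            raise ConfigurationError(
                f"swing requested but hinge residue {domains.hinge_residue} "
                f"(CA) is absent from chain {motion.moving_chain!r}"
            )
    pivot = base[hinge_ca][0] if hinge_ca.any() else np.zeros(3)
    axis = np.asarray(motion.swing_axis, dtype=float)

    displace_mask = np.zeros(n_atoms, dtype=bool)
    displace_vec = np.zeros(3)
    if motion.displaced_residue is not None:
        chain, resnum, vec = motion.displaced_residue
        displace_mask = (chain_ids == chain) & (res_numbers == resnum)
        if not displace_mask.any():
            raise ConfigurationError(
                f"displaced residue {resnum} not found in chain {chain!r}"
            )
        displace_vec = np.asarray(vec, dtype=float)

    angles = _swing_angles(motion, n_frames)
    ramp = (
        np.zeros(n_frames)
        if n_frames == 1
        else np.arange(n_frames) / (n_frames - 1)
    )

    frames = np.empty((n_frames, n_atoms, 3))
    for k in range(n_frames):
        coords = base.copy()
        if motion.swing_amplitude != 0.0 and angles[k] != 0.0:
            rot = Rotation.from_rotvec(axis * angles[k]).as_matrix()
            coords[swing_mask] = (coords[swing_mask] - pivot) @ rot.T + pivot
        if displace_mask.any():
            coords[displace_mask] += ramp[k] * displace_vec
        if motion.jitter_sd > 0:
            coords += rng.normal(0.0, motion.jitter_sd, size=coords.shape)
        if motion.global_rigid:
            quat = rng.normal(size=4)
            rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
            shift = rng.uniform(-10.0, 10.0, size=3)
            coords = coords @ rot.T + shift
        frames[k] = coords
    return Trajectory(template, frames)


def simulate_kinetics(
    params: KineticsParams, condition: str = "synthetic"
) -> KineticsDataset:
    """Noisy saturation dataset from known Hill parameters.

    activity_i = a*S_i^h/(c^h+S_i^h) * (1 + eps_i), eps_i ~ N(0, noise_sd);
    the activity at S = 0 is exactly zero.
    """
    rng = np.random.default_rng(params.seed)
    s = np.asarray(params.s_grid, dtype=float)
    clean = hill_activity(s, params.a, params.c, params.h)
    eps = rng.normal(0.0, params.noise_sd, size=s.shape) if params.noise_sd > 0 else 0.0
    activity = clean * (1.0 + eps)
    return KineticsDataset(substrate=s, activity=activity, condition=condition)
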