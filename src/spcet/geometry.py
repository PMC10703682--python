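"""Tilt geometry, Euler conventions, and the constrained pose-composition mapping.

In constrained tomographic refinement every 2D particle projection inherits its
alignment from two shared sets of parameters: the acquisition geometry of the
tilt image it came from (tilt-axis angle ``alpha``, stage tilt ``beta``, image
shifts) and the single rigid 3D transformation of the particle (three Euler
angles and a 3D position).  The mapping implemented by
:func:`compose_projection_pose` turns these into the five per-projection
alignment parameters (two shifts, three angles); projections never carry free
alignment parameters of their own.

Conventions (fixed here and used consistently by the simulator, the refiners
and the reconstructor, so that round trips are exactly testable):

* Euler angles are intrinsic ZYZ, in degrees: ``R = Rz(theta) @ Ry(phi) @
  Rz(psi)``.  ``R`` maps reference-frame coordinates to the particle's
  placement in the tomogram.
* The tilt operator rotates the coordinate frame by ``-alpha`` so that the
  tilt axis is the vertical (y) axis, tilts about it by ``beta``, and rotates
  back: ``M = Rz(alpha) @ Ry(beta) @ Rz(-alpha)``.  The microscope projects
  along z after applying ``M``.
* Tomogram coordinates are 0-based voxels; the rotation origin is the voxel
  ``(nx//2, ny//2, nz//2)``.
* Per-tilt/per-region image shifts are applied last, in the projection plane,
  in unbinned pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TiltGeometry",
    "ParticlePose",
    "ProjectionPose",
    "GeometryDelta",
    "RegionGrid",
    "rot_z",
    "rot_y",
    "euler_to_matrix",
    "matrix_to_euler",
    "canonicalize_euler",
    "tilt_matrix",
    "compose_projection_pose",
    "assign_regions",
    "volume_center",
]

_GIMBAL_EPS = 1e-9


def rot_z(angle_deg: float) -> np.ndarray:
    """3x3 rotation about z by ``angle_deg`` degrees (right-handed)."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_y(angle_deg: float) -> np.ndarray:
    """3x3 rotation about y by ``angle_deg`` degrees (right-handed)."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_to_matrix(angles) -> np.ndarray:
    """Rotation matrix for intrinsic ZYZ Euler angles ``(theta, phi, psi)`` in degrees."""
    theta, phi, psi = angles
    return rot_z(theta) @ rot_y(phi) @ rot_z(psi)


def _wrap180(a: float) -> float:
    # map to [-180, 180)
    return float((a + 180.0) % 360.0 - 180.0)


def matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix`, returning canonical-range angles.

    Canonical ranges: theta, psi in [-180, 180), phi in [0, 180].  At gimbal
    lock (phi ~ 0 or 180, where theta and psi rotate about the same axis) psi
    is set to 0 and the in-plane rotation is folded into theta.
    """
    R = np.asarray(R, dtype=float)
    cphi = float(np.clip(R[2, 2], -1.0, 1.0))
    phi = float(np.degrees(np.arccos(cphi)))
    sphi = np.sqrt(max(0.0, 1.0 - cphi * cphi))
    if sphi > _GIMBAL_EPS:
        theta = float(np.degrees(np.arctan2(R[1, 2], R[0, 2])))
        psi = float(np.degrees(np.arctan2(R[2, 1], -R[2, 0])))
    elif cphi > 0.0:  # phi ~ 0: R = Rz(theta + psi)
        theta = float(np.degrees(np.arctan2(R[1, 0], R[0, 0])))
        psi = 0.0
        phi = 0.0
    else:  # phi ~ 180: R = Rz(theta - psi) @ Ry(180)
        theta = float(np.degrees(np.arctan2(-R[1, 0], -R[0, 0])))
        psi = 0.0
        phi = 180.0
    return (_wrap180(theta), phi, _wrap180(psi))


def canonicalize_euler(angles) -> tuple[float, float, float]:
    """Map an arbitrary ZYZ triplet to the canonical storage range."""
    return matrix_to_euler(euler_to_matrix(angles))


def tilt_matrix(alpha_deg: float, beta_deg: float) -> np.ndarray:
    """Specimen rotation at tilt angle ``beta`` with tilt-axis angle ``alpha``."""
    return rot_z(alpha_deg) @ rot_y(beta_deg) @ rot_z(-alpha_deg)


@dataclass
class TiltGeometry:
    """Acquisition parameters of one image of a tilt series.

    ``exposure_order`` is the position of this tilt in the acquisition
    sequence (0 = first exposure); it drives dose accounting.
    """

    tilt_index: int
    alpha: float  # tilt-axis angle, degrees
    beta: float  # stage tilt angle, degrees
    shift_x: float = 0.0  # in-plane image shift, pixels
    shift_y: float = 0.0
    exposure_order: int = 0

    def __post_init__(self) -> None:
        if not (-90.0 <= self.beta < 90.0):
            raise ValueError(f"tilt angle beta={self.beta} outside [-90, 90)")
        if not (-180.0 <= self.alpha < 180.0):
            raise ValueError(f"tilt-axis angle alpha={self.alpha} outside [-180, 180)")

    def matrix(self, d_alpha: float = 0.0, d_beta: float = 0.0) -> np.ndarray:
        return tilt_matrix(self.alpha + d_alpha, self.beta + d_beta)


@dataclass
class ParticlePose:
    """One particle's rigid transformation inside a tomogram (6 DOF) plus its score."""

    particle_id: int
    pos: np.ndarray  # (x, y, z) voxels, tomogram frame
    angles: tuple[float, float, float]  # ZYZ degrees, canonical range
    score: float = 0.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.angles = canonicalize_euler(self.angles)

    def matrix(self) -> np.ndarray:
        return euler_to_matrix(self.angles)


@dataclass
class ProjectionPose:
    """Derived 2D alignment of one particle projection (never a free parameter)."""

    particle_id: int
    tilt_index: int
    shift: tuple[float, float]  # pixels in the tilt image
    angles: tuple[float, float, float]  # ZYZ degrees

    def matrix(self) -> np.ndarray:
        return euler_to_matrix(self.angles)


@dataclass
class GeometryDelta:
    """Per-region correction to the tilt geometry (beam-induced deformation model)."""

    d_alpha: float = 0.0
    d_beta: float = 0.0
    d_shift_x: float = 0.0
    d_shift_y: float = 0.0


def volume_center(dims) -> np.ndarray:
    """Rotation origin of a tomogram: voxel (nx//2, ny//2, nz//2)."""
    return np.array([d // 2 for d in dims], dtype=float)


def compose_projection_pose(
    tilt: TiltGeometry,
    particle: ParticlePose,
    region_delta: GeometryDelta | None = None,
    center=(0.0, 0.0, 0.0),
) -> ProjectionPose:
    """The mapping from (tilt geometry, particle pose) to a 2D projection pose.

    The projection orientation is the composition of the tilt rotation with the
    particle rotation; the projection shift is the tilted particle position
    projected on the image plane plus the per-tilt (and per-region) image
    shifts.  Exact rotation-matrix algebra throughout; no small-angle
    approximation.

    Parameters
    ----------
    center:
        Rotation origin in the same frame as ``particle.pos``.  Pass
        ``volume_center(dims)`` when positions are absolute voxels; the
        default assumes positions already relative to the tomogram center.
    """
    d = region_delta or GeometryDelta()
    M = tilt.matrix(d.d_alpha, d.d_beta)
    Q = M @ particle.matrix()
    u = M @ (particle.pos - np.asarray(center, dtype=float))
    shift = (
        float(u[0]) + tilt.shift_x + d.d_shift_x,
        float(u[1]) + tilt.shift_y + d.d_shift_y,
    )
    return ProjectionPose(particle.particle_id, tilt.tilt_index, shift, matrix_to_euler(Q))


def assign_regions(positions, grid: tuple[int, int, int], tomogram_dims) -> np.ndarray:
    """Assign 3D positions to cells of a uniform spatial grid.

    The bounding box ``[0, dim)`` per axis is partitioned into half-open
    uniform intervals; a coordinate exactly on an interior boundary falls in
    the upper cell.  The flat region index is ``ix + n_x*iy + n_x*n_y*iz``.

    Raises
    ------
    ValueError
        If any position lies outside the tomogram bounding box; the error
        names the offending particle index.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = np.asarray(grid, dtype=int)
    dims = np.asarray(tomogram_dims, dtype=float)
    if np.any(n < 1):
        raise ValueError(f"grid counts must be >= 1, got {tuple(grid)}")
    bad = np.where(np.any((pos < 0) | (pos >= dims), axis=1))[0]
    if bad.size:
        raise ValueError(
            f"particle {bad[0]} at position {tuple(pos[bad[0]])} lies outside "
            f"the tomogram bounding box {tuple(tomogram_dims)}"
        )
    cell = dims / n
    idx = np.floor(pos / cell).astype(int)
    idx = np.minimum(idx, n - 1)  # guard float round-up at the far edge
    return idx[:, 0] + n[0] * idx[:, 1] + n[0] * n[1] * idx[:, 2]


@dataclass
class RegionGrid:
    """Uniform spatial partition of a tomogram used for region-based refinement.

    Carries the per-region, per-tilt geometry corrections (all zero until a
    refinement writes them).  Total number of regions ``G = n_x * n_y * n_z``.
    """

    n_x: int
    n_y: int
    n_z: int
    tomogram_dims: tuple[int, int, int]
    geom_deltas: np.ndarray | None = field(default=None, repr=False)  # (G, T, 4)

    @property
    def n_regions(self) -> int:
        return self.n_x * self.n_y * self.n_z

    def init_deltas(self, n_tilts: int) -> np.ndarray:
        self.geom_deltas = np.zeros((self.n_regions, n_tilts, 4))
        return self.geom_deltas

    def assign(self, positions) -> np.ndarray:
        return assign_regions(positions, (self.n_x, self.n_y, self.n_z), self.tomogram_dims)

    def delta(self, region: int, tilt_index: int) -> GeometryDelta:
        if self.geom_deltas is None:
            return GeometryDelta()
        da, db, dx, dy = self.geom_deltas[region, tilt_index]
        return GeometryDelta(da, db, dx, dy)
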