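"""Voxel-grid geometry, rigid transforms, and trilinear resampling.

World coordinates are millimetres.  The origin of an :class:`ImageGeometry`
addresses the *center* of voxel ``(0, 0, 0)`` and all sampling happens at
target voxel centers; with this convention a translation by an exact multiple
of the voxel size onto an identically spaced grid moves data without any
interpolation at all, which is the central mechanism this package studies.

Trilinear interpolation is implemented here directly (not delegated) because
it *is* the object of study: the value at an off-grid point is the convex
combination of its eight surrounding voxel values, which bounds every
resampled value by the source extrema and therefore can only lower a lesion's
apparent maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "ImageGeometry",
    "Volume",
    "RigidTransform",
    "trilinear_sample",
    "resample_volume",
    "preset_geometry",
    "PRESET_SPACINGS",
]

#: Continuous indices this close (in voxel units) to an integer are snapped to
#: it before interpolation, so identity resampling is bit-exact and
#: integer-voxel shifts incur no interpolation error (IEEE division of
#: ``i * 4.1 / 4.1`` alone would not be exact).
_SNAP_TOL = 1e-9

# In-plane / axial spacings of the scanner grids studied: the PET
# reconstruction grid, the 1-mm diagnostic CT and the 5-mm low-dose CT.
PRESET_SPACINGS: dict[str, tuple[float, float, float]] = {
    "pet": (4.1, 4.1, 5.0),
    "ct1": (1.4, 1.4, 1.0),
    "ct5": (1.4, 1.4, 5.0),
}


def _as_triple(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(3)
    return a


@dataclass(eq=False)
class ImageGeometry:
    """Mapping between a voxel grid and world (mm) space.

    Parameters
    ----------
    shape
        Number of voxels per axis (positive integers).
    spacing
        Voxel size in mm per axis (> 0).
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    direction
        3x3 orthonormal direction matrix with determinant +1 (columns are the
        world directions of the voxel axes).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        sp = _as_triple(self.spacing)
        if np.any(sp <= 0):
            raise ValueError(f"spacing must be positive, got {sp}")
        self.spacing = tuple(float(s) for s in sp)
        self.origin = tuple(float(o) for o in _as_triple(self.origin))
        D = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(D @ D.T, np.eye(3), atol=1e-10):
            raise ValueError("direction matrix must be orthonormal")
        if np.linalg.det(D) < 0:
            raise ValueError("direction matrix must be proper (det +1)")
        self.direction = D

    # -- voxel <-> world ---------------------------------------------------
    def voxel_to_world(self, idx) -> np.ndarray:
        """World position (mm) of a continuous voxel index (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        scaled = idx * np.asarray(self.spacing)
        return scaled @ self.direction.T + np.asarray(self.origin)

    def world_to_voxel(self, p) -> np.ndarray:
        """Continuous voxel index of a world point (exact inverse of voxel_to_world)."""
        p = np.asarray(p, dtype=float)
        local = (p - np.asarray(self.origin)) @ self.direction
        return local / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(N, 3)`` in C order."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=-1).astype(float)
        return self.voxel_to_world(idx)

    @property
    def center_world(self) -> np.ndarray:
        """World position of the grid's geometric center."""
        return self.voxel_to_world((np.asarray(self.shape, dtype=float) - 1.0) / 2.0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def extent_mm(self) -> np.ndarray:
        """Physical edge length of the grid per axis (mm)."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ImageGeometry):
            return NotImplemented
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and self.origin == other.origin
            and np.array_equal(self.direction, other.direction)
        )


def preset_geometry(
    name: str,
    extent_mm=(160.0, 160.0, 120.0),
    center=(0.0, 0.0, 0.0),
) -> ImageGeometry:
    """Build a named scanner grid ("pet", "ct1", "ct5") covering ``extent_mm``.

    The grid is centered on ``center``; the shape is the number of whole
    voxels fitting the requested extent (at least 1 per axis).
    """
    try:
        spacing = np.asarray(PRESET_SPACINGS[name.lower()])
    except KeyError:
        raise ValueError(f"unknown geometry preset {name!r}; choose from {sorted(PRESET_SPACINGS)}")
    extent = _as_triple(extent_mm)
    shape = np.maximum(np.round(extent / spacing).astype(int), 1)
    center = _as_triple(center)
    origin = center - spacing * (shape - 1) / 2.0
    return ImageGeometry(shape=tuple(shape), spacing=tuple(spacing), origin=tuple(origin))


@dataclass
class Volume:
    """A 3D scalar field (SUV for PET, arbitrary intensity for CT) on a grid."""

    geometry: ImageGeometry
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF world-space rigid map ``y = R (x - c) + c + t``.

    ``rotation_deg`` are intrinsic Z-Y-X Euler angles in degrees,
    ``R = Rz(rz) @ Ry(ry) @ Rx(rx)``, applied about the explicit ``center``
    ``c`` (mm); ``t`` is the translation in mm.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(translation=tuple(float(v) for v in _as_triple(t)))

    @property
    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation_deg
        return Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True).as_matrix()

    @property
    def is_identity(self) -> bool:
        return (
            all(a == 0.0 for a in self.rotation_deg)
            and all(t == 0.0 for t in self.translation)
        )

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        if self.is_identity:
            return p.copy()
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (p - c) @ self.matrix.T + c + t

    def apply_inverse(self, points) -> np.ndarray:
        """Exact inverse mapping (no Euler round trip): ``x = R^T (y - c - t) + c``."""
        p = np.asarray(points, dtype=float)
        if self.is_identity:
            return p.copy()
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (p - c - t) @ self.matrix + c

    def inverse(self) -> "RigidTransform":
        R = self.matrix
        rz, ry, rx = Rotation.from_matrix(R.T).as_euler("ZYX", degrees=True)
        t_inv = -(R.T @ np.asarray(self.translation))
        return RigidTransform(
            rotation_deg=(float(rx), float(ry), float(rz)),
            translation=tuple(float(v) for v in t_inv),
            center=self.center,
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition ``x -> a(b(x))``; the result keeps ``a``'s rotation center."""
    Ra, Rb = a.matrix, b.matrix
    ca = np.asarray(a.center)
    cb = np.asarray(b.center)
    mb = cb + np.asarray(b.translation) - Rb @ cb
    ma = ca + np.asarray(a.translation) - Ra @ ca
    R = Ra @ Rb
    m = Ra @ mb + ma
    rz, ry, rx = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
    t = m - ca + R @ ca
    return RigidTransform(
        rotation_deg=(float(rx), float(ry), float(rz)),
        translation=tuple(float(v) for v in t),
        center=a.center,
    )


def invert(t: RigidTransform) -> RigidTransform:
    return t.inverse()


def _continuous_indices(geometry: ImageGeometry, points: np.ndarray) -> np.ndarray:
    idx = geometry.world_to_voxel(points)
    snapped = np.round(idx)
    near = np.abs(idx - snapped) <= _SNAP_TOL
    return np.where(near, snapped, idx)


def trilinear_sample(volume: Volume, points, fill: float = 0.0):
    """Sample a volume at world points by trilinear interpolation.

    The value at a point is the convex combination of the eight voxel values
    surrounding its continuous index; points whose continuous index falls
    outside ``[0, shape - 1]`` on any axis return ``fill``.  Accepts a single
    point or an ``(..., 3)`` array; returns a scalar or matching array.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    idx = _continuous_indices(volume.geometry, pts)
    shape = np.asarray(volume.geometry.shape)

    inside = np.all((idx >= 0.0) & (idx <= shape - 1.0), axis=-1)

    base = np.floor(idx)
    # Keep the 8-corner cell valid at the upper boundary (d becomes 1 there).
    base = np.minimum(np.maximum(base, 0.0), shape - 2.0)
    d = np.clip(idx - base, 0.0, 1.0)
    i0 = base.astype(np.intp)
    i1 = i0 + 1

    v = volume.values
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    x1, y1, z1 = i1[:, 0], i1[:, 1], i1[:, 2]
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    ex, ey, ez = 1.0 - dx, 1.0 - dy, 1.0 - dz

    out = (
        v[x0, y0, z0] * ex * ey * ez
        + v[x1, y0, z0] * dx * ey * ez
        + v[x0, y1, z0] * ex * dy * ez
        + v[x0, y0, z1] * ex * ey * dz
        + v[x1, y1, z0] * dx * dy * ez
        + v[x1, y0, z1] * dx * ey * dz
        + v[x0, y1, z1] * ex * dy * dz
        + v[x1, y1, z1] * dx * dy * dz
    )
    out = np.where(inside, out, fill)
    if single:
        return float(out[0])
    return out


def resample_volume(
    src: Volume,
    transform: RigidTransform,
    target: ImageGeometry,
    fill: float = 0.0,
    label: str | None = None,
) -> Volume:
    """Resample ``src`` onto ``target`` under a rigid transform.

    For every target voxel center ``x`` the output value is
    ``trilinear_sample(src, transform^{-1}(x), fill)`` — i.e. ``transform``
    maps source (moving) world space into target (fixed) world space, the
    convention under which a registration result is applied directly.
    """
    pts = target.voxel_centers()
    src_pts = transform.apply_inverse(pts)
    vals = trilinear_sample(src, src_pts, fill=fill)
    return Volume(
        geometry=target,
        values=np.asarray(vals).reshape(target.shape),
        label=label if label is not None else src.label,
    )
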