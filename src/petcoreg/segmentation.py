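"""Threshold-based lesion delineation: fixed T40/T50/T60 and adaptive AT.

The fixed methods include every VOI voxel with at least 40/50/60 % of the
measured maximum activity ("at least" — the boundary voxel is included) and
keep the 26-connected component containing the maximum voxel.

The adaptive method (AT) applies a volume-reproducing threshold after
subtraction of local background: a fixed-point iteration alternates between
estimating the background in a shell around the current mask and
re-thresholding at ``background + f * (max - background)``.  The fraction
``f`` is the volume-reproducing parameter; it can be calibrated on sphere
phantoms of known volume.  Because both the maximum and the background shift
equally under a global additive intensity offset, the AT mask is invariant to
such offsets — the defining property that distinguishes background-adapted
from fixed thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, label as cc_label

from .geometry import ImageGeometry, Volume

__all__ = [
    "LesionVOI",
    "LesionMask",
    "voi_around_point",
    "voi_full",
    "fixed_threshold_segment",
    "estimate_background",
    "adaptive_threshold_segment",
    "calibrate_volume_reproducing_fraction",
    "DEFAULT_VOLUME_FRACTION",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: Default volume-reproducing fraction: a blurred sphere's edge profile
#: crosses background + 0.5*(max-background) at the true boundary once the
#: maximum is fully recovered, so 0.5 is the analytic large-lesion value.
DEFAULT_VOLUME_FRACTION = 0.5


@dataclass(frozen=True)
class LesionVOI:
    """Axis-aligned voxel-index box (half-open) enclosing one lesion + margin."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(l < 0 for l in self.lo) or any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"invalid VOI box {self.lo}..{self.hi}")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def clip(self, shape) -> "LesionVOI":
        lo = tuple(max(0, l) for l in self.lo)
        hi = tuple(min(int(s), h) for s, h in zip(shape, self.hi))
        return LesionVOI(lo, hi)


def voi_full(g: ImageGeometry) -> LesionVOI:
    return LesionVOI((0, 0, 0), g.shape)


def voi_around_point(
    g: ImageGeometry, center_world, half_extent_mm
) -> LesionVOI:
    """Box of ±half_extent_mm (per axis) around a world point, clipped to the grid."""
    c_idx = g.world_to_voxel(np.asarray(center_world, dtype=float))
    half_vox = np.asarray(half_extent_mm, dtype=float) / np.asarray(g.spacing)
    lo = np.maximum(np.floor(c_idx - half_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c_idx + half_vox).astype(int) + 1, np.asarray(g.shape))
    return LesionVOI(tuple(int(v) for v in lo), tuple(int(v) for v in hi))


@dataclass
class LesionMask:
    """Boolean lesion segmentation on the volume's grid.

    The mask is a single 26-connected component containing the seed (the
    VOI's maximum voxel) and is confined to the VOI.
    """

    mask: np.ndarray
    method: str                 # "AT" | "T40" | "T50" | "T60"
    threshold: float            # absolute SUV threshold applied
    voi: LesionVOI
    seed_index: tuple[int, int, int]
    converged: bool = True

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _voi_max(v: Volume, voi: LesionVOI) -> tuple[float, tuple[int, int, int]]:
    sub = v.values[voi.slices()]
    flat = int(np.argmax(sub))  # ties -> lowest linear index, deterministic
    local = np.unravel_index(flat, sub.shape)
    seed = tuple(int(l + o) for l, o in zip(local, voi.lo))
    return float(sub[local]), seed


def _component_mask(
    v: Volume, voi: LesionVOI, threshold: float, seed: tuple[int, int, int]
) -> np.ndarray:
    """Voxels >= threshold inside the VOI, 26-connected component of the seed."""
    sub = v.values[voi.slices()]
    above = sub >= threshold
    labels, _ = cc_label(above, structure=_CONN26)
    seed_local = tuple(s - o for s, o in zip(seed, voi.lo))
    lab = labels[seed_local]
    full = np.zeros(v.geometry.shape, dtype=bool)
    if lab > 0:
        full[voi.slices()] = labels == lab
    return full


def fixed_threshold_segment(v: Volume, voi: LesionVOI, fraction: float) -> LesionMask:
    """Threshold at ``fraction`` of the measured VOI maximum (>= semantics)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    mx, seed = _voi_max(v, voi)
    if mx <= 0:
        raise ValueError("VOI maximum must be positive")
    thr = fraction * mx
    mask = _component_mask(v, voi, thr, seed)
    return LesionMask(
        mask=mask,
        method=f"T{int(round(fraction * 100))}",
        threshold=thr,
        voi=voi,
        seed_index=seed,
    )


def estimate_background(
    v: Volume, mask: LesionMask, exclude: np.ndarray | None = None
) -> float:
    """Mean intensity in a shell 2-3 dilation steps (26-conn.) outside the mask.

    The shell is ``dilate^3(mask) \\ dilate^1(mask)`` restricted to the VOI;
    voxels in ``exclude`` (e.g. other lesions' masks) are dropped.  Raises
    ``ValueError`` if the shell is empty.
    """
    sl = mask.voi.slices()
    m = mask.mask[sl]
    if not m.any():
        raise ValueError("mask is empty")
    d1 = binary_dilation(m, structure=_CONN26, iterations=1)
    d3 = binary_dilation(m, structure=_CONN26, iterations=3)
    shell = d3 & ~d1
    if exclude is not None:
        shell &= ~exclude[sl]
    if not shell.any():
        raise ValueError("background shell is empty (VOI too tight or fully excluded)")
    return float(v.values[sl][shell].mean())


def adaptive_threshold_segment(
    v: Volume,
    voi: LesionVOI,
    volume_fraction: float = DEFAULT_VOLUME_FRACTION,
    max_iter: int = 25,
    exclude: np.ndarray | None = None,
) -> LesionMask:
    """Background-adapted volume-reproducing threshold segmentation (AT).

    Fixed-point iteration: the start mask thresholds at
    ``B_0 + 0.40 * (max - B_0)`` with ``B_0`` a robust initial background
    (25th percentile of the VOI, so the start reduces to a plain T40 mask on
    zero background); each step then estimates the local background ``B_k``
    in a shell around the current mask and re-thresholds at
    ``B_k + f * (max - B_k)``, stopping when the mask repeats.  Every step is
    equivariant under a global additive intensity offset, hence so is the
    final mask.  An oscillation that never settles returns the last mask with
    ``converged=False``.
    """
    mx, seed = _voi_max(v, voi)
    b0 = float(np.quantile(v.values[voi.slices()], 0.25))
    start_thr = b0 + 0.40 * (mx - b0)
    start = _component_mask(v, voi, start_thr, seed)
    if not start.any():
        raise ValueError("empty start mask; VOI maximum does not exceed background")
    current = LesionMask(start, "AT", start_thr, voi, seed, False)
    thr = start_thr
    seen: list[bytes] = [current.mask.tobytes()]
    converged = False
    for _ in range(max_iter):
        background = estimate_background(v, current, exclude=exclude)
        if mx <= background:
            raise ValueError("VOI maximum does not exceed local background")
        thr = background + volume_fraction * (mx - background)
        new = _component_mask(v, voi, thr, seed)
        if not new.any():
            raise ValueError("adaptive threshold removed the whole lesion")
        key = new.tobytes()
        if key == seen[-1]:
            converged = True
            current = LesionMask(new, "AT", thr, voi, seed, True)
            break
        cycling = key in seen
        seen.append(key)
        current = LesionMask(new, "AT", thr, voi, seed, False)
        if cycling:
            break
    return LesionMask(
        mask=current.mask,
        method="AT",
        threshold=thr,
        voi=voi,
        seed_index=seed,
        converged=converged,
    )


def calibrate_volume_reproducing_fraction(
    calibration_set: list[tuple[Volume, LesionVOI, float]],
    f_grid: np.ndarray | None = None,
) -> float:
    """Find the AT fraction minimizing mean squared relative volume error.

    ``calibration_set`` holds (volume, VOI, true volume in ml) triples; at
    least 3 phantoms spanning at least a decade of volume are required.  The
    search is an exhaustive grid over (0.2, 0.8); a minimizer on the grid
    boundary raises (no interior volume-reproducing fraction exists).
    """
    if len(calibration_set) < 3:
        raise ValueError("need at least 3 calibration phantoms")
    vols = [t for _, _, t in calibration_set]
    if max(vols) / min(vols) < 10.0:
        raise ValueError("calibration phantoms must span at least a decade of volume")
    if f_grid is None:
        f_grid = np.arange(0.20, 0.8001, 0.01)
    errors = np.empty(len(f_grid))
    for i, f in enumerate(f_grid):
        errs = []
        for vol, voi, true_ml in calibration_set:
            m = adaptive_threshold_segment(vol, voi, volume_fraction=float(f))
            mtv = m.n_voxels * vol.geometry.voxel_volume_mm3 / 1000.0
            errs.append(((mtv - true_ml) / true_ml) ** 2)
        errors[i] = float(np.mean(errs))
    best = int(np.argmin(errors))
    if best in (0, len(f_grid) - 1):
        raise ValueError("no interior minimizer in (0.2, 0.8)")
    return float(f_grid[best])
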