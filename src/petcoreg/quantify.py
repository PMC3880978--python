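"""Lesion quantification (SUVmax, MTV, SUVmean, TLG) and deviation records.

SUVmax is measured over the lesion's VOI (not the segmented mask), which
makes it independent of the delineation method; MTV is the segmented voxel
count times the voxel volume in ml; TLG = MTV * SUVmean with SUVmean averaged
over the segmented mask.  Deviations are relative differences
``100 * (coregistered - original) / original`` per quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import Volume
from .segmentation import LesionMask

__all__ = ["QuantResult", "DeviationRecord", "quantify_lesion", "relative_difference"]


@dataclass(frozen=True)
class QuantResult:
    suvmax: float
    mtv_ml: float
    suvmean: float
    tlg_ml: float
    method: str = ""
    grid: str = ""       # "CT1" | "CT5" | ...
    pipeline: str = ""   # "OR" | "RF" | "RS" | "oracle"

    def __post_init__(self) -> None:
        if self.mtv_ml <= 0:
            raise ValueError("MTV must be positive")
        if self.suvmean > self.suvmax + 1e-12:
            raise ValueError("SUVmean cannot exceed SUVmax")


@dataclass(frozen=True)
class DeviationRecord:
    """Relative differences (%) of coregistered vs original quantification."""

    lesion_id: int
    grid: str
    mode: str
    method: str
    d_suvmax_pct: float
    d_mtv_pct: float
    d_tlg_pct: float

    @property
    def abs_d_suvmax_pct(self) -> float:
        return abs(self.d_suvmax_pct)

    @property
    def abs_d_mtv_pct(self) -> float:
        return abs(self.d_mtv_pct)

    @property
    def abs_d_tlg_pct(self) -> float:
        return abs(self.d_tlg_pct)


def quantify_lesion(
    v: Volume,
    mask: LesionMask,
    method: str | None = None,
    grid: str = "",
    pipeline: str = "",
) -> QuantResult:
    """Measure SUVmax (VOI max), MTV (ml), SUVmean and TLG for one lesion."""
    if not mask.mask.any():
        raise ValueError("cannot quantify an empty mask")
    suvmax = float(v.values[mask.voi.slices()].max())
    n = mask.n_voxels
    mtv = n * v.geometry.voxel_volume_mm3 / 1000.0
    suvmean = float(v.values[mask.mask].mean())
    return QuantResult(
        suvmax=suvmax,
        mtv_ml=mtv,
        suvmean=suvmean,
        tlg_ml=mtv * suvmean,
        method=method if method is not None else mask.method,
        grid=grid,
        pipeline=pipeline,
    )


def relative_difference(
    coreg: QuantResult, original: QuantResult, lesion_id: int = 0, mode: str = ""
) -> DeviationRecord:
    """Per-quantity relative difference (%) of coregistered minus original."""
    if coreg.method != original.method or coreg.grid != original.grid:
        raise ValueError("can only compare matching method/grid results")
    for name in ("suvmax", "mtv_ml", "tlg_ml"):
        if getattr(original, name) == 0:
            raise ValueError(f"original {name} is zero; relative difference undefined")
    return DeviationRecord(
        lesion_id=lesion_id,
        grid=coreg.grid,
        mode=mode or coreg.pipeline,
        method=coreg.method,
        d_suvmax_pct=100.0 * (coreg.suvmax - original.suvmax) / original.suvmax,
        d_mtv_pct=100.0 * (coreg.mtv_ml - original.mtv_ml) / original.mtv_ml,
        d_tlg_pct=100.0 * (coreg.tlg_ml - original.tlg_ml) / original.tlg_ml,
    )
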