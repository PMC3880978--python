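"""Synthetic FDG-PET lesion phantoms and aligned pseudo-CT volumes.

The generator emulates the imaging chain the study design assumes: a
piecewise-constant activity distribution (lung background, solid lesion,
optional cold necrotic core) voxelized by center-inclusion on the PET grid,
convolved with the scanner's isotropic Gaussian reconstruction filter
(5 mm FWHM), with additive Gaussian noise on the resulting SUV map.  Every
phantom carries its analytic ground truth (binary lesion support and exact
volume in ml), which enables accuracy checks a patient study cannot perform.

The pseudo-CT counterpart is a structural image on a CT grid whose intensity
mapping is deliberately unrelated to the PET one (lung dark, lesion
soft-tissue bright, necrotic core *not* visible, independent noise) so that
cross-modality registration must rely on mutual information rather than
intensity identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import ImageGeometry, RigidTransform, Volume

__all__ = [
    "Necrosis",
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "generate_phantom",
    "generate_pseudo_ct",
    "generate_cohort",
    "FWHM_TO_SIGMA",
]

#: sigma = FWHM / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


@dataclass(frozen=True)
class Necrosis:
    """Cold concentric core: radius fraction of the lesion radii, own SUV."""

    core_fraction: float = 0.5
    core_suv: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 < self.core_fraction < 1.0:
            raise ValueError("core_fraction must be in (0, 1)")
        if self.core_suv < 0:
            raise ValueError("core_suv must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic description of one lesion phantom.

    ``radii_mm`` equal on all axes gives a sphere, otherwise an axis-aligned
    ellipsoid.  ``psf_fwhm`` is the isotropic Gaussian reconstruction filter
    in mm; ``noise_sd`` is the i.i.d. Gaussian noise SD in SUV added after
    blurring (negative excursions are clipped at 0 SUV).
    """

    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radii_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    lesion_suv: float = 8.0
    background_suv: float = 0.4
    necrosis: Necrosis | None = None
    psf_fwhm: float = 5.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("radii must be positive")
        if not self.lesion_suv > self.background_suv >= 0:
            raise ValueError("need lesion_suv > background_suv >= 0")
        if self.psf_fwhm < 0 or self.noise_sd < 0:
            raise ValueError("psf_fwhm and noise_sd must be >= 0")
        if self.necrosis is not None and self.necrosis.core_suv >= self.lesion_suv:
            raise ValueError("necrotic core must be colder than the lesion")

    @classmethod
    def sphere(cls, radius_mm: float, **kwargs) -> "PhantomSpec":
        return cls(radii_mm=(radius_mm,) * 3, **kwargs)

    @property
    def true_volume_ml(self) -> float:
        """Analytic lesion volume 4/3*pi*r1*r2*r3 in ml (core not subtracted)."""
        return 4.0 / 3.0 * np.pi * float(np.prod(self.radii_mm)) / 1000.0


@dataclass
class PhantomTruth:
    """Ground truth carried alongside every phantom."""

    spec: PhantomSpec
    support: np.ndarray          # boolean center-inclusion lesion support
    true_volume_ml: float        # analytic, exact
    voxelized_volume_ml: float   # support voxel count x voxel volume


@dataclass(frozen=True)
class CohortSpec:
    """A lesion population mimicking the study cohort's printed ranges."""

    n_lesions: int = 28
    volume_range_ml: tuple[float, float] = (1.1, 27.2)
    suv_range: tuple[float, float] = (1.6, 30.9)
    frac_heterogeneous: float = 0.25
    background_suv: float = 0.4
    noise_sd: float = 0.2
    psf_fwhm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        lo, hi = self.volume_range_ml
        if not 0 < lo <= hi:
            raise ValueError("invalid volume range")
        lo, hi = self.suv_range
        if not 0 < lo <= hi:
            raise ValueError("invalid SUV range")
        if not 0.0 <= self.frac_heterogeneous <= 1.0:
            raise ValueError("frac_heterogeneous must be in [0, 1]")


def _check_fits(spec: PhantomSpec, g: ImageGeometry) -> None:
    margin = np.asarray(spec.radii_mm) + spec.psf_fwhm
    center = np.asarray(spec.center_mm)
    corners = center + margin * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    idx = g.world_to_voxel(corners)
    if np.any(idx < 0) or np.any(idx > np.asarray(g.shape) - 1):
        raise ValueError(
            "lesion (plus PSF margin) does not fit inside the grid: "
            f"center {spec.center_mm}, radii {spec.radii_mm}, fwhm {spec.psf_fwhm}"
        )


def _support(spec: PhantomSpec, g: ImageGeometry, fraction: float = 1.0) -> np.ndarray:
    """Center-inclusion voxelization of the (scaled) analytic ellipsoid."""
    pts = g.voxel_centers()
    rel = (pts - np.asarray(spec.center_mm)) / (np.asarray(spec.radii_mm) * fraction)
    return (np.sum(rel * rel, axis=-1) <= 1.0).reshape(g.shape)


def generate_phantom(spec: PhantomSpec, g: ImageGeometry) -> tuple[Volume, PhantomTruth]:
    """Voxelize, blur and add noise to one lesion phantom.

    Returns the SUV volume together with its ground truth.  The blur is
    applied to the background-subtracted activity with zero boundary value so
    that total lesion-excess activity is conserved (normalized kernel) and the
    far field stays at ``background_suv``.
    """
    _check_fits(spec, g)
    support = _support(spec, g)
    act = np.full(g.shape, spec.background_suv, dtype=float)
    act[support] = spec.lesion_suv
    if spec.necrosis is not None:
        core = _support(spec, g, fraction=spec.necrosis.core_fraction)
        act[core] = spec.necrosis.core_suv

    if spec.psf_fwhm > 0:
        sigma_vox = spec.psf_fwhm * FWHM_TO_SIGMA / np.asarray(g.spacing)
        excess = act - spec.background_suv
        act = spec.background_suv + gaussian_filter(
            excess, sigma=sigma_vox, mode="constant", cval=0.0
        )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        act = act + rng.normal(0.0, spec.noise_sd, size=g.shape)
        np.clip(act, 0.0, None, out=act)

    truth = PhantomTruth(
        spec=spec,
        support=support,
        true_volume_ml=spec.true_volume_ml,
        voxelized_volume_ml=float(support.sum()) * g.voxel_volume_mm3 / 1000.0,
    )
    return Volume(geometry=g, values=act, label="pet-phantom"), truth


def generate_pseudo_ct(
    spec: PhantomSpec,
    g: ImageGeometry,
    misalignment: RigidTransform | None = None,
    lung_value: float = -750.0,
    lesion_value: float = 40.0,
    noise_sd: float = 60.0,
    blur_fwhm: float = 1.0,
) -> Volume:
    """Structural counterpart of a PET phantom on a CT grid.

    Intensities are HU-like: dark lung background, soft-tissue lesion.  The
    necrotic core, if any, is *not* reproduced (solid on CT), and independent
    noise is added, so PET and CT intensities are not related by any monotone
    map.  If ``misalignment`` is given (a map from PET world space into CT
    world space) the lesion is drawn displaced accordingly.
    """
    pts = g.voxel_centers()
    if misalignment is not None:
        pts = misalignment.apply_inverse(pts)
    rel = (pts - np.asarray(spec.center_mm)) / np.asarray(spec.radii_mm)
    inside = (np.sum(rel * rel, axis=-1) <= 1.0).reshape(g.shape)
    vals = np.full(g.shape, lung_value, dtype=float)
    vals[inside] = lesion_value
    if blur_fwhm > 0:
        sigma_vox = blur_fwhm * FWHM_TO_SIGMA / np.asarray(g.spacing)
        vals = lung_value + gaussian_filter(
            vals - lung_value, sigma=sigma_vox, mode="constant", cval=0.0
        )
    if noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 10_000_019)
        vals = vals + rng.normal(0.0, noise_sd, size=g.shape)
    return Volume(geometry=g, values=vals, label="pseudo-ct")


def combine_phantoms(
    specs: list[PhantomSpec],
    g: ImageGeometry,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Volume:
    """PET scene with several lesions: background plus summed lesion excesses.

    Component specs are generated noise-free; scene-level Gaussian noise is
    added once at the end (clipped at 0 SUV).  All specs must share the same
    background SUV.
    """
    if not specs:
        raise ValueError("need at least one lesion spec")
    bg = specs[0].background_suv
    if any(s.background_suv != bg for s in specs):
        raise ValueError("all specs must share one background SUV")
    total = np.full(g.shape, bg, dtype=float)
    for s in specs:
        quiet = PhantomSpec(
            center_mm=s.center_mm, radii_mm=s.radii_mm, lesion_suv=s.lesion_suv,
            background_suv=bg, necrosis=s.necrosis, psf_fwhm=s.psf_fwhm,
            noise_sd=0.0, seed=s.seed,
        )
        vol, _ = generate_phantom(quiet, g)
        total += vol.values - bg
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        total = np.clip(total + rng.normal(0.0, noise_sd, size=g.shape), 0.0, None)
    return Volume(geometry=g, values=total, label="pet-scene")


def combine_pseudo_cts(
    specs: list[PhantomSpec],
    g: ImageGeometry,
    misalignment: RigidTransform | None = None,
    lung_value: float = -750.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Volume:
    """Structural scene matching :func:`combine_phantoms` on a CT grid."""
    total = np.full(g.shape, lung_value, dtype=float)
    for s in specs:
        ct = generate_pseudo_ct(
            s, g, misalignment=misalignment, lung_value=lung_value, noise_sd=0.0
        )
        total += ct.values - lung_value
    if noise_sd > 0:
        rng = np.random.default_rng(seed + 10_000_019)
        total = total + rng.normal(0.0, noise_sd, size=g.shape)
    return Volume(geometry=g, values=total, label="pseudo-ct-scene")


def cohort_specs(c: CohortSpec, center_mm=(0.0, 0.0, 0.0)) -> list[PhantomSpec]:
    """Draw the lesion specs of a cohort (deterministic given the master seed).

    Volumes are log-uniform across the cohort range, lesion SUV uniform, the
    lesion center jittered by up to half a PET voxel per axis so fractional
    grid alignment varies across the cohort, and a fixed fraction of lesions
    carries a cold necrotic core.  Per-lesion noise seeds are
    ``master seed + lesion index``.
    """
    rng = np.random.default_rng(c.seed)
    specs: list[PhantomSpec] = []
    jitter_half = np.array([2.05, 2.05, 2.5])  # half a PET voxel
    for i in range(c.n_lesions):
        vol_ml = float(
            np.exp(rng.uniform(np.log(c.volume_range_ml[0]), np.log(c.volume_range_ml[1])))
        )
        radius = (3.0 * vol_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        suv = float(rng.uniform(*c.suv_range))
        hetero = bool(rng.uniform() < c.frac_heterogeneous)
        jitter = rng.uniform(-jitter_half, jitter_half)
        specs.append(
            PhantomSpec(
                center_mm=tuple(np.asarray(center_mm) + jitter),
                radii_mm=(radius,) * 3,
                lesion_suv=suv,
                background_suv=c.background_suv,
                necrosis=Necrosis(core_fraction=0.5, core_suv=c.background_suv)
                if hetero
                else None,
                psf_fwhm=c.psf_fwhm,
                noise_sd=c.noise_sd,
                seed=c.seed + i,
            )
        )
    return specs


def generate_cohort(
    c: CohortSpec, g: ImageGeometry, center_mm=(0.0, 0.0, 0.0)
) -> list[tuple[PhantomSpec, Volume, PhantomTruth]]:
    """Generate the full cohort of phantoms on grid ``g``."""
    out = []
    for spec in cohort_specs(c, center_mm=center_mm):
        vol, truth = generate_phantom(spec, g)
        out.append((spec, vol, truth))
    return out
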