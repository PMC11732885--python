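"""Digital liver phantoms emulating pre-treatment MAA SPECT and post-treatment PET.

The generator builds a liver ellipsoid with a perfused sub-volume and
spherical/ellipsoidal hypervascular lesions, then simulates a count map the
way a SPECT acquisition would see it: tracer concentrates in perfused tissue,
tumors take up T/N times the normal concentration, the point-spread function
blurs the map (Gaussian, FWHM in mm), and Poisson noise is applied per voxel.
The post-treatment activity map reuses the same spatial distribution rescaled
to the administered activity, modulated by a voxelwise multiplicative
log-normal discordance field, and optionally translated by a rigid
misregistration shift.

All randomness flows from one top-level seed through named
``numpy.random.SeedSequence`` substreams, so identical configs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import VoxelGrid

__all__ = [
    "Lesion",
    "LesionSpec",
    "PhantomConfig",
    "Phantom",
    "generate_phantom",
    "simulate_misregistration",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM * this


@dataclass
class Lesion:
    """A segmented tumor: mask plus its longest-axis diameter."""

    id: str
    mask: np.ndarray
    diameter_cm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"lesion {self.id!r}: mask is empty")
        if not (self.diameter_cm >= 0):
            raise ValueError(f"lesion {self.id!r}: diameter must be >= 0")


@dataclass
class LesionSpec:
    """Placement request for a spherical lesion: center (mm, world) + diameter."""

    center_mm: tuple[float, float, float]
    diameter_cm: float
    id: str = ""


@dataclass
class PhantomConfig:
    """Parameters of the digital phantom.

    Geometry defaults give a SPECT-like 64x64x48 grid at 4 mm pitch with a
    liver ellipsoid filling most of the field of view and a perfused
    sub-ellipsoid standing in for a lobar infusion territory.
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: float = 4.0
    liver_semiaxes_mm: tuple[float, float, float] = (100.0, 70.0, 60.0)
    liver_center_mm: tuple[float, float, float] | None = None
    perfused_semiaxes_mm: tuple[float, float, float] = (60.0, 55.0, 50.0)
    perfused_offset_mm: tuple[float, float, float] = (35.0, 0.0, 0.0)
    lesions: list[LesionSpec] = field(default_factory=list)
    tumor_to_normal: float = 5.0          # T/N uptake ratio, >= 0
    counts_per_normal_voxel: float = 100.0
    administered_activity_GBq: float = 2.5
    poisson_noise: bool = True
    psf_fwhm_mm: float = 8.0
    discordance_sigma: float = 0.0        # log-scale sigma of pre/post field
    misregistration_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_to_normal < 0:
            raise ValueError("tumor_to_normal must be >= 0")
        if self.administered_activity_GBq <= 0:
            raise ValueError("administered_activity_GBq must be positive")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        if self.discordance_sigma < 0:
            raise ValueError("discordance_sigma must be >= 0")
        self.lesions = [
            ls if isinstance(ls, LesionSpec) else LesionSpec(**ls) for ls in self.lesions
        ]
        for i, ls in enumerate(self.lesions):
            if not ls.id:
                ls.id = f"T{i + 1}"


@dataclass
class Phantom:
    """Generated phantom: masks plus pre-counts and post-activity grids."""

    whole_liver: np.ndarray
    perfused: np.ndarray
    lesions: list[Lesion]
    pre_counts: VoxelGrid
    post_activity: VoxelGrid
    config: PhantomConfig


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing_mm: float,
    center_mm: tuple[float, float, float],
    semiaxes_mm: tuple[float, float, float],
) -> np.ndarray:
    coords = [np.arange(n) * spacing_mm for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    return (
        ((x - center_mm[0]) / semiaxes_mm[0]) ** 2
        + ((y - center_mm[1]) / semiaxes_mm[1]) ** 2
        + ((z - center_mm[2]) / semiaxes_mm[2]) ** 2
    ) <= 1.0


def _sphere_mask(
    shape: tuple[int, int, int],
    spacing_mm: float,
    center_mm: tuple[float, float, float],
    diameter_cm: float,
) -> np.ndarray:
    r = diameter_cm * 10.0 / 2.0
    return _ellipsoid_mask(shape, spacing_mm, center_mm, (r, r, r))


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Build masks, a pre-treatment count map, and a post-treatment activity map.

    Raises
    ------
    ValueError
        If a lesion extends outside the grid or two lesions overlap.
    """
    shape, sp = config.shape, config.spacing_mm
    extent_mm = tuple((n - 1) * sp for n in shape)
    liver_center = config.liver_center_mm or tuple(e / 2 for e in extent_mm)

    liver = _ellipsoid_mask(shape, sp, liver_center, config.liver_semiaxes_mm)
    perf_center = tuple(c + o for c, o in zip(liver_center, config.perfused_offset_mm))
    perfused = _ellipsoid_mask(shape, sp, perf_center, config.perfused_semiaxes_mm) & liver

    lesions: list[Lesion] = []
    occupied = np.zeros(shape, dtype=bool)
    for ls in config.lesions:
        r_mm = ls.diameter_cm * 10.0 / 2.0
        for c, e in zip(ls.center_mm, extent_mm):
            if c - r_mm < -sp / 2 or c + r_mm > e + sp / 2:
                raise ValueError(f"lesion {ls.id!r} extends outside the grid")
        mask = _sphere_mask(shape, sp, ls.center_mm, ls.diameter_cm) & liver
        if not mask.any():
            raise ValueError(f"lesion {ls.id!r} does not intersect the liver")
        if (mask & occupied).any():
            raise ValueError(f"lesion {ls.id!r} overlaps a previous lesion")
        occupied |= mask
        lesions.append(Lesion(ls.id, mask, ls.diameter_cm))

    tumor_union = occupied

    # Named substreams off the top-level seed: one per stochastic stage.
    ss = np.random.SeedSequence(config.seed)
    ss_pre, ss_post, ss_disc = ss.spawn(3)

    # Ideal tracer concentration: perfused normal tissue at the baseline
    # count level, perfused tumor at T/N times that, nothing elsewhere.
    conc = np.zeros(shape, dtype=float)
    conc[perfused] = config.counts_per_normal_voxel
    conc[perfused & tumor_union] = config.counts_per_normal_voxel * config.tumor_to_normal

    pre = conc
    if config.psf_fwhm_mm > 0:
        sigma_vox = config.psf_fwhm_mm * _FWHM_TO_SIGMA / sp
        total = pre.sum()
        pre = ndimage.gaussian_filter(pre, sigma=sigma_vox)
        # Reconstruction support: counts are confined to the liver (no lung
        # shunt or extrahepatic deposition modeled); renormalize to conserve
        # the total.
        pre = np.where(liver, pre, 0.0)
        if pre.sum() > 0:
            pre *= total / pre.sum()
    if config.poisson_noise:
        pre = np.random.default_rng(ss_pre).poisson(pre).astype(float)

    # Post-treatment activity: the same distribution rescaled so the perfused
    # volume carries the administered activity, modulated by a log-normal
    # discordance field, then rigidly shifted if misregistration is requested.
    perf_total = pre[perfused].sum()
    if perf_total > 0:
        post = pre * (config.administered_activity_GBq / perf_total)
    else:
        post = np.zeros_like(pre)
    if config.discordance_sigma > 0:
        rng = np.random.default_rng(ss_disc)
        lnfield = rng.normal(0.0, config.discordance_sigma, size=shape)
        post = post * np.exp(lnfield - config.discordance_sigma**2 / 2.0)
    post_grid = VoxelGrid(post, sp)
    if any(s != 0 for s in config.misregistration_mm):
        post_grid = simulate_misregistration(post_grid, config.misregistration_mm)

    return Phantom(
        whole_liver=liver,
        perfused=perfused,
        lesions=lesions,
        pre_counts=VoxelGrid(pre, sp),
        post_activity=post_grid,
        config=config,
    )


def simulate_misregistration(
    grid: VoxelGrid, shift_mm: tuple[float, float, float]
) -> VoxelGrid:
    """Rigidly translate a grid by a whole-voxel shift (nearest-voxel rounding).

    Voxels shifted in from outside the field of view are zero; content shifted
    past the border is truncated, so total counts are conserved only for
    interior-supported images.
    """
    shift_vox = [int(round(s / grid.spacing_mm)) for s in shift_mm]
    for s, n in zip(shift_vox, grid.shape):
        if abs(s) >= n:
            raise ValueError(f"shift {s} voxels exceeds grid extent {n}")
    out = np.zeros_like(grid.values)
    src = []
    dst = []
    for s, n in zip(shift_vox, grid.shape):
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = grid.values[tuple(src)]
    return grid.like(out)
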