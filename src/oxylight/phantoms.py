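"""Synthetic phantoms: blood-filled tubes in scattering media, speckled
B-mode images, and forward photoacoustic images.

The generator reproduces the two bench configurations used to validate
fluence compensation — a homogeneous soft-tissue-mimicking medium, and a
two-slab phantom with a water coupling layer over the tissue slab — with
thin polymer tubes carrying blood of known oxygenation crossing the
imaging plane at chosen depths.  Forward PA images are initial-pressure
maps ``p = Gamma * mu_a * Phi`` plus optional Gaussian noise: acoustic
propagation and reconstruction are deliberately not simulated, since the
spectral-unmixing math operates on reconstructed amplitude proportional to
the initial pressure (band-limited detection is out of scope).

The tubes are treated as optically transparent in the light-propagation
medium (thin-walled polythene), while their blood absorption drives the PA
signal — matching how the bench experiments are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import Grid3D, MediumGrid, OpticalProperties
from .segmentation import USImage
from .spectra import ChromophoreSpectra, blood_mua_cm, water_mua_cm
from .unmixing import PAImage

__all__ = [
    "Tube",
    "PhantomSpec",
    "SyntheticFrame",
    "make_tube_phantom",
    "phantom_medium",
    "forward_pa_image",
    "synth_us_image",
]

#: soft-tissue-mimicking phantom optical properties (1/cm, g = 0.9)
SOFT_TISSUE = {
    750: OpticalProperties(0.101, 10.5, 0.9),
    850: OpticalProperties(0.089, 9.0, 0.9),
}


def water_props(wavelength_nm: int) -> OpticalProperties:
    """Background water: tabulated absorption, negligible scattering."""
    return OpticalProperties(water_mua_cm(wavelength_nm), 0.0, 0.0)


@dataclass(frozen=True)
class Tube:
    """A blood-filled tube crossing the imaging plane."""

    center_x_mm: float
    depth_mm: float
    inner_diameter_mm: float = 0.5
    so2_percent: float = 96.0
    total_hemoglobin_gL: float = 150.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.so2_percent <= 100.0:
            raise ValueError("tube sO2 must lie in [0, 100]")
        if self.inner_diameter_mm <= 0:
            raise ValueError("tube diameter must be positive")


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic phantom scene.

    ``image_shape`` is ``(depth, lateral)`` pixels at ``pixel_pitch_mm``;
    ``grid`` is the 3-D simulation grid (same spacing as the raster).  The
    defaults reproduce the bench geometry: a 545 x 512 px image at 74 um
    and a 744 x 744 x 512 voxel volume.
    """

    tubes: tuple[Tube, ...] = ()
    medium_kind: str = "homogeneous"
    interface_depth_mm: float = 8.0
    tissue_props: dict[int, OpticalProperties] = field(
        default_factory=lambda: dict(SOFT_TISSUE)
    )
    image_shape: tuple[int, int] = (512, 545)
    pixel_pitch_mm: float = 0.074
    grid_shape: tuple[int, int, int] = (744, 744, 512)
    grueneisen: float = 1.0

    def __post_init__(self) -> None:
        if self.medium_kind not in ("homogeneous", "two_slab"):
            raise ValueError("medium_kind must be homogeneous or two_slab")
        nz = self.image_shape[0]
        depth = nz * self.pixel_pitch_mm
        for t in self.tubes:
            if not 0 < t.depth_mm < depth:
                raise ValueError(
                    f"tube depth {t.depth_mm} mm outside image depth range"
                )
        for i, a in enumerate(self.tubes):
            for b in self.tubes[i + 1 :]:
                gap = np.hypot(
                    a.center_x_mm - b.center_x_mm, a.depth_mm - b.depth_mm
                )
                if gap < 0.5 * (a.inner_diameter_mm + b.inner_diameter_mm):
                    raise ValueError("tubes overlap")

    @property
    def grid(self) -> Grid3D:
        return Grid3D(shape=self.grid_shape, spacing_mm=self.pixel_pitch_mm)

    # --- raster coordinate helpers ------------------------------------
    def _coords(self) -> tuple[np.ndarray, np.ndarray]:
        nz, nx = self.image_shape
        x = (np.arange(nx) - 0.5 * (nx - 1)) * self.pixel_pitch_mm
        z = (np.arange(nz) + 0.5) * self.pixel_pitch_mm
        return x, z

    def tube_masks(self) -> list[np.ndarray]:
        """Boolean disk mask of each tube cross-section on the raster."""
        x, z = self._coords()
        xx, zz = np.meshgrid(x, z)
        return [
            (xx - t.center_x_mm) ** 2 + (zz - t.depth_mm) ** 2
            <= (0.5 * t.inner_diameter_mm) ** 2
            for t in self.tubes
        ]

    def tissue_mask(self) -> np.ndarray:
        """Tissue-region mask of the raster (1 = tissue slab)."""
        nz, nx = self.image_shape
        mask = np.ones((nz, nx), dtype=bool)
        if self.medium_kind == "two_slab":
            _, z = self._coords()
            mask[z < self.interface_depth_mm, :] = False
        return mask

    def truth_so2(self) -> np.ndarray:
        """Ground-truth sO2 raster (percent; NaN outside tubes)."""
        out = np.full(self.image_shape, np.nan)
        for t, m in zip(self.tubes, self.tube_masks()):
            out[m] = t.so2_percent
        return out


@dataclass
class SyntheticFrame:
    """One synthetic acquisition: US image, PA image pair, ground truth."""

    us: USImage
    pa: dict[int, PAImage]
    truth: dict


def make_tube_phantom(
    depths_mm: list[float],
    so2_percent: float = 96.0,
    medium_kind: str = "homogeneous",
    lateral_offsets_mm: list[float] | None = None,
    interface_depth_mm: float = 8.0,
    inner_diameter_mm: float = 0.5,
    **kwargs,
) -> PhantomSpec:
    """One tube cross-section per requested depth, laterally centered.

    Mirrors the bench arrangement in which a single blood-carrying tube
    crosses the imaging plane at several depths, so every cross-section
    shares the same oxygenation.
    """
    if lateral_offsets_mm is None:
        lateral_offsets_mm = [0.0] * len(depths_mm)
    if len(lateral_offsets_mm) != len(depths_mm):
        raise ValueError("one lateral offset per depth is required")
    tubes = tuple(
        Tube(
            center_x_mm=dx,
            depth_mm=d,
            inner_diameter_mm=inner_diameter_mm,
            so2_percent=so2_percent,
        )
        for d, dx in zip(depths_mm, lateral_offsets_mm)
    )
    return PhantomSpec(
        tubes=tubes,
        medium_kind=medium_kind,
        interface_depth_mm=interface_depth_mm,
        **kwargs,
    )


def phantom_medium(spec: PhantomSpec, wavelengths=(750, 850)) -> MediumGrid:
    """The labeled 3-D volume seen by the light model.

    Tubes are transparent and do not appear; the volume is the tissue
    slab (label 1) with water (label 0) above the interface for two-slab
    phantoms, extruded uniformly along the elevational axis.
    """
    grid = spec.grid
    nx, ny, nz = grid.shape
    labels = np.ones((nx, ny, nz), dtype=np.uint8)
    if spec.medium_kind == "two_slab":
        k = int(round(spec.interface_depth_mm / grid.spacing_mm))
        labels[:, :, : min(k, nz)] = 0
    properties = {}
    for wl in wavelengths:
        if wl not in spec.tissue_props:
            raise KeyError(f"no tissue properties at {wl} nm")
        properties[(1, wl)] = spec.tissue_props[wl]
        properties[(0, wl)] = water_props(wl)
    return MediumGrid(grid=grid, labels=labels, properties=properties)


def mua_image_cm(
    spec: PhantomSpec, wavelength_nm: int, spectra: ChromophoreSpectra
) -> np.ndarray:
    """Per-pixel absorption coefficient (1/cm) on the imaging raster.

    Background follows the medium (tissue table / water), tube interiors
    carry whole-blood absorption implied by their oxygenation.
    """
    if wavelength_nm not in spec.tissue_props:
        raise KeyError(f"no tissue properties at {wavelength_nm} nm")
    mua = np.full(
        spec.image_shape, spec.tissue_props[wavelength_nm].mua_cm
    )
    if spec.medium_kind == "two_slab":
        mua[~spec.tissue_mask()] = water_mua_cm(wavelength_nm)
    for t, m in zip(spec.tubes, spec.tube_masks()):
        mua[m] = blood_mua_cm(
            spectra, wavelength_nm, t.so2_percent, t.total_hemoglobin_gL
        )
    return mua


def forward_pa_image(
    spec: PhantomSpec,
    fl,
    wavelength_nm: int,
    spectra: ChromophoreSpectra,
    seed: int = 0,
    noise_sigma: float = 0.0,
    pulse_energy_uJ: float = 1.0,
) -> PAImage:
    """Initial-pressure image p = Gamma * mu_a * Phi * E plus noise.

    ``fl`` is the 2-D fluence map per unit energy on the same raster; the
    pulse energy scales the delivered fluence, so the image carries the
    instrument's wavelength-dependent energy exactly as exported data
    would (compensation later divides it back out).
    """
    if fl.ndim != 2:
        raise ValueError("a 2-D imaging-plane fluence map is required")
    if fl.values.shape != spec.image_shape:
        raise ValueError("fluence map raster does not match the phantom")
    if fl.wavelength_nm != wavelength_nm:
        raise ValueError("fluence map wavelength mismatch")
    mua = mua_image_cm(spec, wavelength_nm, spectra)
    p = spec.grueneisen * mua * np.asarray(fl.values) * pulse_energy_uJ
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        p = p + rng.normal(0.0, noise_sigma, size=p.shape)
    return PAImage(
        pixels=p,
        wavelength_nm=wavelength_nm,
        pulse_energy_uJ=pulse_energy_uJ,
        pixel_pitch_mm=spec.pixel_pitch_mm,
    )


def synth_us_image(
    spec: PhantomSpec,
    speckle_density: float = 4.0,
    psf_sigma_px: float = 1.2,
    seed: int = 0,
    interface_brightness: float = 3.0,
    noise_floor: float = 0.01,
) -> USImage:
    """Speckled B-mode image of the phantom scene.

    Tissue carries fully developed speckle — a dense complex Gaussian
    scatterer field convolved with a small Gaussian point-spread kernel
    and envelope-detected, giving Rayleigh-distributed amplitudes.  The
    water slab is dark except for a bright line at the separating film.
    Mean tissue amplitude is normalized to 1.
    """
    rng = np.random.default_rng(seed)
    nz, nx = spec.image_shape
    tissue = spec.tissue_mask()

    re = rng.normal(size=(nz, nx))
    im = rng.normal(size=(nz, nx))
    re[~tissue] = 0.0
    im[~tissue] = 0.0
    re = ndimage.gaussian_filter(re, psf_sigma_px)
    im = ndimage.gaussian_filter(im, psf_sigma_px)
    env = np.hypot(re, im)
    inside = tissue.copy()
    # PSF bleed across the boundary is part of the image, but normalize on
    # well-inside pixels
    core = ndimage.binary_erosion(inside, iterations=int(3 * psf_sigma_px) + 1)
    scale = env[core].mean() if core.any() else env.max() or 1.0
    img = env / scale

    if spec.medium_kind == "two_slab":
        k = int(round(spec.interface_depth_mm / spec.pixel_pitch_mm))
        if 0 <= k < nz:
            img[k, :] += interface_brightness
    img += rng.rayleigh(noise_floor, size=img.shape)
    return USImage(pixels=img, pixel_pitch_mm=spec.pixel_pitch_mm)


def boundary_truth_rows(spec: PhantomSpec) -> np.ndarray:
    """Per-column first tissue row of the phantom (the segmentation truth)."""
    tissue = spec.tissue_mask()
    return np.argmax(tissue, axis=0)


def synth_frame(
    spec: PhantomSpec,
    fluence: dict[int, object],
    spectra: ChromophoreSpectra,
    seed: int = 0,
    noise_sigma: float = 0.0,
    pulse_energies_uJ: dict[int, float] | None = None,
) -> SyntheticFrame:
    """Bundle a US image, the PA image pair and the ground truth."""
    if pulse_energies_uJ is None:
        pulse_energies_uJ = {750: 100.0, 850: 200.0}
    pa = {}
    for i, (wl, fl) in enumerate(sorted(fluence.items())):
        pa[wl] = forward_pa_image(
            spec,
            fl,
            wl,
            spectra,
            seed=seed + 17 * (i + 1),
            noise_sigma=noise_sigma,
            pulse_energy_uJ=pulse_energies_uJ[wl],
        )
    truth = {
        "so2": spec.truth_so2(),
        "tube_masks": spec.tube_masks(),
        "boundary_rows": boundary_truth_rows(spec),
    }
    return SyntheticFrame(
        us=synth_us_image(spec, seed=seed), pa=pa, truth=truth
    )
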