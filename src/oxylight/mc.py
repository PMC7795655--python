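"""Monte-Carlo fluence simulation on labeled voxel media.

`simulate_fluence` traces weighted photons from the probe's LED elements
through a :class:`~oxylight.grids.MediumGrid` and returns the 3-D fluence
per unit delivered pulse energy (1/cm^2).  `extract_imaging_plane` resamples
the center elevational slice onto the photoacoustic image raster, and
`one_over_e_depth` measures the axial decay length used to characterize
penetration below the LED tips.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from . import _kernel
from .grids import FluenceMap, MediumGrid
from .probe import EmitterElement

__all__ = [
    "simulate_fluence",
    "extract_imaging_plane",
    "one_over_e_depth",
]


def _source_arrays(sources: list[EmitterElement], origin: np.ndarray):
    """Pack emitter geometry into kernel arrays (positions grid-local)."""
    n = len(sources)
    pos = np.empty((n, 3))
    axis = np.empty((n, 3))
    b1 = np.empty((n, 3))
    b2 = np.empty((n, 3))
    cos_half = np.empty(n)
    power = np.empty(n)
    for i, el in enumerate(sources):
        a = np.asarray(el.axis, dtype=float)
        norm = np.linalg.norm(a)
        if not math.isclose(norm, 1.0, rel_tol=1e-6):
            raise ValueError("emitter axis must be a unit vector")
        a = a / norm
        # orthonormal frame about the cone axis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        v1 = np.cross(a, helper)
        v1 /= np.linalg.norm(v1)
        v2 = np.cross(a, v1)
        pos[i] = np.asarray(el.position_mm, dtype=float) - origin
        axis[i] = a
        b1[i] = v1
        b2[i] = v2
        cos_half[i] = math.cos(math.radians(el.half_angle_deg))
        power[i] = el.relative_power
    w_total = float(power.sum())
    if w_total <= 0:
        raise ValueError("total source power must be positive")
    cdf = np.cumsum(power) / w_total
    cdf[-1] = 1.0
    return pos, axis, b1, b2, cos_half, cdf, w_total


def simulate_fluence(
    medium: MediumGrid,
    sources: list[EmitterElement],
    wavelength_nm: int,
    n_photons: int,
    seed: int,
    cosine_weighted: bool = False,
    importance_box_mm: tuple[float, float, float, float, float, float]
    | None = None,
    importance_survival: float = 0.25,
    mirror_elevation: bool = False,
    scoring_box_mm: tuple[float, float, float, float, float, float]
    | None = None,
) -> FluenceMap:
    """Run the photon transport and return the 3-D fluence map.

    The result is normalized per launched photon (equivalently, per unit
    delivered energy at this wavelength) and is deterministic for a fixed
    ``(seed, inputs)`` pair.  Fluence units are 1/cm^2.

    ``importance_box_mm`` is an optional ``(x0, x1, y0, y1, z0, z1)`` region
    in probe coordinates: photons colliding outside it undergo
    weight-compensated Russian roulette (survival ``importance_survival``),
    which shortens far-wandering walks without biasing the expectation.
    The surviving weights are heavy-tailed, so at moderate photon counts
    this can undersample rare return paths; leave it ``None`` for
    quantitative profile work and give the box generous margins otherwise.

    ``mirror_elevation`` treats the imaging plane (probe y = 0) as a
    specular mirror.  For the mirror-symmetric LED probe this is exactly
    equivalent to the full domain: pass a half grid whose elevational axis
    starts at y = 0 (``origin_mm[1] == 0``) together with the sources of
    the +y unit only, and the folded fluence equals the full two-unit
    fluence per unit total energy.

    ``scoring_box_mm`` restricts fluence accumulation to a probe-frame
    region ``(x0, x1, y0, y1, z0, z1)``; trajectories are unchanged, so
    in-box values equal those of a full-scoring run, while a narrow box
    markedly speeds up analyses that only read a small band.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be at least 1")
    selected = [s for s in sources if s.wavelength_nm == wavelength_nm]
    if not selected:
        raise ValueError(f"no sources at {wavelength_nm} nm")

    grid = medium.grid
    origin = np.asarray(grid.origin_mm, dtype=float)
    if mirror_elevation:
        if abs(origin[1]) > 1e-9:
            raise ValueError(
                "mirror_elevation requires a half grid with origin_mm[1] == 0"
            )
        if any(s.position_mm[1] < 0 for s in selected):
            raise ValueError(
                "mirror_elevation expects only the +y unit's sources"
            )
    pos, axis, b1, b2, cos_half, cdf, w_total = _source_arrays(selected, origin)

    extent = np.array(grid.extent_mm)
    inside = np.all((pos >= 0) & (pos <= extent), axis=1)
    pointing_in = np.array(
        [_ray_hits_box(pos[i], axis[i], extent) for i in range(len(selected))]
    )
    if not np.any(inside | pointing_in):
        raise ValueError("all sources lie outside the grid and miss it")

    if importance_box_mm is None:
        roi_box = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        roi_survival = 1.0
    else:
        b = np.asarray(importance_box_mm, dtype=float)
        roi_box = np.array(
            [
                b[0] - origin[0],
                b[1] - origin[0],
                b[2] - origin[1],
                b[3] - origin[1],
                b[4] - origin[2],
                b[5] - origin[2],
            ]
        )
        if not 0.0 < importance_survival <= 1.0:
            raise ValueError("importance_survival must lie in (0, 1]")
        roi_survival = float(importance_survival)

    if scoring_box_mm is None:
        score_box = np.array([0, -1, 0, -1, 0, -1], dtype=np.int64)
    else:
        b = np.asarray(scoring_box_mm, dtype=float)
        h = grid.spacing_mm
        score_box = np.array(
            [
                max(int(np.floor((b[0] - origin[0]) / h)), 0),
                min(int(np.ceil((b[1] - origin[0]) / h)), grid.shape[0] - 1),
                max(int(np.floor((b[2] - origin[1]) / h)), 0),
                min(int(np.ceil((b[3] - origin[1]) / h)), grid.shape[1] - 1),
                max(int(np.floor((b[4] - origin[2]) / h)), 0),
                min(int(np.ceil((b[5] - origin[2]) / h)), grid.shape[2] - 1),
            ],
            dtype=np.int64,
        )

    mua, mus, g = medium.property_tables(wavelength_nm)
    fluence = np.zeros(grid.shape, dtype=np.float32)
    launched, absorbed, escaped, rkilled, rboost = _kernel.transport(
        medium.labels,
        mua,
        mus,
        g,
        grid.spacing_mm,
        pos,
        axis,
        b1,
        b2,
        cos_half,
        cdf,
        cosine_weighted,
        n_photons,
        seed,
        w_total,
        fluence,
        roi_box,
        roi_survival,
        mirror_elevation,
        score_box,
    )

    # track-length sums are weight*mm per voxel; convert to fluence per
    # launched unit energy in 1/cm^2: divide by voxel volume and photon
    # count, x100 for mm^-2 -> cm^-2
    voxel_mm3 = grid.spacing_mm**3
    values = fluence * np.float32(100.0 / (voxel_mm3 * n_photons))
    return FluenceMap(
        values=values,
        wavelength_nm=wavelength_nm,
        photons=n_photons,
        seed=seed,
        spacing_mm=grid.spacing_mm,
        origin_mm=tuple(origin),
        ledger={
            "launched": launched,
            "absorbed": absorbed,
            "escaped": escaped,
            "roulette_killed": rkilled,
            "roulette_boost": rboost,
        },
    )


def _ray_hits_box(p: np.ndarray, d: np.ndarray, extent: np.ndarray) -> bool:
    tmin, tmax = 0.0, np.inf
    for ax in range(3):
        if d[ax] == 0.0:
            if p[ax] < 0 or p[ax] > extent[ax]:
                return False
        else:
            t1 = (0.0 - p[ax]) / d[ax]
            t2 = (extent[ax] - p[ax]) / d[ax]
            if t1 > t2:
                t1, t2 = t2, t1
            tmin = max(tmin, t1)
            tmax = min(tmax, t2)
    return tmax > tmin


def extract_imaging_plane(
    fmap: FluenceMap,
    image_shape: tuple[int, int] = (512, 545),
    pixel_pitch_mm: float = 0.074,
    elevation_mm: float = 0.0,
) -> FluenceMap:
    """Elevational slice of a 3-D map on the image raster.

    By default the slice is the imaging plane (y = 0; mean of the two
    central slices for an even elevational count).  ``elevation_mm``
    selects an off-plane slice instead — e.g. the plane through an LED row,
    where the illumination peaks — by linear interpolation between the two
    nearest stored slices.  The slice is cropped laterally around the grid
    center and resampled onto ``image_shape = (depth, lateral)`` pixels at
    ``pixel_pitch_mm``, matching the reconstructed PA/US raster.
    """
    if fmap.ndim != 3:
        raise ValueError("a 3-D fluence map is required")
    nx, ny, nz = fmap.values.shape
    h = fmap.spacing_mm
    img_nz, img_nx = image_shape
    if img_nx * pixel_pitch_mm > nx * h + 1e-9 or img_nz * pixel_pitch_mm > nz * h + 1e-9:
        raise ValueError(
            "grid extent is smaller than the requested image footprint"
        )

    # fractional slice index at the requested elevation (voxel centers at
    # (iy + 0.5) h relative to the grid edge; y = 0 is the grid center)
    fy = elevation_mm / h + 0.5 * ny - 0.5
    if fy < 0 or fy > ny - 1:
        raise ValueError("elevation_mm lies outside the grid")
    iy0 = int(np.floor(fy))
    iy1 = min(iy0 + 1, ny - 1)
    t = fy - iy0
    plane = (1.0 - t) * fmap.values[:, iy0, :] + t * fmap.values[:, iy1, :]
    plane = np.asarray(plane, dtype=np.float64)

    # grid voxel-center coordinates, x centered on the transducer
    gx = (np.arange(nx) + 0.5) * h - 0.5 * nx * h
    gz = (np.arange(nz) + 0.5) * h
    # image pixel centers
    px = (np.arange(img_nx) - 0.5 * (img_nx - 1)) * pixel_pitch_mm
    pz = (np.arange(img_nz) + 0.5) * pixel_pitch_mm

    interp = RegularGridInterpolator(
        (gx, gz), plane, bounds_error=False, fill_value=None
    )
    xx, zz = np.meshgrid(px, pz, indexing="xy")
    values = interp(np.stack([xx.ravel(), zz.ravel()], axis=1)).reshape(
        img_nz, img_nx
    )
    values = np.clip(values, 0.0, None).astype(np.float32)
    return FluenceMap(
        values=values,
        wavelength_nm=fmap.wavelength_nm,
        photons=fmap.photons,
        seed=fmap.seed,
        spacing_mm=pixel_pitch_mm,
        origin_mm=fmap.origin_mm,
        ledger=dict(fmap.ledger),
    )


def one_over_e_depth(
    fmap: FluenceMap,
    roi_start_depth_mm: float = 9.2,
    band_halfwidth_mm: float = 1.5,
) -> float:
    """Depth below ``roi_start_depth_mm`` at which the axial fluence
    profile first falls to 1/e of its value at the ROI start.

    The profile is the lateral mean over the central band (default +-1.5 mm
    about the axis) of the 2-D map; the crossing is located by linear
    interpolation between pixel centers.  The ROI start defaults to the
    advanced position of the LED tips, below which the image is usable.
    """
    if fmap.ndim != 2:
        raise ValueError("a 2-D imaging-plane fluence map is required")
    nz, nx = fmap.values.shape
    p = fmap.spacing_mm
    x = (np.arange(nx) - 0.5 * (nx - 1)) * p
    band = np.abs(x) <= band_halfwidth_mm
    if not band.any():
        band = np.zeros(nx, dtype=bool)
        band[nx // 2] = True
    profile = fmap.values[:, band].mean(axis=1)
    z = (np.arange(nz) + 0.5) * p

    if roi_start_depth_mm < z[0] or roi_start_depth_mm > z[-1]:
        raise ValueError("roi_start_depth_mm lies outside the map")
    ref = float(np.interp(roi_start_depth_mm, z, profile))
    if ref <= 0:
        raise ValueError("fluence at the ROI start depth is not positive")
    target = ref / math.e

    below = (z > roi_start_depth_mm) & (profile <= target)
    if not below.any():
        raise ValueError(
            "fluence never drops to 1/e within the grid; simulate a deeper "
            "volume or lower the ROI start depth"
        )
    k = int(np.argmax(below))
    z1, f1 = z[k], profile[k]
    z0 = max(roi_start_depth_mm, z[k - 1]) if k > 0 else roi_start_depth_mm
    f0 = float(np.interp(z0, z, profile))
    if f0 == f1:
        crossing = z1
    else:
        crossing = z0 + (f0 - target) * (z1 - z0) / (f0 - f1)
    return float(crossing - roi_start_depth_mm)
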