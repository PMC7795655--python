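"""Voxel grids, optical properties and fluence-map containers.

Conventions used throughout the package:

* Volumes are indexed ``[ix, iy, iz]`` (lateral, elevational, depth) with
  isotropic voxel spacing in mm.  The default grid matches the probe's
  simulation geometry: 744 x 744 x 512 voxels at 74 um (55 x 55 x 37.9 mm),
  laterally centered on the transducer with ``z = 0`` at its face.
* 2-D images (ultrasound, photoacoustic, fluence slices, sO2 maps) are
  ``[iz, ix]`` arrays — row 0 is the shallowest sample, matching the usual
  top-left display convention of B-mode imaging.
* Absorption and reduced scattering coefficients are stored in 1/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid3D",
    "OpticalProperties",
    "MediumGrid",
    "FluenceMap",
    "default_grid",
]


@dataclass(frozen=True)
class Grid3D:
    """Axis-aligned voxel grid with isotropic spacing.

    ``origin`` is the position (mm) of the corner of voxel (0, 0, 0); voxel
    centers sit at ``origin + (i + 0.5) * spacing``.
    """

    shape: tuple[int, int, int]
    spacing_mm: float = 0.074
    origin_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")
        if self.origin_mm is None:
            nx, ny, _ = self.shape
            object.__setattr__(
                self,
                "origin_mm",
                (
                    -0.5 * nx * self.spacing_mm,
                    -0.5 * ny * self.spacing_mm,
                    0.0,
                ),
            )

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.spacing_mm for n in self.shape)

    def voxel_volume_cm3(self) -> float:
        return (self.spacing_mm / 10.0) ** 3


def default_grid() -> Grid3D:
    """The full-resolution simulation grid of the default probe geometry."""
    return Grid3D(shape=(744, 744, 512), spacing_mm=0.074)


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption, reduced scattering and Henyey-Greenstein anisotropy.

    The Monte-Carlo model scatters at the full coefficient
    ``mus = musp / (1 - g)``; ``musp`` is what tissue tables quote.
    """

    mua_cm: float
    musp_cm: float
    g: float = 0.9

    def __post_init__(self) -> None:
        if self.mua_cm < 0 or self.musp_cm < 0:
            raise ValueError("mua_cm and musp_cm must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must lie in (-1, 1)")

    @property
    def mus_cm(self) -> float:
        return self.musp_cm / (1.0 - self.g)


@dataclass
class MediumGrid:
    """Labeled voxel volume with per-(label, wavelength) optical properties.

    Label 0 is the background (water by convention); labels 1..K are tissue
    types.  Every label present in ``labels`` must have properties for every
    wavelength that is simulated.
    """

    grid: Grid3D
    labels: np.ndarray
    properties: dict[tuple[int, int], OpticalProperties]

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.shape != tuple(self.grid.shape):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match grid "
                f"shape {self.grid.shape}"
            )

    def wavelengths(self) -> tuple[int, ...]:
        return tuple(sorted({wl for _, wl in self.properties}))

    def property_tables(
        self, wavelength_nm: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-label (mua, mus, g) lookup tables in 1/mm for one wavelength.

        Raises ``KeyError`` if any label present in the volume lacks
        properties at the requested wavelength.
        """
        present = np.unique(self.labels)
        n = int(present.max()) + 1
        mua = np.zeros(n)
        mus = np.zeros(n)
        g = np.zeros(n)
        for lab in present:
            key = (int(lab), int(wavelength_nm))
            if key not in self.properties:
                raise KeyError(
                    f"no optical properties for label {lab} at "
                    f"{wavelength_nm} nm"
                )
            props = self.properties[key]
            mua[lab] = props.mua_cm / 10.0
            mus[lab] = props.mus_cm / 10.0
            g[lab] = props.g
        return mua, mus, g


@dataclass
class FluenceMap:
    """Fluence per unit delivered pulse energy, 1/cm^2.

    ``values`` is either the full 3-D grid ``[ix, iy, iz]`` or an
    imaging-plane slice ``[iz, ix]``.  ``ledger`` carries the Monte-Carlo
    energy bookkeeping (launched / absorbed / escaped / roulette weights).
    """

    values: np.ndarray
    wavelength_nm: int
    photons: int
    seed: int
    spacing_mm: float
    origin_mm: tuple[float, float, float] | None = None
    ledger: dict[str, float] = field(default_factory=dict)

    @property
    def ndim(self) -> int:
        return self.values.ndim
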