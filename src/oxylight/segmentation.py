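"""Ultrasound tissue segmentation and medium construction.

The light model needs to know where tissue is.  A B-mode ultrasound image
co-registered with the photoacoustic frames is turned into a binary tissue
mask (`segment_tissue`) and the mask is extruded into the 3-D labeled
volume consumed by the Monte-Carlo simulation (`mask_to_medium`).

The segmentation pipeline is deliberately simple and fixed in order:
median filter (speckle smoothing), global threshold, Sobel edge detection
of the boundary, morphological hole filling, and selection of the largest
connected component.  The threshold is a required input — speckle
statistics differ between tissue types, so no automatic value is applied
silently; an Otsu suggestion is reported in the result for guidance.  The
Sobel boundary map is returned as a diagnostic; the mask itself is the
filled largest component of the thresholded image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .grids import Grid3D, MediumGrid, OpticalProperties

__all__ = [
    "USImage",
    "BinaryMask",
    "segment_tissue",
    "mask_to_medium",
]


@dataclass
class USImage:
    """Grayscale B-mode image, ``[depth, lateral]``, row 0 shallowest."""

    pixels: np.ndarray
    pixel_pitch_mm: float = 0.074

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("US image must be 2-D")
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise ValueError("US intensities must be finite and non-negative")


@dataclass
class BinaryMask:
    """Tissue mask on the US raster; 1 = tissue, 0 = background/water."""

    pixels: np.ndarray
    pixel_pitch_mm: float = 0.074
    edges: np.ndarray | None = None  # Sobel boundary diagnostic
    threshold_suggestion: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(np.uint8)
        if set(np.unique(self.pixels)) - {0, 1}:
            raise ValueError("mask must be binary")

    @property
    def boundary_rows(self) -> np.ndarray:
        """Per-column index of the first tissue row (-1 where none)."""
        any_t = self.pixels.any(axis=0)
        first = np.argmax(self.pixels, axis=0)
        return np.where(any_t, first, -1)


def segment_tissue(
    us: USImage,
    threshold: float,
    median_kernel: int = 5,
    water_above_row: int | None = None,
) -> BinaryMask:
    """Segment the tissue region of a B-mode image.

    Parameters
    ----------
    us : USImage
        Input image.
    threshold : float
        Global intensity threshold applied after median filtering; must lie
        within the image's intensity range.  Chosen manually per tissue
        type.
    median_kernel : int
        Side of the square median-filter footprint in pixels.
    water_above_row : int, optional
        For two-slab (water-over-tissue) acquisitions: force every pixel
        above this row to background, mirroring the convention that the
        coupling-water region is zeroed.

    Returns
    -------
    BinaryMask
        Filled largest connected component, with the Sobel boundary map and
        an Otsu threshold suggestion attached as diagnostics.
    """
    img = us.pixels
    lo, hi = float(img.min()), float(img.max())
    if not lo <= threshold <= hi:
        raise ValueError(
            f"threshold {threshold} outside image intensity range "
            f"[{lo:.4g}, {hi:.4g}]"
        )
    if median_kernel < 1:
        raise ValueError("median_kernel must be >= 1")

    smoothed = ndimage.median_filter(img, size=median_kernel)
    binary = smoothed > threshold
    if water_above_row is not None:
        binary[:water_above_row, :] = False
    if not binary.any():
        raise ValueError(
            "thresholding produced an empty mask; lower the threshold "
            f"(Otsu suggests {filters.threshold_otsu(smoothed):.4g})"
        )

    edges = filters.sobel(binary.astype(float))
    filled = ndimage.binary_fill_holes(binary)
    labeled = measure.label(filled, connectivity=2)
    largest = np.argmax(np.bincount(labeled.ravel())[1:]) + 1
    mask = (labeled == largest).astype(np.uint8)

    return BinaryMask(
        pixels=mask,
        pixel_pitch_mm=us.pixel_pitch_mm,
        edges=edges,
        threshold_suggestion=float(filters.threshold_otsu(smoothed)),
    )


def mask_to_medium(
    mask: BinaryMask,
    tissue_props: dict[int, OpticalProperties],
    background_props: dict[int, OpticalProperties],
    grid: Grid3D,
) -> MediumGrid:
    """Extrude a 2-D tissue mask into the 3-D simulation volume.

    The mask is placed at the lateral center of the grid; the first and
    last mask columns are replicated outward to fill the grid width, and
    the resulting 2-D label field is stacked uniformly along the
    elevational axis.  In-footprint pixels are transferred exactly — the
    mask's pixel pitch must equal the grid spacing.

    ``tissue_props`` / ``background_props`` map wavelength (nm) to the
    optical properties of labels 1 / 0.
    """
    if not np.isclose(mask.pixel_pitch_mm, grid.spacing_mm, rtol=1e-6):
        raise ValueError(
            f"mask pitch {mask.pixel_pitch_mm} mm does not match grid "
            f"spacing {grid.spacing_mm} mm"
        )
    m_nz, m_nx = mask.pixels.shape
    nx, ny, nz = grid.shape
    if m_nx > nx or m_nz > nz:
        raise ValueError(
            f"mask ({m_nx} wide x {m_nz} deep) exceeds the grid "
            f"({nx} x {nz})"
        )

    pad_left = (nx - m_nx) // 2
    pad_right = nx - m_nx - pad_left
    # mask is [depth, lateral]; the volume is [lateral, elevational, depth]
    sheet = np.pad(
        mask.pixels.T, ((pad_left, pad_right), (0, 0)), mode="edge"
    )  # (nx, m_nz)
    if m_nz < nz:
        sheet = np.pad(sheet, ((0, 0), (0, nz - m_nz)), mode="edge")
    labels = np.broadcast_to(sheet[:, None, :], (nx, ny, nz)).copy()

    properties = {}
    for wl, props in background_props.items():
        properties[(0, wl)] = props
    for wl, props in tissue_props.items():
        properties[(1, wl)] = props
    missing = set(w for _, w in properties) - set(background_props)
    if missing:
        warnings.warn(f"background properties missing for {missing} nm")
    return MediumGrid(grid=grid, labels=labels, properties=properties)
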