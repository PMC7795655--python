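"""Fluence compensation and linear spectral unmixing.

A reconstructed photoacoustic image is, per pixel, the product of the
local fluence and the blood absorption coefficient (times the Grüneisen
conversion efficiency):

    p(r, l) = Gamma * mu_a(r, l) * Phi(r, l),
    mu_a(r, l) = eps_HbR(l) c_HbR(r) + eps_HbO2(l) c_HbO2(r).

Dividing by the modeled fluence (`compensate_fluence`) removes the
depth- and wavelength-dependent illumination so the per-pixel 2x2 linear
system A x = b can be solved for the two hemoglobin concentrations
(`linear_unmix`); oxygen saturation follows as their ratio (`so2_map`).
sO2 is invariant to any common rescaling of the two compensated images and
to the overall scale of A, so neither the unknown Grüneisen parameter nor
the extinction-table log convention can bias it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import FluenceMap
from .spectra import ChromophoreSpectra

__all__ = [
    "PAImage",
    "CompensatedImage",
    "ConcentrationMaps",
    "SO2Map",
    "compensate_fluence",
    "linear_unmix",
    "so2_map",
    "roi_mean_so2",
    "amplitude_mask",
    "average_frames",
]


@dataclass
class PAImage:
    """Reconstructed PA amplitude image, ``[depth, lateral]``."""

    pixels: np.ndarray
    wavelength_nm: int
    pulse_energy_uJ: float = 1.0
    pixel_pitch_mm: float = 0.074

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("PA image must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("PA image must be finite")
        if self.pulse_energy_uJ <= 0:
            raise ValueError("pulse energy must be positive")


@dataclass
class CompensatedImage:
    """Fluence-normalized PA amplitude b = (p / E) / Phi."""

    pixels: np.ndarray
    wavelength_nm: int
    valid: np.ndarray
    floor_applied: np.ndarray


@dataclass
class ConcentrationMaps:
    """Relative HbR / HbO2 concentrations (arbitrary common scale).

    Least-squares estimates may be negative in noisy pixels; they are kept
    as-is here (diagnostics) and only handled at the sO2 stage.
    """

    c_hbr: np.ndarray
    c_hbo2: np.ndarray
    valid: np.ndarray


@dataclass
class SO2Map:
    """Per-pixel oxygen saturation in percent with a validity mask."""

    so2: np.ndarray
    valid: np.ndarray
    pixel_pitch_mm: float = 0.074


def average_frames(frames: list[PAImage]) -> PAImage:
    """Mean of repeated PA frames (the standard multi-frame convention)."""
    if not frames:
        raise ValueError("no frames to average")
    wl = frames[0].wavelength_nm
    if any(f.wavelength_nm != wl for f in frames):
        raise ValueError("cannot average frames of different wavelengths")
    if any(f.pixels.shape != frames[0].pixels.shape for f in frames):
        raise ValueError("frame shapes differ")
    return PAImage(
        pixels=np.mean([f.pixels for f in frames], axis=0),
        wavelength_nm=wl,
        pulse_energy_uJ=frames[0].pulse_energy_uJ,
        pixel_pitch_mm=frames[0].pixel_pitch_mm,
    )


def compensate_fluence(
    pa: PAImage,
    fl: FluenceMap,
    floor_fraction: float = 1e-3,
    normalize_energy: bool = True,
) -> CompensatedImage:
    """Divide a PA image by the modeled fluence map.

    The image is first divided by its pulse energy (unless
    ``normalize_energy`` is off, for data already exported
    energy-normalized) so both wavelengths share one energy scale.  Pixels
    where the fluence falls below ``floor_fraction`` of its maximum are
    marked invalid instead of being amplified into noise.
    """
    if fl.ndim != 2:
        raise ValueError("a 2-D imaging-plane fluence map is required")
    if pa.pixels.shape != fl.values.shape:
        raise ValueError(
            f"PA image shape {pa.pixels.shape} does not match fluence map "
            f"shape {fl.values.shape}"
        )
    if not 0.0 < floor_fraction < 1.0:
        raise ValueError("floor_fraction must lie in (0, 1)")

    phi = np.asarray(fl.values, dtype=np.float64)
    floor = floor_fraction * phi.max()
    ok = phi >= floor
    p = pa.pixels / pa.pulse_energy_uJ if normalize_energy else pa.pixels
    b = np.zeros_like(p)
    np.divide(p, phi, out=b, where=ok)
    return CompensatedImage(
        pixels=b,
        wavelength_nm=pa.wavelength_nm,
        valid=ok,
        floor_applied=~ok,
    )


def linear_unmix(
    b750: CompensatedImage,
    b850: CompensatedImage,
    spectra: ChromophoreSpectra,
) -> ConcentrationMaps:
    """Per-pixel least-squares solution of A x = b.

    With two wavelengths and two chromophores the normal equations reduce
    to the exact 2x2 solve; the closed form is applied vectorized over the
    image.
    """
    lo, hi = spectra.wavelengths_nm
    if (b750.wavelength_nm, b850.wavelength_nm) != (lo, hi):
        raise ValueError(
            f"compensated images ({b750.wavelength_nm}, {b850.wavelength_nm})"
            f" do not match spectra wavelengths ({lo}, {hi})"
        )
    if b750.pixels.shape != b850.pixels.shape:
        raise ValueError("compensated image shapes differ")
    a = spectra.matrix
    cond = np.linalg.cond(a)
    if cond > 1e6:
        raise ValueError(
            f"extinction matrix is ill-conditioned (cond={cond:.3g})"
        )
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    b1 = b750.pixels
    b2 = b850.pixels
    c_hbr = (a[1, 1] * b1 - a[0, 1] * b2) / det
    c_hbo2 = (-a[1, 0] * b1 + a[0, 0] * b2) / det
    return ConcentrationMaps(
        c_hbr=c_hbr,
        c_hbo2=c_hbo2,
        valid=b750.valid & b850.valid,
    )


def so2_map(
    conc: ConcentrationMaps,
    amplitude_mask: np.ndarray | None = None,
    pixel_pitch_mm: float = 0.074,
) -> SO2Map:
    """Oxygen saturation sO2 = 100 * cHbO2 / (cHbO2 + cHbR), clipped to
    [0, 100].

    Pixels with non-positive total hemoglobin, outside the fluence-validity
    mask, or outside ``amplitude_mask`` (a display/noise gate) are invalid.
    """
    total = conc.c_hbr + conc.c_hbo2
    valid = conc.valid & (total > 0)
    if amplitude_mask is not None:
        if amplitude_mask.shape != total.shape:
            raise ValueError("amplitude mask shape mismatch")
        valid = valid & amplitude_mask.astype(bool)
    so2 = np.zeros_like(total)
    np.divide(conc.c_hbo2, total, out=so2, where=valid)
    so2 = np.clip(100.0 * so2, 0.0, 100.0)
    so2[~valid] = np.nan
    return SO2Map(so2=so2, valid=valid, pixel_pitch_mm=pixel_pitch_mm)


def amplitude_mask(
    pa750: PAImage,
    pa850: PAImage,
    gate_multiple: float = 2.0,
    normalize_energy: bool = True,
) -> np.ndarray:
    """Noise gate: keep pixels whose mean energy-normalized amplitude
    exceeds ``gate_multiple`` times a robust noise estimate.

    The noise scale is 1.4826x the median absolute deviation of the image,
    which is dominated by background pixels when the signal is sparse.
    """
    p1 = np.abs(pa750.pixels) / (pa750.pulse_energy_uJ if normalize_energy else 1.0)
    p2 = np.abs(pa850.pixels) / (pa850.pulse_energy_uJ if normalize_energy else 1.0)
    mean_amp = 0.5 * (p1 + p2)
    mad = np.median(np.abs(mean_amp - np.median(mean_amp)))
    noise = 1.4826 * mad
    if noise == 0:
        return mean_amp > 0
    return mean_amp > gate_multiple * noise


def roi_mean_so2(
    m: SO2Map,
    roi_mm: tuple[float, float, float, float],
) -> tuple[float, int]:
    """Mean sO2 over the valid pixels of a rectangular region of interest.

    ``roi_mm`` is ``(x_min, x_max, z_min, z_max)`` in mm, with x centered
    on the image and z the depth from the top row.  Returns the mean and
    the number of valid pixels; raises if no valid pixel falls inside.
    """
    nz, nx = m.so2.shape
    p = m.pixel_pitch_mm
    x = (np.arange(nx) - 0.5 * (nx - 1)) * p
    z = (np.arange(nz) + 0.5) * p
    x0, x1, z0, z1 = roi_mm
    cols = (x >= x0) & (x <= x1)
    rows = (z >= z0) & (z <= z1)
    if not cols.any() or not rows.any():
        raise ValueError("ROI does not intersect the image")
    sub = m.so2[np.ix_(rows, cols)]
    sub_valid = m.valid[np.ix_(rows, cols)]
    n = int(sub_valid.sum())
    if n == 0:
        raise ValueError("ROI contains no valid pixels")
    return float(np.nanmean(sub[sub_valid])), n
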