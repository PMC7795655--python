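"""Chromophore extinction spectra and background absorption data.

Spectral unmixing of dual-wavelength photoacoustic images needs the molar
extinction coefficients of oxy- and deoxyhemoglobin at the two operating
wavelengths, arranged as the 2x2 system matrix

    A = [[eps_HbR(l1), eps_HbO2(l1)],
         [eps_HbR(l2), eps_HbO2(l2)]],   l1 = 750 nm, l2 = 850 nm.

Oxygen saturation is a concentration ratio, so it is invariant to the
overall scale of A and to the base-10 vs natural-log absorbance convention;
the bundled table uses the base-10 convention of the standard compiled
hemoglobin tabulations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ChromophoreSpectra",
    "default_spectra",
    "load_extinction_table",
    "water_mua_cm",
    "blood_mua_cm",
    "LN10",
]

LN10 = float(np.log(10.0))


def _parse_table(text: str) -> np.ndarray:
    """Parse a small CSV with '#' comments and one header line."""
    rows = [
        line
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if rows and not rows[0][0].isdigit():
        rows = rows[1:]
    return np.loadtxt(io.StringIO("\n".join(rows)), delimiter=",")


def _read_csv(name: str) -> np.ndarray:
    ref = resources.files("oxylight.data").joinpath(name)
    return _parse_table(ref.read_text())


def load_extinction_table(path: str | Path | None = None) -> np.ndarray:
    """Columns: wavelength (nm), eps_HbO2, eps_HbR  [1/(cm M), base 10]."""
    if path is None:
        return _read_csv("hemoglobin_extinction.csv")
    return _parse_table(Path(path).read_text())


@dataclass(frozen=True)
class ChromophoreSpectra:
    """HbR/HbO2 extinction coefficients at the probe's two wavelengths."""

    wavelengths_nm: tuple[int, int]
    eps_hbr: tuple[float, float]
    eps_hbo2: tuple[float, float]

    def __post_init__(self) -> None:
        if len(set(self.wavelengths_nm)) != 2:
            raise ValueError("two distinct wavelengths are required")
        if any(e <= 0 for e in self.eps_hbr + self.eps_hbo2):
            raise ValueError("extinction coefficients must be positive")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("extinction matrix is singular")

    @property
    def matrix(self) -> np.ndarray:
        """The 2x2 system matrix A; rows are wavelengths, columns (HbR, HbO2)."""
        return np.array(
            [
                [self.eps_hbr[0], self.eps_hbo2[0]],
                [self.eps_hbr[1], self.eps_hbo2[1]],
            ]
        )

    def mua_cm(self, wavelength_nm: int, c_hbr_M: float, c_hbo2_M: float) -> float:
        """Blood absorption coefficient (1/cm) at one of the two wavelengths
        for molar concentrations, base-10 extinction convention."""
        i = self.wavelengths_nm.index(wavelength_nm)
        return LN10 * (self.eps_hbr[i] * c_hbr_M + self.eps_hbo2[i] * c_hbo2_M)


def default_spectra(
    wavelengths_nm: tuple[int, int] = (750, 850),
    table: np.ndarray | None = None,
) -> ChromophoreSpectra:
    """Interpolate the bundled extinction table at the probe wavelengths.

    Sanity-checks the expected ordering around the ~800 nm isosbestic
    point: HbR dominates below it, HbO2 above.
    """
    if table is None:
        table = load_extinction_table()
    wl, hbo2, hbr = table[:, 0], table[:, 1], table[:, 2]
    lo, hi = sorted(wavelengths_nm)
    spectra = ChromophoreSpectra(
        wavelengths_nm=(lo, hi),
        eps_hbr=(float(np.interp(lo, wl, hbr)), float(np.interp(hi, wl, hbr))),
        eps_hbo2=(float(np.interp(lo, wl, hbo2)), float(np.interp(hi, wl, hbo2))),
    )
    if lo < 800 and spectra.eps_hbr[0] <= spectra.eps_hbo2[0]:
        raise ValueError(f"expected eps_HbR > eps_HbO2 at {lo} nm")
    if hi > 800 and spectra.eps_hbo2[1] <= spectra.eps_hbr[1]:
        raise ValueError(f"expected eps_HbO2 > eps_HbR at {hi} nm")
    return spectra


def water_mua_cm(wavelength_nm: float) -> float:
    """Pure-water absorption coefficient (1/cm) from the bundled table."""
    table = _read_csv("water_absorption.csv")
    return float(np.interp(wavelength_nm, table[:, 0], table[:, 1]))


def blood_mua_cm(
    spectra: ChromophoreSpectra,
    wavelength_nm: int,
    so2_percent: float,
    total_hemoglobin_gL: float = 150.0,
) -> float:
    """Whole-blood absorption coefficient (1/cm) at a given oxygenation.

    Total hemoglobin is converted to molar units with the 64,500 g/mol
    tetramer weight; only concentration ratios matter for sO2 estimation,
    but absolute values set realistic photoacoustic signal levels.
    """
    if not 0.0 <= so2_percent <= 100.0:
        raise ValueError("so2_percent must lie in [0, 100]")
    c_total = total_hemoglobin_gL / 64500.0
    frac = so2_percent / 100.0
    return spectra.mua_cm(wavelength_nm, c_total * (1 - frac), c_total * frac)
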