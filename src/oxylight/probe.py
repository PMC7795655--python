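"""LED-array probe geometry.

The probe couples a linear ultrasound transducer with two LED units, one on
each side of the transducer, inclined toward the imaging plane.  Each unit
carries four rows of LED elements, alternating between the two operating
wavelengths (850 nm and 750 nm for the default probe).  This module turns a
declarative :class:`ProbeConfig` into the explicit list of point emitters
used by the Monte-Carlo light model.

Coordinate frame (right-handed, mm):

* ``x`` — lateral, along the transducer array; ``x = 0`` at the array center.
* ``y`` — elevational; the imaging plane is ``y = 0``.
* ``z`` — depth, increasing into the medium; the transducer face is ``z = 0``.

Each LED unit is a ``unit_length x unit_width`` rectangle whose outer
(shallow) edge sits ``unit_standoff`` in front of the transducer face and
whose width direction descends into the medium at ``tilt_angle`` while
moving toward the imaging plane; the deep (advanced) edges of the two units
face each other across ``inter_unit_gap``.  Element rows run along ``x``;
the row list in the configuration is ordered from the outer edge inward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ProbeConfig",
    "EmitterElement",
    "build_led_sources",
    "total_source_weight",
    "load_probe_config",
    "default_probe_config",
]


@dataclass(frozen=True)
class ProbeConfig:
    """Declarative description of the dual-wavelength LED probe."""

    unit_length_mm: float = 50.0
    unit_width_mm: float = 10.0
    tilt_angle_deg: float = 41.4
    unit_standoff_mm: float = 0.15
    inter_unit_gap_mm: float = 9.56
    element_pitch_mm: float = 1.4
    row_pitch_mm: float = 1.72
    rows_per_unit: tuple[tuple[int, int], ...] = (
        (850, 36),
        (750, 24),
        (850, 36),
        (750, 24),
    )
    cone_full_angle_deg: float = 120.0
    pulse_energy_uJ: dict[int, float] = field(
        default_factory=lambda: {850: 200.0, 750: 100.0}
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.tilt_angle_deg < 90.0:
            raise ValueError("tilt_angle_deg must lie in (0, 90)")
        if not 0.0 < self.cone_full_angle_deg <= 180.0:
            raise ValueError("cone_full_angle_deg must lie in (0, 180]")
        for wl, count in self.rows_per_unit:
            if count <= 0:
                raise ValueError(f"row at {wl} nm has non-positive element count")
            if wl not in self.pulse_energy_uJ:
                raise ValueError(f"no pulse energy configured for {wl} nm")
        for wl, energy in self.pulse_energy_uJ.items():
            if energy <= 0:
                raise ValueError(f"pulse energy for {wl} nm must be positive")

    @property
    def wavelengths(self) -> tuple[int, ...]:
        """Distinct wavelengths present in the row layout, ascending."""
        return tuple(sorted({wl for wl, _ in self.rows_per_unit}))


@dataclass(frozen=True)
class EmitterElement:
    """One LED element as a point source with a cone emission pattern.

    ``relative_power`` is the element's fraction of its wavelength's total
    pulse energy (elements of one wavelength sum to 1);
    ``wavelength_energy_uJ`` carries that wavelength's absolute pulse energy
    so that cross-wavelength energy shares can be recovered from the element
    list alone.
    """

    position_mm: np.ndarray
    axis: np.ndarray
    half_angle_deg: float
    wavelength_nm: int
    relative_power: float
    wavelength_energy_uJ: float


def _row_offsets(cfg: ProbeConfig) -> np.ndarray:
    """Distances of the row centers from the unit's outer edge, centered
    across the unit width."""
    n_rows = len(cfg.rows_per_unit)
    span = (n_rows - 1) * cfg.row_pitch_mm
    if span > cfg.unit_width_mm:
        raise ValueError(
            f"{n_rows} rows at {cfg.row_pitch_mm} mm pitch do not fit within "
            f"the {cfg.unit_width_mm} mm unit width"
        )
    start = 0.5 * (cfg.unit_width_mm - span)
    return start + cfg.row_pitch_mm * np.arange(n_rows)


def _element_xs(cfg: ProbeConfig, count: int) -> np.ndarray:
    """Lateral element positions of one row, centered in the unit length."""
    span = (count - 1) * cfg.element_pitch_mm
    if span > cfg.unit_length_mm:
        raise ValueError(
            f"{count} elements at {cfg.element_pitch_mm} mm pitch exceed the "
            f"{cfg.unit_length_mm} mm unit length"
        )
    return cfg.element_pitch_mm * (np.arange(count) - 0.5 * (count - 1))


def build_led_sources(cfg: ProbeConfig) -> list[EmitterElement]:
    """Construct every LED element of both units in the probe frame.

    Elements of one wavelength share the pulse energy equally, so the
    ``relative_power`` values of each wavelength sum to 1.  The two units are
    mirror images across the imaging plane ``y = 0``.
    """
    theta = math.radians(cfg.tilt_angle_deg)
    sin_t, cos_t = math.sin(theta), math.cos(theta)
    half_angle = 0.5 * cfg.cone_full_angle_deg
    offsets = _row_offsets(cfg)

    counts_per_wl: dict[int, int] = {}
    for wl, count in cfg.rows_per_unit:
        counts_per_wl[wl] = counts_per_wl.get(wl, 0) + 2 * count  # both units

    elements: list[EmitterElement] = []
    for side in (+1.0, -1.0):
        # unit face normal, pointing into the medium and toward y = 0
        axis = np.array([0.0, -side * sin_t, cos_t])
        for d_row, (wl, count) in zip(offsets, cfg.rows_per_unit):
            y = side * (
                0.5 * cfg.inter_unit_gap_mm + (cfg.unit_width_mm - d_row) * cos_t
            )
            z = cfg.unit_standoff_mm + d_row * sin_t
            for x in _element_xs(cfg, count):
                elements.append(
                    EmitterElement(
                        position_mm=np.array([x, y, z]),
                        axis=axis.copy(),
                        half_angle_deg=half_angle,
                        wavelength_nm=wl,
                        relative_power=1.0 / counts_per_wl[wl],
                        wavelength_energy_uJ=cfg.pulse_energy_uJ[wl],
                    )
                )
    return elements


def total_source_weight(
    elements: list[EmitterElement], wavelength_nm: int
) -> float:
    """Fraction of the probe's total delivered pulse energy carried by one
    wavelength.

    For the default probe the 850 nm arrays run at twice the pulse energy of
    the 750 nm arrays, so ``total_source_weight(els, 850) /
    total_source_weight(els, 750) == 2``.
    """
    if not elements:
        raise ValueError("element list is empty")
    energies = {e.wavelength_nm: e.wavelength_energy_uJ for e in elements}
    if wavelength_nm not in energies:
        raise ValueError(
            f"no elements at {wavelength_nm} nm "
            f"(present: {sorted(energies)})"
        )
    return energies[wavelength_nm] / sum(energies.values())


def advanced_row_elevation_mm(
    cfg: ProbeConfig, wavelength_nm: int
) -> float:
    """Elevational distance from the imaging plane of the wavelength's most
    advanced (deepest, innermost) LED row.

    The illumination of one wavelength peaks around its advanced row; axial
    decay profiles for penetration analysis are taken through this plane.
    """
    elements = build_led_sources(cfg)
    ys = [
        abs(float(e.position_mm[1]))
        for e in elements
        if e.wavelength_nm == wavelength_nm
    ]
    if not ys:
        raise ValueError(f"no rows at {wavelength_nm} nm")
    return min(ys)


def load_probe_config(path: str | Path) -> ProbeConfig:
    """Read a probe configuration from a YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _config_from_dict(doc)


def _config_from_dict(doc: dict) -> ProbeConfig:
    rows = tuple((int(wl), int(n)) for wl, n in doc["rows_per_unit"])
    energies = {int(k): float(v) for k, v in doc["pulse_energy_uJ"].items()}
    return ProbeConfig(
        unit_length_mm=float(doc["unit_length_mm"]),
        unit_width_mm=float(doc["unit_width_mm"]),
        tilt_angle_deg=float(doc["tilt_angle_deg"]),
        unit_standoff_mm=float(doc["unit_standoff_mm"]),
        inter_unit_gap_mm=float(doc["inter_unit_gap_mm"]),
        element_pitch_mm=float(doc["element_pitch_mm"]),
        row_pitch_mm=float(doc["row_pitch_mm"]),
        rows_per_unit=rows,
        cone_full_angle_deg=float(doc["cone_full_angle_deg"]),
        pulse_energy_uJ=energies,
    )


def default_probe_config() -> ProbeConfig:
    """The bundled default probe (dual 750/850 nm LED units)."""
    ref = resources.files("oxylight.data").joinpath("probe_default.yaml")
    doc = yaml.safe_load(ref.read_text())
    return _config_from_dict(doc)
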