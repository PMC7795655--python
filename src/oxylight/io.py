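"""Raster and volume I/O: 32-bit float TIFF for images, HDF5 for volumes."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .grids import FluenceMap, Grid3D, MediumGrid, OpticalProperties

__all__ = [
    "read_image",
    "write_image",
    "write_fluence_h5",
    "read_fluence_h5",
    "write_medium_h5",
    "read_medium_h5",
]


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_image(path: str | Path, array: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))


def write_fluence_h5(path: str | Path, fmap: FluenceMap) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("values", data=fmap.values, compression="gzip")
        ds.attrs["wavelength_nm"] = fmap.wavelength_nm
        ds.attrs["photons"] = fmap.photons
        ds.attrs["seed"] = fmap.seed
        ds.attrs["spacing_mm"] = fmap.spacing_mm
        if fmap.origin_mm is not None:
            ds.attrs["origin_mm"] = np.asarray(fmap.origin_mm)
        for k, v in fmap.ledger.items():
            ds.attrs[f"ledger_{k}"] = v


def read_fluence_h5(path: str | Path) -> FluenceMap:
    with h5py.File(path, "r") as fh:
        ds = fh["values"]
        ledger = {
            k[len("ledger_") :]: float(v)
            for k, v in ds.attrs.items()
            if k.startswith("ledger_")
        }
        origin = ds.attrs.get("origin_mm")
        return FluenceMap(
            values=ds[...],
            wavelength_nm=int(ds.attrs["wavelength_nm"]),
            photons=int(ds.attrs["photons"]),
            seed=int(ds.attrs["seed"]),
            spacing_mm=float(ds.attrs["spacing_mm"]),
            origin_mm=tuple(origin) if origin is not None else None,
            ledger=ledger,
        )


def write_medium_h5(path: str | Path, medium: MediumGrid) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("labels", data=medium.labels, compression="gzip")
        ds.attrs["spacing_mm"] = medium.grid.spacing_mm
        ds.attrs["origin_mm"] = np.asarray(medium.grid.origin_mm)
        tab = fh.create_group("properties")
        for (label, wl), props in medium.properties.items():
            g = tab.create_group(f"{label}_{wl}")
            g.attrs["mua_cm"] = props.mua_cm
            g.attrs["musp_cm"] = props.musp_cm
            g.attrs["g"] = props.g


def read_medium_h5(path: str | Path) -> MediumGrid:
    with h5py.File(path, "r") as fh:
        labels = fh["labels"][...]
        spacing = float(fh["labels"].attrs["spacing_mm"])
        origin = tuple(fh["labels"].attrs["origin_mm"])
        properties = {}
        for key, g in fh["properties"].items():
            label, wl = key.split("_")
            properties[(int(label), int(wl))] = OpticalProperties(
                float(g.attrs["mua_cm"]),
                float(g.attrs["musp_cm"]),
                float(g.attrs["g"]),
            )
    grid = Grid3D(
        shape=tuple(labels.shape), spacing_mm=spacing, origin_mm=origin
    )
    return MediumGrid(grid=grid, labels=labels, properties=properties)
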