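"""Plain-text external interfaces: ASCII rasters, CSV tables, JSON records.

Rasters use the ESRI ASCII grid format (human-readable, one header block
plus whitespace-separated values) with the affine placement carried in the
header; multi-category fraction grids are written one file per category
with a JSON sidecar declaring the category/file mapping, year and cell
area.  Reference and price tables round-trip through CSV with explicit key
columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridGeometry
from .landuse import LandUseGrid

NODATA = -9999.0


def write_ascii_grid(path, arr: np.ndarray, geometry: GridGeometry) -> None:
    arr = np.asarray(arr, dtype=float)
    rows, cols = arr.shape
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {geometry.origin[0]:.6f}\n"
        f"yllcorner {geometry.origin[1]:.6f}\n"
        f"cellsize {geometry.cell_size:.6f}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.where(np.isfinite(arr), arr, NODATA), fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridGeometry]:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    arr[arr == header.get("nodata_value", NODATA)] = np.nan
    cell = header["cellsize"]
    geometry = GridGeometry(
        shape=(int(header["nrows"]), int(header["ncols"])),
        cell_area=cell * cell / 1e4,
        origin=(header["xllcorner"], header["yllcorner"]),
    )
    return arr, geometry


def write_landuse_grid(directory, grid: LandUseGrid, prefix: str = "landuse") -> Path:
    """One .asc per category plus a sidecar JSON; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for cat in grid.categories:
        fname = f"{prefix}_{grid.year}_{cat}.asc"
        write_ascii_grid(directory / fname, grid.fractions[cat], grid.geometry)
        files[cat] = fname
    sidecar = directory / f"{prefix}_{grid.year}.json"
    sidecar.write_text(
        json.dumps(
            {
                "year": grid.year,
                "cell_area_ha": grid.geometry.cell_area,
                "categories": files,
            },
            indent=2,
        )
    )
    return sidecar


def read_landuse_grid(sidecar) -> LandUseGrid:
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    fractions = {}
    geometry = None
    for cat, fname in meta["categories"].items():
        arr, geometry = read_ascii_grid(sidecar.parent / fname)
        fractions[cat] = arr
    assert geometry is not None
    return LandUseGrid(year=int(meta["year"]), fractions=fractions, geometry=geometry)


def write_occurrences(path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False)


def carbon_refs_to_frames(refs) -> dict[str, pd.DataFrame]:
    """CarbonReferenceTable -> tidy frames with explicit key columns."""
    return {
        "socref": pd.DataFrame(
            [(cl, so, v) for (cl, so), v in refs.socref.items()],
            columns=["climate_zone", "soil_class", "t_c_per_ha"],
        ),
        "stock_change_factor": pd.DataFrame(
            [(lu, b, v) for (lu, b), v in refs.stock_change_factor.items()],
            columns=["land_use", "biome", "factor"],
        ),
        "biomass": pd.DataFrame(
            [
                (lu, b, cl, refs.agb_ref[(lu, b, cl)], refs.bgb_ref[(lu, b, cl)])
                for (lu, b, cl) in refs.agb_ref
            ],
            columns=["land_use", "biome", "climate_zone", "agb_t_c_per_ha", "bgb_t_c_per_ha"],
        ),
        "managed_biomass": pd.DataFrame(
            [(lu, cl, v) for (lu, cl), v in refs.managed_biomass.items()],
            columns=["land_use", "climate_zone", "t_c_per_ha"],
        ),
    }


def write_carbon_refs(directory, refs) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, frame in carbon_refs_to_frames(refs).items():
        frame.to_csv(directory / f"{name}.csv", index=False)


def read_carbon_refs(directory):
    from .carbon import CarbonReferenceTable

    directory = Path(directory)
    # round_trip parsing: the default float parser is not bit-exact
    read = lambda p: pd.read_csv(p, float_precision="round_trip")
    socref = read(directory / "socref.csv")
    f = read(directory / "stock_change_factor.csv")
    bio = read(directory / "biomass.csv")
    managed = read(directory / "managed_biomass.csv")
    return CarbonReferenceTable(
        socref={(r.climate_zone, r.soil_class): r.t_c_per_ha for r in socref.itertuples()},
        stock_change_factor={(r.land_use, r.biome): r.factor for r in f.itertuples()},
        agb_ref={
            (r.land_use, r.biome, r.climate_zone): r.agb_t_c_per_ha for r in bio.itertuples()
        },
        bgb_ref={
            (r.land_use, r.biome, r.climate_zone): r.bgb_t_c_per_ha for r in bio.itertuples()
        },
        managed_biomass={
            (r.land_use, r.climate_zone): r.t_c_per_ha for r in managed.itertuples()
        },
    )
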