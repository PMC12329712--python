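"""Tier-1 terrestrial carbon accounting on land-use fraction grids.

Carbon density per cell (t C/ha) is the fraction-weighted sum over land-use
categories of a soil pool and a living-biomass pool:

* soil: ``SOCref(climate zone, soil class) x F(land use, biome)`` for the
  top 30 cm, where F is the stock-change factor (1 for natural vegetation);
* biomass: ``AGBref + BGBref`` for natural categories (forest, grassland,
  instantaneous mature systems), managed defaults for pasture / croplands /
  plantations, and zero for the "other" category.

Dead wood and litter pools are set to zero; stock changes between timesteps
are instantaneous.  National totals are reported in Gt C; carbon-to-CO2
conversion uses the molar ratio 44/12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import CategoricalMap, GridGeometry
from .landuse import CATEGORIES, NATURAL_CATEGORIES, LandUseGrid

CO2_PER_C = 44.0 / 12.0

MANAGED_CATEGORIES = (
    "pasture",
    "cropland_annual",
    "cropland_perennial",
    "cropland_semiperennial",
    "forest_plantation",
)


class MissingReferenceError(KeyError):
    """A required reference-table key is absent."""


@dataclass
class CarbonReferenceTable:
    """Reference densities and stock-change factors.

    socref : t C/ha keyed by (climate zone, soil class)
    stock_change_factor : dimensionless F keyed by (land use, biome)
    agb_ref, bgb_ref : t C/ha keyed by (land use, biome, climate zone), for
        the natural categories forest and grassland
    managed_biomass : total living biomass t C/ha keyed by (land use,
        climate zone), for managed categories
    """

    socref: dict[tuple[str, str], float]
    stock_change_factor: dict[tuple[str, str], float]
    agb_ref: dict[tuple[str, str, str], float]
    bgb_ref: dict[tuple[str, str, str], float]
    managed_biomass: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table, name in (
            (self.socref, "SOCref"),
            (self.agb_ref, "AGBref"),
            (self.bgb_ref, "BGBref"),
            (self.managed_biomass, "managed biomass"),
        ):
            for key, v in table.items():
                if v < 0:
                    raise ValueError(f"{name}{key} must be >= 0, got {v}")
        for (lu, biome), f in self.stock_change_factor.items():
            if f <= 0:
                raise ValueError(f"F({lu}, {biome}) must be > 0, got {f}")
            if lu in NATURAL_CATEGORIES and abs(f - 1.0) > 1e-12:
                raise ValueError(
                    f"natural vegetation must have F = 1, got F({lu}, {biome}) = {f}"
                )

    def get_socref(self, climate: str, soil: str) -> float:
        try:
            return self.socref[(climate, soil)]
        except KeyError:
            raise MissingReferenceError(
                f"SOCref missing for (climate={climate!r}, soil={soil!r})"
            ) from None

    def get_f(self, land_use: str, biome: str) -> float:
        try:
            return self.stock_change_factor[(land_use, biome)]
        except KeyError:
            raise MissingReferenceError(
                f"stock-change factor missing for (land_use={land_use!r}, biome={biome!r})"
            ) from None

    def get_biomass(self, land_use: str, biome: str, climate: str) -> float:
        """Total living biomass density (AGB + BGB) for one category."""
        if land_use == "other":
            return 0.0
        if land_use in NATURAL_CATEGORIES:
            try:
                return (
                    self.agb_ref[(land_use, biome, climate)]
                    + self.bgb_ref[(land_use, biome, climate)]
                )
            except KeyError:
                raise MissingReferenceError(
                    f"AGB/BGB reference missing for (land_use={land_use!r}, "
                    f"biome={biome!r}, climate={climate!r})"
                ) from None
        try:
            return self.managed_biomass[(land_use, climate)]
        except KeyError:
            raise MissingReferenceError(
                f"managed biomass missing for (land_use={land_use!r}, climate={climate!r})"
            ) from None


@dataclass
class CarbonStockMap:
    """Per-cell carbon density (t C/ha) with soil/biomass components."""

    density: np.ndarray
    year: int
    geometry: GridGeometry
    components: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density.shape != self.geometry.shape:
            raise ValueError("density shape mismatch")


def _lookup_grid(table_fn, keys_a: CategoricalMap, keys_b: CategoricalMap) -> np.ndarray:
    """Vectorised 2-key lookup over a pair of categorical maps."""
    out = np.empty((keys_a.n_classes, keys_b.n_classes))
    for i, la in enumerate(keys_a.labels):
        for j, lb in enumerate(keys_b.labels):
            out[i, j] = table_fn(la, lb)
    return out[keys_a.values, keys_b.values]


def soil_carbon_density(
    grid: LandUseGrid,
    refs: CarbonReferenceTable,
    climate: CategoricalMap,
    soil: CategoricalMap,
    biome: CategoricalMap,
) -> np.ndarray:
    """Top-30 cm soil organic carbon density, t C/ha per cell.

    Per cell: sum over land uses of fraction x SOCref(climate, soil)
    x F(land use, biome).
    """
    for m in (climate, soil, biome):
        grid.geometry.check_same(m.geometry)
    socref = _lookup_grid(refs.get_socref, climate, soil)
    density = np.zeros(grid.geometry.shape)
    for cat in grid.categories:
        f_by_biome = np.array([refs.get_f(cat, b) for b in biome.labels])
        density += grid.fractions[cat] * socref * f_by_biome[biome.values]
    return density


def biomass_carbon_density(
    grid: LandUseGrid,
    refs: CarbonReferenceTable,
    biome: CategoricalMap,
    climate: CategoricalMap,
) -> np.ndarray:
    """Living biomass (AGB + BGB) carbon density, t C/ha per cell."""
    for m in (biome, climate):
        grid.geometry.check_same(m.geometry)
    density = np.zeros(grid.geometry.shape)
    for cat in grid.categories:
        table = np.empty((biome.n_classes, climate.n_classes))
        for i, b in enumerate(biome.labels):
            for j, cl in enumerate(climate.labels):
                table[i, j] = refs.get_biomass(cat, b, cl)
        density += grid.fractions[cat] * table[biome.values, climate.values]
    return density


def carbon_stock_map(
    grid: LandUseGrid,
    refs: CarbonReferenceTable,
    climate: CategoricalMap,
    soil: CategoricalMap,
    biome: CategoricalMap,
) -> CarbonStockMap:
    """Total (soil + biomass) carbon stock map for one timestep."""
    soil_c = soil_carbon_density(grid, refs, climate, soil, biome)
    bio_c = biomass_carbon_density(grid, refs, biome, climate)
    return CarbonStockMap(
        density=soil_c + bio_c,
        year=grid.year,
        geometry=grid.geometry,
        components={"soil": soil_c, "biomass": bio_c},
    )


def national_carbon_stock(stock: CarbonStockMap) -> float:
    """National total carbon stock in Gt C (density x cell area, summed)."""
    return float(stock.density.sum() * stock.geometry.cell_area / 1e9)


def carbon_change(stock_a: CarbonStockMap, stock_b: CarbonStockMap):
    """Per-cell density delta (b - a, t C/ha) and national delta (Gt C)."""
    stock_a.geometry.check_same(stock_b.geometry)
    delta = stock_b.density - stock_a.density
    national = national_carbon_stock(stock_b) - national_carbon_stock(stock_a)
    return delta, national


def annualize_co2(delta_c_gt: float, years: int) -> float:
    """Convert a carbon stock change (Gt C) over a period to Gt CO2 per year.

    Positive input (carbon gained) maps to positive sequestration.
    """
    if years <= 0:
        raise ValueError(f"years must be > 0, got {years}")
    return delta_c_gt * CO2_PER_C / years


def carbon_density_loop_reference(
    grid: LandUseGrid,
    refs: CarbonReferenceTable,
    climate: CategoricalMap,
    soil: CategoricalMap,
    biome: CategoricalMap,
) -> np.ndarray:
    """Plain per-cell, per-category loop oracle for total carbon density.

    Kept deliberately naive and independent of the vectorised path; used by
    equivalence tests.
    """
    rows, cols = grid.geometry.shape
    out = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            cl = climate.label_at(r, c)
            so = soil.label_at(r, c)
            b = biome.label_at(r, c)
            acc = 0.0
            for cat in grid.categories:
                frac = grid.fractions[cat][r, c]
                acc += frac * refs.get_socref(cl, so) * refs.get_f(cat, b)
                acc += frac * refs.get_biomass(cat, b, cl)
            out[r, c] = acc
    return out
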