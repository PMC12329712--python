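"""Agricultural revenue on land-use fraction grids.

National revenue at a timestep is the sum over pasture and the three
cropland classes of price x yield x area, with prices indexed to the base
year and yields decomposed as potential yield x management factor x
cropping intensity (crops) or grass yield x grazing intensity / feed
efficiency (pasture, intensive systems).  Each land use is proxied by its
dominant commodity: soybean (annual), coffee (perennial), sugarcane
(semi-perennial) and bovine carcass (pasture).  Forest, grassland,
plantation and "other" contribute no agricultural revenue; forestry revenue
and production costs are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import CategoricalMap
from .landuse import LandUseGrid

logger = logging.getLogger(__name__)

#: Land-use category -> commodity proxy (dominant crop / product).
COMMODITY_PROXY = {
    "pasture": "cattle",
    "cropland_annual": "soybean",
    "cropland_perennial": "coffee",
    "cropland_semiperennial": "sugarcane",
}

#: Revenue-component label per agricultural category.
COMPONENT_NAME = {
    "pasture": "R_pa",
    "cropland_annual": "R_ca",
    "cropland_perennial": "R_cp",
    "cropland_semiperennial": "R_cs",
}


class MissingPriceError(KeyError):
    pass


@dataclass
class PriceTable:
    """Base-year prices per (commodity, admin unit) and price indices.

    ``base_price`` is USD2015/t; ``index`` maps (commodity, year) to the
    dimensionless multiplier (1 in the base year).  A state with no price
    for a commodity falls back to the average over states of its region
    (``region_of``); a region with no data at all raises.
    """

    base_price: dict[tuple[str, str], float]
    index: dict[tuple[str, int], float]
    region_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.base_price.values()):
            raise ValueError("base prices must be >= 0")

    def state_price(self, commodity: str, state: str) -> float:
        """Base-year price with regional-average fallback."""
        key = (commodity, state)
        if key in self.base_price:
            return self.base_price[key]
        region = self.region_of.get(state)
        peers = [
            v
            for (c, st), v in self.base_price.items()
            if c == commodity and self.region_of.get(st) == region
        ]
        if region is None or not peers:
            raise MissingPriceError(
                f"no price for ({commodity!r}, {state!r}) and no regional fallback"
            )
        logger.info(
            "price fallback: (%s, %s) -> regional average over %d states",
            commodity, state, len(peers),
        )
        return float(np.mean(peers))

    def get_index(self, commodity: str, year: int) -> float:
        try:
            return self.index[(commodity, year)]
        except KeyError:
            raise MissingPriceError(
                f"no price index for ({commodity!r}, {year})"
            ) from None


@dataclass
class CropYieldParams:
    """Potential yield (t/ha/yr), management factor, cropping intensity."""

    potential_yield: float
    management_factor: float
    cropping_intensity: float

    def __post_init__(self) -> None:
        for v in (self.potential_yield, self.management_factor, self.cropping_intensity):
            if v < 0:
                raise ValueError("crop yield parameters must be >= 0")


@dataclass
class PastureYieldParams:
    """Grass potential (t dm/ha/yr), grazing intensity, feed efficiency
    (t dm per t carcass)."""

    potential_grass: float
    grazing_intensity: float
    feed_efficiency: float

    def __post_init__(self) -> None:
        if self.feed_efficiency <= 0:
            raise ValueError("feed efficiency must be > 0")
        if self.potential_grass < 0 or self.grazing_intensity < 0:
            raise ValueError("pasture yield parameters must be >= 0")


@dataclass
class RevenueResult:
    """Per-cell revenue density (USD2015/ha/yr), national total and
    components (USD2015/yr)."""

    density: np.ndarray
    national: float
    components: dict[str, float]
    year: int


def indexed_price(base: float, index: float) -> float:
    """Price at time t: base price x index (identity in the base year)."""
    if base < 0 or index < 0:
        raise ValueError("price and index must be >= 0")
    return base * index


def crop_yield(params: CropYieldParams) -> float:
    """Crop yield, t/ha/yr: potential x management x cropping intensity."""
    return params.potential_yield * params.management_factor * params.cropping_intensity


def pasture_yield(params: PastureYieldParams) -> float:
    """Carcass yield, t/ha/yr: grass potential x grazing intensity / feed
    efficiency."""
    return params.potential_grass * params.grazing_intensity / params.feed_efficiency


def landuse_revenue(price: float, yield_t: float, area_ha: float) -> float:
    """Revenue of one land use, USD/yr: price x yield x area."""
    if price < 0 or yield_t < 0 or area_ha < 0:
        raise ValueError("price, yield and area must be >= 0")
    return price * yield_t * area_ha


def revenue_assessment(
    grid: LandUseGrid,
    prices: PriceTable,
    crop_params: dict[tuple[str, int], CropYieldParams],
    pasture_params: dict[int, PastureYieldParams],
    state_map: CategoricalMap,
    year: int | None = None,
) -> RevenueResult:
    """Spatially explicit revenue for one timestep.

    Per cell, each agricultural category contributes fraction x cell area x
    state-level indexed price x year-specific yield; non-agricultural
    categories contribute zero.
    """
    grid.geometry.check_same(state_map.geometry)
    year = grid.year if year is None else year
    density = np.zeros(grid.geometry.shape)
    components: dict[str, float] = {v: 0.0 for v in COMPONENT_NAME.values()}
    cell_area = grid.geometry.cell_area
    for cat, commodity in COMMODITY_PROXY.items():
        if cat not in grid.fractions:
            continue
        if cat == "pasture":
            try:
                yld = pasture_yield(pasture_params[year])
            except KeyError:
                raise MissingPriceError(f"no pasture yield parameters for {year}") from None
        else:
            try:
                yld = crop_yield(crop_params[(commodity, year)])
            except KeyError:
                raise MissingPriceError(
                    f"no crop yield parameters for ({commodity!r}, {year})"
                ) from None
        idx = prices.get_index(commodity, year)
        price_by_state = np.array(
            [indexed_price(prices.state_price(commodity, st), idx)
             for st in state_map.labels]
        )
        price_grid = price_by_state[state_map.values]
        dens = grid.fractions[cat] * price_grid * yld  # USD per ha of cell
        density += dens
        components[COMPONENT_NAME[cat]] += float(dens.sum() * cell_area)
    national = float(sum(components.values()))
    return RevenueResult(density=density, national=national, components=components, year=year)
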