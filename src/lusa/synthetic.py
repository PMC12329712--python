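"""Synthetic study systems with known ground truth.

Everything the assessment pipeline consumes can be generated here: scenario
land-use fraction grids with prescribed national category trajectories,
spatially autocorrelated environmental layers and categorical maps (biome,
climate zone, soil class, admin unit), synthetic species with known logistic
suitability, and carbon / price / yield reference tables in plausible
Brazilian ranges.  All draws are reproducible from one integer seed, split
deterministically per sub-generator.

The scenario generator redistributes fractions between consecutive
timesteps by biproportional (RAS) scaling of a seed matrix that favours
expansion adjacent to existing cells of a category, so change is spatially
contiguous without re-implementing a full land-use allocation model.
National totals follow linear paths from the base year to
``(1 + trajectory) x base total``; one designated balance category absorbs
the (small) residual needed to conserve total land area exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import CategoricalMap, GridGeometry
from .landuse import RAW_CATEGORIES, LandUseGrid

ENV_LAYERS = (
    "forest",
    "cropland",
    "forest_plantation",
    "grassland_pasture",
    "slope",
    "elevation",
    "temperature",
    "temperature_seasonality",
    "precipitation",
    "precipitation_seasonality",
)

COMMODITIES = ("soybean", "coffee", "sugarcane", "cattle")

BIOME_LABELS = ("amazon", "cerrado", "atlantic_forest")
CLIMATE_LABELS = ("tropical", "subtropical")
SOIL_LABELS = ("clayey", "loamy", "sandy")


class InfeasibleTrajectoryError(ValueError):
    """A category trajectory cannot be realised on the grid."""


class DegenerateSpeciesError(ValueError):
    """A synthetic species has no suitable cells."""


def _stream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of one master seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode()) & 0x7FFFFFFF])


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardised spatially autocorrelated Gaussian field."""
    f = gaussian_filter(rng.normal(size=shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / (f.std() + 1e-12)


@dataclass
class ScenarioConfig:
    """One land-use scenario: grid, horizon, trajectories, price paths.

    ``category_trajectories`` gives, per raw category, the relative change of
    its national total over the horizon (e.g. +0.23 means the 2050 total is
    1.23x the 2015 total).  ``balance_category`` absorbs the residual so
    total land area is conserved exactly; set it to ``None`` to require
    balanced trajectories.  ``price_index_trajectories`` gives the end-year
    multiplicative price index per commodity (index is 1 in the start year
    and follows a linear path).
    """

    scenario_id: str = "SSP2-like"
    start_year: int = 2015
    end_year: int = 2050
    step: int = 5
    grid_shape: tuple[int, int] = (50, 50)
    cell_area: float = 10_000.0  # ha: a 10 x 10 km cell
    base_shares: dict[str, float] = field(
        default_factory=lambda: {
            "forest": 0.45,
            "grassland": 0.20,
            "pasture": 0.19,
            "cropland": 0.094,
            "forest_plantation": 0.011,
            "mosaic": 0.025,
            "other": 0.03,
        }
    )
    category_trajectories: dict[str, float] = field(
        default_factory=lambda: {
            "forest": -0.01,
            "grassland": -0.19,
            "pasture": 0.12,
            "cropland": 0.21,
            "forest_plantation": -0.07,
            "other": 0.09,
        }
    )
    balance_category: str | None = "mosaic"
    price_index_trajectories: dict[str, float] = field(
        default_factory=lambda: {c: 0.85 for c in COMMODITIES}
    )
    management_trend: float = 1.15  # end-year multiplier on crop management factor
    feed_efficiency_trend: float = 0.9  # end-year multiplier on feed per carcass
    n_species: int = 10
    mean_presences: float = 66.0
    n_pseudo_absences: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0 or (self.end_year - self.start_year) % self.step:
            raise ValueError("step must be positive and divide the horizon")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be > 0")
        unknown = set(self.base_shares) - set(RAW_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown base-share categories: {sorted(unknown)}")
        if abs(sum(self.base_shares.values()) - 1.0) > 1e-9:
            raise ValueError("base shares must sum to 1")
        for cat, tr in self.category_trajectories.items():
            if cat not in RAW_CATEGORIES:
                raise ValueError(f"trajectory for unknown category {cat!r}")
            if 1.0 + tr < 0:
                raise InfeasibleTrajectoryError(
                    f"trajectory {tr:+.2f} would drive {cat!r} below zero area"
                )

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1, self.step))

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(shape=self.grid_shape, cell_area=self.cell_area)

    def price_index(self, commodity: str, year: int) -> float:
        """Linear index path from 1 at start year to the end multiplier."""
        end = self.price_index_trajectories.get(commodity, 1.0)
        s = (year - self.start_year) / (self.end_year - self.start_year)
        return 1.0 + (end - 1.0) * s


def ssp1_like(**overrides) -> ScenarioConfig:
    """Sustainability pathway: natural vegetation expands, agriculture and
    prices contract."""
    cfg = ScenarioConfig(
        scenario_id="SSP1-like",
        category_trajectories={
            "forest": 0.23,
            "grassland": -0.07,
            "pasture": -0.36,
            "cropland": -0.15,
            "forest_plantation": -0.54,
            "other": 0.23,
        },
        price_index_trajectories={c: 0.70 for c in COMMODITIES},
        management_trend=1.30,
        feed_efficiency_trend=0.80,
    )
    return replace(cfg, **overrides)


def ssp2_like(**overrides) -> ScenarioConfig:
    """Middle-of-the-road pathway: agriculture expands, prices drift down."""
    cfg = ScenarioConfig(
        scenario_id="SSP2-like",
        category_trajectories={
            "forest": -0.01,
            "grassland": -0.19,
            "pasture": 0.12,
            "cropland": 0.21,
            "forest_plantation": -0.07,
            "other": 0.09,
        },
        price_index_trajectories={c: 0.85 for c in COMMODITIES},
        management_trend=1.15,
        feed_efficiency_trend=0.90,
    )
    return replace(cfg, **overrides)


def ssp3_like(**overrides) -> ScenarioConfig:
    """Inequality pathway: strong agricultural expansion, rising prices."""
    cfg = ScenarioConfig(
        scenario_id="SSP3-like",
        category_trajectories={
            "forest": -0.03,
            "grassland": -0.29,
            "pasture": 0.26,
            "cropland": 0.26,
            "forest_plantation": 0.09,
            "other": 0.10,
        },
        price_index_trajectories={c: 1.25 for c in COMMODITIES},
        management_trend=1.05,
        feed_efficiency_trend=1.00,
    )
    return replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# scenario land-use grids
# ---------------------------------------------------------------------------


def _ras(seed_matrix: np.ndarray, col_targets: np.ndarray, n_iter: int = 500,
         tol: float = 1e-12) -> np.ndarray:
    """Biproportional fit: rows sum to 1 exactly, columns to targets.

    ``seed_matrix`` is (n_cells, n_categories) and strictly positive where a
    category may occur; ``col_targets`` sums to n_cells (fraction units).
    """
    m = seed_matrix.copy()
    active = col_targets > 0
    m[:, ~active] = 0.0
    total = col_targets.sum()
    for _ in range(n_iter):
        cs = m.sum(axis=0)
        scale = np.ones_like(cs)
        scale[active] = col_targets[active] / np.maximum(cs[active], 1e-300)
        m *= scale
        rs = m.sum(axis=1, keepdims=True)
        m /= np.maximum(rs, 1e-300)
        if np.abs(m.sum(axis=0) - col_targets).max() < tol * total:
            break
    m /= m.sum(axis=1, keepdims=True)  # end on rows: per-cell sum exactly 1
    return m


def _resolve_targets(config: ScenarioConfig) -> dict[str, np.ndarray]:
    """Per-category national totals (fraction units, cells) per timestep."""
    n = config.geometry.n_cells
    base = {c: config.base_shares.get(c, 0.0) * n for c in RAW_CATEGORIES}
    traj = {c: config.category_trajectories.get(c, 0.0) for c in RAW_CATEGORIES}
    bal = config.balance_category
    residual = sum(base[c] * traj[c] for c in RAW_CATEGORIES if c != bal)
    if bal is not None:
        if base[bal] <= 0:
            raise InfeasibleTrajectoryError(
                f"balance category {bal!r} has zero base area; cannot absorb "
                f"residual of {residual:.1f} cells"
            )
        traj[bal] = -residual / base[bal]
        if 1.0 + traj[bal] < 0:
            raise InfeasibleTrajectoryError(
                f"balance category {bal!r} would need trajectory "
                f"{traj[bal]:+.2f} (< -1) to conserve total land area"
            )
    else:
        residual_all = sum(base[c] * traj[c] for c in RAW_CATEGORIES)
        if abs(residual_all) > 1e-6 * n:
            raise InfeasibleTrajectoryError(
                "trajectories do not conserve total land area "
                f"(residual {residual_all / n:+.4%} of territory) and no "
                "balance category is set"
            )
    steps = config.years
    horizon = steps[-1] - steps[0]
    out: dict[str, np.ndarray] = {}
    for c in RAW_CATEGORIES:
        s = np.array([(y - steps[0]) / horizon for y in steps])
        out[c] = base[c] * (1.0 + traj[c] * s)
        if (out[c] < -1e-9).any():
            raise InfeasibleTrajectoryError(f"category {c!r} total goes negative")
    return out


def _base_map(config: ScenarioConfig) -> np.ndarray:
    """Spatially coherent base-year fractions matching national base shares."""
    rng = _stream(config.seed, "base_map")
    rows, cols = config.grid_shape
    sigma = max(rows, cols) / 12
    n = rows * cols
    fields = np.stack(
        [np.exp(1.8 * _smooth_field(rng, (rows, cols), sigma)) for _ in RAW_CATEGORIES],
        axis=-1,
    ).reshape(n, len(RAW_CATEGORIES))
    fields /= fields.sum(axis=1, keepdims=True)
    targets = np.array([config.base_shares.get(c, 0.0) * n for c in RAW_CATEGORIES])
    return _ras(fields, targets)


def generate_scenario(config: ScenarioConfig) -> list[LandUseGrid]:
    """Generate one raw-category fraction grid per scenario timestep.

    Per-cell fractions are valid at every timestep, total land area is
    conserved exactly, and each category's national total follows a linear,
    monotone path to ``(1 + trajectory) x base`` (balance category aside).
    """
    targets = _resolve_targets(config)
    geometry = config.geometry
    rows, cols = config.grid_shape
    n = geometry.n_cells
    frontier_sigma = max(rows, cols) / 25 + 1.0

    m = _base_map(config)
    grids = []
    target_mat = np.stack([targets[c] for c in RAW_CATEGORIES], axis=-1)
    for i, year in enumerate(config.years):
        # reallocate only when demand changed; otherwise the map stays frozen
        if i > 0 and np.abs(target_mat[i] - target_mat[i - 1]).max() > 1e-12 * n:
            # seed allocation: current pattern plus a smoothed frontier term so
            # growth attaches to existing patches, plus a tiny floor so any
            # cell can ultimately convert
            seed = np.empty_like(m)
            for k in range(len(RAW_CATEGORIES)):
                layer = m[:, k].reshape(rows, cols)
                front = gaussian_filter(layer, sigma=frontier_sigma, mode="reflect")
                seed[:, k] = m[:, k] + 0.08 * front.ravel() + 1e-9
            m = _ras(seed, target_mat[i])
        frac = {
            c: m[:, k].reshape(rows, cols).copy()
            for k, c in enumerate(RAW_CATEGORIES)
        }
        grids.append(LandUseGrid(year=year, fractions=frac, geometry=geometry))
    return grids


# ---------------------------------------------------------------------------
# landscape layers
# ---------------------------------------------------------------------------


@dataclass
class Landscape:
    """Static environmental layers and categorical maps of the study area."""

    static_layers: dict[str, np.ndarray]  # slope..precipitation_seasonality
    biome: CategoricalMap
    climate: CategoricalMap
    soil: CategoricalMap
    state: CategoricalMap
    geometry: GridGeometry


def _voronoi_partition(rng: np.random.Generator, shape, n_regions: int) -> np.ndarray:
    rows, cols = shape
    seeds = np.column_stack(
        [rng.uniform(0, rows, n_regions), rng.uniform(0, cols, n_regions)]
    )
    rr, cc = np.meshgrid(np.arange(rows) + 0.5, np.arange(cols) + 0.5, indexing="ij")
    d = (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
    return d.argmin(axis=-1)


def generate_landscape(config: ScenarioConfig, n_states: int = 8) -> Landscape:
    """Biome/climate/soil/state maps plus static topographic/climatic layers.

    Categorical maps partition the grid; continuous layers are spatially
    autocorrelated with a latitudinal gradient on temperature.  Climate and
    topography are static over the scenario horizon.
    """
    rng = _stream(config.seed, "landscape")
    rows, cols = config.grid_shape
    shape = (rows, cols)
    sigma = max(rows, cols) / 10

    lat = np.linspace(0.0, 1.0, rows)[:, None] * np.ones((1, cols))
    elevation = 600.0 + 450.0 * _smooth_field(rng, shape, sigma)
    elevation = np.clip(elevation, 0.0, None)
    slope = np.clip(2.0 + 1.5 * _smooth_field(rng, shape, sigma / 2)
                    + 0.004 * np.abs(elevation - elevation.mean()), 0.0, 25.0)
    temperature = 27.0 - 7.0 * lat - 0.004 * elevation + 0.8 * _smooth_field(rng, shape, sigma)
    temp_seasonality = 1.0 + 2.5 * lat + 0.4 * _smooth_field(rng, shape, sigma)
    precipitation = np.clip(
        1800.0 - 900.0 * lat + 350.0 * _smooth_field(rng, shape, sigma), 200.0, None
    )
    precip_seasonality = np.clip(
        45.0 + 18.0 * _smooth_field(rng, shape, sigma) + 10.0 * lat, 5.0, 100.0
    )

    geometry = config.geometry
    biome = CategoricalMap(
        _voronoi_partition(rng, shape, len(BIOME_LABELS)), list(BIOME_LABELS), geometry
    )
    climate_vals = (temperature < np.quantile(temperature, 0.35)).astype(int)
    climate = CategoricalMap(climate_vals, ["tropical", "subtropical"], geometry)
    soil_field = _smooth_field(rng, shape, sigma)
    soil_vals = np.digitize(soil_field, np.quantile(soil_field, [1 / 3, 2 / 3]))
    soil = CategoricalMap(soil_vals, list(SOIL_LABELS), geometry)
    state = CategoricalMap(
        _voronoi_partition(rng, shape, n_states),
        [f"state_{i + 1:02d}" for i in range(n_states)],
        geometry,
    )
    return Landscape(
        static_layers={
            "slope": slope,
            "elevation": elevation,
            "temperature": temperature,
            "temperature_seasonality": temp_seasonality,
            "precipitation": precipitation,
            "precipitation_seasonality": precip_seasonality,
        },
        biome=biome,
        climate=climate,
        soil=soil,
        state=state,
        geometry=geometry,
    )


@dataclass
class EnvStack:
    """The ten SDM predictor layers on one grid.

    Four land-use fractions (forest, cropland, forest plantation,
    grassland-pasture), two topographic and four climatic layers.
    """

    layers: dict[str, np.ndarray]
    geometry: GridGeometry

    def __post_init__(self) -> None:
        missing = set(ENV_LAYERS) - set(self.layers)
        if missing:
            raise ValueError(f"EnvStack missing layers: {sorted(missing)}")
        for name, arr in self.layers.items():
            if arr.shape != self.geometry.shape:
                raise ValueError(f"layer {name!r} shape mismatch")

    def matrix(self, names=ENV_LAYERS) -> np.ndarray:
        """(n_cells, len(names)) design matrix of per-cell layer values."""
        return np.column_stack([self.layers[n].ravel() for n in names])

    def values_at(self, x, y, names=ENV_LAYERS) -> np.ndarray:
        row, col = self.geometry.cell_of(x, y)
        return np.column_stack([self.layers[n][row, col] for n in names])


def env_stack(grid: LandUseGrid, landscape: Landscape) -> EnvStack:
    """Combine a land-use grid (raw or canonical) with static layers."""
    grid.geometry.check_same(landscape.geometry)
    f = grid.fractions
    if "cropland" in f:  # raw vocabulary
        cropland = f["cropland"]
    else:
        cropland = (
            f["cropland_annual"] + f["cropland_perennial"] + f["cropland_semiperennial"]
        )
    layers = {
        "forest": f["forest"],
        "cropland": cropland,
        "forest_plantation": f["forest_plantation"],
        "grassland_pasture": f["grassland"] + f["pasture"],
        **landscape.static_layers,
    }
    return EnvStack(layers=layers, geometry=grid.geometry)


# ---------------------------------------------------------------------------
# synthetic species
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpecies:
    """Ground truth for one species: logistic coefficients and range mask.

    ``true_coefficients`` maps ``"intercept"`` and predictor names to
    raw-scale logistic weights; suitability is the logistic of their linear
    combination over the environmental layers.
    """

    species_id: str
    true_coefficients: dict[str, float]
    true_range_mask: np.ndarray
    n_presences: int

    def __post_init__(self) -> None:
        if not self.true_range_mask.any():
            raise DegenerateSpeciesError(f"{self.species_id}: empty range mask")
        if not all(np.isfinite(v) for v in self.true_coefficients.values()):
            raise DegenerateSpeciesError(f"{self.species_id}: non-finite coefficients")


def true_suitability(species: SyntheticSpecies, env: EnvStack) -> np.ndarray:
    """Per-cell logistic suitability of a synthetic species."""
    eta = np.full(env.geometry.shape, species.true_coefficients["intercept"])
    for name, beta in species.true_coefficients.items():
        if name != "intercept":
            eta = eta + beta * env.layers[name]
    return 1.0 / (1.0 + np.exp(-eta))


def _make_species(
    env: EnvStack,
    rng: np.random.Generator,
    species_id: str,
    mean_presences: float,
    n_active: tuple[int, int] = (2, 4),
    prevalence: float = 0.35,
) -> SyntheticSpecies:
    names = list(ENV_LAYERS)
    mat = env.matrix(names)
    mu, sd = mat.mean(axis=0), mat.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)

    rows, cols = env.geometry.shape
    sigma = max(rows, cols) / 8
    blob = _smooth_field(rng, (rows, cols), sigma)
    coverage = rng.uniform(0.3, 0.6)
    mask = blob >= np.quantile(blob, 1.0 - coverage)
    if not mask.any() or mask.all():
        raise DegenerateSpeciesError(f"{species_id}: degenerate range mask")

    # restrict true drivers to layers that are mutually weakly correlated
    # *within the range mask* (stricter than downstream pruning), so the
    # generating model stays identifiable after correlation pruning of a
    # design matrix sampled from the range
    z = (mat - mu) / sd
    corr = np.abs(np.corrcoef(z[mask.ravel()].T))
    corr = np.nan_to_num(corr)
    np.fill_diagonal(corr, 0.0)
    candidates = list(range(len(names)))
    while len(candidates) > 2:
        sub = corr[np.ix_(candidates, candidates)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < 0.5:
            break
        drop = i if sub[i].mean() >= sub[j].mean() else j
        candidates.pop(drop)

    k = int(rng.integers(n_active[0], n_active[1] + 1))
    k = min(k, len(candidates))
    active = rng.choice(candidates, size=k, replace=False)
    beta_std = rng.uniform(0.8, 2.0, size=k) * rng.choice([-1.0, 1.0], size=k)

    # calibrate intercept (standardised scale) so mean suitability inside the
    # range mask is close to the target prevalence
    eta_no_b0 = z[:, active] @ beta_std
    inside = eta_no_b0[mask.ravel()]

    def mean_p(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + inside)))))

    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    b0_std = 0.5 * (lo + hi)

    coeffs = {"intercept": float(b0_std - np.sum(beta_std * mu[active] / sd[active]))}
    for j, idx in enumerate(active):
        coeffs[names[idx]] = float(beta_std[j] / sd[idx])

    n = max(1, int(rng.poisson(mean_presences)))
    return SyntheticSpecies(
        species_id=species_id,
        true_coefficients=coeffs,
        true_range_mask=mask,
        n_presences=n,
    )


def sample_presences(
    species: SyntheticSpecies, env: EnvStack, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Presence records inside the range mask, accepted with probability equal
    to the true suitability of the visited cell (rejection sampling over
    uniformly chosen mask cells)."""
    p = true_suitability(species, env).ravel()
    mask_cells = np.flatnonzero(species.true_range_mask.ravel())
    if mask_cells.size == 0:
        raise DegenerateSpeciesError(species.species_id)
    chosen: list[np.ndarray] = []
    n_found = 0
    while n_found < n:
        batch = max(64, 2 * (n - n_found))
        cells = rng.choice(mask_cells, size=batch)
        keep = rng.random(batch) < p[cells]
        acc = cells[keep]
        if acc.size:
            chosen.append(acc)
            n_found += acc.size
    cells = np.concatenate(chosen)[:n]
    rows, cols = np.divmod(cells, env.geometry.shape[1])
    x, y = env.geometry.cell_center(rows, cols)
    jitter = env.geometry.cell_size * 0.45
    x = x + rng.uniform(-jitter, jitter, size=n)
    y = y + rng.uniform(-jitter, jitter, size=n)
    return pd.DataFrame(
        {"species_id": species.species_id, "x": x, "y": y, "source": "synthetic"}
    )


def labeled_survey(
    species: SyntheticSpecies, env: EnvStack, n: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Labelled survey inside the range mask: uniform cells, Bernoulli(p) labels.

    Under this design the presence/absence log-density ratio is exactly the
    generating linear logit, so logistic fits are consistent for the true
    coefficients — the design used by coefficient-recovery tests.
    """
    mask_cells = np.flatnonzero(species.true_range_mask.ravel())
    cells = rng.choice(mask_cells, size=n)
    p = true_suitability(species, env).ravel()[cells]
    y = (rng.random(n) < p).astype(int)
    mat = env.matrix()
    X = pd.DataFrame(mat[cells], columns=list(ENV_LAYERS))
    return X, y


def generate_species(
    env: EnvStack,
    n_species: int,
    config: ScenarioConfig,
    mean_presences: float | None = None,
) -> tuple[list[SyntheticSpecies], pd.DataFrame]:
    """Synthetic species pool plus pooled presence records.

    Record counts per species are Poisson around ``mean_presences`` (default
    the configured mean of 66, matching typical occurrence-database yields
    per species after cleaning).
    """
    rng = _stream(config.seed, "species")
    mean_presences = mean_presences if mean_presences is not None else config.mean_presences
    species: list[SyntheticSpecies] = []
    records = []
    for i in range(n_species):
        sp = None
        for _ in range(10):  # re-draw on degenerate masks
            try:
                sp = _make_species(env, rng, f"sp_{i + 1:03d}", mean_presences)
                break
            except DegenerateSpeciesError:
                continue
        if sp is None:
            raise DegenerateSpeciesError(f"could not generate species {i + 1}")
        species.append(sp)
        records.append(sample_presences(sp, env, sp.n_presences, rng))
    return species, pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# reference tables
# ---------------------------------------------------------------------------


def generate_reference_tables(config: ScenarioConfig, landscape: Landscape):
    """Carbon, price and yield reference tables covering the landscape.

    Returns ``(carbon_refs, price_table, crop_yields, pasture_yields)``.
    Every (land use x biome/climate/soil) combination occurring on the
    landscape has a value; natural vegetation keeps stock-change factor 1.
    Magnitudes sit in plausible Brazilian ranges (SOCref tens of t C/ha,
    forest biomass ~100 t C/ha, 2015 commodity prices in USD2015/t).
    """
    from .carbon import CarbonReferenceTable
    from .revenue import CropYieldParams, PastureYieldParams, PriceTable

    rng = _stream(config.seed, "reference_tables")
    biomes = landscape.biome.labels
    climates = landscape.climate.labels
    soils = landscape.soil.labels
    states = landscape.state.labels

    soil_base = {"clayey": 70.0, "loamy": 55.0, "sandy": 40.0}
    climate_mult = {"tropical": 1.0, "subtropical": 1.12}
    socref = {
        (cl, so): soil_base.get(so, 55.0) * climate_mult.get(cl, 1.0)
        * rng.uniform(0.95, 1.05)
        for cl in climates
        for so in soils
    }

    f_range = {
        "forest": (1.0, 1.0),
        "grassland": (1.0, 1.0),
        "pasture": (0.75, 0.95),
        "cropland_annual": (0.50, 0.70),
        "cropland_perennial": (0.60, 0.80),
        "cropland_semiperennial": (0.55, 0.75),
        "forest_plantation": (0.75, 0.90),
        "other": (1.0, 1.0),
    }
    stock_change = {
        (lu, b): float(rng.uniform(*f_range[lu])) for lu in f_range for b in biomes
    }

    agb_base = {"amazon": 110.0, "atlantic_forest": 85.0, "cerrado": 45.0}
    agb_ref, bgb_ref = {}, {}
    for b in biomes:
        for cl in climates:
            fa = agb_base.get(b, 70.0) * climate_mult.get(cl, 1.0) * rng.uniform(0.9, 1.1)
            agb_ref[("forest", b, cl)] = fa
            bgb_ref[("forest", b, cl)] = fa * rng.uniform(0.2, 0.3)
            ga = rng.uniform(4.0, 10.0)
            agb_ref[("grassland", b, cl)] = ga
            bgb_ref[("grassland", b, cl)] = ga * rng.uniform(1.0, 1.6)
    managed = {}
    for cl in climates:
        managed[("pasture", cl)] = float(rng.uniform(5.0, 9.0))
        managed[("cropland_annual", cl)] = float(rng.uniform(3.0, 6.0))
        managed[("cropland_perennial", cl)] = float(rng.uniform(8.0, 15.0))
        managed[("cropland_semiperennial", cl)] = float(rng.uniform(6.0, 10.0))
        managed[("forest_plantation", cl)] = float(rng.uniform(30.0, 45.0))
    carbon_refs = CarbonReferenceTable(
        socref=socref,
        stock_change_factor=stock_change,
        agb_ref=agb_ref,
        bgb_ref=bgb_ref,
        managed_biomass=managed,
    )

    base_price = {"soybean": 290.0, "coffee": 2800.0, "sugarcane": 22.0, "cattle": 2900.0}
    prices = {
        (c, st): base_price[c] * float(rng.uniform(0.9, 1.1))
        for c in COMMODITIES
        for st in states
    }
    # two macro-regions of states: the fallback pool when a state price is absent
    region_of = {
        st: ("north" if i < len(states) / 2 else "south") for i, st in enumerate(states)
    }
    index = {
        (c, y): config.price_index(c, y) for c in COMMODITIES for y in config.years
    }
    price_table = PriceTable(base_price=prices, index=index, region_of=region_of)

    crop_base = {
        "soybean": (4.0, 0.65, 1.05),
        "coffee": (2.2, 0.60, 1.00),
        "sugarcane": (85.0, 0.75, 1.00),
    }
    crop_yields = {}
    horizon = config.end_year - config.start_year
    for c, (py, m0, ci) in crop_base.items():
        for y in config.years:
            s = (y - config.start_year) / horizon
            m = m0 * (1.0 + (config.management_trend - 1.0) * s)
            crop_yields[(c, y)] = CropYieldParams(
                potential_yield=py, management_factor=min(m, 1.0), cropping_intensity=ci
            )
    pasture_yields = {}
    for y in config.years:
        s = (y - config.start_year) / horizon
        f = 22.0 * (1.0 + (config.feed_efficiency_trend - 1.0) * s)
        pasture_yields[y] = PastureYieldParams(
            potential_grass=11.0, grazing_intensity=0.55, feed_efficiency=f
        )
    return carbon_refs, price_table, crop_yields, pasture_yields
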