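"""Land-use data model: fraction grids, disaggregation, area accounting.

A :class:`LandUseGrid` stores, for one scenario timestep, the fraction of
every cell occupied by each land-use category.  Two category vocabularies are
used:

* raw categories, as projections deliver them:
  ``forest, grassland, pasture, cropland, forest_plantation, mosaic, other``;
* canonical categories, after disaggregating cropland into annual /
  perennial / semi-perennial and distributing the mosaic class over its
  component uses:
  ``forest, grassland, pasture, cropland_annual, cropland_perennial,
  cropland_semiperennial, forest_plantation, other``.

Disaggregation is exactly mass-conserving per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import GridGeometry

RAW_CATEGORIES = (
    "forest",
    "grassland",
    "pasture",
    "cropland",
    "forest_plantation",
    "mosaic",
    "other",
)

CATEGORIES = (
    "forest",
    "grassland",
    "pasture",
    "cropland_annual",
    "cropland_perennial",
    "cropland_semiperennial",
    "forest_plantation",
    "other",
)

CROPLAND_SUBTYPES = (
    "cropland_annual",
    "cropland_perennial",
    "cropland_semiperennial",
)

#: Natural-vegetation categories (reference carbon state, F = 1).
NATURAL_CATEGORIES = ("forest", "grassland")

#: Tolerance on the per-cell fraction sum (float accumulation).
FRACTION_SUM_TOL = 1e-6


class UnknownCategoryError(KeyError):
    pass


@dataclass
class LandUseGrid:
    """Per-timestep raster of land-use category fractions.

    ``fractions`` maps category name to a 2-D array of per-cell fractions in
    [0, 1]; per cell the fractions sum to 1 within :data:`FRACTION_SUM_TOL`.
    """

    year: int
    fractions: dict[str, np.ndarray]
    geometry: GridGeometry

    def __post_init__(self) -> None:
        shapes = {f.shape for f in self.fractions.values()}
        if len(shapes) > 1 or (shapes and shapes.pop() != self.geometry.shape):
            raise ValueError("all fraction layers must match the grid geometry")
        self.fractions = {k: np.asarray(v, dtype=float) for k, v in self.fractions.items()}

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.fractions)

    def stack(self) -> np.ndarray:
        """(n_categories, rows, cols) array in category order."""
        return np.stack([self.fractions[c] for c in self.categories])

    def copy(self) -> "LandUseGrid":
        return LandUseGrid(
            year=self.year,
            fractions={k: v.copy() for k, v in self.fractions.items()},
            geometry=self.geometry,
        )


@dataclass
class ValidationReport:
    """Cells violating fraction-range or fraction-sum invariants."""

    range_violations: list[tuple[str, int, int, float]] = field(default_factory=list)
    sum_violations: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.range_violations and not self.sum_violations

    def __str__(self) -> str:  # pragma: no cover - diagnostics
        if self.ok:
            return "valid"
        lines = [
            f"range: {cat}[{r},{c}] = {v:.6g}" for cat, r, c, v in self.range_violations
        ] + [f"sum: [{r},{c}] = {s:.6g}" for r, c, s in self.sum_violations]
        return "\n".join(lines)


def validate_fractions(grid: LandUseGrid, tol: float = FRACTION_SUM_TOL) -> ValidationReport:
    """Check fraction range [0, 1] per layer and per-cell sum ≈ 1.

    Never raises on content: violations are listed in the report.
    """
    report = ValidationReport()
    for cat, frac in grid.fractions.items():
        bad = np.argwhere((frac < 0) | (frac > 1) | ~np.isfinite(frac))
        for r, c in bad:
            report.range_violations.append((cat, int(r), int(c), float(frac[r, c])))
    total = sum(grid.fractions.values())
    bad = np.argwhere(np.abs(total - 1.0) > tol)
    for r, c in bad:
        report.sum_violations.append((int(r), int(c), float(total[r, c])))
    return report


@dataclass
class DisaggregationShares:
    """Shares splitting raw cropland and mosaic into canonical categories.

    ``cropland`` maps an admin-unit label (or the global fallback key
    ``"*"``) to shares over :data:`CROPLAND_SUBTYPES`; ``mosaic`` maps the
    mosaic fraction onto component canonical categories.  Shares are
    non-negative and sum to 1 within 1e-9.
    """

    cropland: dict[str, dict[str, float]]
    mosaic: dict[str, float]

    GLOBAL = "*"

    def __post_init__(self) -> None:
        for unit, shares in self.cropland.items():
            if set(shares) != set(CROPLAND_SUBTYPES):
                raise ValueError(f"cropland shares for {unit!r} must cover {CROPLAND_SUBTYPES}")
            self._check(shares, f"cropland[{unit}]")
        unknown = set(self.mosaic) - set(CATEGORIES)
        if unknown:
            raise UnknownCategoryError(
                f"mosaic shares reference unknown categories: {sorted(unknown)}"
            )
        self._check(self.mosaic, "mosaic")

    @staticmethod
    def _check(shares: dict[str, float], what: str) -> None:
        vals = np.array(list(shares.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError(f"{what} shares must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"{what} shares must sum to 1, got {vals.sum()!r}")

    def cropland_for(self, unit: str) -> dict[str, float]:
        if unit in self.cropland:
            return self.cropland[unit]
        if self.GLOBAL in self.cropland:
            return self.cropland[self.GLOBAL]
        raise KeyError(f"no cropland shares for admin unit {unit!r} and no global fallback")


def default_shares() -> DisaggregationShares:
    """Global fallback split: annual-dominated cropland, mixed-use mosaic."""
    return DisaggregationShares(
        cropland={
            DisaggregationShares.GLOBAL: {
                "cropland_annual": 0.70,
                "cropland_perennial": 0.10,
                "cropland_semiperennial": 0.20,
            }
        },
        mosaic={
            "pasture": 0.40,
            "cropland_annual": 0.30,
            "grassland": 0.20,
            "forest": 0.10,
        },
    )


def _exact_residual(raw: np.ndarray, parts: list[np.ndarray]) -> list[np.ndarray]:
    """Adjust the last part so the in-order sum equals ``raw`` bitwise.

    The last part is set to ``raw - (sum of the earlier parts)``, with the
    partial sum taken in the same left-to-right association the total uses.
    That residual is exactly representable whenever the partial sum shares
    the magnitude of ``raw`` (the usual case), making the balance exact
    immediately; the remaining round-to-even tie cases are resolved by a
    one-ulp ``nextafter`` walk of the residual along the rounding
    staircase.
    """
    raw = np.asarray(raw, dtype=float)
    stack = np.stack([np.asarray(p, dtype=float) for p in parts])
    k = len(parts) - 1
    if k == 0:
        return [raw.copy()]

    def _partial() -> np.ndarray:
        acc = stack[0].copy()
        for i in range(1, k):
            acc = acc + stack[i]
        return acc

    def _nudge_earlier(sel: np.ndarray, direction: np.ndarray) -> None:
        idx = np.argmax(stack[:k], axis=0)[None]
        vals = np.take_along_axis(stack, idx, axis=0)
        new = np.nextafter(vals, direction[None])
        np.put_along_axis(stack, idx, np.where(sel[None], new, vals), axis=0)

    for _outer in range(16):
        partial = _partial()
        stack[k] = raw - partial
        neg = stack[k] < 0
        if neg.any():
            # partial sum overshot raw by rounding; lower the largest
            # earlier part one ulp so the residual is non-negative
            _nudge_earlier(neg, np.full(raw.shape, -np.inf))
            continue
        err = raw - (partial + stack[k])
        sel = err != 0
        if not sel.any():
            return list(stack)
        for _ in range(3):  # one-ulp walk of the residual
            step = np.nextafter(stack[k], np.where(err > 0, np.inf, -np.inf)) - stack[k]
            stack[k] = np.where(sel, stack[k] + step, stack[k])
            err = raw - (partial + stack[k])
            sel = err != 0
            if not sel.any():
                return list(stack)
        # round-to-even tie at the residual's ulp spacing: change the
        # partial-sum parity by nudging the largest earlier part
        _nudge_earlier(sel, np.where(err > 0, np.inf, -np.inf))
    return list(stack)


def disaggregate_cropland(
    raw_cropland: np.ndarray,
    shares: DisaggregationShares,
    admin_map=None,
) -> dict[str, np.ndarray]:
    """Split a raw cropland fraction grid into the three cropland subtypes.

    With ``admin_map`` (a :class:`~lusa.grids.CategoricalMap` of admin
    units), shares are looked up per unit; otherwise the global fallback is
    used.  The three outputs sum to the input exactly, per cell (the last
    subtype takes the corrected residual).
    """
    raw_cropland = np.asarray(raw_cropland, dtype=float)
    if admin_map is None:
        s = shares.cropland_for(DisaggregationShares.GLOBAL)
        share_grid = {sub: np.full_like(raw_cropland, s[sub]) for sub in CROPLAND_SUBTYPES}
    else:
        share_grid = {sub: np.zeros_like(raw_cropland) for sub in CROPLAND_SUBTYPES}
        for code, unit in enumerate(admin_map.labels):
            mask = admin_map.values == code
            if not mask.any():
                continue
            s = shares.cropland_for(unit)
            for sub in CROPLAND_SUBTYPES:
                share_grid[sub][mask] = s[sub]
    parts = [raw_cropland * share_grid[sub] for sub in CROPLAND_SUBTYPES[:-1]]
    parts.append(np.zeros_like(raw_cropland))
    parts = _exact_residual(raw_cropland, parts)
    return dict(zip(CROPLAND_SUBTYPES, parts))


def disaggregate_mosaic(
    mosaic: np.ndarray, shares: DisaggregationShares
) -> dict[str, np.ndarray]:
    """Distribute the mosaic fraction over component canonical categories.

    Returns per-category increments whose per-cell sum equals the mosaic
    fraction exactly (residual goes to the last share category).
    """
    mosaic = np.asarray(mosaic, dtype=float)
    cats = list(shares.mosaic)
    parts = [mosaic * shares.mosaic[cat] for cat in cats[:-1]]
    parts.append(np.zeros_like(mosaic))
    parts = _exact_residual(mosaic, parts)
    return dict(zip(cats, parts))


def to_canonical(
    grid: LandUseGrid,
    shares: DisaggregationShares | None = None,
    admin_map=None,
) -> LandUseGrid:
    """Raw 7-category grid -> canonical 8-category grid.

    Cropland is split by (optionally per-admin-unit) shares; the mosaic
    fraction is folded into its component categories.  Total area per cell
    is conserved exactly.
    """
    shares = shares or default_shares()
    missing = set(RAW_CATEGORIES) - set(grid.categories)
    if missing:
        raise UnknownCategoryError(f"raw grid missing categories: {sorted(missing)}")
    zeros = np.zeros(grid.geometry.shape)
    frac: dict[str, np.ndarray] = {c: zeros.copy() for c in CATEGORIES}
    for cat in ("forest", "grassland", "pasture", "forest_plantation", "other"):
        frac[cat] += grid.fractions[cat]
    for sub, arr in disaggregate_cropland(grid.fractions["cropland"], shares, admin_map).items():
        frac[sub] += arr
    for cat, arr in disaggregate_mosaic(grid.fractions["mosaic"], shares).items():
        frac[cat] += arr
    return LandUseGrid(year=grid.year, fractions=frac, geometry=grid.geometry)


def category_area(grid: LandUseGrid, category: str) -> float:
    """National area of one category in hectares (sum fraction x cell area)."""
    if category not in grid.fractions:
        raise UnknownCategoryError(
            f"unknown category {category!r}; grid has {grid.categories}"
        )
    return float(grid.fractions[category].sum() * grid.geometry.cell_area)


def total_area(grid: LandUseGrid) -> float:
    """Total land area accounted for by the grid, hectares."""
    return float(sum(grid.fractions.values()).sum() * grid.geometry.cell_area)


def changed_mask(a: LandUseGrid, b: LandUseGrid, tol: float = 1e-6) -> np.ndarray:
    """Boolean grid: cells where any category fraction changed by more than tol."""
    a.geometry.check_same(b.geometry)
    if a.categories != b.categories:
        raise UnknownCategoryError("grids have different category sets")
    delta = np.zeros(a.geometry.shape)
    for cat in a.categories:
        delta = np.maximum(delta, np.abs(b.fractions[cat] - a.fractions[cat]))
    return delta > tol
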