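"""Trade-off and synergy quantification across the three objectives.

National level: changes between the base and end year in (i) total carbon
stock (Gt C), (ii) mean relative change of species distribution areas (%),
and (iii) total agricultural revenue (USD/yr) are paired into ratios with a
relation label (synergy / tradeoff / loss-loss; improvement means the
indicator rises).  Pixel level: each cell is classified into one of seven
mutually exclusive outcome categories from the signs of its three deltas
and a land-use-change flag, and magnitude maps summarise how strong the
classified outcome is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: "No change" tolerance in native indicator units (exact-zero intent).
DEFAULT_TAU = 1e-9


class OutcomeClass(IntEnum):
    """Per-cell outcome categories (codes used in classification rasters)."""

    NO_CHANGE = 0
    SYNERGY_GAIN_GAIN = 1
    TRADEOFF_ENV_GAIN_ECON_LOSS = 2
    TRADEOFF_ECON_GAIN_ENV_LOSS = 3
    LOSS_LOSS = 4
    PRICE_ONLY_GAIN = 5
    PRICE_ONLY_LOSS = 6


@dataclass
class NationalIndicators:
    """National indicator values for one scenario timestep."""

    scenario: str
    year: int
    carbon_stock_gt: float
    mean_range_change_pct: float
    revenue_usd: float


def indicators_frame(rows: list[NationalIndicators]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scenario": r.scenario,
                "year": r.year,
                "carbon_stock_gt": r.carbon_stock_gt,
                "mean_range_change_pct": r.mean_range_change_pct,
                "revenue_usd": r.revenue_usd,
            }
            for r in rows
        ]
    )


def national_deltas(
    base: NationalIndicators, end: NationalIndicators
) -> tuple[float, float, float]:
    """(ΔC Gt, Δrange %, ΔR USD/yr) between two timesteps of one scenario.

    The range indicator is already expressed relative to the base year, so
    its delta is the difference of the reported percentages.
    """
    if base.scenario != end.scenario:
        raise ValueError(
            f"scenario mismatch: {base.scenario!r} vs {end.scenario!r}"
        )
    return (
        end.carbon_stock_gt - base.carbon_stock_gt,
        end.mean_range_change_pct - base.mean_range_change_pct,
        end.revenue_usd - base.revenue_usd,
    )


@dataclass
class TradeoffRatio:
    """|Δb| per unit |Δa| plus the relation between the two objectives."""

    ratio: float  # nan when delta_a == 0
    relation: str  # synergy | tradeoff | loss_loss | no_change


def tradeoff_ratio(delta_a: float, delta_b: float) -> TradeoffRatio:
    """Pair two indicator deltas into a trade-off/synergy ratio.

    Improvement direction is "up" for all three indicators.  Both improve:
    synergy; signs oppose: tradeoff; both decline: loss-loss.  A zero delta
    is neutral: the relation follows the moving indicator (both zero: no
    change).  The ratio |delta_b| / |delta_a| is undefined (nan) when
    delta_a is zero.
    """
    ratio = abs(delta_b) / abs(delta_a) if delta_a != 0 else float("nan")
    if delta_a == 0 and delta_b == 0:
        relation = "no_change"
    elif delta_a >= 0 and delta_b >= 0:
        relation = "synergy"
    elif delta_a <= 0 and delta_b <= 0:
        relation = "loss_loss"
    else:
        relation = "tradeoff"
    return TradeoffRatio(ratio=ratio, relation=relation)


def _env_sign(
    dc: float, drich: float, tau: float, c_scale: float, r_scale: float
) -> int:
    """Combine carbon and richness deltas into one environmental sign.

    Sign agreement wins outright; on disagreement the indicator with the
    larger map-normalised magnitude dominates (ties to carbon).
    """
    sc = 0 if abs(dc) <= tau else (1 if dc > 0 else -1)
    sr = 0 if abs(drich) <= tau else (1 if drich > 0 else -1)
    if sc == 0 and sr == 0:
        return 0
    if sc == 0:
        return sr
    if sr == 0:
        return sc
    if sc == sr:
        return sc
    nc = abs(dc) / c_scale if c_scale > 0 else 0.0
    nr = abs(drich) / r_scale if r_scale > 0 else 0.0
    return sc if nc >= nr else sr


def classify_cell(
    dc: float,
    drich: float,
    drev: float,
    lu_changed: bool,
    tau: float = DEFAULT_TAU,
    c_scale: float = 1.0,
    r_scale: float = 1.0,
) -> OutcomeClass:
    """Scalar classification rule (reference path for the vectorised map).

    A neutral axis joins the direction of the moving one, which makes the
    seven categories exhaustive for every sign triple and flag.
    """
    env_zero = abs(dc) <= tau and abs(drich) <= tau
    if env_zero and abs(drev) <= tau:
        return OutcomeClass.NO_CHANGE
    if not lu_changed and env_zero:
        return OutcomeClass.PRICE_ONLY_GAIN if drev > tau else OutcomeClass.PRICE_ONLY_LOSS
    env = _env_sign(dc, drich, tau, c_scale, r_scale)
    econ = 0 if abs(drev) <= tau else (1 if drev > 0 else -1)
    if env == 0:
        env = econ  # neutral environment follows the economic direction
    if econ == 0:
        econ = env  # neutral economy follows the environmental direction
    if env > 0 and econ > 0:
        return OutcomeClass.SYNERGY_GAIN_GAIN
    if env > 0 and econ < 0:
        return OutcomeClass.TRADEOFF_ENV_GAIN_ECON_LOSS
    if env < 0 and econ > 0:
        return OutcomeClass.TRADEOFF_ECON_GAIN_ENV_LOSS
    return OutcomeClass.LOSS_LOSS


def classify_cells(
    delta_carbon: np.ndarray,
    delta_richness: np.ndarray,
    delta_revenue: np.ndarray,
    lu_changed: np.ndarray,
    tau: float = DEFAULT_TAU,
) -> np.ndarray:
    """Vectorised per-cell outcome classification (integer OutcomeClass codes)."""
    dc = np.asarray(delta_carbon, float)
    dr = np.asarray(delta_richness, float)
    dv = np.asarray(delta_revenue, float)
    if not (dc.shape == dr.shape == dv.shape == np.asarray(lu_changed).shape):
        raise ValueError("delta maps and land-use-change mask must share a shape")
    c_scale = float(np.abs(dc).max())
    r_scale = float(np.abs(dr).max())

    sc = np.where(np.abs(dc) <= tau, 0, np.sign(dc)).astype(int)
    sr = np.where(np.abs(dr) <= tau, 0, np.sign(dr)).astype(int)
    sv = np.where(np.abs(dv) <= tau, 0, np.sign(dv)).astype(int)

    nc = np.abs(dc) / c_scale if c_scale > 0 else np.zeros_like(dc)
    nr = np.abs(dr) / r_scale if r_scale > 0 else np.zeros_like(dr)
    env = np.where(
        sc == sr, sc,
        np.where(sc == 0, sr, np.where(sr == 0, sc, np.where(nc >= nr, sc, sr))),
    )
    env_eff = np.where(env == 0, sv, env)
    econ_eff = np.where(sv == 0, env_eff, sv)

    out = np.full(dc.shape, int(OutcomeClass.LOSS_LOSS), dtype=int)
    out[(env_eff > 0) & (econ_eff > 0)] = int(OutcomeClass.SYNERGY_GAIN_GAIN)
    out[(env_eff > 0) & (econ_eff < 0)] = int(OutcomeClass.TRADEOFF_ENV_GAIN_ECON_LOSS)
    out[(env_eff < 0) & (econ_eff > 0)] = int(OutcomeClass.TRADEOFF_ECON_GAIN_ENV_LOSS)

    price_only = ~np.asarray(lu_changed, bool) & (sc == 0) & (sr == 0) & (sv != 0)
    out[price_only & (sv > 0)] = int(OutcomeClass.PRICE_ONLY_GAIN)
    out[price_only & (sv < 0)] = int(OutcomeClass.PRICE_ONLY_LOSS)
    out[(sc == 0) & (sr == 0) & (sv == 0)] = int(OutcomeClass.NO_CHANGE)
    return out


def magnitude_maps(
    delta_carbon: np.ndarray,
    delta_richness: np.ndarray,
    delta_revenue: np.ndarray,
    classification: np.ndarray,
    tau: float = DEFAULT_TAU,
) -> dict[str, np.ndarray]:
    """Per-cell outcome magnitudes.

    For each cell the raw indicator deltas are reported together with a
    scalar summary: the geometric mean of the min-max-normalised absolute
    deltas of the two indicators defining the cell's class (the dominant
    environmental indicator and revenue; revenue alone for price-only
    cells; 0 for no-change cells).  Normalisation bounds are the per-map
    min/max of |delta|; a degenerate range yields 0 and is logged.
    """
    dc = np.asarray(delta_carbon, float)
    dr = np.asarray(delta_richness, float)
    dv = np.asarray(delta_revenue, float)
    cls = np.asarray(classification, int)

    def _norm(a: np.ndarray, name: str) -> np.ndarray:
        lo, hi = float(np.abs(a).min()), float(np.abs(a).max())
        if hi - lo <= 0:
            logger.info("degenerate normalisation range for %s; magnitudes set to 0", name)
            return np.zeros_like(a)
        return (np.abs(a) - lo) / (hi - lo)

    nc = _norm(dc, "carbon")
    nr = _norm(dr, "richness")
    nv = _norm(dv, "revenue")

    env_mag = np.where(np.abs(dc) >= np.abs(dr), nc, nr)  # dominant env indicator
    scalar = np.sqrt(env_mag * nv)
    price_only = np.isin(cls, (int(OutcomeClass.PRICE_ONLY_GAIN), int(OutcomeClass.PRICE_ONLY_LOSS)))
    scalar = np.where(price_only, nv, scalar)
    scalar = np.where(cls == int(OutcomeClass.NO_CHANGE), 0.0, scalar)
    return {
        "scalar": scalar,
        "delta_carbon": dc,
        "delta_richness": dr,
        "delta_revenue": dv,
    }


def scenario_report(
    base: NationalIndicators, end: NationalIndicators
) -> dict:
    """Structured per-scenario summary: deltas, pairwise ratios, relations.

    Ratios are reported to 2 significant figures alongside full precision;
    revenue deltas are expressed in billion USD/yr for the pairings so the
    ratio units match the conventional reporting (billion USD per Gt, etc.).
    """
    dc, drange, drev = national_deltas(base, end)
    drev_b = drev / 1e9
    pairs = {
        "revenue_per_carbon": tradeoff_ratio(dc, drev_b),
        "revenue_per_range": tradeoff_ratio(drange, drev_b),
        "carbon_per_range": tradeoff_ratio(drange, dc),
        "carbon_per_revenue": tradeoff_ratio(drev_b, dc),
        "range_per_revenue": tradeoff_ratio(drev_b, drange),
    }

    def _round2(x: float) -> float:
        if not np.isfinite(x) or x == 0:
            return x
        return float(np.format_float_positional(x, precision=2, fractional=False))

    return {
        "scenario": base.scenario,
        "base_year": base.year,
        "end_year": end.year,
        "delta_carbon_gt": dc,
        "delta_range_pct": drange,
        "delta_revenue_usd": drev,
        "ratios": {
            name: {"ratio": tr.ratio, "ratio_2sf": _round2(tr.ratio), "relation": tr.relation}
            for name, tr in pairs.items()
        },
    }
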