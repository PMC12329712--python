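"""Scenario-assessment orchestration.

``run_assessment`` wires the stages in dependency order for each scenario:
synthetic inputs (grids, landscape, species, reference tables) -> cropland
and mosaic disaggregation -> carbon stocks -> species models fitted on the
base-year environment and projected to every timestep -> agricultural
revenue -> national indicator series -> trade-off ratios and per-pixel
outcome classification (base vs end year).  All randomness derives from the
config seed; a run manifest records the config, seeds, software version and
digests of every written output, so a rerun with an identical manifest
reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .carbon import carbon_stock_map, national_carbon_stock
from .grids import GridGeometry
from .landuse import changed_mask, default_shares, to_canonical, validate_fractions
from .revenue import revenue_assessment
from .sdm import (
    SDModel,
    build_species_dataset,
    fit_species_model,
    mean_range_change,
    project_range,
    stack_richness,
)
from .synthetic import (
    Landscape,
    ScenarioConfig,
    env_stack,
    generate_landscape,
    generate_reference_tables,
    generate_scenario,
    generate_species,
    ssp1_like,
    ssp2_like,
    ssp3_like,
)
from .tradeoffs import (
    NationalIndicators,
    classify_cells,
    indicators_frame,
    magnitude_maps,
    scenario_report,
)
from . import io as lio

logger = logging.getLogger(__name__)

PRESETS = {"ssp1": ssp1_like, "ssp2": ssp2_like, "ssp3": ssp3_like}


def _substream_seed(seed: int, name: str) -> int:
    return (seed * 1_000_003 + (zlib.crc32(name.encode()) & 0x7FFFFFFF)) % (2**31)


@dataclass
class ScenarioOutputs:
    """Everything computed for one scenario."""

    config: ScenarioConfig
    indicators: list[NationalIndicators]
    report: dict
    classification: np.ndarray
    magnitudes: dict[str, np.ndarray]
    models: dict[str, SDModel]
    richness_base: np.ndarray
    richness_end: np.ndarray


def assess_scenario(
    config: ScenarioConfig,
    landscape: Landscape | None = None,
    species=None,
    records: pd.DataFrame | None = None,
    refs=None,
) -> ScenarioOutputs:
    """Run the full indicator chain for one scenario.

    Landscape, species pool and reference tables may be shared across
    scenarios (they depend on the seed, not the trajectories); they are
    generated on demand otherwise.
    """
    landscape = landscape or generate_landscape(config)
    grids = generate_scenario(config)
    shares = default_shares()
    canonical = [to_canonical(g, shares) for g in grids]
    for g in canonical:
        rep = validate_fractions(g)
        if not rep.ok:
            raise RuntimeError(f"invalid fractions in {config.scenario_id} {g.year}: {rep}")

    if refs is None:
        refs, price_table, crop_yields, pasture_yields = generate_reference_tables(
            config, landscape
        )
    else:
        refs, price_table, crop_yields, pasture_yields = refs

    base_env = env_stack(canonical[0], landscape)
    if species is None:
        species, records = generate_species(base_env, config.n_species, config)

    # fit one model per species on the base-year environment
    models: dict[str, SDModel] = {}
    masks: dict[str, np.ndarray] = {}
    for sp in species:
        seed = _substream_seed(config.seed, f"sdm:{sp.species_id}")
        dataset = build_species_dataset(
            sp.species_id,
            records[records["species_id"] == sp.species_id],
            sp.true_range_mask,
            base_env,
            n_absences=config.n_pseudo_absences,
            seed=seed,
        )
        model = fit_species_model(dataset, seed=seed)
        if model.retained:
            models[sp.species_id] = model
            masks[sp.species_id] = sp.true_range_mask
        else:
            logger.info("%s: %s not retained (AUC %.3f, TSS %.3f)",
                        config.scenario_id, sp.species_id,
                        model.cv_auc_mean, model.cv_tss_mean)
    if not models:
        raise RuntimeError("no species model retained; cannot compute richness")

    # per-timestep indicators
    indicators: list[NationalIndicators] = []
    stocks, dists_by_year, revenues = {}, {}, {}
    for grid in canonical:
        stock = carbon_stock_map(grid, refs, landscape.climate, landscape.soil, landscape.biome)
        stocks[grid.year] = stock
        env = env_stack(grid, landscape)
        dists = {sid: project_range(m, env, masks[sid]) for sid, m in models.items()}
        dists_by_year[grid.year] = dists
        rev = revenue_assessment(
            grid, price_table, crop_yields, pasture_yields, landscape.state
        )
        revenues[grid.year] = rev
        base_dists = dists_by_year[canonical[0].year]
        indicators.append(
            NationalIndicators(
                scenario=config.scenario_id,
                year=grid.year,
                carbon_stock_gt=national_carbon_stock(stock),
                mean_range_change_pct=mean_range_change(dists, base_dists),
                revenue_usd=rev.national,
            )
        )

    base_year, end_year = canonical[0].year, canonical[-1].year
    report = scenario_report(indicators[0], indicators[-1])

    cell_area = config.geometry.cell_area
    delta_c = (stocks[end_year].density - stocks[base_year].density) * cell_area
    rich_base = stack_richness(dists_by_year[base_year], config.geometry, base_year,
                               config.scenario_id)
    rich_end = stack_richness(dists_by_year[end_year], config.geometry, end_year,
                              config.scenario_id)
    delta_rich = (rich_end.counts - rich_base.counts).astype(float)
    delta_rev = (revenues[end_year].density - revenues[base_year].density) * cell_area
    lu_changed = changed_mask(canonical[0], canonical[-1])
    classification = classify_cells(delta_c, delta_rich, delta_rev, lu_changed)
    magnitudes = magnitude_maps(delta_c, delta_rich, delta_rev, classification)

    return ScenarioOutputs(
        config=config,
        indicators=indicators,
        report=report,
        classification=classification,
        magnitudes=magnitudes,
        models=models,
        richness_base=rich_base.counts,
        richness_end=rich_end.counts,
    )


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_assessment(
    configs: list[ScenarioConfig],
    outdir,
    write_maps: bool = True,
) -> RunManifest:
    """Run every scenario and write indicator series, reports and maps.

    Scenarios share the landscape, species pool and reference tables of the
    first config (all seed-derived), so base-year conditions are common and
    only trajectories and price/yield paths differ.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    first = configs[0]
    landscape = generate_landscape(first)
    base_env = env_stack(
        to_canonical(generate_scenario(first)[0], default_shares()), landscape
    )
    species, records = generate_species(base_env, first.n_species, first)
    refs = generate_reference_tables(first, landscape)

    all_rows: list[NationalIndicators] = []
    reports = {}
    manifest = RunManifest(
        config={c.scenario_id: dataclasses.asdict(c) for c in configs},
        seed=first.seed,
        version=__version__,
    )
    for cfg in configs:
        out = assess_scenario(cfg, landscape=landscape, species=species,
                              records=records, refs=refs)
        all_rows.extend(out.indicators)
        reports[cfg.scenario_id] = out.report
        if write_maps:
            lio.write_ascii_grid(
                outdir / f"classification_{cfg.scenario_id}.asc",
                out.classification, cfg.geometry,
            )
            lio.write_ascii_grid(
                outdir / f"magnitude_{cfg.scenario_id}.asc",
                out.magnitudes["scalar"], cfg.geometry,
            )
        model_cards = {sid: m.to_dict() for sid, m in out.models.items()}
        (outdir / f"models_{cfg.scenario_id}.json").write_text(
            json.dumps(model_cards, indent=2, sort_keys=True)
        )

    frame = indicators_frame(all_rows)
    frame.to_csv(outdir / "national_indicators.csv", index=False)
    (outdir / "tradeoff_report.json").write_text(json.dumps(reports, indent=2, sort_keys=True))
    lio.write_occurrences(outdir / "occurrences.csv", records)
    lio.write_carbon_refs(outdir / "reference_tables", refs[0])

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.outputs[str(path.relative_to(outdir))] = _digest(path)
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def default_configs(seed: int = 0, **overrides) -> list[ScenarioConfig]:
    """The three socio-economic pathway presets sharing one seed."""
    return [
        PRESETS[name](seed=seed, **overrides) for name in ("ssp1", "ssp2", "ssp3")
    ]


def load_config(path) -> list[ScenarioConfig]:
    """Load scenario configs from a YAML file.

    Schema: top-level keys ``seed``, ``grid_shape``, ``cell_area``,
    ``years`` (``[start, end, step]``), ``species`` (``n_species``,
    ``mean_presences``, ``n_pseudo_absences``) and ``scenarios`` — either a
    list of preset names (``ssp1``/``ssp2``/``ssp3``) or mappings of
    ScenarioConfig fields.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    common: dict = {}
    if "seed" in raw:
        common["seed"] = int(raw["seed"])
    if "grid_shape" in raw:
        common["grid_shape"] = tuple(raw["grid_shape"])
    if "cell_area" in raw:
        common["cell_area"] = float(raw["cell_area"])
    if "years" in raw:
        start, end, step = raw["years"]
        common.update(start_year=start, end_year=end, step=step)
    for key, val in raw.get("species", {}).items():
        common[key] = val
    configs = []
    for entry in raw.get("scenarios", ["ssp1", "ssp2", "ssp3"]):
        if isinstance(entry, str):
            configs.append(PRESETS[entry](**common))
        else:
            params = {**common, **entry}
            if "grid_shape" in params:
                params["grid_shape"] = tuple(params["grid_shape"])
            configs.append(ScenarioConfig(**params))
    return configs
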