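"""End-to-end orchestration from a single config.

``run`` executes: synthetic-world generation (or ingest) → occurrence QC →
collinearity screening and GCM ensembling → per-species cross-validated
suitability models → evaluation/retention → expansion potentials per RCP
(including biome and growth-form rollups and the cross-RCP regression) →
climate-feature attribution.  All outputs land under the output directory
together with a machine-readable manifest (seeds, per-stage counts, SHA-256
checksums), so identical configs produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as climate_mod
from . import climate_features as feat_mod
from . import expansion as exp_mod
from . import io as io_mod
from . import occ_qc, synthgen
from .evaluation import evaluate_species
from .grid import GridSpec
from .regions import FRESHWATER_BIOMES, TERRESTRIAL_BIOMES
from .sdm import cross_validate
from .synthgen import Contamination, NicheSpec, ScenarioDelta, child_seed

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Pipeline settings; defaults follow the study's stated settings."""

    seed: int = 0
    # synthetic world
    n_rows: int = 40
    n_cols: int = 60
    cell_size: float = 1.0 / 6.0
    origin_lon: float = 0.0
    origin_lat: float = 30.0
    autocorr_scale: float = 5.0
    n_species: int = 6
    n_clean_per_species: int = 150
    niche_breadth_factor: float = 0.06  # niche SD as a fraction of the variable range
    contamination: dict = field(
        default_factory=lambda: dict(
            n_cell_duplicates=5, n_zero_zero=3, n_lon_eq_lat=3, n_bad_names=4
        )
    )
    n_terrestrial_regions: int = 8
    n_freshwater_regions: int = 6
    n_gcms: int = 2
    rcp45_bio1_delta: float = 2.0
    rcp45_bio4_delta: float = 60.0
    rcp85_factor: float = 2.0
    # QC
    min_records: int = 100
    strict_min_records: bool = True
    # climate screening
    collinearity_threshold: float = 0.85
    # SDM
    beta: float = 1.5
    k_folds: int = 10
    n_background: int = 10_000
    n_knots: int = 20
    bias_bandwidth: float | None = None
    # retention
    auc_min: float = 0.7
    omission_max: float = 0.017
    # attribution
    top_k_variables: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def demo_config(seed: int = 0) -> RunConfig:
    """A small, fast configuration exercising every stage."""
    return RunConfig(
        seed=seed,
        n_rows=40,
        n_cols=60,
        n_species=6,
        n_clean_per_species=150,
        min_records=100,
        k_folds=4,
        n_background=1000,
        n_knots=8,
        # the demo grid is small, so presences cover a sizeable share of the
        # landscape and the study-scale omission bound is not attainable;
        # relaxed here only for the demo (the RunConfig default stays 0.017)
        omission_max=0.1,
    )


def _make_niches(cfg: RunConfig, stack) -> list[NicheSpec]:
    """Deterministic species pool with Bio1/Bio4-driven Gaussian niches."""
    rng = np.random.default_rng(child_seed(cfg.seed, "occurrences", 999))
    valid = stack.grid.valid_mask
    b1 = stack.layers["Bio1"][valid]
    b4 = stack.layers["Bio4"][valid]
    niches = []
    for i in range(cfg.n_species):
        q = rng.uniform(0.25, 0.75)
        niches.append(
            NicheSpec(
                species_id=f"sp{i:03d}",
                growth_form=synthgen.GROWTH_FORMS[i % len(synthgen.GROWTH_FORMS)],
                optimum={
                    "Bio1": float(np.quantile(b1, q)),
                    "Bio4": float(np.quantile(b4, rng.uniform(0.25, 0.75))),
                },
                breadth={
                    "Bio1": float(cfg.niche_breadth_factor * (b1.max() - b1.min())),
                    "Bio4": float(cfg.niche_breadth_factor * (b4.max() - b4.min())),
                },
                max_prob=1.0,
            )
        )
    return niches


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}

    # --- stage 1: synthetic world ---------------------------------------
    grid = GridSpec(
        config.n_rows,
        config.n_cols,
        cell_size=config.cell_size,
        origin_lon=config.origin_lon,
        origin_lat=config.origin_lat,
    )
    current = synthgen.generate_climate(
        grid, child_seed(config.seed, "climate"), autocorr_scale=config.autocorr_scale
    )
    terrestrial = synthgen.generate_ecoregions(
        grid,
        config.n_terrestrial_regions,
        TERRESTRIAL_BIOMES,
        child_seed(config.seed, "ecoregions", 0),
    )
    freshwater = synthgen.generate_ecoregions(
        grid,
        config.n_freshwater_regions,
        FRESHWATER_BIOMES,
        child_seed(config.seed, "ecoregions", 1),
    )
    niches = _make_niches(config, current)
    occ_tables = []
    contamination = Contamination(**config.contamination)
    for i, niche in enumerate(niches):
        occ_tables.append(
            synthgen.sample_occurrences(
                niche,
                current,
                n_clean=config.n_clean_per_species,
                contamination=contamination,
                seed=child_seed(config.seed, "occurrences", i),
            )
        )
    occurrences = pd.concat(occ_tables, ignore_index=True)
    io_mod.write_stack(outdir / "climate" / "current", current)
    io_mod.write_ecoregions(outdir / "regions", terrestrial, "terrestrial")
    io_mod.write_ecoregions(outdir / "regions", freshwater, "freshwater")
    occurrences.to_csv(outdir / "occurrences.csv", index=False)
    counts["occurrence_records"] = len(occurrences)

    # --- stage 2: occurrence QC -----------------------------------------
    cleaned, qc_report = occ_qc.clean_occurrences(
        occurrences.drop(columns=["_truth"]), grid
    )
    filtered, filt_report = occ_qc.filter_species(
        cleaned, min_records=config.min_records, strict=config.strict_min_records
    )
    qc_report.to_frame().to_csv(outdir / "qc_report.csv", index=False)
    filtered.to_csv(outdir / "occurrences_clean.csv", index=False)
    counts["records_removed"] = qc_report.n_removed
    counts["species_after_filter"] = len(filt_report.retained_species)
    if not filt_report.retained_species:
        raise RuntimeError("stage occ_qc: no species left after the minimum-record filter")

    # --- stage 3: climate screening and future scenarios ------------------
    retained_codes, screen_report = climate_mod.screen_collinearity(
        current, threshold=config.collinearity_threshold, seed=config.seed
    )
    screen_report.to_csv(outdir / "collinearity_report.csv", index=False)
    counts["variables_retained"] = len(retained_codes)
    current_screened = current.subset(retained_codes)

    base_delta = {"Bio1": config.rcp45_bio1_delta, "Bio4": config.rcp45_bio4_delta}
    rng_gcm = np.random.default_rng(child_seed(config.seed, "climate", 1))
    futures: dict[str, object] = {}
    for rcp, factor in (("RCP4.5", 1.0), ("RCP8.5", config.rcp85_factor)):
        members = []
        for g in range(config.n_gcms):
            jitter = rng_gcm.normal(0.0, 0.1, size=len(base_delta))
            deltas = {
                c: factor * v * (1.0 + jitter[j])
                for j, (c, v) in enumerate(base_delta.items())
                if c in retained_codes
            }
            members.append(
                synthgen.apply_scenario(
                    current_screened, ScenarioDelta(scenario=rcp, deltas=deltas, gcm=f"gcm{g}")
                )
            )
        ensemble = climate_mod.ensemble_mean(members)
        futures[rcp] = ensemble
        io_mod.write_stack(outdir / "climate" / rcp.replace(".", "_"), ensemble)

    # --- stage 4-5: per-species models and evaluation ---------------------
    models_dir = outdir / "models"
    models_dir.mkdir(exist_ok=True)
    species_order = sorted(filt_report.retained_species)
    eval_rows = []
    cv_results = {}
    for i, sp in enumerate(species_order):
        occ_sp = filtered[filtered["species"] == sp]
        cv = cross_validate(
            occ_sp,
            current_screened,
            k=config.k_folds,
            seed=child_seed(config.seed, "folds", i),
            n_background=config.n_background,
            bias_bandwidth=config.bias_bandwidth,
            beta=config.beta,
            n_knots=config.n_knots,
        )
        report = evaluate_species(cv, auc_min=config.auc_min, omission_max=config.omission_max)
        cv_results[sp] = (cv, report)
        eval_rows.append(report.to_frame())
        cv.models[0].to_json(models_dir / f"{sp}_fold0.json")
    evaluation_table = pd.concat(eval_rows, ignore_index=True)
    evaluation_table.to_csv(outdir / "evaluation.csv", index=False)
    retained_species = [sp for sp in species_order if cv_results[sp][1].retained]
    counts["species_retained"] = len(retained_species)
    if not retained_species:
        raise RuntimeError("stage evaluation: every species failed the retention rule")

    # --- stage 6: expansion potentials ------------------------------------
    form_of = {n.species_id: n.growth_form for n in niches}
    current_maps = {sp: cv_results[sp][0].mean_logistic for sp in retained_species}
    suit_dir = outdir / "suitability"
    suit_dir.mkdir(exist_ok=True)
    for sp in retained_species:
        io_mod.write_ascii_grid(suit_dir / f"{sp}_current.asc", current_maps[sp], grid)
    potentials: dict[str, dict[str, pd.DataFrame]] = {}
    per_species_change: dict[str, dict[str, np.ndarray]] = {}
    for rcp, future_stack in futures.items():
        future_maps = {
            sp: cv_results[sp][0].mean_logistic_on(future_stack) for sp in retained_species
        }
        for sp in retained_species:
            io_mod.write_ascii_grid(
                suit_dir / f"{sp}_{rcp.replace('.', '_')}.asc", future_maps[sp], grid
            )
        per_species_change[rcp] = {
            sp: future_maps[sp] - current_maps[sp] for sp in retained_species
        }
        e_cur = exp_mod.multi_species_suitability(
            [current_maps[sp] for sp in retained_species], scenario="current"
        )
        e_fut = exp_mod.multi_species_suitability(
            [future_maps[sp] for sp in retained_species], scenario=rcp
        )
        change = exp_mod.suitability_change(e_fut, e_cur)
        io_mod.write_ascii_grid(
            outdir / f"change_{rcp.replace('.', '_')}.asc", change.values, grid
        )
        tables = {}
        for realm_name, regions in (("terrestrial", terrestrial), ("freshwater", freshwater)):
            table = exp_mod.ecoregion_potential(change, regions)
            tables[realm_name] = table
        potentials[rcp] = tables
        combined = pd.concat(tables.values(), ignore_index=True)
        combined.to_csv(outdir / f"expansion_{rcp.replace('.', '_')}.csv", index=False)
        exp_mod.group_potentials(combined, by="biome").to_csv(
            outdir / f"expansion_biomes_{rcp.replace('.', '_')}.csv", index=False
        )
        # growth-form stratification: Eq. 1 recomputed over species subsets
        form_rows = []
        for form in sorted({form_of[sp] for sp in retained_species}):
            subset = [sp for sp in retained_species if form_of[sp] == form]
            e_c = exp_mod.multi_species_suitability(
                [current_maps[sp] for sp in subset], scenario="current"
            )
            e_f = exp_mod.multi_species_suitability(
                [future_maps[sp] for sp in subset], scenario=rcp
            )
            ch = exp_mod.suitability_change(e_f, e_c)
            for realm_name, regions in (
                ("terrestrial", terrestrial),
                ("freshwater", freshwater),
            ):
                t = exp_mod.ecoregion_potential(ch, regions)
                t["growth_form"] = form
                form_rows.append(t)
        form_table = pd.concat(form_rows, ignore_index=True)
        form_table.to_csv(outdir / f"expansion_forms_{rcp.replace('.', '_')}.csv", index=False)
        exp_mod.group_potentials(form_table, by="growth_form").to_csv(
            outdir / f"expansion_form_sums_{rcp.replace('.', '_')}.csv", index=False
        )

    # cross-RCP regression per realm (paired by ecoregion)
    regression_rows = []
    for realm_name in ("terrestrial", "freshwater"):
        t45 = potentials["RCP4.5"][realm_name].set_index("ecoregion_id")["potential"]
        t85 = potentials["RCP8.5"][realm_name].set_index("ecoregion_id")["potential"]
        try:
            res = exp_mod.scenario_regression(t45.to_numpy(), t85.reindex(t45.index).to_numpy())
            res["realm"] = realm_name
            regression_rows.append(res)
        except ValueError as err:
            warnings.warn(f"scenario regression skipped for {realm_name}: {err}", stacklevel=2)
    pd.DataFrame(regression_rows).to_csv(outdir / "rcp_regression.csv", index=False)

    # --- stage 7: climate-feature attribution -----------------------------
    importance_per_species = {}
    for sp in retained_species:
        cv = cv_results[sp][0]
        bg = cv.background
        bg_values = current_screened.values_at(bg.rows, bg.cols, cv.codes)
        importance_per_species[sp] = feat_mod.jackknife_importance(
            cv.presence_values,
            bg_values,
            cv.codes,
            beta=config.beta,
            n_knots=config.n_knots,
        )
    imp_wide = pd.concat(
        {sp: df["percent"] for sp, df in importance_per_species.items()}, axis=1
    )
    imp_wide.to_csv(outdir / "importance.csv")
    mean_imp = feat_mod.mean_importance(importance_per_species)
    top_vars = feat_mod.select_top_variables(mean_imp, k=config.top_k_variables)
    (outdir / "top_variables.json").write_text(json.dumps(top_vars))
    counts["top_variables"] = top_vars

    table2_rows, fig4_rows = [], []
    for rcp, future_stack in futures.items():
        for var in top_vars:
            for realm_name, regions in (
                ("terrestrial", terrestrial),
                ("freshwater", freshwater),
            ):
                cvt = feat_mod.variable_change(current_screened, future_stack, regions, var)
                pot = potentials[rcp][realm_name]
                reg = feat_mod.potential_vs_change_regression(pot, cvt)
                reg["rcp"] = rcp
                table2_rows.append(reg)
                if rcp == "RCP4.5":
                    summ = feat_mod.biome_change_summary(cvt, pot)
                    summ["realm"] = realm_name
                    fig4_rows.append(summ)
    pd.concat(table2_rows, ignore_index=True).to_csv(
        outdir / "biome_regressions.csv", index=False
    )
    pd.concat(fig4_rows, ignore_index=True).to_csv(
        outdir / "biome_change_summary.csv", index=False
    )

    # --- manifest ---------------------------------------------------------
    files = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "species_order": species_order,
        "retained_species": retained_species,
        "counts": counts,
        "checksums": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
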