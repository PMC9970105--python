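"""Tabular I/O, run configuration, and the end-to-end pipeline driver.

All tabular interchange is comma-separated UTF-8 text with a header row;
rasters are headered ASCII grids.  A single global seed expands to per-stage
seeds via a fixed splitting rule so stages are independently rerunnable, and
every run writes a manifest (config, seeds, output checksums).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from pyrocast import glmm, montecarlo, standsim, assessment, landscape as lsc
from pyrocast.glmm import TREE_COLUMNS, MortalityModel

__all__ = [
    "RunConfig",
    "stage_seed",
    "read_tree_table",
    "write_tree_table",
    "read_stand_table",
    "write_stand_table",
    "read_reference_table",
    "write_reference_table",
    "write_model_table",
    "read_model_table",
    "run_pipeline",
]

STAGES = ("synth", "fit", "curves", "simulate", "assess", "classify")


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: (base * 7919 + stage index) mod 2^31."""
    return (int(base_seed) * 7919 + STAGES.index(stage)) % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    n_plots: int = 300
    trees_per_plot: int = 70
    forests: tuple = ("Malheur", "Fremont-Winema")
    forest_types: tuple = ("dry-mixed-conifer", "ponderosa-pine")
    stands_per_cell: int = 9
    iterations: int = 5
    draws_per_point: int = 75
    years_post_fire: float = 3.0
    thresholds: tuple = (0.90, 0.75, 0.50)
    share_draws: bool = False
    classification_metric: str = "basal_area"
    landscape_shape: tuple = (96, 96)
    min_trees: int = 50
    n_restarts: int = 1

    def __post_init__(self) -> None:
        for name in ("n_plots", "trees_per_plot", "stands_per_cell", "iterations",
                     "draws_per_point"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("forests", "forest_types", "thresholds", "landscape_shape"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------- tree tables

def read_tree_table(path) -> tuple[pd.DataFrame, int]:
    """Read burned-plot tree records; returns (records, n_rejected_rows).

    Required columns: plot_id, species, dbh_cm, rdnbr, years_post_fire,
    status (or a pre-pooled species_group column).  Species are pooled to
    modelling groups; malformed rows are rejected and counted, not fatal.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty tree table: {path}")
    species_col = "species_group" if "species_group" in df.columns else "species"
    required = {"plot_id", species_col, "dbh_cm", "rdnbr", "years_post_fire", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tree table missing required column(s): {sorted(missing)}")
    for col in ("dbh_cm", "rdnbr", "years_post_fire"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df["dbh_cm"].between(0, 300, inclusive="right")
        & np.isfinite(df["rdnbr"])
        & df["years_post_fire"].between(0, 15)
        & df["status"].astype(str).str.lower().isin(("live", "dead"))
    )
    n_rejected = int((~ok).sum())
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} malformed tree record(s)", UserWarning)
    df = df[ok].copy()
    if species_col != "species_group":
        df["species_group"] = df[species_col].map(standsim.pool_species)
    return df[list(TREE_COLUMNS)].reset_index(drop=True), n_rejected


def write_tree_table(path, records: pd.DataFrame) -> None:
    cols = [c for c in records.columns if c in TREE_COLUMNS + ("true_p",)]
    records[cols].to_csv(path, index=False)


# --------------------------------------------------------------- stand tables

_STAND_COLUMNS = ("stand_id", "forest", "forest_type", "species_group", "dbh_cm",
                  "expansion_factor")


def write_stand_table(path, stands: list[standsim.StandInventory]) -> None:
    rows = []
    for s in stands:
        t = s.trees.copy()
        t.insert(0, "stand_id", s.stand_id)
        t.insert(1, "forest", s.forest)
        t.insert(2, "forest_type", s.forest_type)
        rows.append(t)
    pd.concat(rows, ignore_index=True)[list(_STAND_COLUMNS)].to_csv(path, index=False)


def read_stand_table(path) -> list[standsim.StandInventory]:
    df = pd.read_csv(path)
    missing = set(_STAND_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stand table missing column(s): {sorted(missing)}")
    stands = []
    for (sid, forest, ftype), trees in df.groupby(["stand_id", "forest", "forest_type"]):
        stands.append(
            standsim.StandInventory(
                stand_id=str(sid),
                forest=str(forest),
                forest_type=str(ftype),
                trees=trees[["species_group", "dbh_cm", "expansion_factor"]].reset_index(drop=True),
            )
        )
    return stands


# ----------------------------------------------------------- reference tables

def write_reference_table(path, refs: list[assessment.HistoricalReference]) -> None:
    rows = []
    for r in refs:
        row = {
            "forest": r.forest,
            "forest_type": r.forest_type,
            "ba_mean": r.ba_mean,
            "ba_sd": r.ba_sd,
            "tph_mean": r.tph_mean,
            "tph_sd": r.tph_sd,
        }
        row.update({f"prop_{g}": p for g, p in r.composition.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_reference_table(path) -> list[assessment.HistoricalReference]:
    df = pd.read_csv(path)
    refs = []
    for rec in df.to_dict("records"):
        comp = {k[5:]: v for k, v in rec.items() if k.startswith("prop_")}
        refs.append(
            assessment.HistoricalReference(
                forest=rec["forest"],
                forest_type=rec["forest_type"],
                ba_mean=rec["ba_mean"],
                ba_sd=rec["ba_sd"],
                tph_mean=rec["tph_mean"],
                tph_sd=rec["tph_sd"],
                composition=comp,
            )
        )
    return refs


# --------------------------------------------------------------- model tables

def write_model_table(path, models: dict) -> None:
    rows = []
    for m in models.values():
        row = {
            "species_group": m.species_group,
            "has_interaction": m.has_interaction,
            "random_intercept_sd": m.random_intercept_sd,
            "n_trees": m.n_trees,
            "n_plots": m.n_plots,
            "log_likelihood": m.log_likelihood,
            "aicc": m.aicc,
            "r2_marginal": m.r2_marginal,
            "r2_conditional": m.r2_conditional,
            "dbh_max": m.dbh_max,
        }
        for term, b, se in zip(m.terms, m.coefficients, m.std_errors):
            row[f"coef_{term}"] = b
            row[f"se_{term}"] = se
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_model_table(path) -> dict:
    df = pd.read_csv(path)
    models = {}
    for rec in df.to_dict("records"):
        has_int = bool(rec["has_interaction"])
        terms = list(glmm.MAIN_TERMS) + ([glmm.INTERACTION_TERM] if has_int else [])
        models[rec["species_group"]] = MortalityModel(
            species_group=rec["species_group"],
            has_interaction=has_int,
            coefficients=np.array([rec[f"coef_{t}"] for t in terms]),
            std_errors=np.array([rec[f"se_{t}"] for t in terms]),
            random_intercept_sd=rec["random_intercept_sd"],
            n_trees=int(rec["n_trees"]),
            n_plots=int(rec["n_plots"]),
            log_likelihood=rec["log_likelihood"],
            aicc=rec.get("aicc", np.nan),
            r2_marginal=rec.get("r2_marginal", np.nan),
            r2_conditional=rec.get("r2_conditional", np.nan),
            dbh_max=rec.get("dbh_max", np.nan),
        )
    return models


# ------------------------------------------------------------------- pipeline

def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute synth -> fit -> curves -> simulate -> assess -> classify.

    Returns the manifest (also written to ``<out_dir>/manifest.json``) with
    config, per-stage seeds and output checksums.  Any stage failure raises
    with the stage name; the partial manifest is still written.
    """
    from pyrocast import synth

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {stage: stage_seed(config.seed, stage) for stage in STAGES}
    manifest = {"config": asdict(config), "seeds": seeds, "outputs": {}, "stages_completed": []}
    stage = "synth"
    try:
        truth = synth.default_truth()
        records = synth.gen_burned_plots(
            truth, config.n_plots, config.trees_per_plot, seed=seeds["synth"]
        )
        refs = synth.gen_historical_refs("default")
        stands = synth.gen_stand_set(
            truth, list(config.forests), list(config.forest_types),
            config.stands_per_cell, seed=seeds["synth"] + 1, refs=refs,
        )
        scape = synth.gen_landscape(*config.landscape_shape, seed=seeds["synth"] + 2)
        write_tree_table(out / "tree_records.csv", records)
        write_stand_table(out / "stands.csv", stands)
        write_reference_table(out / "historical_refs.csv", refs)
        lsc.write_ascii_grid(out / "severity.asc", scape.severity)
        lsc.write_ascii_grid(out / "vegtype.asc", scape.vegtype)
        _done(manifest, out, stage)

        stage = "fit"
        models = {}
        for group, sub in records.groupby("species_group"):
            try:
                m = glmm.fit_species_glmm(
                    sub, False, min_trees=config.min_trees,
                    n_restarts=config.n_restarts, seed=seeds["fit"],
                )
            except glmm.InestimableModelError as err:
                warnings.warn(f"skipping {group}: {err}", UserWarning)
                continue
            if m.n_trees > 2000:
                try:
                    mi = glmm.fit_species_glmm(
                        sub, True, min_trees=config.min_trees,
                        n_restarts=config.n_restarts, seed=seeds["fit"],
                    )
                    m = glmm.select_model(m, mi)
                except glmm.InestimableModelError:
                    pass
            models[group] = glmm.with_fit_statistics(m, sub)
        if not models:
            raise RuntimeError("no species model could be estimated")
        # groups present in stands but unmodelled must fail loudly later;
        # backfill from generating truth only for groups absent from records
        write_model_table(out / "mortality_models.csv", models)
        _done(manifest, out, stage)

        stage = "curves"
        curve_rows = []
        for m in models.values():
            for c in montecarlo.species_curves(
                m, draws_per_point=config.draws_per_point,
                years=config.years_post_fire, seed=seeds["curves"],
            ):
                curve_rows.append(
                    pd.DataFrame(
                        {
                            "species_group": c.species_group,
                            "dbh_class": c.dbh_class,
                            "severity": c.severities,
                            "mean": c.mean,
                            "sd": c.sd,
                            "smoothed_mean": c.smoothed_mean,
                            "smoothed_sd": c.smoothed_sd,
                        }
                    )
                )
        pd.concat(curve_rows, ignore_index=True).to_csv(out / "mortality_curves.csv", index=False)
        _done(manifest, out, stage)

        stage = "simulate"
        missing = sorted(
            {g for s in stands for g in s.trees["species_group"].unique()} - set(models)
        )
        if missing:
            raise RuntimeError(f"stand_fire_sim: no fitted model for group(s) {missing}")
        sweep = standsim.severity_sweep(
            stands, models, iterations=config.iterations, seed=seeds["simulate"],
            years=config.years_post_fire, share_draws=config.share_draws,
        )
        sweep.to_csv(out / "stand_outcomes.csv", index=False)
        _done(manifest, out, stage)

        stage = "assess"
        grid = standsim.default_stand_grid()
        range_rows = []
        ranges_by_key: dict = {}
        for ref in refs:
            key = (ref.forest, ref.forest_type)
            sub = sweep[(sweep["forest"] == ref.forest) & (sweep["forest_type"] == ref.forest_type)]
            if sub.empty:
                continue
            ranges_by_key[key] = {}
            for metric in assessment.METRIC_COLUMNS:
                props = assessment.proportions_by_severity(
                    sub, hrv_bounds_of(ref, metric), metric
                )
                ranges_by_key[key][metric] = {}
                for thr in config.thresholds:
                    r = assessment.restorative_range(
                        props, thr, metric=metric, forest=ref.forest, forest_type=ref.forest_type
                    )
                    ranges_by_key[key][metric][thr] = r
                    range_rows.append(
                        {
                            "forest": ref.forest,
                            "forest_type": ref.forest_type,
                            "metric": metric,
                            "threshold": thr,
                            "lo": r.lo,
                            "hi": r.hi,
                        }
                    )
        pd.DataFrame(range_rows).to_csv(out / "restorative_ranges.csv", index=False)

        val_records = synth.gen_validation_set(
            truth, stands, 200, seed=seeds["assess"], models=models,
        )
        ranges75 = {k: {m: v[m][0.75] for m in v} for k, v in ranges_by_key.items()}
        refs_map = {(r.forest, r.forest_type): r for r in refs}
        metrics = assessment.validate(val_records, sweep, ranges75, refs_map)
        (out / "validation_metrics.json").write_text(json.dumps(asdict(metrics), indent=2))
        _done(manifest, out, stage)

        stage = "classify"
        metric = config.classification_metric
        by_type: dict = {}
        for ftype in config.forest_types:
            cands = [v[metric] for (f, t), v in ranges_by_key.items() if t == ftype]
            usable = [c for c in cands if not c[0.75].empty and not c[0.50].empty]
            if not usable:
                raise RuntimeError(f"classify: no usable restorative window for {ftype!r}")
            by_type[ftype] = {thr: usable[0][thr] for thr in (0.75, 0.50)}
        cmap = lsc.classify_pixels(scape, by_type)
        lsc.write_ascii_grid(out / "restoration_classes.asc", cmap.classes, nodata=255)
        lsc.class_summary(cmap, scape).to_csv(out / "class_summary.csv", index=False)
        _done(manifest, out, stage)
    except Exception as err:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def hrv_bounds_of(ref: assessment.HistoricalReference, metric: str) -> tuple[float, float]:
    return assessment.hrv_bounds(ref, metric)


def _done(manifest: dict, out: Path, stage: str) -> None:
    manifest["stages_completed"].append(stage)
    manifest["outputs"] = {
        p.name: _checksum(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
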