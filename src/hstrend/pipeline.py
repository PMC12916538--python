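"""End-to-end pipeline: screen -> fit -> null -> trend -> aggregate.

Each stage reads and writes plain-text artifacts in the run directory, so
a run can be resumed: a stage whose outputs already exist (and are marked
complete in the manifest) is skipped.  The manifest records the
configuration, seed and per-stage status; config + seed fully determine
every numeric output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import grid as gio
from .grid import PredictorStack, read_stack_dir, read_occurrences, write_ascii_grid
from .maxent import hsi_series, HsiSeries
from .nullmodels import null_auc_distribution, wilcoxon_paired
from .predictors import screen_collinearity
from .trends import trend_map, TrendMap
from .vulnerability import (species_range, mask_trends, species_summary,
                            group_aggregate, compare_groups, conservation_tables)

logger = logging.getLogger("hstrend")

STAGES = ("screen", "fit", "null", "trend", "aggregate")


@dataclass
class RunConfig:
    """All paths, thresholds and defaults of one pipeline run.

    Defaults follow the standard protocol: 10 replicates per year, 70/30
    train/test, 100 null datasets, alpha = 0.05, VIF < 4, |r| < 0.75,
    minimum 15 occurrence records per species.
    """

    stack_dir: str = ""
    occurrences: str = ""
    traits: str = ""
    out_dir: str = "run"
    seed: int = 0
    years: list | None = None
    n_replicates: int = 10
    train_frac: float = 0.7
    n_null: int = 100
    null_species: list | None = None   # default: all species
    alpha: float = 0.05
    vif_threshold: float = 4.0
    r_threshold: float = 0.75
    min_records: int = 15
    beta_multiplier: float = 1.0
    range_method: str = "convex-hull"
    buffer_cells: int = 2
    aggregation: str = "pooled"
    background_region: str | None = None  # optional .asc mask: train sub-region

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.stack_dir, self.occurrences):
            if p and not os.path.exists(p):
                raise FileNotFoundError(p)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _manifest_path(cfg: RunConfig) -> str:
    return os.path.join(cfg.out_dir, "manifest.json")


def _load_manifest(cfg: RunConfig) -> dict:
    path = _manifest_path(cfg)
    if os.path.exists(path):
        with open(path) as fh:
            m = json.load(fh)
        if m.get("config_hash") != cfg.digest():
            logger.warning("config changed since last run; restarting all stages")
            m = {}
    else:
        m = {}
    m.setdefault("config_hash", cfg.digest())
    m.setdefault("config", asdict(cfg))
    m.setdefault("seed", cfg.seed)
    m.setdefault("stages", {})
    m.setdefault("warnings", [])
    return m


def _save_manifest(cfg: RunConfig, manifest: dict) -> None:
    with open(_manifest_path(cfg), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def _background(cfg: RunConfig, stack: PredictorStack) -> np.ndarray:
    if cfg.background_region:
        mask_layer = gio.read_ascii_grid(cfg.background_region)
        sub = (mask_layer.values > 0) & stack.grid.valid_mask.ravel()
        return np.flatnonzero(sub)
    return stack.grid.valid_cell_ids()


def _write_hsi(hsi: HsiSeries, out_dir: str) -> None:
    stack = PredictorStack(hsi.grid, hsi.years, ["hsi"],
                           {(y, "hsi"): hsi.hsi[y] for y in hsi.years})
    gio.write_raster_stack(stack, out_dir)


def _read_hsi(species_id: str, hsi_dir: str) -> HsiSeries:
    stack = read_stack_dir(hsi_dir)
    return HsiSeries(species_id, stack.grid, stack.years,
                     {y: stack.layers[(y, "hsi")] for y in stack.years})


def run_pipeline(cfg: RunConfig, stages=STAGES) -> dict:
    """Execute the pipeline; returns the manifest. Stages are resumable."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest = _load_manifest(cfg)
    stack = read_stack_dir(cfg.stack_dir)
    years = cfg.years or stack.years
    occ = read_occurrences(cfg.occurrences, stack.grid,
                           min_records=cfg.min_records,
                           traits_path=cfg.traits or None)
    background = _background(cfg, stack)

    try:
        if "screen" in stages:
            _stage_screen(cfg, manifest, stack)
        if "fit" in stages:
            _stage_fit(cfg, manifest, stack, occ, years, background)
        if "null" in stages:
            _stage_null(cfg, manifest, stack, occ, years, background)
        if "trend" in stages:
            _stage_trend(cfg, manifest, occ)
        if "aggregate" in stages:
            _stage_aggregate(cfg, manifest, stack, occ)
    except Exception as exc:  # record partial state before propagating
        manifest["error"] = repr(exc)
        _save_manifest(cfg, manifest)
        raise
    _save_manifest(cfg, manifest)
    return manifest


def _done(manifest, stage, *outputs) -> bool:
    return (manifest["stages"].get(stage) == "done"
            and all(os.path.exists(o) for o in outputs))


def _finish(cfg, manifest, stage) -> None:
    manifest["stages"][stage] = "done"
    _save_manifest(cfg, manifest)
    logger.info("stage %s done", stage)


def _stage_screen(cfg, manifest, stack) -> None:
    out = os.path.join(cfg.out_dir, "collinearity.json")
    if _done(manifest, "screen", out):
        return
    report = screen_collinearity(stack, cfg.vif_threshold, cfg.r_threshold)
    payload = {
        "retained": report.retained,
        "dropped": [list(d) for d in report.dropped],
        "vif": report.vif,
        "pearson": report.pearson.tolist() if report.pearson is not None else None,
    }
    with open(out, "w") as fh:
        json.dump(payload, fh, indent=1)
    _finish(cfg, manifest, "screen")


def _stage_fit(cfg, manifest, stack, occ, years, background) -> None:
    auc_csv = os.path.join(cfg.out_dir, "replicate_auc.csv")
    hsi_root = os.path.join(cfg.out_dir, "hsi")
    if _done(manifest, "fit", auc_csv):
        return
    os.makedirs(hsi_root, exist_ok=True)
    rows = []
    for sp in occ:
        logger.info("fit: %s (%d records)", sp.species_id, sp.n_records)
        hsi = hsi_series(sp, stack, years, n_replicates=cfg.n_replicates,
                         train_frac=cfg.train_frac, seed=cfg.seed,
                         background=background,
                         beta_multiplier=cfg.beta_multiplier)
        _write_hsi(hsi, os.path.join(hsi_root, sp.species_id))
        rows += [(sp.species_id, y, r, at, ae) for y, r, at, ae in hsi.auc_table]
    pd.DataFrame(rows, columns=["species_id", "year", "replicate", "auc_train",
                                "auc_test"]).to_csv(auc_csv, index=False)
    _finish(cfg, manifest, "fit")


def _stage_null(cfg, manifest, stack, occ, years, background) -> None:
    out = os.path.join(cfg.out_dir, "null_models.csv")
    if _done(manifest, "null", out):
        return
    wanted = set(cfg.null_species) if cfg.null_species else None
    rows = []
    emp_tr, null_tr_means = [], []
    for sp in occ:
        if wanted is not None and sp.species_id not in wanted:
            continue
        logger.info("null models: %s", sp.species_id)
        rep = null_auc_distribution(
            sp, stack, years, n_null=cfg.n_null,
            n_replicates=cfg.n_replicates, train_frac=cfg.train_frac,
            seed=cfg.seed, background=background,
            beta_multiplier=cfg.beta_multiplier)
        rows.append((sp.species_id, rep.n_null, rep.empirical_auc_train,
                     rep.empirical_auc_test, float(rep.null_auc_train.mean()),
                     float(rep.null_auc_test.mean()), rep.percentile_rank_train,
                     rep.significant))
        emp_tr.append(rep.empirical_auc_train)
        null_tr_means.append(float(rep.null_auc_train.mean()))
    df = pd.DataFrame(rows, columns=[
        "species_id", "n_null", "empirical_auc_train", "empirical_auc_test",
        "null_auc_train_mean", "null_auc_test_mean", "percentile_rank_train",
        "significant"])
    df.to_csv(out, index=False)
    if len(emp_tr) >= 5:
        V, p = wilcoxon_paired(emp_tr, null_tr_means)
        with open(os.path.join(cfg.out_dir, "wilcoxon.json"), "w") as fh:
            json.dump({"V": V, "p_two_sided": p, "n_species": len(emp_tr)}, fh)
    _finish(cfg, manifest, "null")


def _stage_trend(cfg, manifest, occ) -> None:
    trend_root = os.path.join(cfg.out_dir, "trends")
    marker = os.path.join(trend_root, ".complete")
    if _done(manifest, "trend", marker):
        return
    os.makedirs(trend_root, exist_ok=True)
    hsi_root = os.path.join(cfg.out_dir, "hsi")
    for sp in occ:
        hsi = _read_hsi(sp.species_id, os.path.join(hsi_root, sp.species_id))
        tm = trend_map(hsi)
        write_ascii_grid(tm.slope, os.path.join(trend_root,
                                                f"slope_{sp.species_id}.asc"))
        write_ascii_grid(tm.p_value, os.path.join(trend_root,
                                                  f"p_{sp.species_id}.asc"))
    with open(marker, "w") as fh:
        fh.write("ok\n")
    _finish(cfg, manifest, "trend")


def _read_trend(species_id: str, trend_root: str, grid) -> TrendMap:
    slope = gio.read_ascii_grid(os.path.join(trend_root, f"slope_{species_id}.asc"))
    p = gio.read_ascii_grid(os.path.join(trend_root, f"p_{species_id}.asc"))
    n_eff = (~p.is_missing()).astype(int)
    return TrendMap(species_id, slope.grid, slope, p,
                    np.zeros(grid.n_cells, dtype=int), n_eff)


def _stage_aggregate(cfg, manifest, stack, occ) -> None:
    out_csv = os.path.join(cfg.out_dir, "species_summary.csv")
    if _done(manifest, "aggregate", out_csv):
        return
    trend_root = os.path.join(cfg.out_dir, "trends")
    members = {}
    rows = []
    for sp in occ:
        tm = _read_trend(sp.species_id, trend_root, stack.grid)
        rng = species_range(sp, stack.grid, method=cfg.range_method,
                            buffer_cells=cfg.buffer_cells)
        masked = mask_trends(tm, rng, alpha=cfg.alpha)
        summ = species_summary(masked, rng)
        members[sp.species_id] = (summ, masked, rng)
        rows.append(asdict(summ))
    pd.DataFrame(rows).to_csv(out_csv, index=False)

    grouping = {sp.species_id: sp.traits.get("group", "ungrouped") for sp in occ}
    group_rows = []
    for g in sorted(set(grouping.values())):
        mem = [members[s] for s, gg in grouping.items() if gg == g]
        summ, mean_l, sd_l = group_aggregate(mem, unit_id=g, mode=cfg.aggregation)
        write_ascii_grid(mean_l, os.path.join(cfg.out_dir, f"group_{g}_mean.asc"))
        write_ascii_grid(sd_l, os.path.join(cfg.out_dir, f"group_{g}_sd.asc"))
        group_rows.append(asdict(summ))
    all_summ, all_mean, all_sd = group_aggregate(list(members.values()),
                                                 unit_id="all_species",
                                                 mode=cfg.aggregation)
    write_ascii_grid(all_mean, os.path.join(cfg.out_dir, "all_species_mean.asc"))
    write_ascii_grid(all_sd, os.path.join(cfg.out_dir, "all_species_sd.asc"))
    group_rows.append(asdict(all_summ))
    pd.DataFrame(group_rows).to_csv(os.path.join(cfg.out_dir,
                                                 "group_summary.csv"), index=False)

    props = {s: members[s][0].prop_neg for s in members}
    n_per_group = pd.Series(list(grouping.values())).value_counts()
    if len(n_per_group) >= 2 and (n_per_group >= 2).all():
        try:
            F, p, tukey = compare_groups(props, grouping)
            with open(os.path.join(cfg.out_dir, "anova_tukey.json"), "w") as fh:
                json.dump({"anova_F": F, "anova_p": p,
                           "tukey": [[list(pair), d, padj]
                                     for pair, d, padj in tukey]}, fh, indent=1)
        except ValueError as exc:
            manifest["warnings"].append(f"group comparison skipped: {exc}")

    for level, attr in (("regional", "status_regional"),
                        ("european", "status_european")):
        statuses = {sp.species_id: getattr(sp, attr) for sp in occ}
        tables = conservation_tables(members, statuses, mode=cfg.aggregation)
        pd.DataFrame([asdict(s) for s in tables.values()]).to_csv(
            os.path.join(cfg.out_dir, f"conservation_{level}.csv"), index=False)
    _finish(cfg, manifest, "aggregate")
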