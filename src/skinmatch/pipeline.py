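"""End-to-end orchestration: simulate or load data, then chain depth
filtering, rarefaction, diversity, distances, ordination, matching,
PERMANOVA sweeps, pairing nulls, and indicator analyses into a report
bundle of TSV/JSON artifacts with a run manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

import skinmatch
from skinmatch import alpha as alpha_mod
from skinmatch import indicators as ind_mod
from skinmatch import matching as match_mod
from skinmatch import pairing as pair_mod
from skinmatch import permanova as perm_mod
from skinmatch.beta import bray_curtis, pcoa, write_distance_matrix, write_ordination
from skinmatch.simulate import SimConfig, seed_low_depth_samples, simulate_community
from skinmatch.tables import (
    filter_low_depth,
    rarefy,
    read_metadata,
    read_otu_table,
    write_metadata,
    write_otu_table,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Full-run configuration; the zero-config defaults are the
    full-scale analysis settings (depth 5,293; 1,000 permutations for
    PERMANOVA and the pairing null; 999 for indicators and alpha tests;
    1,000 trees; 10 folds; indval >= 0.7, mean >= 10, alpha 0.05)."""

    otu_table: str | None = None
    metadata: str | None = None
    rarefaction_depth: int = 5293
    alpha_min_depth: int = 100
    alpha_max_depth: int = 5290
    alpha_step: int = 100
    alpha_reps: int = 10
    permanova_perms: int = 1000
    pairing_perms: int = 1000
    indval_perms: int = 999
    alpha_perms: int = 999
    n_trees: int = 1000
    n_folds: int = 10
    indval_min: float = 0.7
    indval_mean_min: float = 10.0
    alpha_level: float = 0.05
    abundance_threshold: float = 0.01
    seed: int = 0
    scaled_down: bool = False
    n_low_depth: int = 10
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        for name in ("rarefaction_depth", "permanova_perms", "pairing_perms",
                     "indval_perms", "alpha_perms", "n_trees", "n_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def effective(self) -> "PipelineConfig":
        """Scaled-down settings for fast smoke runs (recorded in the manifest)."""
        if not self.scaled_down:
            return self
        return replace(
            self,
            permanova_perms=min(self.permanova_perms, 99),
            pairing_perms=min(self.pairing_perms, 19),
            indval_perms=min(self.indval_perms, 99),
            alpha_perms=min(self.alpha_perms, 99),
            n_trees=min(self.n_trees, 25),
            n_folds=min(self.n_folds, 3),
            alpha_reps=min(self.alpha_reps, 2),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        sim = SimConfig(**sim_raw) if sim_raw else SimConfig()
        return cls(sim=sim, **raw)


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis chain and write the report bundle.

    Returns the manifest dictionary.  Idempotent per seed: statistical
    outputs are byte-identical across reruns with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.effective()
    manifest: dict = {
        "package_version": skinmatch.__version__,
        "numpy_version": np.__version__,
        "config": {**{k: v for k, v in asdict(cfg).items() if k != "sim"},
                   "sim": asdict(cfg.sim)},
        "stages": {},
        "warnings": [],
    }
    t0 = time.time()

    def stage(name: str):
        manifest["stages"][name] = {"t_start": round(time.time() - t0, 3)}
        log.info("stage: %s", name)
        return name

    try:
        # ---- load or simulate -----------------------------------------
        stage("input")
        if cfg.otu_table and cfg.metadata:
            table = read_otu_table(cfg.otu_table)
            meta = read_metadata(cfg.metadata)
        else:
            table, meta, _ = simulate_community(cfg.sim)
            if cfg.n_low_depth:
                table = seed_low_depth_samples(
                    table, cfg.n_low_depth, cfg.rarefaction_depth, seed=cfg.seed
                )
            write_otu_table(table, outdir / "otu_table.tsv")
            write_metadata(meta, outdir / "mapping.tsv")

        # ---- filter + rarefy -----------------------------------------
        stage("rarefy")
        table, removed = filter_low_depth(table, cfg.rarefaction_depth)
        manifest["removed_samples"] = removed
        meta = meta.subset(table.sample_ids)
        rare = rarefy(table, cfg.rarefaction_depth, seed=cfg.seed)
        write_otu_table(rare, outdir / "rarefied_table.tsv")

        # ---- alpha diversity -----------------------------------------
        stage("alpha")
        max_depth = min(cfg.alpha_max_depth, cfg.rarefaction_depth)
        min_depth = min(cfg.alpha_min_depth, max_depth)
        alpha_res = alpha_mod.multiple_rarefactions_alpha(
            rare, min_depth, max_depth, cfg.alpha_step, cfg.alpha_reps,
            metric="shannon", seed=cfg.seed,
        )
        categories = ["sex", "moisture", "body_location"] + list(meta.lifestyle_categories)
        sweep = alpha_mod.alpha_category_sweep(
            alpha_res, meta, categories, n_perms=cfg.alpha_perms, seed=cfg.seed
        )
        alpha_mod.sweep_to_frame(sweep).to_csv(outdir / "alpha_sweep.tsv", sep="\t", index=False)

        # ---- beta diversity ------------------------------------------
        stage("beta")
        dm = bray_curtis(rare)
        write_distance_matrix(dm, outdir / "distance_matrix.tsv")
        ordination = pcoa(dm, n_axes=min(10, dm.n_samples - 1))
        write_ordination(ordination, outdir / "pcoa.tsv")

        # ---- closest-match -------------------------------------------
        stage("match")
        records = []
        for scope in match_mod.SCOPES:
            records.extend(match_mod.nearest_neighbors(dm, meta, scope, within_location=True))
        summary = match_mod.match_proportions(records, meta)
        summary.to_csv(outdir / "match_summary.tsv", sep="\t", index=False)

        # ---- PERMANOVA sweep -----------------------------------------
        stage("permanova")
        cats = ["participant", "couple", "sex", "moisture"] + list(meta.lifestyle_categories)
        res_all = perm_mod.category_sweep(
            dm, meta, cats + ["body_location"], per_location=False,
            n_perms=cfg.permanova_perms, seed=cfg.seed, alpha=cfg.alpha_level,
        )
        res_loc = perm_mod.category_sweep(
            dm, meta, cats, per_location=True,
            n_perms=cfg.permanova_perms, seed=cfg.seed, alpha=cfg.alpha_level,
        )
        res_all.assign(stratum="global").to_csv(
            outdir / "permanova_global.tsv", sep="\t", index=False
        )
        res_loc.to_csv(outdir / "permanova_by_location.tsv", sep="\t", index=False)

        # ---- pairing nulls -------------------------------------------
        stage("pairing_null")
        n_pairings = min(cfg.pairing_perms, pair_mod.derangement_count(len(meta.couples)))
        pairings = pair_mod.sample_unique_pairings(meta, n_pairings, seed=cfg.seed)
        null_f = pair_mod.pairing_null_permanova(dm, meta, pairings)
        null_err = pair_mod.pairing_null_classifier(
            rare, meta, pairings, n_trees=cfg.n_trees, n_folds=cfg.n_folds, seed=cfg.seed
        )
        _dump_json(null_f.to_dict(), outdir / "pairing_null_permanova.json")
        _dump_json(null_err.to_dict(), outdir / "pairing_null_classifier.json")
        for null, name in ((null_f, "pairing_null_permanova"), (null_err, "pairing_null_classifier")):
            with open(outdir / f"{name}_values.tsv", "w") as fh:
                fh.write("pairing\tvalue\n")
                fh.write(f"observed\t{null.observed:.10g}\n")
                for k, v in enumerate(null.null_values):
                    fh.write(f"null_{k:04d}\t{v:.10g}\n")

        # ---- indicators / core / enrichment --------------------------
        stage("indicators")
        recs = ind_mod.indval(
            rare, meta.df.loc[list(rare.sample_ids), "couple"].to_numpy(),
            n_perms=cfg.indval_perms, seed=cfg.seed,
        )
        kept = ind_mod.filter_indicators(
            recs, cfg.indval_min, cfg.indval_mean_min, cfg.alpha_level
        )
        ind_mod.indicators_to_frame(kept, rare).to_csv(
            outdir / "couple_indicators.tsv", sep="\t", index=False
        )
        enrich = ind_mod.sex_enrichment_table(rare, meta)
        enrich.to_csv(outdir / "sex_enrichment.tsv", sep="\t", index=False)
        core_f = sorted(ind_mod.core_otus(rare, meta, "sex", "female"))
        core_m = sorted(ind_mod.core_otus(rare, meta, "sex", "male"))
        _dump_json({"female": core_f, "male": core_m}, outdir / "core_otus.json")

    except Exception as exc:  # abort with the stage name
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    manifest["wall_time_s"] = round(time.time() - t0, 3)
    _dump_json(manifest, outdir / "manifest.json")
    return manifest
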