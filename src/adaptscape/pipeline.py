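"""End-to-end per-species pipeline and cross-species comparison.

``run_species`` chains the full analysis for one species: quality control,
climate extraction and within-group collinearity pruning, the three genome
scans (PCA-outlier differentiation, latent-factor ridge environment
association, Bayesian covariance environment association), the consensus
partition into putatively adaptive/neutral SNP sets, Weir-Cockerham FST per
set, GDM fitting (with optional permutation backward elimination), deviance
partitioning over geography/temperature/precipitation, and composition maps.
``compare_species`` then contrasts two completed bundles with Procrustes
residuals (adaptive onto neutral, scaled across species) and the
temperature-vs-precipitation deviance shares.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import (McmcSettings, PAPER_SCALE_SETTINGS, bayes_aux_scan,
                    bayes_core_fit, xtx_calibrate)
from .climate import ClimateTable, extract_at_points, population_means, spearman_prune
from .consensus import partition_loci
from .fst import pairwise_matrix, scale_unit
from .gdm import GEO, backward_eliminate, build_pair_table, fit_gdm, importance, \
    partition_deviance
from .genotypes import GenotypeMatrix, pop_allele_counts, run_qc
from .scans import choose_k_scree, lfmm_impute, lfmm_ridge_scan, \
    pca_outlier_scan, pca_scree_eigenvalues
from .spatial import pca_rgb, procrustes_residuals, scale_residuals_across, \
    transform_grid

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SpeciesBundle", "run_species", "compare_species"]


@dataclass
class RunConfig:
    """Settings for one species run.

    Desk-scale MCMC and permutation counts are the defaults; ``paper_scale``
    restores the reference run lengths (100k/50k MCMC over 4 chains, 500
    permutations).
    """

    # QC
    max_locus_missing: float = 0.05
    min_repro: float = 0.98
    min_maf: float = 0.05
    max_ind_missing: float = 0.20
    # climate
    spearman_threshold: float = 0.8
    # scans
    k_override: int | None = None
    k_min: int = 2
    k_max: int = 10
    fdr: float = 0.05
    mcmc_iter: int = 2000
    mcmc_burn: int = 1000
    mcmc_chains: int = 2
    mcmc_thin: int = 5
    n_pseudo: int = 1000
    db_threshold: float = 20.0
    # consensus
    min_methods: int = 2
    # GDM
    n_perm: int = 100
    alpha: float = 0.05
    force_retain: tuple[str, ...] = ()
    do_elimination: bool = True
    scale_method: str = "minmax"
    min_adaptive_loci: int = 3
    # general
    seed: int = 0
    paper_scale: bool = False

    def __post_init__(self) -> None:
        for name in ("max_locus_missing", "min_repro", "min_maf",
                     "max_ind_missing", "fdr", "alpha"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.paper_scale:
            self.mcmc_iter = PAPER_SCALE_SETTINGS["n_iter"]
            self.mcmc_burn = PAPER_SCALE_SETTINGS["burn_in"]
            self.mcmc_chains = PAPER_SCALE_SETTINGS["n_chains"]
            self.mcmc_thin = PAPER_SCALE_SETTINGS["thin"]
            self.n_perm = 500

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "force_retain" in data:
            data["force_retain"] = tuple(data["force_retain"])
        return cls(**data)

    def mcmc_settings(self, seed_offset: int = 0) -> McmcSettings:
        return McmcSettings(n_iter=self.mcmc_iter, burn_in=self.mcmc_burn,
                            n_chains=self.mcmc_chains, thin=self.mcmc_thin,
                            seed=int(self.seed) + seed_offset)


@dataclass
class SpeciesBundle:
    """Everything a species run produces."""

    label: str
    config: RunConfig
    genotypes: GenotypeMatrix
    qc_report: object
    climate: ClimateTable
    retained_variables: list[str]
    pop_env: pd.DataFrame
    pop_coords: pd.DataFrame
    K: int
    scans: dict = field(default_factory=dict)
    partition: object = None
    xtx_thresholds: tuple[float, float] | None = None
    fst: dict = field(default_factory=dict)
    gdm_models: dict = field(default_factory=dict)
    deviance_partition: dict = field(default_factory=dict)
    maps: dict = field(default_factory=dict)
    grids: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)


def _variable_groups(climate: ClimateTable, variables):
    groups = {"geo": [GEO], "temperature": [], "precipitation": []}
    for v in variables:
        groups[climate.groups[v]].append(v)
    return {k: v for k, v in groups.items() if v}


def run_species(genotypes: GenotypeMatrix, grids: dict, config: RunConfig,
                label: str = "species", outdir=None) -> SpeciesBundle:
    """Run the full single-species analysis; see module docstring for stages."""
    t0 = time.perf_counter()
    timings = {}

    def tick(stage):
        nonlocal t0
        timings[stage] = round(time.perf_counter() - t0, 3)
        t0 = time.perf_counter()

    # ---- QC ---------------------------------------------------------------
    g, qc_report = run_qc(genotypes, config.max_locus_missing, config.min_repro,
                          config.min_maf, config.max_ind_missing,
                          seed=config.seed)
    logger.info("%s: QC kept %d loci, %d individuals", label, g.n_loci,
                g.n_samples)
    tick("qc")

    # ---- climate ----------------------------------------------------------
    climate = extract_at_points(grids, g.samples)
    retained = []
    for group in ("temperature", "precipitation"):
        if climate.variables_in_group(group):
            retained.extend(spearman_prune(climate, group,
                                           config.spearman_threshold))
    climate_kept = climate.subset(retained)
    pop_env, pop_coords = population_means(climate_kept, g.samples)
    tick("climate")

    # ---- scans ------------------------------------------------------------
    ev = pca_scree_eigenvalues(g, k_max=config.k_max)
    # floor the scree choice: structured multi-population sampling always has
    # at least two axes of structure worth conditioning on
    K = config.k_override or max(choose_k_scree(ev, k_max=config.k_max),
                                 min(config.k_min, g.n_samples - 1))
    scan_pd = pca_outlier_scan(g, K=K, fdr=config.fdr, seed=config.seed)
    tick("scan_pca")

    imputed = lfmm_impute(g, K=max(K, 1), seed=config.seed)
    env_ind = climate_kept.values.loc[g.samples["sample_id"]]
    scan_lfmm = lfmm_ridge_scan(g if not (g.counts == -1).any() else imputed,
                                env_ind, K=K, fdr=config.fdr)
    scan_lfmm.table["locus_id"] = list(g.loci["locus_id"])
    for t in scan_lfmm.per_variable.values():
        t["locus_id"] = list(g.loci["locus_id"])
    tick("scan_lfmm")

    pops, alt, tot = pop_allele_counts(g)
    settings = config.mcmc_settings()
    core = bayes_core_fit(alt, tot, pop_labels=pops,
                          locus_ids=list(g.loci["locus_id"]),
                          settings=settings)
    q03, q97, outlier_flags = xtx_calibrate(core, alt, tot, seed=config.seed,
                                            n_pseudo=config.n_pseudo,
                                            settings=settings)
    neutral_idx = np.flatnonzero(~outlier_flags)
    core_neutral = bayes_core_fit(alt[:, neutral_idx], tot[:, neutral_idx],
                                  pop_labels=pops,
                                  settings=config.mcmc_settings(seed_offset=1))
    scan_bayes = bayes_aux_scan(core_neutral, alt, tot, pop_env,
                                threshold_db=config.db_threshold,
                                settings=settings, seed=config.seed,
                                locus_ids=list(g.loci["locus_id"]))
    tick("scan_bayes")

    # ---- consensus --------------------------------------------------------
    part = partition_loci([scan_pd, scan_lfmm, scan_bayes],
                          min_methods=config.min_methods)
    logger.info("%s: consensus adaptive=%d neutral=%d single=%d", label,
                len(part.adaptive), len(part.neutral), len(part.single_method))
    tick("consensus")

    # ---- FST / GDM per subset ----------------------------------------------
    bundle = SpeciesBundle(label=label, config=config, genotypes=g,
                           qc_report=qc_report, climate=climate_kept,
                           retained_variables=retained, pop_env=pop_env,
                           pop_coords=pop_coords, K=K,
                           scans={"pca_outlier": scan_pd,
                                  "lfmm_ridge": scan_lfmm,
                                  "bayes_ea": scan_bayes},
                           partition=part, xtx_thresholds=(q03, q97),
                           grids=grids)
    groups = _variable_groups(climate_kept, retained)
    forced: dict = {}
    for subset, ids in (("neutral", part.neutral), ("adaptive", part.adaptive)):
        if len(ids) < config.min_adaptive_loci:
            logger.warning("%s: %s set too small (%d loci); GDM skipped",
                           label, subset, len(ids))
            continue
        fst = scale_unit(pairwise_matrix(g, locus_ids=ids),
                         method=config.scale_method)
        bundle.fst[subset] = fst
        pair_table = build_pair_table(fst.scaled, pop_env, pop_coords)
        if config.do_elimination:
            model = backward_eliminate(pair_table, n_perm=config.n_perm,
                                       alpha=config.alpha, seed=config.seed,
                                       force_retain=config.force_retain)
            if not any(p != GEO for p in model.predictors):
                # keep the strongest climate variable even when it misses the
                # significance cut, so the subset can still be mapped (the
                # study retained its best near-significant variable the same
                # way); the forced predictor is visible in the manifest
                full = fit_gdm(pair_table)
                climate_imp = {p: v for p, v in importance(full).items()
                               if p != GEO}
                if climate_imp:
                    best = max(climate_imp, key=climate_imp.get)
                    model = backward_eliminate(
                        pair_table, n_perm=config.n_perm, alpha=config.alpha,
                        seed=config.seed,
                        force_retain=tuple(config.force_retain) + (best,))
                    forced[subset] = best
        else:
            model = fit_gdm(pair_table)
        bundle.gdm_models[subset] = model
        model_groups = {gname: [p for p in preds if p in model.predictors]
                        for gname, preds in groups.items()}
        model_groups = {k: v for k, v in model_groups.items() if v}
        if model_groups:
            bundle.deviance_partition[subset] = partition_deviance(
                pair_table, model_groups)
        climate_preds = [p for p in model.predictors if p != GEO]
        if climate_preds:
            surfaces = transform_grid(model, grids)
            bundle.maps[subset] = pca_rgb(surfaces)
    tick("fst_gdm_maps")

    bundle.timings = timings
    bundle.manifest = {
        "package_version": __version__,
        "label": label,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "K": K,
        "lambda_pca": scan_pd.params["lambda"],
        "xtx_thresholds": [q03, q97],
        "n_loci_scanned": g.n_loci,
        "n_adaptive": len(part.adaptive),
        "n_neutral": len(part.neutral),
        "force_retained": forced,
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: SpeciesBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.qc_report.to_json(outdir / "qc_report.json")
    bundle.climate.to_csv(outdir / "climate_table.csv")
    for name, scan in bundle.scans.items():
        scan.to_csv(outdir / f"scan_{name}.csv")
    bundle.partition.to_json(outdir / "consensus_partition.json")
    pd.DataFrame([bundle.partition.venn_counts]).T.rename(
        columns={0: "count"}).rename_axis("region").to_csv(
        outdir / "venn_counts.csv")
    for subset, fst in bundle.fst.items():
        fst.to_csv(outdir / f"fst_{subset}.csv")
        fst.to_json(outdir / f"fst_{subset}.json")
    for subset, model in bundle.gdm_models.items():
        dump = {
            "intercept": model.intercept,
            "predictors": model.predictors,
            "coefficients": {p: model.coefs[p].tolist() for p in model.predictors},
            "knots": {p: list(model.basis[p].knots) for p in model.predictors},
            "deviance_model": model.deviance_model,
            "deviance_null": model.deviance_null,
            "pct_explained": model.pct_explained,
            "p_values": model.p_values,
            "importance": importance(model),
        }
        with open(outdir / f"gdm_{subset}.json", "w") as fh:
            json.dump(dump, fh, indent=2)
    for subset, table in bundle.deviance_partition.items():
        table.to_csv(outdir / f"deviance_partition_{subset}.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)


def _climate_share(table: pd.DataFrame, group: str) -> float:
    """Total explained-deviance share (unique + joint) touching one group."""
    rows = table[table["component"].str.split("&").apply(lambda cs: group in cs)]
    return float(rows["pct_of_explained"].sum())


def compare_species(bundle_a: SpeciesBundle, bundle_b: SpeciesBundle) -> dict:
    """Cross-species comparison report (see module docstring)."""
    ga = next(iter(bundle_a.grids.values()))
    gb = next(iter(bundle_b.grids.values()))
    if ga.shape != gb.shape or ga.extent != gb.extent:
        raise ValueError("species bundles use different climate grids")

    report: dict = {"species": [bundle_a.label, bundle_b.label]}
    residual_sets = {}
    for bundle in (bundle_a, bundle_b):
        entry: dict = {}
        if "neutral" in bundle.maps and "adaptive" in bundle.maps:
            pr = procrustes_residuals(bundle.maps["neutral"],
                                      bundle.maps["adaptive"])
            entry["procrustes"] = pr
            residual_sets[bundle.label] = pr
        for subset, table in bundle.deviance_partition.items():
            entry[f"deviance_partition_{subset}"] = table
            entry[f"{subset}_temperature_share"] = _climate_share(table, "temperature")
            entry[f"{subset}_precipitation_share"] = _climate_share(table, "precipitation")
            entry[f"{subset}_geo_share"] = _climate_share(table, "geo")
        report[bundle.label] = entry

    if len(residual_sets) == 2:
        (la, ra), (lb, rb) = residual_sets.items()
        sa, sb = scale_residuals_across(ra.residuals, rb.residuals)
        ra.scaled_residual_grid = np.full(ra.residual_grid.shape, np.nan)
        ra.scaled_residual_grid[~np.isnan(ra.residual_grid)] = sa
        rb.scaled_residual_grid = np.full(rb.residual_grid.shape, np.nan)
        rb.scaled_residual_grid[~np.isnan(rb.residual_grid)] = sb
        pooled = np.concatenate([ra.residuals, rb.residuals])
        report["residual_scaling"] = {"min": float(pooled.min()),
                                      "max": float(pooled.max())}
    return report
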