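"""Run the full single-species pipeline for the host and the parasite.

Reads the inputs written by ``01_simulate_pair.py`` and runs, per species:
QC -> climate extraction and Spearman pruning -> three genome scans
(PCA-outlier, latent-factor ridge, Bayesian environmental association) ->
consensus partition -> Weir-Cockerham FST per subset -> GDM with permutation
backward elimination -> deviance partitioning -> adaptive/neutral
composition maps.  Artifacts land in ``results/<species>/``.

Usage: python analysis/02_run_species.py [--seed 1] [--data results/data]
       [--out results] [--paper-scale]
"""

import argparse
import json
import pickle
from pathlib import Path

from adaptscape.genotypes import attach_sample_metadata, read_samples_csv, \
    read_snp_table
from adaptscape.grids import ClimateGrid
from adaptscape.pipeline import RunConfig, run_species


def load_grids(grid_dir: Path) -> dict:
    with open(grid_dir / "manifest.json") as fh:
        groups = json.load(fh)
    return {name: ClimateGrid.from_ascii(grid_dir / f"{name}.asc",
                                         name=name, group=group)
            for name, group in groups.items()}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--paper-scale", action="store_true",
                    help="use publication-scale MCMC/permutation settings "
                    "(much slower)")
    args = ap.parse_args()

    grids = load_grids(args.data / "grids")
    config = RunConfig(seed=args.seed, paper_scale=args.paper_scale)

    for label in ("host", "parasite"):
        g = read_snp_table(args.data / f"{label}_snps.csv")
        g = attach_sample_metadata(g, read_samples_csv(
            args.data / f"{label}_samples.csv"))
        bundle = run_species(g, grids, config, label=label,
                             outdir=args.out / label)
        # local cache for 03_compare_species.py (not a portable artifact)
        with open(args.out / label / "bundle.pkl", "wb") as fh:
            pickle.dump(bundle, fh)
        part = bundle.partition
        print(f"\n== {label} ==")
        print(f"QC: {bundle.genotypes.n_loci} loci, "
              f"{bundle.genotypes.n_samples} individuals retained; K={bundle.K}")
        print(f"consensus: {len(part.adaptive)} adaptive, "
              f"{len(part.neutral)} neutral, "
              f"{len(part.single_method)} single-method")
        for subset, fst in bundle.fst.items():
            print(f"global WC theta ({subset}): {fst.global_theta:.4f}")
        for subset, model in bundle.gdm_models.items():
            print(f"GDM {subset}: retained {model.predictors}, "
                  f"{model.pct_explained:.1f}% deviance explained")
        for subset, table in bundle.deviance_partition.items():
            print(f"deviance partition ({subset}):")
            print(table.to_string(index=False))


if __name__ == "__main__":
    main()
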