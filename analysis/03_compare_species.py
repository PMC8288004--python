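"""Cross-species comparison: composition maps, Procrustes residuals, shares.

Loads the host and parasite bundles cached by ``02_run_species.py`` and
writes, under ``results/compare/``:

* ``shares.csv``           -- per species x subset: temperature, precipitation
                              and geographic shares of explained GDM deviance
* ``procrustes.json``      -- neutral-vs-adaptive Procrustes summary per species
* ``map_<species>_<subset>.png``      -- RGB adaptive/neutral composition maps
* ``residuals_<species>.png``         -- cross-species scaled residual surfaces

Usage: python analysis/03_compare_species.py [--results results]
"""

import argparse
import json
import pickle
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from adaptscape.pipeline import compare_species


def _extent(grid):
    x0, y0, x1, y1 = grid.extent
    return (x0, x1, y0, y1)


def plot_rgb(comp_map, grid, title, path):
    rgb = comp_map.rgb.astype(float) / 255.0
    rgba = np.dstack([rgb, comp_map.valid_mask.astype(float)])
    fig, ax = plt.subplots(figsize=(4, 5))
    ax.imshow(rgba, origin="lower", extent=_extent(grid))
    ax.set(title=title, xlabel="longitude", ylabel="latitude")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_residuals(grid, residual_grid, title, path, vmax):
    fig, ax = plt.subplots(figsize=(4, 5))
    im = ax.imshow(residual_grid, origin="lower", extent=_extent(grid),
                   cmap="magma", vmin=0.0, vmax=vmax)
    fig.colorbar(im, ax=ax, label="scaled neutral-adaptive mismatch")
    ax.set(title=title, xlabel="longitude", ylabel="latitude")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundles = {}
    for label in ("host", "parasite"):
        with open(args.results / label / "bundle.pkl", "rb") as fh:
            bundles[label] = pickle.load(fh)
    report = compare_species(bundles["host"], bundles["parasite"])

    out = args.results / "compare"
    out.mkdir(parents=True, exist_ok=True)

    rows, pr_summary = [], {}
    for label, bundle in bundles.items():
        entry = report[label]
        for subset in ("neutral", "adaptive"):
            if f"deviance_partition_{subset}" not in entry:
                continue
            rows.append({
                "species": label, "subset": subset,
                "temperature_share_pct": entry[f"{subset}_temperature_share"],
                "precipitation_share_pct": entry[f"{subset}_precipitation_share"],
                "geographic_share_pct": entry[f"{subset}_geo_share"],
            })
        if "procrustes" in entry:
            pr = entry["procrustes"]
            pr_summary[label] = {
                "scale": pr.scale,
                "mean_residual": float(np.mean(pr.residuals)),
                "max_residual": float(np.max(pr.residuals)),
            }
        grid = next(iter(bundle.grids.values()))
        for subset, comp in bundle.maps.items():
            plot_rgb(comp, grid, f"{label}: {subset} composition",
                     out / f"map_{label}_{subset}.png")
        if "procrustes" in entry and entry["procrustes"].scaled_residual_grid is not None:
            plot_residuals(grid, entry["procrustes"].scaled_residual_grid,
                           f"{label}: neutral vs adaptive mismatch",
                           out / f"residuals_{label}.png", vmax=1.0)

    shares = pd.DataFrame(rows)
    shares.to_csv(out / "shares.csv", index=False)
    if "residual_scaling" in report:
        pr_summary["pooled_residual_scaling"] = report["residual_scaling"]
    with open(out / "procrustes.json", "w") as fh:
        json.dump(pr_summary, fh, indent=2)

    print("deviance shares (% of explained deviance touching each group):")
    print(shares.to_string(index=False))
    print("\nProcrustes neutral-vs-adaptive summary:")
    print(json.dumps(pr_summary, indent=2))


if __name__ == "__main__":
    main()
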