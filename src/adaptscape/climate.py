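"""Climate predictors: point extraction, collinearity pruning, population means.

Values are read from the raster cell containing each sample point
(nearest-cell rule, half-open cell intervals).  Within each variable group
(temperature, precipitation) highly rank-correlated variables are pruned with
a deterministic rule so the retained set has pairwise |Spearman rho| below a
threshold (0.8 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ClimateTable", "extract_at_points", "spearman_prune",
           "population_means"]


@dataclass
class ClimateTable:
    """Per-sample climate values plus variable group tags."""

    values: pd.DataFrame = field(repr=False)  # index sample_id, one col/variable
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"variables without group tags: {sorted(missing)}")
        if self.values.isna().any().any():
            raise ValueError("climate table contains nodata values")

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def variables_in_group(self, group: str) -> list[str]:
        return [v for v in self.values.columns if self.groups[v] == group]

    def subset(self, variables) -> "ClimateTable":
        return ClimateTable(values=self.values[list(variables)].copy(),
                            groups={v: self.groups[v] for v in variables})

    def to_csv(self, path) -> None:
        self.values.rename_axis("sample_id").to_csv(path)


def extract_at_points(grids: dict, samples: pd.DataFrame) -> ClimateTable:
    """Extract every grid's containing-cell value at each sample point.

    Raises ``ValueError`` listing offending samples if any point falls outside
    a grid extent or in a nodata cell.
    """
    cols = {}
    problems = []
    for name, grid in grids.items():
        vals = np.empty(len(samples))
        for i, row in enumerate(samples.itertuples()):
            try:
                v = grid.value_at(row.lon, row.lat)
            except ValueError:
                problems.append(f"{row.sample_id} outside {name}")
                v = np.nan
            else:
                if np.isnan(v):
                    problems.append(f"{row.sample_id} in nodata cell of {name}")
            vals[i] = v
        cols[name] = vals
    if problems:
        raise ValueError("climate extraction failed: " + "; ".join(problems[:10]))
    values = pd.DataFrame(cols, index=pd.Index(samples["sample_id"], name="sample_id"))
    groups = {name: grid.group for name, grid in grids.items()}
    return ClimateTable(values=values, groups=groups)


def spearman_prune(table: ClimateTable, group: str, threshold: float = 0.8):
    """Deterministically prune collinear variables within one group.

    While any retained pair has |Spearman rho| >= threshold, drop the variable
    with the largest mean absolute within-group correlation (ties: drop the
    variable later in input order).  Returns the retained names in input order.
    """
    names = table.variables_in_group(group)
    if not names:
        raise ValueError(f"no variables in group {group!r}")
    if len(table.values) < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    if len(names) == 1:
        return list(names)
    data = table.values[names].to_numpy()
    rho = stats.spearmanr(data).statistic
    rho = np.atleast_2d(rho) if np.ndim(rho) == 0 else rho
    if len(names) == 2:  # spearmanr returns a scalar for two columns
        r = float(stats.spearmanr(data[:, 0], data[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    keep = list(range(len(names)))
    while True:
        sub = np.abs(rho[np.ix_(keep, keep)])
        np.fill_diagonal(sub, 0.0)
        if sub.size == 0 or sub.max() < threshold:
            break
        mean_abs = sub.mean(axis=1)
        # ties broken toward the later variable in input order
        worst = int(np.flatnonzero(mean_abs == mean_abs.max())[-1])
        keep.pop(worst)
    return [names[i] for i in keep]


def population_means(table: ClimateTable, samples: pd.DataFrame):
    """Arithmetic per-population means of predictors and centroid coordinates.

    Returns (pop x variable DataFrame, pop x (lon, lat) DataFrame), with
    populations in order of first appearance in ``samples``.
    """
    pops = list(dict.fromkeys(samples["population"]))
    counts = samples.groupby("population").size()
    if (counts == 0).any():
        raise ValueError("empty population")
    vals = table.values.loc[samples["sample_id"]].to_numpy()
    df = pd.DataFrame(vals, index=samples["population"].to_numpy(),
                      columns=table.variables)
    means = df.groupby(level=0).mean().loc[pops]
    coords = (samples.set_index("population")[["lon", "lat"]]
              .groupby(level=0).mean().loc[pops])
    means.index.name = coords.index.name = "population"
    return means, coords
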