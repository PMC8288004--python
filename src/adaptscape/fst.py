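"""Weir-Cockerham theta (FST): variance components, pairwise matrices,
and unit-interval scaling of the pairwise matrix for dissimilarity modelling.

The estimator is the classic variance-components theta: per locus, the
among-population (a), among-individual-within-population (b) and
within-individual (c) components are formed from sample-size-weighted allele
frequencies and observed heterozygosities, and the multilocus estimate is
ratio-of-sums theta = sum(a) / sum(a+b+c).  Loci monomorphic across the
involved populations contribute zero components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = ["FstMatrix", "wc_theta", "wc_components", "pairwise_matrix",
           "scale_unit"]


@dataclass
class FstMatrix:
    theta: pd.DataFrame = field(repr=False)  # populations x populations
    global_theta: float = np.nan
    scaled: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def populations(self) -> list[str]:
        return list(self.theta.index)

    def to_csv(self, path) -> None:
        self.theta.to_csv(path)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"populations": self.populations,
                       "theta": self.theta.to_numpy().tolist(),
                       "global_theta": self.global_theta,
                       "scaled": None if self.scaled is None
                       else self.scaled.to_numpy().tolist()}, fh)


def _pop_summaries(g: GenotypeMatrix, pops: list[str]):
    """Per population x locus: sample sizes (called individuals), alternate
    allele frequencies and observed heterozygote frequencies."""
    pop_arr = g.samples["population"].to_numpy()
    r = len(pops)
    L = g.n_loci
    n = np.zeros((r, L))
    p = np.zeros((r, L))
    h = np.zeros((r, L))
    for i, pop in enumerate(pops):
        block = g.counts[pop_arr == pop, :]
        if block.shape[0] == 0:
            raise ValueError(f"population {pop!r} has no individuals")
        called = block != MISSING
        ni = called.sum(axis=0)
        n[i] = ni
        with np.errstate(divide="ignore", invalid="ignore"):
            p[i] = np.where(ni > 0, np.where(called, block, 0).sum(axis=0) / (2 * ni), 0.0)
            h[i] = np.where(ni > 0, np.where(called, block == 1, False).sum(axis=0) / ni, 0.0)
    if (n.sum(axis=1) == 0).any():
        bad = [pops[i] for i in np.flatnonzero(n.sum(axis=1) == 0)]
        raise ValueError(f"population(s) with no data at every locus: {bad}")
    return n, p, h


def wc_components(g: GenotypeMatrix, pops: list[str] | None = None):
    """Per-locus variance components (a, b, c) over the given populations.

    Loci with fewer than 2 populations carrying data, or monomorphic across
    the involved populations, get zero components.
    """
    pops = pops if pops is not None else g.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    n, p, h = _pop_summaries(g, pops)
    has = n > 0
    r_eff = has.sum(axis=0).astype(float)          # populations with data
    usable = r_eff >= 2

    nsum = n.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = nsum / r_eff
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r_eff - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar[None, :])**2).sum(axis=0) / ((r_eff - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum

        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r_eff - 1) / r_eff * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                   - (r_eff - 1) / r_eff * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2

    mono = (pbar <= 0) | (pbar >= 1)
    bad = ~usable | mono | ~np.isfinite(a) | ~np.isfinite(b) | ~np.isfinite(c)
    for arr in (a, b, c):
        arr[bad] = 0.0
    return a, b, c


def wc_theta(g: GenotypeMatrix, locus_ids=None, pops=None) -> float:
    """Multilocus theta = sum(a) / sum(a+b+c) over the locus subset."""
    if locus_ids is not None:
        g = g.loci_by_ids(locus_ids)
    a, b, c = wc_components(g, pops=list(pops) if pops is not None else None)
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError("no polymorphic loci among the involved populations")
    return float(a.sum() / denom)


def pairwise_matrix(g: GenotypeMatrix, locus_ids=None) -> FstMatrix:
    """Multilocus theta for every population pair plus the global estimate."""
    if locus_ids is not None:
        g = g.loci_by_ids(locus_ids)
    pops = g.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    mat = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            th = wc_theta(g, pops=[pops[i], pops[j]])
            mat[i, j] = mat[j, i] = th
    theta = pd.DataFrame(mat, index=pops, columns=pops)
    return FstMatrix(theta=theta, global_theta=wc_theta(g))


def scale_unit(fst: FstMatrix, method: str = "minmax") -> FstMatrix:
    """Scale off-diagonal theta into [0, 1]; the diagonal stays 0.

    ``minmax`` (default) maps (x - min)/(max - min); ``maxdiv`` divides by
    the maximum (clamping negatives to 0).
    """
    mat = fst.theta.to_numpy().astype(float)
    off = mat[~np.eye(len(mat), dtype=bool)]
    if np.unique(off).size < 2:
        raise ValueError("all off-diagonal values equal; scaling degenerate")
    if method == "minmax":
        scaled = (mat - off.min()) / (off.max() - off.min())
    elif method == "maxdiv":
        if off.max() <= 0:
            raise ValueError("non-positive maximum; cannot divide")
        scaled = np.clip(mat / off.max(), 0.0, 1.0)
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    np.fill_diagonal(scaled, 0.0)
    fst.scaled = pd.DataFrame(scaled, index=fst.theta.index,
                              columns=fst.theta.columns)
    return fst
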