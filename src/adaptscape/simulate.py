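"""Synthetic paired host/parasite landscape-genomic data with known truth.

The generator emulates a two-species comparative design: 10-11 populations of
10-16 individuals per species sampled across a shared landscape, thousands of
neutral biallelic SNPs with hierarchical population structure (stronger
differentiation in the parasite), and a handful of adaptive loci whose
population allele frequencies follow monotone logistic clines in a designated
climate variable -- temperature-driven for the parasite, precipitation-driven
for the host.  Reduced-representation artefacts (missing calls, multiple SNPs
per sequenced fragment, per-locus technical reproducibility scores) are
layered on top so the quality-control stage has something real to do.

Neutral structure follows the Balding-Nichols model: population allele
frequencies are Beta-distributed around a shared ancestral frequency with
variance p(1-p)*F, so the differentiation parameter F is directly comparable
to a multilocus Weir-Cockerham theta estimate.

All randomness flows from a single integer seed; each stage draws from a
generator sub-seeded with a fixed offset so stages are independently
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.special import expit

from .grids import ClimateGrid

__all__ = [
    "VariableSpec",
    "SimConfig",
    "SimTruth",
    "make_climate_grid",
    "sample_sites",
    "simulate_genotypes",
    "simulate_pair",
    "default_variable_specs",
    "default_landscape",
    "default_pair_configs",
]

# Fixed sub-seed offsets, one per stage (single global seed, derived streams).
_OFF_GRID = 11
_OFF_SITES = 23
_OFF_GENO = 37
_OFF_PAIR = 53


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(offset)])


# --------------------------------------------------------------------------- types
@dataclass
class VariableSpec:
    """One synthetic climate variable: a planar gradient plus smooth noise.

    ``direction_deg`` is the compass-free angle of the gradient in the
    lon/lat plane (0 = increases west->east, 90 = increases south->north).
    ``amplitude`` is the value range contributed by the gradient (variable
    units); ``noise_amp`` the standard deviation of the added smooth noise.
    """

    name: str
    group: str  # "temperature" | "precipitation"
    direction_deg: float = 0.0
    base: float = 0.0
    amplitude: float = 1.0
    noise_amp: float = 0.0
    smooth_cells: float = 3.0


@dataclass
class SimConfig:
    """Per-species simulation settings.

    ``fst_target`` is the Balding-Nichols F (expected multilocus theta);
    ``effect_beta`` the logistic slope per standardized climate unit shared by
    the planted adaptive loci; ``driver_map`` assigns each adaptive locus
    index (0..n_adaptive-1) to the climate variable that drives it.
    """

    n_pops: int = 10
    n_ind_per_pop: tuple[int, int] = (10, 16)
    n_neutral: int = 2000
    n_adaptive: int = 10
    driver_map: dict[int, str] = field(default_factory=dict)
    effect_beta: float = 3.0
    fst_target: float = 0.1
    region_frac: float = 0.5
    region_axis: str = "ns"
    region2_frac: float = 0.0
    spatial_frac: float = 0.9
    spatial_range_frac: float = 0.7
    missing_rate: float = 0.012
    snps_per_fragment: dict[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.35, 3: 0.25})
    repro_score_range: tuple[float, float] = (0.985, 1.0)
    low_repro_frac: float = 0.02
    low_repro_range: tuple[float, float] = (0.90, 0.98)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fst_target < 1):
            raise ValueError("fst_target must be in [0, 1)")
        if not (0 <= self.missing_rate <= 0.5):
            raise ValueError("missing_rate must be in [0, 0.5]")
        if self.n_adaptive > self.n_neutral:
            raise ValueError("n_adaptive must not exceed n_neutral")
        bad = set(self.driver_map) - set(range(self.n_adaptive))
        if bad:
            raise ValueError(f"driver_map keys outside adaptive range: {sorted(bad)}")


@dataclass
class SimTruth:
    """Ground truth for recovery tests."""

    adaptive_ids: list[str]
    drivers: dict[str, str]  # adaptive locus id -> climate variable name
    pop_freqs: pd.DataFrame  # populations x loci, allele frequencies in [0,1]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "adaptive_ids": self.adaptive_ids,
                "drivers": self.drivers,
                "populations": list(self.pop_freqs.index),
                "loci": list(self.pop_freqs.columns),
                "pop_freqs": self.pop_freqs.to_numpy().tolist(),
            }, fh)


# --------------------------------------------------------------------- climate
def make_climate_grid(extent, cell_size, variable_specs, seed=0):
    """Generate one :class:`ClimateGrid` per variable spec.

    extent : (lon_min, lat_min, lon_max, lat_max), positive span.
    Each grid is a deterministic planar gradient in the spec's direction plus
    seeded smooth (Gaussian-filtered white) noise.  Same seed, same grids.
    """
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    specs = list(variable_specs)
    if not specs:
        raise ValueError("variable list is empty")
    lon_min, lat_min, lon_max, lat_max = extent
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError("extent must have positive span")
    nx = max(1, int(round((lon_max - lon_min) / cell_size)))
    ny = max(1, int(round((lat_max - lat_min) / cell_size)))
    # unit-range coordinates of cell centres
    u = (np.arange(nx) + 0.5) / nx - 0.5
    v = (np.arange(ny) + 0.5) / ny - 0.5
    uu, vv = np.meshgrid(u, v)
    grids = {}
    for k, spec in enumerate(specs):
        theta = np.deg2rad(spec.direction_deg)
        grad = np.cos(theta) * uu + np.sin(theta) * vv
        gsd = grad.std()
        if gsd > 0:
            grad = grad / gsd  # unit-sd gradient so amplitude is comparable
        vals = spec.base + spec.amplitude * grad
        if spec.noise_amp > 0:
            rng = _rng(seed, _OFF_GRID + k)
            white = rng.standard_normal((ny, nx))
            smooth = ndimage.gaussian_filter(white, sigma=spec.smooth_cells)
            ssd = smooth.std()
            if ssd > 0:
                smooth = smooth / ssd
            vals = vals + spec.noise_amp * smooth
        grids[spec.name] = ClimateGrid(name=spec.name, group=spec.group,
                                       lon0=lon_min, lat0=lat_min,
                                       cell=cell_size, values=vals)
    return grids


# ----------------------------------------------------------------------- sites
def sample_sites(grids, n_pops, n_ind_per_pop, seed=0, jitter=0.03):
    """Place population centroids by seeded max-min dispersion, jitter individuals.

    Centroids are chosen greedily from the grid's cell centres: start from a
    random cell and repeatedly add the cell farthest (in its nearest-chosen
    distance) from the current set -- a deterministic farthest-point rule given
    the seed.  Individuals are uniformly jittered around their centroid and
    clipped strictly inside the grid extent.

    Returns a DataFrame with columns ``sample_id, population, lon, lat``.
    """
    if n_pops < 2:
        raise ValueError("need at least 2 populations")
    grid = next(iter(grids.values())) if isinstance(grids, dict) else grids
    lons, lats = np.meshgrid(grid.lon_centers, grid.lat_centers)
    cand = np.column_stack([lons.ravel(), lats.ravel()])
    if n_pops > len(cand):
        raise ValueError(f"n_pops={n_pops} exceeds available cells ({len(cand)})")
    rng = _rng(seed, _OFF_SITES)
    first = rng.integers(len(cand))
    chosen = [first]
    d2 = np.sum((cand - cand[first]) ** 2, axis=1)
    for _ in range(n_pops - 1):
        nxt = int(np.argmax(d2))
        chosen.append(nxt)
        d2 = np.minimum(d2, np.sum((cand - cand[nxt]) ** 2, axis=1))
    centroids = cand[chosen]

    lo, hi = (n_ind_per_pop, n_ind_per_pop) if np.isscalar(n_ind_per_pop) else n_ind_per_pop
    lon_min, lat_min, lon_max, lat_max = grid.extent
    eps = 1e-9
    rows = []
    for p, (cx, cy) in enumerate(centroids):
        pop = f"P{p + 1:02d}"
        n_ind = int(rng.integers(lo, hi + 1))
        for i in range(n_ind):
            x = cx + rng.uniform(-jitter, jitter)
            y = cy + rng.uniform(-jitter, jitter)
            x = min(max(x, lon_min), lon_max - eps)
            y = min(max(y, lat_min), lat_max - eps)
            rows.append((f"{pop}_{i + 1:02d}", pop, x, y))
    return pd.DataFrame(rows, columns=["sample_id", "population", "lon", "lat"])


# ------------------------------------------------------------------- genotypes
def _population_driver_z(samples: pd.DataFrame, climate_table: pd.DataFrame,
                         variable: str) -> pd.Series:
    """Standardized population means of one climate variable."""
    vals = climate_table.loc[samples["sample_id"], variable].to_numpy()
    means = pd.Series(vals, index=samples["population"].to_numpy()).groupby(level=0).mean()
    sd = means.std(ddof=0)
    if sd == 0:
        raise ValueError(f"driver variable {variable!r} constant across populations")
    return (means - means.mean()) / sd


def simulate_genotypes(samples: pd.DataFrame, climate_table: pd.DataFrame,
                       config: SimConfig):
    """Draw genotypes for one species; returns (GenotypeMatrix, SimTruth).

    Neutral structure is a hierarchical, spatially correlated Balding-Nichols
    model: per locus, population deviations come from a Gaussian copula whose
    correlation composes a north/south region block of weight ``region_frac``,
    an optional secondary east/west block of weight ``region2_frac`` (nested
    bioregion-style structure), an exponential isolation-by-distance term and
    an independent nugget sharing the remaining weight; deviations
    are mapped through the Balding-Nichols Beta quantile function around the
    ancestral frequency p_j ~ U(0.1, 0.9), so marginal between-population
    variance is p(1-p)*F exactly.  The marginal F is inflated analytically so
    the expected multilocus Weir-Cockerham theta equals ``fst_target``
    despite the positive between-population covariance.  The result mirrors
    real reduced-representation data: a dominant north/south axis, decaying
    spatial structure, and a scree elbow at a small K.  Adaptive locus
    with driver v: population frequency expit(beta * z_v(pop)) with z_v the
    standardized population-mean of v.  Genotypes Binomial(2, freq); missing
    entries masked at ``missing_rate``; loci grouped into fragments; technical
    reproducibility scores drawn from ``repro_score_range`` with a small
    fraction below the QC threshold.
    """
    from .genotypes import GenotypeMatrix  # local import; avoids a cycle

    missing_sam = set(samples["sample_id"]) - set(climate_table.index)
    if missing_sam:
        raise ValueError(f"samples without climate values: {sorted(missing_sam)[:5]}")

    rng = _rng(config.seed, _OFF_GENO)
    pops = list(dict.fromkeys(samples["population"]))
    n_pops = len(pops)
    pop_idx = np.array([pops.index(p) for p in samples["population"]])
    n_ind = len(samples)
    n_loci = config.n_neutral + config.n_adaptive

    # neutral population allele frequencies: hierarchical spatial BN copula
    cent = samples.groupby("population")[["lon", "lat"]].mean().loc[pops].to_numpy()
    dist = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=-1)
    diag = dist.max() if dist.max() > 0 else 1.0
    axis = 1 if config.region_axis == "ns" else 0
    region_ns = (cent[:, axis] >= np.median(cent[:, axis])).astype(int)
    region_ew = (cent[:, 1 - axis] >= np.median(cent[:, 1 - axis])).astype(int)
    h1 = float(np.clip(config.region_frac, 0.0, 1.0))
    h2 = float(np.clip(config.region2_frac, 0.0, 1.0 - h1))
    s_frac = float(np.clip(config.spatial_frac, 0.0, 1.0))
    rho = max(config.spatial_range_frac * diag, 1e-9)
    block_ns = (region_ns[:, None] == region_ns[None, :]).astype(float)
    block_ew = (region_ew[:, None] == region_ew[None, :]).astype(float)
    rest = 1.0 - h1 - h2
    corr = h1 * block_ns + h2 * block_ew \
        + rest * (s_frac * np.exp(-dist / rho) + (1 - s_frac) * np.eye(n_pops))
    np.fill_diagonal(corr, 1.0)
    # positive covariance attenuates the Weir-Cockerham estimate:
    # theta_hat ~= F(1 - c)/(1 - cF) with c the mean off-diagonal correlation
    # of the transformed frequencies (the Beta quantile map shrinks Gaussian
    # correlations by ~5%); solve for the marginal F so expected theta equals
    # fst_target
    c = 0.95 * float(corr[~np.eye(n_pops, dtype=bool)].mean())
    t = config.fst_target
    F = min(t / max(1.0 - c + c * t, 1e-6), 0.95)
    p_anc = rng.uniform(0.1, 0.9, size=config.n_neutral)
    if F > 1e-12:
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n_pops))
        zmat = chol @ rng.standard_normal((n_pops, config.n_neutral))
        umat = stats.norm.cdf(zmat)
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        freq_neutral = stats.beta.ppf(umat, a[None, :], b[None, :])
    else:
        freq_neutral = np.broadcast_to(p_anc, (n_pops, config.n_neutral)).copy()

    freq_adaptive = np.empty((n_pops, config.n_adaptive))
    drivers_by_idx = {}
    default_driver = None
    if config.n_adaptive > 0:
        if config.driver_map:
            default_driver = next(iter(config.driver_map.values()))
        else:
            raise ValueError("driver_map required when n_adaptive > 0")
    z_cache: dict[str, np.ndarray] = {}
    for k in range(config.n_adaptive):
        var = config.driver_map.get(k, default_driver)
        drivers_by_idx[k] = var
        if var not in z_cache:
            z = _population_driver_z(samples, climate_table, var)
            z_cache[var] = np.array([z[p] for p in pops])
        freq_adaptive[:, k] = expit(config.effect_beta * z_cache[var])

    # interleave: place adaptive loci at seeded random positions
    order = rng.permutation(n_loci)
    adaptive_slots = np.sort(order[:config.n_adaptive])
    freqs = np.empty((n_pops, n_loci))
    is_adaptive = np.zeros(n_loci, dtype=bool)
    is_adaptive[adaptive_slots] = True
    freqs[:, is_adaptive] = freq_adaptive
    freqs[:, ~is_adaptive] = freq_neutral

    counts = rng.binomial(2, freqs[pop_idx, :]).astype(np.int16)
    if config.missing_rate > 0:
        miss = rng.random((n_ind, n_loci)) < config.missing_rate
        counts[miss] = -1

    # fragments: consecutive blocks with sizes from the configured distribution
    sizes_keys = np.array(sorted(config.snps_per_fragment))
    sizes_p = np.array([config.snps_per_fragment[k] for k in sizes_keys], dtype=float)
    sizes_p = sizes_p / sizes_p.sum()
    frag_ids = np.empty(n_loci, dtype=object)
    pos = 0
    frag = 0
    while pos < n_loci:
        size = int(rng.choice(sizes_keys, p=sizes_p))
        frag += 1
        for j in range(pos, min(pos + size, n_loci)):
            frag_ids[j] = f"F{frag:05d}"
        pos += size

    repro = rng.uniform(*config.repro_score_range, size=n_loci)
    n_low = int(round(config.low_repro_frac * n_loci))
    if n_low > 0:
        low_idx = rng.choice(n_loci, size=n_low, replace=False)
        repro[low_idx] = rng.uniform(*config.low_repro_range, size=n_low)

    locus_ids = [f"L{j + 1:06d}" for j in range(n_loci)]
    loci = pd.DataFrame({"locus_id": locus_ids, "fragment_id": frag_ids,
                         "reproducibility": repro})
    g = GenotypeMatrix(counts=counts, samples=samples.reset_index(drop=True),
                       loci=loci)
    adaptive_ids = [locus_ids[j] for j in adaptive_slots]
    truth = SimTruth(
        adaptive_ids=adaptive_ids,
        drivers={locus_ids[j]: drivers_by_idx[k]
                 for k, j in enumerate(adaptive_slots)},
        pop_freqs=pd.DataFrame(freqs, index=pops, columns=locus_ids),
    )
    return g, truth


# ----------------------------------------------------------------------- pair
def default_variable_specs():
    """Seven variables mirroring a pruned bioclim set: 4 temperature, 3 precipitation.

    Gradient angles put the temperature and precipitation axes ~90 degrees
    apart so the two groups are statistically distinguishable; within-group
    angles and noise keep pairwise |Spearman rho| below the 0.8 pruning
    threshold.
    """
    return [
        VariableSpec("isothermality", "temperature", 10, 52.0, 6.0, 4.8),
        VariableSpec("temp_seasonality", "temperature", 25, 560.0, 90.0, 72.0),
        VariableSpec("temp_wettest_q", "temperature", 40, 13.0, 4.0, 3.2),
        VariableSpec("temp_driest_q", "temperature", 55, 24.0, 5.0, 4.0),
        VariableSpec("annual_precip", "precipitation", 115, 330.0, 120.0, 96.0),
        VariableSpec("precip_seasonality", "precipitation", 130, 45.0, 15.0, 12.0),
        VariableSpec("precip_warmest_q", "precipitation", 145, 40.0, 20.0, 16.0),
    ]


DEFAULT_EXTENT = (116.0, -32.0, 119.0, -27.5)  # ~300 km E-W x 500 km N-S
DEFAULT_CELL = 0.05


def default_landscape(seed=0, extent=DEFAULT_EXTENT, cell=DEFAULT_CELL):
    return make_climate_grid(extent, cell, default_variable_specs(), seed=seed)


def default_pair_configs(seed=0, n_pops=10, n_ind=(15, 15), n_neutral=2000,
                         n_adaptive=10, beta=3.0, host_f=0.08, parasite_f=0.3,
                         missing_rate=0.012):
    """Study-condition defaults: parasite temperature-driven and more
    differentiated (F=0.3, strong north/south hierarchy) than the
    precipitation-driven host (F=0.08, mild hierarchy)."""
    host = SimConfig(n_pops=n_pops, n_ind_per_pop=n_ind, n_neutral=n_neutral,
                     n_adaptive=n_adaptive,
                     driver_map={k: "annual_precip" for k in range(n_adaptive)},
                     effect_beta=beta, fst_target=host_f, region_frac=0.25,
                     region_axis="ew", missing_rate=missing_rate, seed=seed)
    parasite = SimConfig(n_pops=n_pops, n_ind_per_pop=n_ind, n_neutral=n_neutral,
                         n_adaptive=n_adaptive,
                         driver_map={k: "temp_seasonality" for k in range(n_adaptive)},
                         effect_beta=beta, fst_target=parasite_f,
                         region_frac=0.8,
                         missing_rate=missing_rate, seed=seed + 1)
    return host, parasite


def simulate_pair(host_config: SimConfig, parasite_config: SimConfig,
                  shared_seed: int = 0, grids=None):
    """Simulate the two species on one landscape with shared coordinates.

    Host and parasite individuals are sampled together (a parasite grows on a
    sampled host plant), so sample coordinates are shared up to the species
    with more populations/individuals.  Population counts may differ by one.

    Returns ``(host_bundle, parasite_bundle)`` dicts with keys
    ``genotypes, truth, samples, climate, grids, config``.
    """
    from .climate import extract_at_points

    if grids is None:
        grids = default_landscape(seed=shared_seed)
    if abs(host_config.n_pops - parasite_config.n_pops) > 1:
        raise ValueError("species population counts may differ by at most 1")

    n_pops_max = max(host_config.n_pops, parasite_config.n_pops)
    hi_ind = max(host_config.n_ind_per_pop[1], parasite_config.n_ind_per_pop[1])
    base = sample_sites(grids, n_pops_max, (hi_ind, hi_ind), seed=shared_seed)

    bundles = []
    for config in (host_config, parasite_config):
        rng = _rng(shared_seed, _OFF_PAIR + config.seed % 7919)
        pops = [f"P{p + 1:02d}" for p in range(config.n_pops)]
        rows = []
        for pop in pops:
            block = base[base["population"] == pop]
            lo, hi = config.n_ind_per_pop
            n_ind = int(rng.integers(lo, hi + 1))
            rows.append(block.iloc[:n_ind])
        samples = pd.concat(rows, ignore_index=True)
        table = extract_at_points(grids, samples)
        g, truth = simulate_genotypes(samples, table.values, config)
        bundles.append({"genotypes": g, "truth": truth, "samples": samples,
                        "climate": table, "grids": grids, "config": config})
    return bundles[0], bundles[1]
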