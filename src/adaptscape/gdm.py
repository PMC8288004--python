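"""Generalized dissimilarity modelling (GDM).

GDM regresses pairwise compositional dissimilarity d in [0, 1] on monotone
I-spline transforms of site predictors through the negative-exponential link
d-hat = 1 - exp(-eta), with

    eta_ij = a0 + sum_p sum_k beta_pk |I_pk(x_pi) - I_pk(x_pj)|

for climate predictors (geographic distance enters through I-splines of the
pairwise great-circle distance itself).  Non-negative coefficients with
monotone basis functions guarantee monotone fitted turnover.  Fitting
minimizes the binomial-type deviance by iteratively reweighted non-negative
least squares.  Predictor significance is assessed by site-level permutation;
backward elimination drops non-significant predictors smallest-importance
first.  Deviance partitioning decomposes the explained deviance into unique
and joint contributions of predictor groups (geography, temperature,
precipitation) by inclusion-exclusion over all group subsets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from itertools import combinations
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

__all__ = ["ISplineBasis", "SitePairTable", "GDMModel", "haversine_km",
           "build_pair_table", "ispline_basis", "fit_gdm",
           "backward_eliminate", "importance", "partition_deviance"]

GEO = "geographic"  # reserved predictor name for pairwise distance

_EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance in km between WGS84 lon/lat points."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


# ------------------------------------------------------------------ I-splines
@dataclass
class ISplineBasis:
    """Three order-2 monotone I-spline basis functions for one predictor.

    Knots sit at the 0th/50th/100th percentiles of the observed site values.
    Each basis function is nondecreasing, 0 at the predictor minimum and 1 at
    the maximum; evaluation clamps x outside [min, max] to {0, 1}.
    """

    knots: tuple[float, float, float]

    def __post_init__(self) -> None:
        t1, t2, t3 = self.knots
        if not (t1 < t3):
            raise ValueError("need at least 3 distinct site values")
        if not (t1 < t2 < t3):
            t2 = 0.5 * (t1 + t3)
            logger.info("median knot coincides with an extreme; recentred to %g", t2)
            self.knots = (t1, t2, t3)

    @property
    def n_splines(self) -> int:
        return 3

    def evaluate(self, x) -> np.ndarray:
        """Basis values at x; shape ``x.shape + (3,)``."""
        t1, t2, t3 = self.knots
        x = np.clip(np.asarray(x, dtype=float), t1, t3)
        lo = x <= t2
        b = np.empty(x.shape + (3,))
        # I1: integral of the M-spline on (t1, t1, t2)
        b[..., 0] = np.where(lo, 1.0 - ((t2 - x) / (t2 - t1)) ** 2, 1.0)
        # I2: integral of the tent M-spline on (t1, t2, t3)
        b[..., 1] = np.where(
            lo,
            (x - t1) ** 2 / ((t3 - t1) * (t2 - t1)),
            1.0 - (t3 - x) ** 2 / ((t3 - t1) * (t3 - t2)),
        )
        # I3: integral of the M-spline on (t2, t3, t3)
        b[..., 2] = np.where(lo, 0.0, ((x - t2) / (t3 - t2)) ** 2)
        return b


def ispline_basis(x_values, n_splines: int = 3) -> ISplineBasis:
    """Basis for one predictor from its observed site values."""
    if n_splines != 3:
        raise ValueError("only the three-spline basis is implemented")
    x = np.asarray(x_values, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct site values")
    t1, t2, t3 = np.percentile(x, [0, 50, 100])
    return ISplineBasis(knots=(float(t1), float(t2), float(t3)))


# ------------------------------------------------------------------ pair table
@dataclass
class SitePairTable:
    """Site-pair data: response dissimilarity, per-predictor site values,
    pairwise geographic distance (km) and site coordinates."""

    pairs: pd.DataFrame = field(repr=False)  # site_i, site_j, d, distance_km
    site_values: pd.DataFrame = field(repr=False)  # site x predictor
    coords: pd.DataFrame = field(repr=False)  # site x (lon, lat)

    @property
    def predictors(self) -> list[str]:
        return list(self.site_values.columns)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def build_pair_table(scaled_fst: pd.DataFrame, pop_predictors: pd.DataFrame,
                     pop_coords: pd.DataFrame) -> SitePairTable:
    """One row per unordered population pair, with great-circle distances.

    ``scaled_fst`` is the unit-scaled symmetric dissimilarity matrix
    (labels must match the predictor and coordinate tables).
    """
    labels = list(scaled_fst.index)
    if list(pop_predictors.index) != labels or list(pop_coords.index) != labels:
        raise ValueError("population labels of FST matrix, predictors and "
                         "coordinates must match")
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        a, b = labels[i], labels[j]
        dist = haversine_km(pop_coords.loc[a, "lon"], pop_coords.loc[a, "lat"],
                            pop_coords.loc[b, "lon"], pop_coords.loc[b, "lat"])
        rows.append((a, b, float(scaled_fst.loc[a, b]), dist))
    pairs = pd.DataFrame(rows, columns=["site_i", "site_j", "d", "distance_km"])
    return SitePairTable(pairs=pairs, site_values=pop_predictors.copy(),
                         coords=pop_coords.copy())


# ----------------------------------------------------------------------- model
@dataclass
class GDMModel:
    intercept: float
    coefs: dict[str, np.ndarray]          # predictor -> 3 nonneg coefficients
    basis: dict[str, ISplineBasis]
    deviance_model: float
    deviance_null: float
    pct_explained: float
    predictors: list[str]
    p_values: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def linear_predictor(self, pair_table: SitePairTable) -> np.ndarray:
        X = _design(pair_table, self.predictors, self.basis)
        beta = np.concatenate([self.coefs[p] for p in self.predictors]) \
            if self.predictors else np.empty(0)
        return self.intercept + (X @ beta if X.size else 0.0)

    def predict(self, pair_table: SitePairTable) -> np.ndarray:
        return 1.0 - np.exp(-self.linear_predictor(pair_table))

    def spline_curve(self, predictor: str, n: int = 200):
        """Sampled turnover function (x, f_p(x)) for plotting."""
        t1, _, t3 = self.basis[predictor].knots
        x = np.linspace(t1, t3, n)
        f = self.basis[predictor].evaluate(x) @ self.coefs[predictor]
        return x, f


def _design(pair_table: SitePairTable, predictors: list[str],
            basis: dict[str, ISplineBasis]) -> np.ndarray:
    """Pair design matrix: per predictor the 3 |I(x_i) - I(x_j)| columns
    (I-splines of the distance itself for the geographic predictor)."""
    cols = []
    pairs = pair_table.pairs
    for p in predictors:
        if p == GEO:
            cols.append(basis[p].evaluate(pairs["distance_km"].to_numpy()))
        else:
            xi = pair_table.site_values.loc[pairs["site_i"], p].to_numpy()
            xj = pair_table.site_values.loc[pairs["site_j"], p].to_numpy()
            cols.append(np.abs(basis[p].evaluate(xi) - basis[p].evaluate(xj)))
    if not cols:
        return np.empty((len(pairs), 0))
    return np.concatenate(cols, axis=1)


def _build_bases(pair_table: SitePairTable, predictors: list[str]):
    basis = {}
    for p in predictors:
        if p == GEO:
            basis[p] = ispline_basis(pair_table.pairs["distance_km"].to_numpy())
        else:
            basis[p] = ispline_basis(pair_table.site_values[p].to_numpy())
    return basis


_MU_EPS = 1e-9


def _deviance(d: np.ndarray, mu: np.ndarray) -> float:
    """Binomial-type deviance with limit terms for d in {0, 1}."""
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(d > 0, d * np.log(d / mu), 0.0)
        t2 = np.where(d < 1, (1 - d) * np.log((1 - d) / (1 - mu)), 0.0)
    return float(2.0 * (t1 + t2).sum())


def _irls_nnls(A: np.ndarray, d: np.ndarray, tol: float = 1e-6,
               max_iter: int = 100):
    """Nonnegative IRLS for the 1-exp(-eta) link / binomial deviance.

    A includes the intercept column; all coefficients constrained >= 0.
    Returns (coefficients, deviance, converged).
    """
    d = np.asarray(d, dtype=float)
    mu = np.clip(d, 0.05, 0.95)
    eta = -np.log1p(-mu)
    dev = _deviance(d, mu)
    best = (None, np.inf)
    converged = False
    for _ in range(max_iter):
        one_mu = np.clip(1.0 - mu, _MU_EPS, None)
        w = one_mu / np.clip(mu, _MU_EPS, None)       # (dmu/deta)^2 / V(mu)
        zwork = eta + (d - mu) / one_mu
        sw = np.sqrt(w)
        beta, _ = nnls(A * sw[:, None], zwork * sw)
        eta = A @ beta
        mu = 1.0 - np.exp(-eta)
        new_dev = _deviance(d, mu)
        if new_dev < best[1]:
            best = (beta, new_dev)
        if abs(new_dev - dev) < tol * max(1.0, abs(dev)):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    beta, dev = best if best[0] is not None else (beta, dev)
    if not converged and abs(dev - best[1]) < 1e-3 * max(best[1], 1e-9):
        converged = True  # oscillation within tolerance of the best iterate
    return beta, dev, converged


def fit_gdm(pair_table: SitePairTable, predictors: list[str] | None = None,
            basis: dict[str, ISplineBasis] | None = None) -> GDMModel:
    """Fit a GDM by nonnegative IRLS; percent explained is relative to the
    intercept-only null deviance."""
    predictors = list(predictors) if predictors is not None \
        else [GEO] + pair_table.predictors
    if basis is None:
        basis = _build_bases(pair_table, predictors)
    d = pair_table.pairs["d"].to_numpy()
    n_pairs = len(d)
    if predictors and n_pairs < 3 * len(predictors) + 1:
        warnings.warn(f"{n_pairs} pairs for {len(predictors)} predictors: "
                      "fit may be unstable")
    X = _design(pair_table, predictors, basis)
    A = np.column_stack([np.ones(n_pairs), X])
    beta, dev, conv = _irls_nnls(A, d)
    beta0, dev0, _ = _irls_nnls(np.ones((n_pairs, 1)), d)
    if not conv:
        warnings.warn("GDM IRLS did not converge; best-deviance iterate kept")
    coefs = {p: beta[1 + 3 * k: 4 + 3 * k] for k, p in enumerate(predictors)}
    pct = 100.0 * (1.0 - dev / dev0) if dev0 > 0 else 0.0
    return GDMModel(intercept=float(beta[0]), coefs=coefs, basis=basis,
                    deviance_model=dev, deviance_null=dev0,
                    pct_explained=float(pct), predictors=predictors,
                    converged=conv)


# ----------------------------------------------------------- permutation tests
def _permute_predictor(pair_table: SitePairTable, predictor: str,
                       rng: np.random.Generator) -> SitePairTable:
    """Permute one predictor's site values (site coordinates for geography)
    across sites and rebuild the pair table rows that depend on it."""
    if predictor == GEO:
        perm = rng.permutation(len(pair_table.coords))
        coords = pair_table.coords.copy()
        coords[["lon", "lat"]] = coords[["lon", "lat"]].to_numpy()[perm]
        pairs = pair_table.pairs.copy()
        pairs["distance_km"] = [
            haversine_km(coords.loc[a, "lon"], coords.loc[a, "lat"],
                         coords.loc[b, "lon"], coords.loc[b, "lat"])
            for a, b in zip(pairs["site_i"], pairs["site_j"])
        ]
        return SitePairTable(pairs=pairs, site_values=pair_table.site_values,
                             coords=coords)
    site_values = pair_table.site_values.copy()
    perm = rng.permutation(len(site_values))
    site_values[predictor] = site_values[predictor].to_numpy()[perm]
    return SitePairTable(pairs=pair_table.pairs, site_values=site_values,
                         coords=pair_table.coords)


def _perm_pvalue(pair_table: SitePairTable, predictors: list[str],
                 predictor: str, observed_pct: float, n_perm: int,
                 seed) -> float:
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        permuted = _permute_predictor(pair_table, predictor, rng)
        m = fit_gdm(permuted, predictors)
        if m.pct_explained >= observed_pct:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def backward_eliminate(pair_table: SitePairTable,
                       predictors: list[str] | None = None,
                       n_perm: int = 500, alpha: float = 0.05, seed: int = 0,
                       force_retain: tuple[str, ...] = ()) -> GDMModel:
    """Permutation-based backward elimination.

    Per predictor, the p-value is the proportion of site-level permutations of
    that predictor whose refitted percent explained reaches the observed
    model's.  The non-significant predictor with the smallest summed
    coefficients is dropped (ties: input order), the model refit, and the
    procedure repeated until every retained predictor is significant at
    ``alpha`` or force-retained.  If everything is eliminated the
    intercept-only model is returned with a warning.
    """
    current = list(predictors) if predictors is not None \
        else [GEO] + pair_table.predictors
    round_no = 0
    while True:
        model = fit_gdm(pair_table, current)
        if not current:
            warnings.warn("all predictors eliminated; intercept-only model")
            return model
        pvals = {}
        for k, p in enumerate(current):
            pvals[p] = _perm_pvalue(pair_table, current, p,
                                    model.pct_explained, n_perm,
                                    seed=[seed, round_no, k])
        model.p_values = pvals
        candidates = [p for p in current
                      if pvals[p] > alpha and p not in force_retain]
        if not candidates:
            return model
        imp = importance(model)
        drop = min(candidates, key=lambda p: (imp[p], current.index(p)))
        current.remove(drop)
        round_no += 1


def importance(model: GDMModel) -> dict[str, float]:
    """Summed spline coefficients per retained predictor (also the maximum
    turnover-function height, since each basis function tops out at 1)."""
    return {p: float(model.coefs[p].sum()) for p in model.predictors}


# --------------------------------------------------------- deviance partition
def partition_deviance(pair_table: SitePairTable,
                       groups: dict[str, list[str]],
                       clamp_threshold: float = 1.0) -> pd.DataFrame:
    """Inclusion-exclusion partition of explained deviance over predictor groups.

    Fits a GDM on every non-empty union of the groups and solves the exact
    linear system for the 2^k - 1 exclusive components, expressed as
    percentages of the full model's explained deviance.  Small negative
    components (> -``clamp_threshold`` points) are clamped to 0 with a log
    note; larger negatives are reported as-is.  Raw (unclamped) components sum
    exactly to 100 by construction.
    """
    names = [g for g in groups if groups[g]]
    if not names:
        raise ValueError("no non-empty predictor groups")
    k = len(names)
    subsets = []
    for r in range(1, k + 1):
        subsets.extend(combinations(range(k), r))
    explained = {}
    for sub in subsets:
        preds = [p for i in sub for p in groups[names[i]]]
        explained[sub] = fit_gdm(pair_table, preds).pct_explained
    full = explained[tuple(range(k))]
    if full <= 0:
        raise ValueError("full model explains no deviance; cannot partition")
    # solve: explained(S) = sum of components of regions intersecting S
    regions = subsets  # region key = frozenset of group indices it belongs to
    M = np.zeros((len(subsets), len(regions)))
    for si, sub in enumerate(subsets):
        for ri, reg in enumerate(regions):
            if set(reg) & set(sub):
                M[si, ri] = 1.0
    rhs = np.array([explained[s] for s in subsets])
    comps = np.linalg.solve(M, rhs)
    comps_pct = 100.0 * comps / full
    clamped = comps_pct.copy()
    for i, v in enumerate(comps_pct):
        if -clamp_threshold < v < 0:
            logger.info("clamped small negative component %s: %.3f -> 0",
                        regions[i], v)
            clamped[i] = 0.0
    labels = ["&".join(names[i] for i in reg) for reg in regions]
    return pd.DataFrame({
        "component": labels,
        "pct_of_explained": comps_pct,
        "pct_clamped": clamped,
        "groups": [len(reg) for reg in regions],
    })
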