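"""Spatial genetic-composition maps and Procrustes comparison.

Fitted GDM turnover functions transform each significant climate layer into
genetic-importance units; PCA over the transformed layers yields three
principal-component layers composited into an RGB image (R=PC1, G=PC2,
B=PC3), so similar colours mean similar predicted genetic composition.
Two maps (e.g. neutral vs adaptive) are compared by least-squares Procrustes
superimposition of their cell x PC configurations; per-cell residuals measure
the absolute difference in predicted composition, and cross-species scaling
pools the min/max over both species so residual maps are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gdm import GEO, GDMModel
from .grids import ClimateGrid

__all__ = ["CompositionMap", "ProcrustesResult", "transform_grid", "pca_rgb",
           "procrustes_residuals", "scale_residuals_across"]


@dataclass
class CompositionMap:
    surfaces: dict[str, np.ndarray] = field(repr=False)  # predictor -> 2-D grid
    pc_layers: np.ndarray = field(repr=False)            # (ny, nx, 3), NaN nodata
    rgb: np.ndarray = field(repr=False)                  # (ny, nx, 3) uint8
    loadings: np.ndarray = field(repr=False)             # predictors x 3
    valid_mask: np.ndarray = field(repr=False)
    explained_var: np.ndarray = field(default=None, repr=False)


@dataclass
class ProcrustesResult:
    rotation: np.ndarray = field(repr=False)
    scale: float = 1.0
    translation: np.ndarray = field(default=None, repr=False)
    residuals: np.ndarray = field(default=None, repr=False)      # per valid cell
    residual_grid: np.ndarray = field(default=None, repr=False)  # 2-D, NaN nodata
    scaled_residual_grid: np.ndarray = field(default=None, repr=False)


def transform_grid(model: GDMModel, climate_grids: dict[str, ClimateGrid]):
    """Per-cell genetic-importance surfaces f_p(x) = sum_k beta_pk I_pk(x).

    Only the model's climate predictors are mapped (geographic distance is a
    pair property, not a site layer); cell values are clamped to the training
    range and nodata propagates as NaN.
    """
    preds = [p for p in model.predictors if p != GEO]
    missing = [p for p in preds if p not in climate_grids]
    if missing:
        raise ValueError(f"no climate grid for model predictor(s): {missing}")
    surfaces = {}
    for p in preds:
        vals = climate_grids[p].values
        out = np.full(vals.shape, np.nan)
        ok = ~np.isnan(vals)
        out[ok] = model.basis[p].evaluate(vals[ok]) @ model.coefs[p]
        surfaces[p] = out
    return surfaces


def _minmax_byte(layer: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.zeros(layer.shape, dtype=np.uint8)
    v = layer[mask]
    if v.size and v.max() > v.min():
        out[mask] = np.round(255 * (v - v.min()) / (v.max() - v.min()))
    return out


def pca_rgb(surfaces: dict[str, np.ndarray]) -> CompositionMap:
    """Reduce importance surfaces to three PCs and composite an RGB image.

    Cells with nodata in any surface are excluded from the PCA.  With fewer
    than 3 surfaces the missing PCs are zero-padded.  PC signs follow the
    convention that each component's largest-magnitude loading is positive.
    """
    if not surfaces:
        raise ValueError("no surfaces given")
    names = list(surfaces)
    stack = np.stack([surfaces[n] for n in names], axis=-1)  # (ny, nx, p)
    mask = ~np.isnan(stack).any(axis=-1)
    X = stack[mask]  # cells x p
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("all surfaces constant; PCA undefined")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_pc = min(3, Vt.shape[0])
    V = Vt[:n_pc].T  # p x n_pc
    # deterministic sign: largest |loading| positive per component
    for k in range(n_pc):
        if V[np.argmax(np.abs(V[:, k])), k] < 0:
            V[:, k] = -V[:, k]
    scores = Xc @ V
    ny, nx = mask.shape
    pc_layers = np.full((ny, nx, 3), np.nan)
    for k in range(n_pc):
        layer = np.full((ny, nx), np.nan)
        layer[mask] = scores[:, k]
        pc_layers[..., k] = layer
    for k in range(n_pc, 3):
        layer = np.full((ny, nx), np.nan)
        layer[mask] = 0.0
        pc_layers[..., k] = layer
    rgb = np.stack([_minmax_byte(pc_layers[..., k], mask) for k in range(3)],
                   axis=-1)
    loadings = np.zeros((len(names), 3))
    loadings[:, :n_pc] = V
    var = S**2 / max(len(X) - 1, 1)
    explained = np.zeros(3)
    explained[:n_pc] = var[:n_pc] / var.sum()
    return CompositionMap(surfaces=dict(surfaces), pc_layers=pc_layers,
                          rgb=rgb, loadings=loadings, valid_mask=mask,
                          explained_var=explained)


def procrustes_residuals(map_ref: CompositionMap,
                         map_target: CompositionMap) -> ProcrustesResult:
    """Superimpose the target configuration onto the reference and map residuals.

    Configurations are the cell x 3 PC matrices (pre-RGB scaling).  The
    least-squares similarity transform (translation, uniform scale, rotation;
    reflections permitted, since PC signs are arbitrary) is found in closed
    form; the per-cell residual is the Euclidean distance between matched
    points after superimposition.
    """
    if map_ref.valid_mask.shape != map_target.valid_mask.shape or \
            not np.array_equal(map_ref.valid_mask, map_target.valid_mask):
        raise ValueError("maps are defined on different cell sets")
    mask = map_ref.valid_mask
    X = map_ref.pc_layers[mask]
    Y = map_target.pc_layers[mask]
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    M = Yc.T @ Xc
    U, S, Vt = np.linalg.svd(M)
    R = U @ Vt  # reflection allowed
    ynorm2 = (Yc**2).sum()
    s = S.sum() / ynorm2 if ynorm2 > 0 else 1.0
    aligned = s * Yc @ R
    resid = np.linalg.norm(Xc - aligned, axis=1)
    grid = np.full(mask.shape, np.nan)
    grid[mask] = resid
    translation = mx - s * (my @ R)
    return ProcrustesResult(rotation=R, scale=float(s), translation=translation,
                            residuals=resid, residual_grid=grid)


def scale_residuals_across(residuals_a: np.ndarray, residuals_b: np.ndarray):
    """Scale two residual sets into [0, 1] with the min/max pooled over both."""
    a = np.asarray(residuals_a, dtype=float)
    b = np.asarray(residuals_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("residual sets must be non-empty")
    lo = min(np.nanmin(a), np.nanmin(b))
    hi = max(np.nanmax(a), np.nanmax(b))
    if hi == lo:
        raise ValueError("pooled residual range is zero; cannot scale")
    return (a - lo) / (hi - lo), (b - lo) / (hi - lo)
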