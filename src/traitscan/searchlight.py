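"""Spherical-searchlight SVR decoding of a continuous trait.

For every in-mask center voxel, the multivoxel pattern of a contrast map
inside a sphere (default radius 3 voxels) is used as the feature set of a
linear epsilon-SVR (C = 1) predicting the trait score across subjects,
under k-fold cross-validation (default 10 folds, one shared random
partition).  Out-of-fold predictions are pooled over all subjects and the
per-voxel performance statistic is the Pearson correlation between
predicted and actual scores, with a two-sided p from the t transform and
Benjamini–Hochberg FDR control over the mask (per-map q = 0.0125 when a
0.05 family level is split over the four emotion contrasts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._svr import cv_predict_batch, svr_fit, svr_predict
from .grid import VolumeGrid

__all__ = [
    "SearchlightSpec",
    "PredictionMap",
    "sphere_offsets",
    "kfold_partition",
    "svr_train_predict",
    "searchlight_predict",
    "fdr_threshold",
    "per_map_q",
]


def per_map_q(family_q: float, n_contrasts: int) -> float:
    """Per-map FDR level when a family level is split over contrasts.

    A 0.05 family level over the four emotion>neutral contrasts gives the
    whole-brain per-map threshold q = 0.0125.
    """
    if not 0 < family_q < 1 or n_contrasts < 1:
        raise ValueError("invalid family level or contrast count")
    return family_q / n_contrasts


@dataclass(frozen=True)
class SearchlightSpec:
    """Searchlight and cross-validation settings."""

    radius_vox: int = 3
    svr_C: float = 1.0
    svr_epsilon: float = 0.1
    n_folds: int = 10
    cv_seed: int = 0
    min_voxels: int = 10
    q_fdr: float = 0.0125
    adjust_fold_means: bool = True
    standardize: bool = False
    p_method: str = "t"
    n_calib_perms: int = 20
    n_calib_centers: int = 128
    svr_tol: float = 0.05
    svr_max_epochs: int = 2000

    def __post_init__(self) -> None:
        if self.radius_vox < 0:
            raise ValueError("radius must be nonnegative")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.svr_C <= 0 or self.svr_epsilon < 0:
            raise ValueError("invalid SVR parameters")
        if self.p_method not in ("t", "calibrated"):
            raise ValueError("p_method must be 't' or 'calibrated'")


@dataclass
class PredictionMap:
    """Voxelwise prediction-outcome correlation and FDR thresholding."""

    r: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    significant: np.ndarray = field(repr=False)
    critical_p: float
    q: float
    contrast: str = ""
    spec: SearchlightSpec | None = None


def sphere_offsets(radius_vox: int) -> np.ndarray:
    """All integer offsets with Euclidean norm <= radius, lexicographic.

    Radius 0 -> the center only; radius 1 -> center + 6 face neighbors
    (7); radius 3 -> 123 lattice points.
    """
    if radius_vox < 0:
        raise ValueError("radius must be nonnegative")
    r = int(radius_vox)
    rng = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(rng, rng, rng, indexing="ij")
    offs = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    offs = offs[(offs**2).sum(axis=1) <= r * r]
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0]))
    return offs[order]


def kfold_partition(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Balanced random fold labels in 0..k-1; sizes differ by at most 1.

    E.g. 229 subjects in 10 folds -> nine folds of 23 and one of 22.
    """
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    rng = np.random.default_rng(seed)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    labels = np.repeat(np.arange(k), sizes)
    out = np.empty(n, dtype=np.int64)
    out[rng.permutation(n)] = labels
    return out


def svr_train_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    C: float = 1.0,
    epsilon: float = 0.1,
    tol: float = 1e-4,
) -> np.ndarray:
    """Linear epsilon-SVR fit on the training set, evaluated on the test set.

    The returned predictor minimizes the standard primal
    ``1/2 ||w||^2 + C * sum(eps-insensitive losses)`` to solver tolerance
    (see :mod:`traitscan._svr` for the dual coordinate-descent solver).
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    if train_X.ndim != 2 or test_X.ndim != 2 or train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train and test feature counts must match")
    beta, y_mean = svr_fit(train_X, train_y, C=C, epsilon=epsilon, tol=tol,
                           max_epochs=100_000)
    return svr_predict(test_X, train_X, beta, y_mean)


def _neighbor_table(grid: VolumeGrid, radius_vox: int) -> np.ndarray:
    """(n_mask_voxels, n_offsets) in-mask flat indices; -1 where invalid."""
    offs = sphere_offsets(radius_vox)
    flat = grid.flat_index_volume()
    centers = grid.mask_ijk
    nb = np.full((centers.shape[0], offs.shape[0]), -1, dtype=np.int64)
    shape = np.asarray(grid.shape)
    for j, off in enumerate(offs):
        pos = centers + off
        ok = ((pos >= 0) & (pos < shape)).all(axis=1)
        nb[ok, j] = flat[tuple(pos[ok].T)]
    return nb


def searchlight_predict(
    maps: np.ndarray,
    traits: np.ndarray,
    grid: VolumeGrid,
    spec: SearchlightSpec = SearchlightSpec(),
    chunk_size: int = 256,
) -> PredictionMap:
    """Run the searchlight over all in-mask centers.

    Parameters
    ----------
    maps : (n_subjects, n_mask_voxels) ndarray
        One contrast map per subject, masked and flattened on ``grid``.
    traits : (n_subjects,) ndarray
        The trait scores to decode.

    Notes
    -----
    One fold assignment is drawn once (``spec.cv_seed``) and shared across
    all centers; out-of-fold predictions are pooled over subjects into a
    single prediction-outcome Pearson r per center.  Centers whose sphere
    contains fewer than ``spec.min_voxels`` in-mask voxels get NaN.
    """
    maps = np.asarray(maps, dtype=np.float64)
    traits = np.asarray(traits, dtype=np.float64)
    n_sub, n_vox = maps.shape
    if traits.shape != (n_sub,):
        raise ValueError("traits length must match number of maps")
    if n_vox != grid.n_voxels:
        raise ValueError("maps do not match the grid mask")
    if np.ptp(traits) == 0:
        raise ValueError("degenerate target: trait scores are constant")
    if spec.n_folds > n_sub:
        raise ValueError("fewer subjects than folds")

    fold = kfold_partition(n_sub, spec.n_folds, spec.cv_seed)
    nb = _neighbor_table(grid, spec.radius_vox)
    n_members = (nb >= 0).sum(axis=1)
    valid = n_members >= spec.min_voxels

    # -1 indices address the appended zero column: zero-padded features
    maps_ext = np.concatenate([maps, np.zeros((n_sub, 1))], axis=1)
    preds = np.full((n_vox, n_sub), np.nan)
    idx_valid = np.where(valid)[0]
    for start in range(0, idx_valid.size, chunk_size):
        sel = idx_valid[start : start + chunk_size]
        feats = maps_ext[:, nb[sel]]  # (n_sub, chunk, n_off)
        feats = np.ascontiguousarray(np.moveaxis(feats, 1, 0))
        if spec.standardize:
            preds[sel] = _cv_predict_standardized(feats, traits, fold, spec)
        else:
            G = np.einsum("cif,cjf->cij", feats, feats)
            preds[sel] = cv_predict_batch(
                G, traits, fold, spec.n_folds, C=spec.svr_C,
                epsilon=spec.svr_epsilon, tol=spec.svr_tol,
                max_epochs=spec.svr_max_epochs,
            )

    fold_adj = fold if spec.adjust_fold_means else None
    r, p = _pooled_correlation(preds, traits, fold_adj)
    if spec.p_method == "calibrated":
        vif = _calibration_vif(maps_ext, nb, idx_valid, traits, fold, spec)
        df = n_sub - 2 - (spec.n_folds - 1 if spec.adjust_fold_means else 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * sps.norm.sf(np.abs(z) / np.sqrt(vif))
        p = np.where(np.isfinite(r), np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
    sig, crit = fdr_threshold(p, spec.q_fdr)
    return PredictionMap(r=r, p=p, significant=sig, critical_p=crit,
                         q=spec.q_fdr, spec=spec)


def _calibration_vif(
    maps_ext: np.ndarray,
    nb: np.ndarray,
    idx_valid: np.ndarray,
    y: np.ndarray,
    fold: np.ndarray,
    spec: SearchlightSpec,
) -> float:
    """Variance-inflation factor of the CV-correlation null, by permutation.

    The null variance of the pooled cross-validated correlation exceeds
    the t reference because predictions reuse the outcomes symmetrically;
    the inflation is a global property of the fold structure and learner,
    so it is estimated once from trait permutations on a random subset of
    centers and applied to every voxel.
    """
    rng = np.random.default_rng([spec.cv_seed, 313])
    n_cal = min(spec.n_calib_centers, idx_valid.size)
    centers = rng.choice(idx_valid, size=n_cal, replace=False)
    feats = np.ascontiguousarray(np.moveaxis(maps_ext[:, nb[centers]], 1, 0))
    G = np.einsum("cif,cjf->cij", feats, feats)
    fold_adj = fold if spec.adjust_fold_means else None
    df = y.size - 2 - (spec.n_folds - 1 if spec.adjust_fold_means else 0)
    z2 = []
    for _ in range(spec.n_calib_perms):
        yp = y[rng.permutation(y.size)]
        preds = cv_predict_batch(G, yp, fold, spec.n_folds, C=spec.svr_C,
                                 epsilon=spec.svr_epsilon, tol=spec.svr_tol,
                                 max_epochs=spec.svr_max_epochs)
        r, _ = _pooled_correlation(preds, yp, fold_adj)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = r * np.sqrt(df / (1.0 - r**2))
        z2.append(np.nanmean(z**2))
    return max(float(np.mean(z2)), 1.0)


def _pooled_correlation(
    preds: np.ndarray, y: np.ndarray, fold: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rowwise Pearson r of pooled predictions vs y, two-sided t-based p.

    When ``fold`` is given, fold means are partialled out of both the
    predictions and the outcomes before correlating and the t test loses
    one degree of freedom per extra fold.  Out-of-fold predictions carry
    the training-set mean, which is anti-correlated with the held-out
    outcomes by construction; without the adjustment the pooled
    correlation is biased negative under the null and its p values are
    anti-conservative (verified by simulation).
    """
    n = y.size
    k_adj = 0
    if fold is not None:
        k = int(fold.max()) + 1
        k_adj = k - 1
        yc = y.astype(float).copy()
        pc = preds.copy()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for f in range(k):
                m = fold == f
                yc[m] -= yc[m].mean()
                pc[:, m] -= np.nanmean(pc[:, m], axis=1, keepdims=True)
    else:
        yc = y - y.mean()
        pc = preds - np.nanmean(preds, axis=1, keepdims=True)
    df = n - 2 - k_adj
    num = pc @ yc
    den = np.sqrt((pc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=df)
    p = np.where(np.isfinite(r), np.minimum(np.maximum(p, np.finfo(float).tiny), 1.0), np.nan)
    r = np.where(np.isfinite(r), r, np.nan)
    return r, p


def _cv_predict_standardized(
    feats: np.ndarray, y: np.ndarray, fold: np.ndarray, spec: SearchlightSpec
) -> np.ndarray:
    """Slow path: z-score features within training folds before the SVR."""
    nc, n_sub, _ = feats.shape
    out = np.empty((nc, n_sub))
    for c in range(nc):
        X = feats[c]
        for f in range(spec.n_folds):
            te = fold == f
            tr = ~te
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            beta, ym = svr_fit((X[tr] - mu) / sd, y[tr], C=spec.svr_C,
                               epsilon=spec.svr_epsilon, tol=spec.svr_tol)
            out[c, te] = svr_predict((X[te] - mu) / sd, (X[tr] - mu) / sd, beta, ym)
    return out


def fdr_threshold(p_values: np.ndarray, q: float) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up over the defined (non-NaN) p values.

    Returns the boolean significance flags (False wherever p is NaN) and
    the critical p value p(k*) — 0.0 when nothing survives.
    """
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise ValueError("empty p-value list")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    defined = np.isfinite(p_values)
    if not defined.any():
        raise ValueError("no defined p values")
    flags = np.zeros(p_values.shape, dtype=bool)
    reject, _, _, _ = multipletests(p_values[defined], alpha=q, method="fdr_bh")
    flags[defined] = reject
    crit = float(p_values[flags].max()) if flags.any() else 0.0
    return flags, crit
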