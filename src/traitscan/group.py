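"""Group-level genotype x trait interaction inference on coupling maps.

Per-subject seed coupling maps enter a voxelwise moderation model
(intercept, carrier group, mean-centered trait, group x trait product);
the interaction t map is thresholded by permutation-based max-|t|
family-wise error control (Freedman–Lane residual permutation), clusters
are extent-filtered (k > 10 by convention), corrected across the tested
emotion contrasts by Bonferroni, and per-group trait-coupling slopes are
reported with a Bonferroni factor for the SNP x allele family (4 x 2 = 8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .grid import VolumeGrid
from .stats import bonferroni, pearson_test

__all__ = [
    "GroupDesign",
    "StatMap",
    "build_interaction_design",
    "interaction_tmap",
    "permutation_fwe",
    "label_clusters",
    "extract_cluster_estimates",
    "group_slope_report",
]

#: index of the interaction column in the group design
INTERACTION_COL = 3


@dataclass
class GroupDesign:
    """Moderation design: intercept, carrier (+/- 1/2), trait, product."""

    matrix: np.ndarray = field(repr=False)
    carriers: np.ndarray = field(repr=False)
    traits_centered: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def df(self) -> int:
        return self.n - self.matrix.shape[1]


@dataclass
class StatMap:
    """Voxelwise interaction t statistics with p values."""

    t: np.ndarray = field(repr=False)
    df: int
    p_uncorrected: np.ndarray = field(repr=False)
    p_fwe: np.ndarray | None = field(default=None, repr=False)


def build_interaction_design(carriers: np.ndarray, traits: np.ndarray) -> GroupDesign:
    """Build the rank-4 genotype x trait design.

    Carriers are coded symmetrically (+1/2 carrier, -1/2 non-carrier) and
    traits are mean-centered before the product is formed, so the main
    effects keep their interpretation at the sample average.
    """
    carriers = np.asarray(carriers)
    traits = np.asarray(traits, dtype=float)
    if carriers.shape != traits.shape or carriers.ndim != 1:
        raise ValueError("carriers and traits must be 1-D and equally long")
    n1 = int((carriers == 1).sum())
    n0 = int((carriers == 0).sum())
    if n1 + n0 != carriers.size:
        raise ValueError("carriers must be binary 0/1")
    if min(n0, n1) < 2:
        raise ValueError("need at least 2 subjects per genotype group")
    g = np.where(carriers == 1, 0.5, -0.5)
    tc = traits - traits.mean()
    X = np.column_stack([np.ones(carriers.size), g, tc, g * tc])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("degenerate design (rank < 4)")
    return GroupDesign(matrix=X, carriers=carriers, traits_centered=tc)


def _tmap(X: np.ndarray, Y: np.ndarray, col: int) -> np.ndarray:
    """OLS t statistics for one coefficient, vectorized over columns of Y."""
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    xtxi = np.linalg.inv(X.T @ X)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[col] / np.sqrt(sigma2 * xtxi[col, col])
    return t


def interaction_tmap(coupling: np.ndarray, design: GroupDesign) -> StatMap:
    """Voxelwise t map of the carrier x trait coefficient (df = n - 4)."""
    coupling = np.asarray(coupling, dtype=float)
    if coupling.shape[0] != design.n:
        raise ValueError("coupling row count must equal design rows")
    t = _tmap(design.matrix, coupling, INTERACTION_COL)
    p = 2.0 * sps.t.sf(np.abs(t), df=design.df)
    return StatMap(t=t, df=design.df, p_uncorrected=p)


def permutation_fwe(
    coupling: np.ndarray,
    design: GroupDesign,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Max-|t| family-wise-error corrected p values by permutation.

    Freedman–Lane scheme: the reduced model (without the interaction
    column) is fitted, its residuals are permuted and added back to the
    reduced fit, and the interaction |t| map is recomputed; the corrected
    p at a voxel is the (+1 smoothed) fraction of permutations whose
    maximum |t| over the mask reaches the observed |t|.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    coupling = np.asarray(coupling, dtype=float)
    X = design.matrix
    if coupling.shape[0] != X.shape[0]:
        raise ValueError("coupling row count must equal design rows")
    t_obs = np.abs(_tmap(X, coupling, INTERACTION_COL))
    Xr = np.delete(X, INTERACTION_COL, axis=1)
    fit_r = Xr @ (np.linalg.pinv(Xr) @ coupling)
    resid_r = coupling - fit_r
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    exceed = np.zeros(coupling.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(n)
        t_perm = np.abs(_tmap(X, fit_r + resid_r[perm], INTERACTION_COL))
        exceed += np.nanmax(t_perm) >= t_obs
    return (1.0 + exceed) / (n_perm + 1.0)


def label_clusters(
    sig_mask: np.ndarray,
    min_k: int = 10,
    stat: np.ndarray | None = None,
    grid: VolumeGrid | None = None,
) -> pd.DataFrame:
    """Connected components of a significance mask, extent-filtered.

    Uses 18-neighbor connectivity (faces + edges).  Components with extent
    ``<= min_k`` are discarded ("minimum voxel size k > min_k").  When a
    3D ``stat`` volume is given, the peak is its max-|stat| voxel; with a
    ``grid``, peak mm coordinates are added.

    Returns a table with columns cluster_id, k, peak_i/j/k (and peak
    stat / mm coordinates when available), sorted by extent.
    """
    sig_mask = np.asarray(sig_mask, dtype=bool)
    if sig_mask.ndim != 3:
        raise ValueError("sig_mask must be a 3D volume")
    structure = ndimage.generate_binary_structure(3, 2)  # faces + edges
    labels, n_comp = ndimage.label(sig_mask, structure=structure)
    rows = []
    for lab in range(1, n_comp + 1):
        members = np.argwhere(labels == lab)
        k = members.shape[0]
        if k <= min_k:
            continue
        if stat is not None:
            vals = np.abs(np.asarray(stat)[tuple(members.T)])
            peak = members[int(np.argmax(vals))]
            peak_stat = float(np.asarray(stat)[tuple(peak)])
        else:
            peak = members[0]
            peak_stat = np.nan
        row = {
            "cluster_id": lab,
            "k": int(k),
            "peak_i": int(peak[0]),
            "peak_j": int(peak[1]),
            "peak_k": int(peak[2]),
            "peak_stat": peak_stat,
        }
        if grid is not None:
            mm = grid.voxel_to_mm(peak)[0]
            row.update({"peak_x_mm": mm[0], "peak_y_mm": mm[1], "peak_z_mm": mm[2]})
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("k", ascending=False).reset_index(drop=True)
    return df


def extract_cluster_estimates(coupling: np.ndarray, cluster_idx: np.ndarray) -> np.ndarray:
    """Per-subject mean coupling over a cluster's (flat, in-mask) voxels."""
    cluster_idx = np.asarray(cluster_idx, dtype=int)
    if cluster_idx.size == 0:
        raise ValueError("empty cluster")
    return np.asarray(coupling, dtype=float)[:, cluster_idx].mean(axis=1)


def group_slope_report(
    estimates: np.ndarray,
    traits: np.ndarray,
    carriers: np.ndarray,
    m: int = 8,
) -> dict:
    """Per-carrier-group trait–coupling Pearson correlations.

    p values are Bonferroni-corrected by ``m`` (default 8: four SNPs x two
    allele groupings).  The report flags sign opposition between groups —
    the signature of a crossover genotype x trait interaction.
    """
    estimates = np.asarray(estimates, dtype=float)
    traits = np.asarray(traits, dtype=float)
    carriers = np.asarray(carriers)
    report: dict = {"m": int(m), "groups": {}}
    signs = {}
    for label, mask_g in (("carrier", carriers == 1), ("noncarrier", carriers == 0)):
        if mask_g.sum() < 3:
            raise ValueError(f"group {label!r} has fewer than 3 subjects")
        if np.ptp(estimates[mask_g]) == 0:
            raise ValueError(f"group {label!r} has zero-variance estimates")
        r, p = pearson_test(traits[mask_g], estimates[mask_g])
        signs[label] = np.sign(r)
        report["groups"][label] = {
            "n": int(mask_g.sum()),
            "r": r,
            "p": p,
            "p_corrected": bonferroni(p, m),
            "slope_sign": "+" if r >= 0 else "-",
        }
    report["sign_opposition"] = bool(signs["carrier"] * signs["noncarrier"] < 0)
    return report
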