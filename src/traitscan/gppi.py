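"""Generalized psychophysiological interaction (gPPI) connectivity.

Per subject: extract a seed time series from a small sphere, estimate the
underlying neural series by ridge-regularized linear deconvolution of the
HRF, form one seed-by-condition interaction regressor per task condition
at the neural resolution, reconvolve, and fit a voxelwise OLS model whose
(angry PPI − neutral PPI) beta difference is the coupling map passed to
the group-level genotype analysis.

The deconvolution is a plain linear inverse problem
``min ||H s - b||^2 + lambda ||s||^2`` rather than the empirical-Bayes
scheme of the classical toolboxes — same role, simpler contract; the
round-trip error of conv(deconv(x)) is bounded in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .glm import DesignMatrix, HRFModel, canonical_hrf
from .grid import VolumeGrid
from .task import CONDITIONS, EventSchedule

__all__ = [
    "SeedSpec",
    "CouplingMap",
    "extract_seed_timeseries",
    "deconvolve_neural",
    "reconvolve",
    "build_gppi_design",
    "ppi_coupling_map",
    "ppi_contrast_weights",
]


@dataclass(frozen=True)
class SeedSpec:
    """Spherical seed in mm coordinates (default 6 mm radius)."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass
class CouplingMap:
    """Per-subject seed→voxel PPI contrast betas (angry − neutral)."""

    subject_id: str
    seed_name: str
    values: np.ndarray = field(repr=False)


def seed_member_indices(grid: VolumeGrid, seed: SeedSpec) -> np.ndarray:
    """In-mask flat indices of voxels whose center lies within the seed."""
    d = np.linalg.norm(grid.mask_mm - np.asarray(seed.center_mm), axis=1)
    idx = np.where(d <= seed.radius_mm)[0]
    if idx.size == 0:
        raise ValueError(f"seed {seed.name!r} does not intersect the mask")
    return idx


def extract_seed_timeseries(
    bold: np.ndarray, grid: VolumeGrid, seed: SeedSpec
) -> np.ndarray:
    """Mean BOLD series over the seed sphere's in-mask voxels.

    ``bold`` is (n_scans, n_mask_voxels) or a 4D (x, y, z, t) volume.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim == 4:
        bold = bold[grid.mask].T
    idx = seed_member_indices(grid, seed)
    return bold[:, idx].mean(axis=1)


# ---------------------------------------------------------------------------
# deconvolution
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _conv_matrix(n_scans: int, hrf: HRFModel) -> np.ndarray:
    """(n_scans, n_fine) matrix mapping a neural series at hrf.dt resolution
    to BOLD sampled at scan onsets."""
    kernel = canonical_hrf(hrf)
    os_ = hrf.oversampling
    n_fine = n_scans * os_
    H = np.zeros((n_scans, n_fine))
    for i in range(n_scans):
        j_hi = i * os_
        lo = max(0, j_hi - kernel.size + 1)
        seg = kernel[: j_hi - lo + 1][::-1]
        H[i, lo : j_hi + 1] = seg
    return H


@lru_cache(maxsize=32)
def _decon_operator(n_scans: int, hrf: HRFModel, lam: float) -> np.ndarray:
    H = _conv_matrix(n_scans, hrf)
    n_fine = H.shape[1]
    return np.linalg.solve(H.T @ H + lam * np.eye(n_fine), H.T)


def deconvolve_neural(
    series: np.ndarray, hrf: HRFModel, ridge_lambda: float = 1e-2
) -> np.ndarray:
    """Estimate the neural-level series behind a BOLD series.

    Least-squares inversion of the HRF convolution operator with an L2
    penalty ``ridge_lambda`` on the neural series; the series mean is
    removed first (the deconvolution model has no baseline term).  The
    result lives on the fine grid ``hrf.dt = tr_s / oversampling``.
    """
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be nonnegative")
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D (one run)")
    if not np.isfinite(series).all():
        raise ValueError("non-finite values in series")
    D = _decon_operator(series.size, hrf, float(ridge_lambda))
    return D @ (series - series.mean())


def reconvolve(neural: np.ndarray, hrf: HRFModel, n_scans: int) -> np.ndarray:
    """Map a fine-grid neural series back to BOLD at scan times."""
    H = _conv_matrix(n_scans, hrf)
    if neural.size != H.shape[1]:
        raise ValueError("neural series length does not match the scan grid")
    return H @ neural


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


def _condition_indicator(events, n_fine: int, dt: float) -> dict[str, np.ndarray]:
    ind = {}
    for cond in CONDITIONS:
        sel = events[events["trial_type"] == cond]
        v = np.zeros(n_fine)
        for onset, dur in zip(sel["onset"], sel["duration"]):
            i0 = int(round(onset / dt))
            i1 = min(n_fine, i0 + max(1, int(round(dur / dt))))
            if i0 >= n_fine:
                raise ValueError(f"event at {onset} s past the run end")
            v[i0:i1] = 1.0
        ind[cond] = v
    return ind


def build_gppi_design(
    neural: np.ndarray | list[np.ndarray],
    events: EventSchedule,
    hrf: HRFModel,
    motion: list[np.ndarray] | None = None,
    seed_series: np.ndarray | list[np.ndarray] | None = None,
) -> DesignMatrix:
    """Assemble the generalized-PPI design.

    Per run: one physiological column (the seed BOLD series), five
    psychological condition columns (HRF-convolved stick trains), five PPI
    columns — the deconvolved neural series gated by each condition's
    indicator at the neural resolution and reconvolved — six motion
    columns when given, and an intercept.

    ``neural`` (and ``seed_series``, ``motion``) are per-run lists; a bare
    array is treated as a single run.  When ``seed_series`` is omitted the
    reconvolved neural series stands in for the physiological column.
    """
    if isinstance(neural, np.ndarray):
        neural = [neural]
    n_runs = events.n_runs
    if len(neural) != n_runs:
        raise ValueError("need one neural series per run")
    if seed_series is not None and isinstance(seed_series, np.ndarray):
        seed_series = [seed_series]
    if motion is not None and len(motion) != n_runs:
        raise ValueError("need one motion array per run")

    kernel = canonical_hrf(hrf)
    os_ = hrf.oversampling
    blocks, names, run_slices = [], [], []
    n_scans_runs = [nr.size // os_ for nr in neural]
    total = sum(n_scans_runs)
    row0 = 0
    for r in range(n_runs):
        ns = n_scans_runs[r]
        n_fine = ns * os_
        if neural[r].size != n_fine:
            raise ValueError(f"run {r}: neural length must be a multiple of oversampling")
        H = _conv_matrix(ns, hrf)
        ind = _condition_indicator(events.runs[r], n_fine, hrf.dt)
        cols, cnames = [], []
        phys = (
            np.asarray(seed_series[r], dtype=float)
            if seed_series is not None
            else H @ neural[r]
        )
        if phys.size != ns:
            raise ValueError(f"run {r}: seed series length != scan count")
        cols.append(phys - phys.mean())
        cnames.append(f"run{r + 1}_phys")
        present = events.conditions_present(r)
        for cond in present:
            sel = events.runs[r][events.runs[r]["trial_type"] == cond]
            train = np.zeros(n_fine)
            for onset in sel["onset"]:
                train[int(round(onset / hrf.dt))] += 1.0
            cols.append(np.convolve(train, kernel)[:n_fine][::os_])
            cnames.append(f"run{r + 1}_psych_{cond}")
        # one PPI column per condition (generalized form); zero whenever
        # either factor (neural series, condition indicator) is zero
        for cond in CONDITIONS:
            cols.append(H @ (neural[r] * ind[cond]))
            cnames.append(f"run{r + 1}_ppi_{cond}")
        if motion is not None:
            mot = np.asarray(motion[r], dtype=float)
            if mot.shape != (ns, 6):
                raise ValueError(f"run {r}: motion must be ({ns}, 6)")
            for j in range(6):
                cols.append(mot[:, j])
                cnames.append(f"run{r + 1}_motion{j + 1}")
        cols.append(np.ones(ns))
        cnames.append(f"run{r + 1}_intercept")
        block = np.zeros((total, len(cols)))
        block[row0 : row0 + ns] = np.column_stack(cols)
        blocks.append(block)
        names.extend(cnames)
        run_slices.append(slice(row0, row0 + ns))
        row0 += ns
    return DesignMatrix(matrix=np.hstack(blocks), names=names,
                        run_slices=run_slices, validate_rank=False)


def ppi_contrast_weights(
    design: DesignMatrix, positive: str = "angry", negative: str = "neutral"
) -> np.ndarray:
    """Weights selecting the PPI beta difference, averaged over runs."""
    pos = [i for i, n in enumerate(design.names) if n.endswith(f"ppi_{positive}")]
    neg = [i for i, n in enumerate(design.names) if n.endswith(f"ppi_{negative}")]
    if not pos or not neg:
        raise ValueError("PPI columns not found in design")
    w = np.zeros(len(design.names))
    w[pos] = 1.0 / len(pos)
    w[neg] = -1.0 / len(neg)
    return w


def ppi_coupling_map(
    bold: np.ndarray,
    design: DesignMatrix,
    grid: VolumeGrid | None = None,
    subject_id: str = "",
    seed_name: str = "",
    positive: str = "angry",
    negative: str = "neutral",
) -> CouplingMap:
    """Voxelwise OLS fit of the PPI design; returns the PPI beta contrast."""
    bold = np.asarray(bold, dtype=float)
    if bold.ndim == 4:
        if grid is None:
            raise ValueError("grid required for 4D input")
        bold = bold[grid.mask].T
    if bold.shape[0] != design.n_scans:
        raise ValueError("bold scan count does not match design rows")
    if not design.full_rank:
        raise ValueError("PPI design is rank deficient")
    betas = np.linalg.pinv(design.matrix) @ bold
    w = ppi_contrast_weights(design, positive, negative)
    return CouplingMap(subject_id=subject_id, seed_name=seed_name, values=w @ betas)
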