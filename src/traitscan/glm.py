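"""First-level GLM: canonical HRF, design matrices, voxelwise OLS, contrasts.

Produces the per-subject emotion>neutral contrast maps that feed the
searchlight.  Runs are fitted jointly with run-specific condition, motion
and intercept columns (block structure); contrasts average the condition
beta difference across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .grid import VolumeGrid
from .task import CONDITIONS, EventSchedule

__all__ = [
    "HRFModel",
    "DesignMatrix",
    "ContrastMap",
    "canonical_hrf",
    "build_design_matrix",
    "fit_glm",
    "contrast_map",
]


@dataclass(frozen=True)
class HRFModel:
    """Canonical double-gamma hemodynamic response model.

    The kernel is the difference of two gamma densities (response peak
    around 5 s, late undershoot around 15 s), sampled at
    ``tr_s / oversampling`` and normalized to unit peak.
    """

    tr_s: float = 2.0
    oversampling: int = 16
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    length_s: float = 32.0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")

    @property
    def dt(self) -> float:
        return self.tr_s / self.oversampling


def canonical_hrf(model: HRFModel) -> np.ndarray:
    """Sample the canonical double-gamma kernel; max value exactly 1."""
    t = np.arange(0.0, model.length_s, model.dt)
    peak = sps.gamma.pdf(
        t, model.peak_delay_s / model.peak_dispersion_s, scale=model.peak_dispersion_s
    )
    under = sps.gamma.pdf(
        t,
        model.undershoot_delay_s / model.undershoot_dispersion_s,
        scale=model.undershoot_dispersion_s,
    )
    kernel = peak - under / model.peak_undershoot_ratio
    return kernel / kernel.max()


@dataclass
class DesignMatrix:
    """Scan-by-regressor design with labeled columns and run structure."""

    matrix: np.ndarray = field(repr=False)
    names: list[str]
    run_slices: list[slice]
    validate_rank: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column count does not match names")
        if self.validate_rank and np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def full_rank(self) -> bool:
        return bool(np.linalg.matrix_rank(self.matrix) == self.matrix.shape[1])

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def condition_weights(self, positive: str, negative: str) -> np.ndarray:
        """Contrast weights for ``positive > negative`` averaged over runs."""
        w = np.zeros(len(self.names))
        pos = [i for i, n in enumerate(self.names) if n.endswith(f"_{positive}")]
        neg = [i for i, n in enumerate(self.names) if n.endswith(f"_{negative}")]
        if not pos or not neg:
            raise ValueError(f"conditions {positive!r}/{negative!r} not in design")
        w[pos] = 1.0 / len(pos)
        w[neg] = -1.0 / len(neg)
        return w


@dataclass
class ContrastMap:
    """Per-subject voxelwise beta difference for one emotion contrast."""

    subject_id: str
    contrast: str
    values: np.ndarray = field(repr=False)  # (n_mask_voxels,)


def _condition_regressors(
    events, n_scans: int, hrf: HRFModel, kernel: np.ndarray, model_durations: bool
) -> dict[str, np.ndarray]:
    """HRF-convolved condition columns for one run, sampled at scan onsets."""
    os_ = hrf.oversampling
    n_fine = n_scans * os_
    run_len = n_scans * hrf.tr_s
    cols: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        sel = events[events["trial_type"] == cond]
        if len(sel) == 0:
            continue
        train = np.zeros(n_fine)
        for onset, dur in zip(sel["onset"], sel["duration"]):
            if onset >= run_len:
                raise ValueError(f"event at {onset} s is past the last scan")
            i0 = int(round(onset / hrf.dt))
            if model_durations and dur > 0:
                i1 = min(n_fine, i0 + max(1, int(round(dur / hrf.dt))))
                train[i0:i1] += 1.0
            else:
                train[i0] += 1.0
        conv = np.convolve(train, kernel)[:n_fine]
        cols[cond] = conv[::os_]
    return cols


def build_design_matrix(
    events: EventSchedule,
    n_scans: int | list[int],
    hrf: HRFModel,
    motion: list[np.ndarray] | None = None,
    model_durations: bool = False,
) -> DesignMatrix:
    """Assemble the multi-run design: condition + motion + intercept per run.

    Parameters
    ----------
    events : EventSchedule
        Per-run event tables.
    n_scans : int or list of int
        Scans per run (a single int applies to every run).
    motion : list of (n_scans, 6) arrays, optional
        Per-run nuisance movement parameters, appended verbatim.
    model_durations : bool
        If False (default) events are modeled as zero-duration impulses.
    """
    n_runs = events.n_runs
    if isinstance(n_scans, int):
        n_scans = [n_scans] * n_runs
    if motion is not None and len(motion) != n_runs:
        raise ValueError("need one motion array per run")
    kernel = canonical_hrf(hrf)

    blocks, names = [], []
    total = sum(n_scans)
    row0 = 0
    run_slices = []
    for r in range(n_runs):
        ns = n_scans[r]
        cols = _condition_regressors(events.runs[r], ns, hrf, kernel, model_durations)
        block_cols, block_names = [], []
        for cond in CONDITIONS:
            if cond in cols:
                block_cols.append(cols[cond])
                block_names.append(f"run{r + 1}_{cond}")
        if motion is not None:
            mot = np.asarray(motion[r], dtype=float)
            if mot.shape != (ns, 6):
                raise ValueError(f"run {r}: motion must be ({ns}, 6)")
            for j in range(6):
                block_cols.append(mot[:, j])
                block_names.append(f"run{r + 1}_motion{j + 1}")
        block_cols.append(np.ones(ns))
        block_names.append(f"run{r + 1}_intercept")
        block = np.zeros((total, len(block_cols)))
        block[row0 : row0 + ns] = np.column_stack(block_cols)
        blocks.append(block)
        names.extend(block_names)
        run_slices.append(slice(row0, row0 + ns))
        row0 += ns
    return DesignMatrix(matrix=np.hstack(blocks), names=names, run_slices=run_slices)


def fit_glm(
    bold: np.ndarray, X: DesignMatrix, grid: VolumeGrid | None = None
) -> np.ndarray:
    """Voxelwise ordinary-least-squares fit.

    Parameters
    ----------
    bold : (n_scans, n_voxels) array or (x, y, z, n_scans) volume
        If 4D, ``grid`` is required and only in-mask voxels are fitted.

    Returns
    -------
    (n_regressors, n_voxels) array of beta estimates.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim == 4:
        if grid is None:
            raise ValueError("grid required for 4D input")
        bold = bold[grid.mask].T
    if bold.ndim != 2 or bold.shape[0] != X.n_scans:
        raise ValueError("bold scan count does not match design rows")
    pinv = np.linalg.pinv(X.matrix)
    return pinv @ bold


def contrast_map(betas: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Voxelwise weighted sum of beta maps."""
    betas = np.asarray(betas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if betas.shape[0] != weights.shape[0]:
        raise ValueError("weight length must equal regressor count")
    return weights @ betas
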