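"""Synthetic fMRI cohort generator with known ground truth.

Emulates the structure of the study the pipeline targets: a five-condition
(angry / fear / happy / neutral / sad) event-related face paradigm shown in
two runs of 173 volumes; a 50-item autistic-trait questionnaire (total
0–50, population mean ≈ 21.4, SD ≈ 5.6); four OXTR SNPs in Hardy–Weinberg
equilibrium with dominant risk-allele carrier grouping; a spatially
localized multivariate pattern whose angry−neutral amplitude encodes the
trait; and seed→target condition-specific coupling whose trait slope
differs in sign between genotype groups.

Everything is deterministic given ``CohortSpec.rng_seed``; per-subject
streams are derived from it so volumes can be regenerated lazily without
holding the whole cohort in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glm import HRFModel, canonical_hrf
from .grid import VolumeGrid
from .task import CONDITIONS, EventSchedule

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "BoldCohort",
    "SNP_IDS",
    "RISK_ALLELES",
    "simulate_asq_responses",
    "score_asq",
    "simulate_genotypes",
    "simulate_phenotypes",
    "build_event_schedule",
    "simulate_cohort_bold",
    "simulate_behavior",
    "calibrate_pattern_strength",
]

#: the four oxytocin-receptor SNPs genotyped in the emulated study
SNP_IDS = ("rs2254298", "rs2268491", "rs2268498", "rs53576")

#: major / minor allele letters per SNP
SNP_ALLELES = {
    "rs2254298": ("G", "A"),
    "rs2268491": ("C", "T"),
    "rs2268498": ("C", "T"),
    "rs53576": ("G", "A"),
}

#: risk allele per SNP (dominant carrier grouping: >=1 risk allele)
RISK_ALLELES = {
    "rs2254298": "A",
    "rs2268491": "T",
    "rs2268498": "T",
    "rs53576": "A",
}

#: approximate East-Asian risk-allele frequencies (defaults, configurable)
DEFAULT_RISK_FREQS = {
    "rs2254298": 0.50,
    "rs2268491": 0.25,
    "rs2268498": 0.45,
    "rs53576": 0.60,
}

#: ASQ item-response model: common logistic discrimination per trait point
ASQ_DISCRIMINATION = 0.35
#: latent trait defaults; SD is below the target total-score SD (5.6)
#: because binary-item noise adds ~1/discrimination to the total variance
DEFAULT_LATENT_MEAN_SD = (21.4, 5.34)

_N_ITEMS = 50


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Everything needed to simulate one cohort.

    Region index sets are (k, 3) integer voxel arrays; when left ``None``
    they default to three disjoint balls near the grid center (pattern:
    radius 4, shifted 2 voxels left; coupling seed: radius 1, 5 voxels
    anterior; coupling target: radius 2, 5 voxels right), all inside the
    grey-matter mask.
    ``pattern_strength`` of ``None`` means "calibrate so that the
    correlation between the trait and the mean true angry−neutral
    amplitude over the pattern region is ``pattern_target_r``".
    """

    n_subjects: int = 60
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 3.0
    n_runs: int = 2
    volumes_per_run: int = 173
    tr_s: float = 2.0
    noise_sd: float = 1.0
    ar1_rho: float = 0.0
    pattern_region: np.ndarray | None = None
    pattern_strength: float | None = None
    pattern_target_r: float = 0.5
    amplitude_shared_sd: float = 0.3
    amplitude_noise_sd: float = 0.5
    amplitude_noise_smooth_vox: float = 1.5
    coupling_seed_region: np.ndarray | None = None
    coupling_target_region: np.ndarray | None = None
    coupling_base_gain: float = 1.0
    coupling_slopes: dict[str, float] = field(
        default_factory=lambda: {"noncarrier": 0.5, "carrier": -0.5}
    )
    coupling_snp: str = "rs2254298"
    gain_noise_sd: float = 0.05
    seed_fluct_sd: float = 1.0
    response_amplitude: float = 1.0
    baseline: float = 100.0
    stimulus_duration_s: float = 1.0
    iti_range_s: tuple[float, float] = (2.0, 6.0)
    first_onset_s: float = 10.0
    oversampling: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.tr_s <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("tr_s and voxel_size_mm must be positive")
        if self.noise_sd < 0 or self.amplitude_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.coupling_snp not in SNP_IDS:
            raise ValueError(f"unknown SNP {self.coupling_snp!r}")

    # -- derived pieces --------------------------------------------------

    def make_grid(self) -> VolumeGrid:
        return VolumeGrid.isotropic(self.grid_shape, self.voxel_size_mm)

    def hrf(self) -> HRFModel:
        return HRFModel(tr_s=self.tr_s, oversampling=self.oversampling)

    @property
    def run_duration_s(self) -> float:
        return self.volumes_per_run * self.tr_s

    def regions(self, grid: VolumeGrid) -> dict[str, np.ndarray]:
        """Resolve (defaulting) the three ground-truth regions; validate."""
        center = np.asarray(self.grid_shape) // 2
        out = {
            "pattern": self.pattern_region,
            "coupling_seed": self.coupling_seed_region,
            "coupling_target": self.coupling_target_region,
        }
        defaults = {
            "pattern": (center - np.array([2, 0, 0]), 4),
            "coupling_seed": (center + np.array([0, 5, 0]), 1),
            "coupling_target": (center + np.array([5, 0, 0]), 2),
        }
        for name, val in out.items():
            if val is None:
                c, r = defaults[name]
                val = _ball_voxels(c, r)
            val = np.atleast_2d(np.asarray(val, dtype=int))
            if (val < 0).any() or (val >= np.asarray(self.grid_shape)).any():
                raise ValueError(f"{name} region outside grid")
            if not grid.mask[tuple(val.T)].all():
                raise ValueError(f"{name} region outside the analysis mask")
            out[name] = val
        # regions must be pairwise disjoint
        keys = list(out)
        sets = {k: {tuple(v) for v in out[k]} for k in keys}
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if sets[a] & sets[b]:
                    raise ValueError(f"regions {a} and {b} overlap")
        return out


def _ball_voxels(center: np.ndarray, radius: int) -> np.ndarray:
    rng = np.arange(-radius, radius + 1)
    ii, jj, kk = np.meshgrid(rng, rng, rng, indexing="ij")
    offs = np.stack([ii, jj, kk], -1).reshape(-1, 3)
    offs = offs[(offs**2).sum(1) <= radius**2]
    return offs + np.asarray(center)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_asq_responses(
    n: int,
    latent_mean_sd: tuple[float, float] = DEFAULT_LATENT_MEAN_SD,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw 50 binary questionnaire items per subject from a 2PL model.

    Each item j is endorsed with probability
    ``logistic(a * (theta_i - b_j))`` where theta is a latent normal trait
    on the total-score scale, the common discrimination a is
    :data:`ASQ_DISCRIMINATION` and difficulties b_j = j - 0.5 are equally
    spaced, which makes E[total | theta] ≈ theta away from the floor and
    ceiling.  ``trait_total`` is the item sum.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mu, sd = latent_mean_sd
    if sd < 0:
        raise ValueError("latent SD must be nonnegative")
    rng = np.random.default_rng(seed)
    theta = rng.normal(mu, sd, size=n)
    b = np.arange(1, _N_ITEMS + 1) - 0.5
    prob = 1.0 / (1.0 + np.exp(-ASQ_DISCRIMINATION * (theta[:, None] - b[None, :])))
    items = (rng.random((n, _N_ITEMS)) < prob).astype(int)
    df = pd.DataFrame(items, columns=[f"item_{j:02d}" for j in range(1, _N_ITEMS + 1)])
    df.insert(0, "asq_total", score_asq(items))
    df["latent_trait"] = theta
    return df


def score_asq(item_responses: np.ndarray) -> np.ndarray:
    """Total ASQ score: the sum of the 50 binary item indicators."""
    items = np.atleast_2d(np.asarray(item_responses))
    if items.shape[-1] != _N_ITEMS:
        raise ValueError(f"expected {_N_ITEMS} items, got {items.shape[-1]}")
    if not np.isin(items, (0, 1)).all():
        raise ValueError("item responses must be binary")
    return items.sum(axis=-1)


def simulate_genotypes(
    n: int,
    allele_freqs: dict[str, float] | None = None,
    risk_alleles: dict[str, str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw genotypes at Hardy–Weinberg proportions; add carrier flags.

    ``allele_freqs`` gives the risk-allele frequency per SNP; each subject
    receives two independent alleles, so genotype classes appear with
    probabilities p^2, 2pq, q^2.  ``carrier_<snp>`` is 1 iff the subject
    holds at least one risk allele (dominant grouping).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    freqs = dict(DEFAULT_RISK_FREQS)
    if allele_freqs:
        freqs.update(allele_freqs)
    risks = dict(RISK_ALLELES)
    if risk_alleles:
        risks.update(risk_alleles)
    for snp, f in freqs.items():
        if not 0.0 < f <= 1.0:
            raise ValueError(f"{snp}: allele frequency must be in (0, 1]")
    rng = np.random.default_rng(seed)
    out = {}
    for snp in SNP_IDS:
        major, minor = SNP_ALLELES[snp]
        risk = risks[snp]
        n_risk = rng.binomial(2, freqs[snp], size=n)
        other = major if risk != major else minor
        geno = np.array(
            ["".join(sorted(other * (2 - k) + risk * k)) for k in n_risk]
        )
        out[f"genotype_{snp}"] = geno
        out[f"carrier_{snp}"] = (n_risk >= 1).astype(int)
    return pd.DataFrame(out)


def simulate_phenotypes(
    n: int,
    latent_mean_sd: tuple[float, float] = DEFAULT_LATENT_MEAN_SD,
    allele_freqs: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full phenotype table: id, ASQ items + total, genotypes, sex, age."""
    rng = np.random.default_rng(seed)
    asq = simulate_asq_responses(n, latent_mean_sd, seed=rng.integers(2**31))
    geno = simulate_genotypes(n, allele_freqs, seed=rng.integers(2**31))
    demo = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "sex": rng.choice(["M", "F"], size=n),
            "age": np.round(np.clip(rng.normal(21.6, 2.3, size=n), 17, 29), 1),
        }
    )
    return pd.concat([demo, asq, geno], axis=1)


# ---------------------------------------------------------------------------
# event schedule
# ---------------------------------------------------------------------------


def build_event_schedule(spec: CohortSpec, seed: int | None = None) -> EventSchedule:
    """Pseudorandom per-run schedules: each stimulus once per run.

    Ten stimuli per condition (50 per run); order is an independent random
    permutation per run; inter-trial intervals are drawn uniformly from
    ``spec.iti_range_s``.
    """
    if seed is None:
        seed = spec.rng_seed
    rng = np.random.default_rng([seed, 11])
    stimuli = [(c, f"{c}_{j:02d}") for c in CONDITIONS for j in range(1, 11)]
    hrf_support = 32.0
    runs = []
    prev_order: np.ndarray | None = None
    for r in range(spec.n_runs):
        order = rng.permutation(len(stimuli))
        if prev_order is not None and np.array_equal(order, prev_order):
            order = rng.permutation(len(stimuli))
        prev_order = order
        itis = rng.uniform(*spec.iti_range_s, size=len(stimuli) - 1)
        onsets = spec.first_onset_s + np.concatenate([[0.0], np.cumsum(itis)])
        if onsets[-1] + hrf_support > spec.run_duration_s:
            raise ValueError(
                f"run of {spec.run_duration_s:.0f} s too short for schedule "
                f"ending at {onsets[-1]:.0f} s (+{hrf_support:.0f} s response)"
            )
        rows = [
            {
                "onset": float(t),
                "duration": spec.stimulus_duration_s,
                "trial_type": stimuli[k][0],
                "stimulus_id": stimuli[k][1],
            }
            for t, k in zip(onsets, order)
        ]
        runs.append(pd.DataFrame(rows))
    return EventSchedule(runs=runs)


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------


def _region_mean_noise_var(region_ijk: np.ndarray, smooth_vox: float) -> float:
    """Variance of the regional mean of a unit-variance smoothed field.

    A Gaussian-filtered (sigma = smooth_vox) unit-variance field has
    spatial autocorrelation rho(d) = exp(-d^2 / (4 sigma^2)); the regional
    mean's variance is the average pairwise correlation.
    """
    region_ijk = np.asarray(region_ijk, dtype=float)
    if smooth_vox <= 0:
        return 1.0 / len(region_ijk)
    d2 = ((region_ijk[:, None, :] - region_ijk[None, :, :]) ** 2).sum(-1)
    return float(np.exp(-d2 / (4.0 * smooth_vox**2)).mean())


def calibrate_pattern_strength(
    target_r: float,
    amplitude_shared_sd: float,
    amplitude_noise_sd: float,
    region_ijk: np.ndarray | int,
    smooth_vox: float = 0.0,
    mean_weight: float = 1.0,
) -> float:
    """Trait→amplitude slope giving correlation ``target_r`` between the
    standardized trait and the mean true angry−neutral amplitude.

    Between-subject amplitude variability has a shared (global gain)
    component sigma_s that survives averaging over the region and a
    voxel-local, spatially smooth component sigma_a whose regional mean
    retains variance sigma_a^2 * rho_bar (rho_bar = average pairwise
    autocorrelation; 1/|R| for unsmoothed noise).  The slope solving
    corr(trait, regional mean) = r is
    ``s = sqrt(sigma_s^2 + sigma_a^2 rho_bar) * r/sqrt(1-r^2) / w_bar``.
    """
    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")
    if isinstance(region_ijk, (int, np.integer)):
        rho_bar = 1.0 / int(region_ijk)
    else:
        rho_bar = _region_mean_noise_var(region_ijk, smooth_vox)
    noise = np.sqrt(amplitude_shared_sd**2 + amplitude_noise_sd**2 * rho_bar)
    return float(noise * target_r / np.sqrt(1 - target_r**2) / mean_weight)


def _smooth_mask_noise(
    rng: np.random.Generator,
    n: int,
    grid: VolumeGrid,
    sd: float,
    smooth_vox: float,
) -> np.ndarray:
    """Per-subject spatially smooth noise over all in-mask voxels.

    Spatial correlation emulates the smoothness of preprocessed beta maps;
    the field is normalized so every voxel has marginal SD ``sd``.
    """
    from scipy import ndimage

    if smooth_vox <= 0:
        return rng.normal(0.0, sd, size=(n, grid.n_voxels))
    delta = np.zeros((25, 25, 25))
    delta[12, 12, 12] = 1.0
    norm = np.sqrt((ndimage.gaussian_filter(delta, smooth_vox) ** 2).sum())
    out = np.empty((n, grid.n_voxels))
    for i in range(n):
        field = ndimage.gaussian_filter(rng.normal(size=grid.shape), smooth_vox)
        out[i] = field[grid.mask] * (sd / norm)
    return out


@dataclass
class GroundTruth:
    """Recovery targets stored alongside every simulated cohort."""

    regions: dict[str, np.ndarray]
    pattern_weights: np.ndarray
    pattern_strength: float
    trait_z: np.ndarray
    true_amplitude: np.ndarray  # (n_subjects, |pattern|) angry-neutral deltas
    coupling_gains: np.ndarray  # (n_subjects, 5) per-condition seed->target gain
    coupling_groups: np.ndarray  # "carrier"/"noncarrier" per subject
    coupling_slopes: dict[str, float]
    coupling_snp: str

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regions": {k: v.tolist() for k, v in self.regions.items()},
            "pattern_weights": self.pattern_weights.tolist(),
            "pattern_strength": self.pattern_strength,
            "trait_z": self.trait_z.tolist(),
            "true_amplitude": self.true_amplitude.tolist(),
            "coupling_gains": self.coupling_gains.tolist(),
            "coupling_groups": self.coupling_groups.tolist(),
            "coupling_slopes": self.coupling_slopes,
            "coupling_snp": self.coupling_snp,
            "conditions": list(CONDITIONS),
        }
        Path(path).write_text(json.dumps(payload))


class BoldCohort:
    """Lazy per-subject BOLD access for a simulated cohort.

    ``subject(i)`` regenerates subject i's concatenated-run time series
    (n_scans_total, n_mask_voxels) deterministically from the cohort seed.
    """

    def __init__(self, spec: CohortSpec, phenotypes: pd.DataFrame,
                 schedule: EventSchedule, grid: VolumeGrid,
                 truth: GroundTruth, angry_amplitude: np.ndarray) -> None:
        self.spec = spec
        self.phenotypes = phenotypes
        self.schedule = schedule
        self.grid = grid
        self.truth = truth
        # (n_subjects, n_mask_voxels) subject-specific angry-neutral deltas
        self.angry_amplitude = angry_amplitude
        self._prepare()

    # -- shared (subject-independent) pieces -----------------------------

    def _prepare(self) -> None:
        spec, grid = self.spec, self.grid
        hrf = spec.hrf()
        kernel = canonical_hrf(hrf)
        os_ = spec.oversampling
        ns = spec.volumes_per_run
        n_fine = ns * os_
        flat = grid.flat_index_volume()
        self._region_idx = {
            k: flat[tuple(v.T)] for k, v in self.truth.regions.items()
        }
        self.n_scans_total = ns * spec.n_runs
        # per run: fine-grid stick trains, condition indicators, convolved columns
        self._conv_cond = []  # list over runs of dict cond -> (ns,) regressor
        self._seed_stick = []  # (n_fine,) all-condition stick train per run
        self._indicator = []  # dict cond -> (n_fine,) boxcar indicator per run
        for r in range(spec.n_runs):
            ev = self.schedule.runs[r]
            conv_r, ind_r = {}, {}
            stick_all = np.zeros(n_fine)
            for cond in CONDITIONS:
                sel = ev[ev["trial_type"] == cond]
                train = np.zeros(n_fine)
                ind = np.zeros(n_fine)
                for onset, dur in zip(sel["onset"], sel["duration"]):
                    i0 = int(round(onset / hrf.dt))
                    train[i0] += 1.0
                    i1 = min(n_fine, i0 + max(1, int(round(dur / hrf.dt))))
                    ind[i0:i1] = 1.0
                conv_r[cond] = np.convolve(train, kernel)[:n_fine][::os_]
                ind_r[cond] = ind
                stick_all += train
            self._conv_cond.append(conv_r)
            self._seed_stick.append(stick_all)
            self._indicator.append(ind_r)
        self._kernel = kernel
        self._os = os_
        self._n_fine = n_fine
        # smoothing kernel for seed neural fluctuations (~1.5 s gaussian)
        tg = np.arange(-4.5, 4.5 + hrf.dt, hrf.dt)
        g = np.exp(-0.5 * (tg / 1.5) ** 2)
        self._fluct_kernel = g / np.sqrt((g**2).sum())

    # -- per-subject synthesis -------------------------------------------

    def _rng(self, i: int, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.spec.rng_seed, 997, i, stream])

    def subject(self, i: int) -> np.ndarray:
        """(n_scans_total, n_mask_voxels) BOLD for subject i."""
        spec = self.spec
        nvox = self.grid.n_voxels
        ns = spec.volumes_per_run
        rng = self._rng(i, 0)
        seed_idx = self._region_idx["coupling_seed"]
        tgt_idx = self._region_idx["coupling_target"]
        delta = self.angry_amplitude[i]  # (n_vox,) angry-neutral amplitude
        gains = self.truth.coupling_gains[i]  # (5,)
        runs = []
        for r in range(spec.n_runs):
            y = np.zeros((ns, nvox))
            # generic evoked response in every mask voxel, all conditions
            for cond in CONDITIONS:
                y += spec.response_amplitude * self._conv_cond[r][cond][:, None]
            # subject-specific angry amplitude (smooth field + trait pattern)
            y += np.outer(self._conv_cond[r]["angry"], delta)
            # seed neural series: evoked sticks + smooth spontaneous drive
            fl = rng.normal(size=self._n_fine + self._fluct_kernel.size - 1)
            fl = np.convolve(fl, self._fluct_kernel, mode="valid")
            neural = spec.response_amplitude * self._seed_stick[r] + spec.seed_fluct_sd * fl
            seed_bold = np.convolve(neural, self._kernel)[: self._n_fine][:: self._os]
            y[:, seed_idx] = spec.baseline + seed_bold[:, None]
            # condition-specific seed->target coupling
            ppi_bold = np.zeros(ns)
            for c, cond in enumerate(CONDITIONS):
                drive = neural * self._indicator[r][cond]
                ppi_bold = ppi_bold + gains[c] * (
                    np.convolve(drive, self._kernel)[: self._n_fine][:: self._os]
                )
            y[:, tgt_idx] += ppi_bold[:, None]
            y[:, self._mask_except(seed_idx)] += spec.baseline
            # scan noise
            if spec.noise_sd > 0:
                eps = rng.normal(0.0, spec.noise_sd, size=(ns, nvox))
                if spec.ar1_rho:
                    rho = spec.ar1_rho
                    for t in range(1, ns):
                        eps[t] = rho * eps[t - 1] + np.sqrt(1 - rho**2) * eps[t]
                y += eps
            runs.append(y)
        return np.vstack(runs)

    def _mask_except(self, idx: np.ndarray) -> np.ndarray:
        keep = np.ones(self.grid.n_voxels, dtype=bool)
        keep[idx] = False
        return np.where(keep)[0]

    def subject_volume(self, i: int) -> np.ndarray:
        """Subject i as an (x, y, z, t) volume (zeros outside the mask)."""
        flat = self.subject(i)
        vol = np.zeros(self.grid.shape + (self.n_scans_total,))
        vol[self.grid.mask] = flat.T
        return vol

    def motion(self, i: int) -> list[np.ndarray]:
        """Per-run (n_scans, 6) nuisance movement parameters (random walks)."""
        rng = self._rng(i, 1)
        out = []
        for _ in range(self.spec.n_runs):
            steps = rng.normal(0.0, 0.02, size=(self.spec.volumes_per_run, 6))
            out.append(np.cumsum(steps, axis=0))
        return out


def simulate_cohort_bold(
    phenotypes: pd.DataFrame, schedule: EventSchedule, spec: CohortSpec
) -> tuple[BoldCohort, GroundTruth]:
    """Synthesize the cohort's BOLD generator and its ground truth.

    The model per voxel and scan is
    ``baseline + sum_c amplitude_c * (HRF ⊛ stick_c) + noise``; pattern-
    region voxels add a trait-scaled angry amplitude, coupling-target
    voxels add condition-gated seed drive (see the class docstrings).
    """
    spec_n = spec.n_subjects
    if len(phenotypes) != spec_n:
        raise ValueError("phenotype row count != spec.n_subjects")
    grid = spec.make_grid()
    regions = spec.regions(grid)
    rng = np.random.default_rng([spec.rng_seed, 23])

    asq = phenotypes["asq_total"].to_numpy(dtype=float)
    sd = asq.std()
    z = (asq - asq.mean()) / sd if sd > 0 else np.zeros_like(asq)

    n_pat = len(regions["pattern"])
    weights = rng.normal(1.0, 0.25, size=n_pat)
    strength = spec.pattern_strength
    if strength is None:
        strength = calibrate_pattern_strength(
            spec.pattern_target_r, spec.amplitude_shared_sd,
            spec.amplitude_noise_sd, regions["pattern"],
            spec.amplitude_noise_smooth_vox,
        )
    shared = rng.normal(0.0, spec.amplitude_shared_sd, size=spec_n)
    # smooth subject-level angry-amplitude variability over the whole mask;
    # the trait-scaled pattern sits on top of it inside the region
    amp_fields = _smooth_mask_noise(
        rng, spec_n, grid, spec.amplitude_noise_sd,
        spec.amplitude_noise_smooth_vox,
    )
    flat = grid.flat_index_volume()
    pat_cols = flat[tuple(regions["pattern"].T)]
    true_amp = np.outer(strength * z + shared, weights) + amp_fields[:, pat_cols]

    carrier = phenotypes[f"carrier_{spec.coupling_snp}"].to_numpy()
    groups = np.where(carrier == 1, "carrier", "noncarrier")
    slopes = np.array([spec.coupling_slopes[g] for g in groups])
    gains = np.full((spec_n, len(CONDITIONS)), spec.coupling_base_gain)
    angry_col = CONDITIONS.index("angry")
    gains[:, angry_col] += slopes * z
    if spec.gain_noise_sd > 0:
        gains[:, angry_col] += rng.normal(0.0, spec.gain_noise_sd, size=spec_n)

    delta_all = amp_fields
    delta_all[:, pat_cols] += np.outer(strength * z + shared, weights)

    truth = GroundTruth(
        regions=regions,
        pattern_weights=weights,
        pattern_strength=float(strength),
        trait_z=z,
        true_amplitude=true_amp,
        coupling_gains=gains,
        coupling_groups=groups,
        coupling_slopes=dict(spec.coupling_slopes),
        coupling_snp=spec.coupling_snp,
    )
    cohort = BoldCohort(spec, phenotypes, schedule, grid, truth,
                        angry_amplitude=delta_all)
    return cohort, truth


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

DEFAULT_BEHAVIOR_EFFECTS = {
    # sex-discrimination accuracy decrement / RT increment for negative faces
    "angry": (-0.05, 0.03),
    "fear": (-0.05, 0.03),
    "sad": (-0.05, 0.03),
    "happy": (0.0, 0.0),
    "neutral": (0.0, 0.0),
}


def simulate_behavior(
    phenotypes: pd.DataFrame,
    effect_spec: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    base_accuracy: float = 0.95,
    base_rt_s: float = 0.65,
) -> pd.DataFrame:
    """Per-subject, per-condition accuracy and reaction time.

    ``effect_spec`` maps condition -> (accuracy offset, RT offset in s)
    relative to the base levels; subjects get random intercepts on both
    measures.  Accuracies are clipped to [0, 1]; RTs are strictly positive.
    """
    effects = dict(DEFAULT_BEHAVIOR_EFFECTS)
    if effect_spec:
        effects.update(effect_spec)
    for cond, (da, _) in effects.items():
        if not 0.0 <= base_accuracy + da <= 1.0:
            raise ValueError(f"{cond}: mean accuracy outside [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(phenotypes)
    acc_int = rng.normal(0.0, 0.04, size=n)
    rt_int = rng.normal(0.0, 0.08, size=n)
    rows = []
    for i in range(n):
        for cond in CONDITIONS:
            da, drt = effects[cond]
            acc = base_accuracy + da + acc_int[i] + rng.normal(0.0, 0.03)
            rt = base_rt_s + drt + rt_int[i] + rng.normal(0.0, 0.05)
            rows.append(
                {
                    "subject_id": phenotypes["subject_id"].iloc[i]
                    if "subject_id" in phenotypes
                    else f"sub-{i + 1:03d}",
                    "condition": cond,
                    "accuracy": float(np.clip(acc, 0.0, 1.0)),
                    "rt_s": float(max(rt, 0.15)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort export
# ---------------------------------------------------------------------------


def write_cohort(
    out_dir: str | Path,
    spec: CohortSpec,
    phenotypes: pd.DataFrame,
    schedule: EventSchedule,
    cohort: BoldCohort,
    truth: GroundTruth,
) -> None:
    """Write a BIDS-like tree: participants.tsv, events, NIfTI BOLD, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    keep = ["subject_id", "asq_total", "sex", "age"] + [
        f"genotype_{s}" for s in SNP_IDS
    ] + [f"carrier_{s}" for s in SNP_IDS]
    phenotypes[keep].to_csv(out / "participants.tsv", sep="\t", index=False)
    schedule.to_tsv(out, prefix="task")
    truth.to_json(out / "ground_truth.json")
    ns = spec.volumes_per_run
    for i in range(spec.n_subjects):
        sub = phenotypes["subject_id"].iloc[i]
        vol = cohort.subject_volume(i)
        for r in range(spec.n_runs):
            img = cohort.grid.to_nifti(vol[..., r * ns : (r + 1) * ns])
            img.to_filename(str(out / f"{sub}_run-{r + 1:02d}_bold.nii"))
        np.savetxt(
            out / f"{sub}_motion.tsv",
            np.vstack(cohort.motion(i)),
            delimiter="\t",
            fmt="%.6f",
        )
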