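"""End-to-end orchestration: cohort -> contrasts -> searchlight / gPPI -> group.

These helpers wire the stage modules together with the defaults used
throughout the documentation and the reproduction script; every stage can
also be driven directly through its own module API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    BoldCohort,
    CohortSpec,
    GroundTruth,
    build_event_schedule,
    simulate_cohort_bold,
    simulate_phenotypes,
)
from .glm import HRFModel, build_design_matrix, contrast_map, fit_glm
from .gppi import (
    SeedSpec,
    build_gppi_design,
    deconvolve_neural,
    extract_seed_timeseries,
    ppi_coupling_map,
)
from .grid import VolumeGrid
from .group import (
    build_interaction_design,
    extract_cluster_estimates,
    group_slope_report,
    interaction_tmap,
    label_clusters,
    permutation_fwe,
)
from .searchlight import PredictionMap, SearchlightSpec, searchlight_predict
from .task import EventSchedule

__all__ = [
    "SimulatedCohort",
    "simulate_cohort",
    "first_level_contrasts",
    "run_searchlight",
    "gppi_coupling_maps",
    "default_seed_spec",
    "run_group_interaction",
]


@dataclass
class SimulatedCohort:
    """A fully simulated cohort with ground truth, ready for analysis."""

    spec: CohortSpec
    phenotypes: pd.DataFrame
    schedule: EventSchedule
    bold: BoldCohort = field(repr=False)
    truth: GroundTruth = field(repr=False)

    @property
    def grid(self) -> VolumeGrid:
        return self.bold.grid

    @property
    def traits(self) -> np.ndarray:
        return self.phenotypes["asq_total"].to_numpy(dtype=float)


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Phenotypes + schedule + BOLD generator from one cohort spec."""
    phenos = simulate_phenotypes(spec.n_subjects, seed=spec.rng_seed)
    schedule = build_event_schedule(spec)
    bold, truth = simulate_cohort_bold(phenos, schedule, spec)
    return SimulatedCohort(spec=spec, phenotypes=phenos, schedule=schedule,
                           bold=bold, truth=truth)


def first_level_contrasts(
    cohort: SimulatedCohort,
    positive: str = "angry",
    negative: str = "neutral",
    include_motion: bool = True,
) -> np.ndarray:
    """Per-subject contrast maps, (n_subjects, n_mask_voxels)."""
    spec = cohort.spec
    hrf = spec.hrf()
    out = np.empty((spec.n_subjects, cohort.grid.n_voxels))
    for i in range(spec.n_subjects):
        motion = cohort.bold.motion(i) if include_motion else None
        X = build_design_matrix(cohort.schedule, spec.volumes_per_run, hrf, motion)
        betas = fit_glm(cohort.bold.subject(i), X)
        out[i] = contrast_map(betas, X.condition_weights(positive, negative))
    return out


def run_searchlight(
    cohort: SimulatedCohort,
    maps: np.ndarray | None = None,
    spec: SearchlightSpec = SearchlightSpec(),
    positive: str = "angry",
    negative: str = "neutral",
) -> PredictionMap:
    """Searchlight decoding of the trait from contrast maps."""
    if maps is None:
        maps = first_level_contrasts(cohort, positive, negative)
    pm = searchlight_predict(maps, cohort.traits, cohort.grid, spec)
    pm.contrast = f"{positive}>{negative}"
    return pm


def default_seed_spec(cohort: SimulatedCohort, radius_mm: float = 6.0) -> SeedSpec:
    """Seed sphere at the centroid of the ground-truth coupling seed region.

    In a real analysis the seed sits at the peak coordinate of a
    significant searchlight cluster; on synthetic data the injected seed
    region plays that role.
    """
    ijk = cohort.truth.regions["coupling_seed"]
    center = cohort.grid.voxel_to_mm(ijk.mean(axis=0))[0]
    return SeedSpec(name="truth_seed", center_mm=tuple(center), radius_mm=radius_mm)


def gppi_coupling_maps(
    cohort: SimulatedCohort,
    seed: SeedSpec | None = None,
    ridge_lambda: float = 1e-2,
    deconv_oversampling: int = 1,
    include_motion: bool = True,
) -> np.ndarray:
    """Per-subject gPPI coupling maps (angry PPI − neutral PPI)."""
    spec = cohort.spec
    if seed is None:
        seed = default_seed_spec(cohort)
    hrf = HRFModel(tr_s=spec.tr_s, oversampling=deconv_oversampling)
    ns = spec.volumes_per_run
    out = np.empty((spec.n_subjects, cohort.grid.n_voxels))
    for i in range(spec.n_subjects):
        bold = cohort.bold.subject(i)
        runs = [bold[r * ns : (r + 1) * ns] for r in range(spec.n_runs)]
        seed_series = [extract_seed_timeseries(b, cohort.grid, seed) for b in runs]
        neural = [deconvolve_neural(s, hrf, ridge_lambda) for s in seed_series]
        motion = cohort.bold.motion(i) if include_motion else None
        design = build_gppi_design(neural, cohort.schedule, hrf, motion, seed_series)
        cm = ppi_coupling_map(bold, design, subject_id=str(i), seed_name=seed.name)
        out[i] = cm.values
    return out


def run_group_interaction(
    coupling: np.ndarray,
    phenotypes: pd.DataFrame,
    grid: VolumeGrid,
    snp: str = "rs2254298",
    alpha: float = 0.05,
    min_k: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    bonferroni_contrasts: int = 3,
    bonferroni_snps: int = 8,
) -> dict:
    """Genotype x trait interaction test with permutation FWE + clusters.

    Returns a dict with the stat map, FWE-corrected p values, the cluster
    table (p_corrected = min(1, 3 * p_fwe) across tested emotions) and a
    per-cluster slope report (Bonferroni x8 across the SNP/allele family).
    """
    carriers = phenotypes[f"carrier_{snp}"].to_numpy()
    traits = phenotypes["asq_total"].to_numpy(dtype=float)
    design = build_interaction_design(carriers, traits)
    smap = interaction_tmap(coupling, design)
    smap.p_fwe = permutation_fwe(coupling, design, n_perm=n_perm, seed=seed)
    sig = smap.p_fwe < alpha
    t_vol = grid.unmask(smap.t)
    clusters = label_clusters(grid.unmask(sig.astype(float)) == 1.0, min_k=min_k,
                              stat=t_vol, grid=grid)
    flat = grid.flat_index_volume()
    labels_vol = None
    reports = []
    if len(clusters):
        from scipy import ndimage

        structure = ndimage.generate_binary_structure(3, 2)
        labels_vol, _ = ndimage.label(grid.unmask(sig.astype(float)) == 1.0,
                                      structure=structure)
        p_fwe_vol = grid.unmask(smap.p_fwe)
        rows = []
        for _, row in clusters.iterrows():
            members = np.argwhere(labels_vol == row["cluster_id"])
            idx = flat[tuple(members.T)]
            peak_pfwe = float(p_fwe_vol[int(row.peak_i), int(row.peak_j), int(row.peak_k)])
            est = extract_cluster_estimates(coupling, idx)
            rep = group_slope_report(est, traits, carriers, m=bonferroni_snps)
            rep["cluster_id"] = int(row["cluster_id"])
            reports.append(rep)
            rows.append({**row.to_dict(),
                         "p_fwe": peak_pfwe,
                         "p_corrected": min(1.0, bonferroni_contrasts * peak_pfwe)})
        clusters = pd.DataFrame(rows)
    return {
        "design": design,
        "stat_map": smap,
        "significant": sig,
        "clusters": clusters,
        "slope_reports": reports,
    }
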