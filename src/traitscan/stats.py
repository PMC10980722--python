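"""Shared statistical primitives.

Hardy–Weinberg genotype QC, Pearson correlation tests, Bonferroni
correction, one-way repeated-measures ANOVA with partial eta squared, and
the power computations behind the cohort sample-size claim (>90% power for
medium effects in every test family used downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GenotypeCounts",
    "AnovaResult",
    "hwe_test",
    "bonferroni",
    "pearson_test",
    "rm_anova",
    "posthoc_bonferroni",
    "min_power",
    "power_correlation",
    "power_two_sample_t",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts for one biallelic SNP."""

    hom_major: int
    het: int
    hom_minor: int

    def __post_init__(self) -> None:
        for v in (self.hom_major, self.het, self.hom_minor):
            if v < 0 or v != int(v):
                raise ValueError("genotype counts must be nonnegative integers")
        if self.n == 0:
            raise ValueError("all-zero genotype counts")

    @property
    def n(self) -> int:
        return self.hom_major + self.het + self.hom_minor


@dataclass(frozen=True)
class AnovaResult:
    """One-way repeated-measures ANOVA summary."""

    F: float
    df_effect: int
    df_error: int
    p: float
    eta_sq_partial: float


def hwe_test(counts: GenotypeCounts | tuple[int, int, int]) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test of Hardy–Weinberg equilibrium.

    The expected genotype proportions are p^2, 2pq, q^2 with the allele
    frequency estimated from the observed counts.  One degree of freedom:
    three classes minus one estimated allele frequency minus one.

    Returns
    -------
    (chi2, p) : floats
    """
    if not isinstance(counts, GenotypeCounts):
        counts = GenotypeCounts(*counts)
    n = counts.n
    p_hat = (2 * counts.hom_major + counts.het) / (2 * n)
    q_hat = 1.0 - p_hat
    expected = np.array([p_hat**2, 2 * p_hat * q_hat, q_hat**2]) * n
    observed = np.array([counts.hom_major, counts.het, counts.hom_minor], dtype=float)
    # monomorphic sample: expected het/minor classes are zero and match observed
    keep = expected > 0
    chi2 = float(((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum())
    return chi2, float(sps.chi2.sf(chi2, df=1))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p value: min(1, m * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1 or m != int(m):
        raise ValueError("m must be a positive integer")
    return min(1.0, m * p)


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t transform.

    p is computed from t = r sqrt((n-2)/(1-r^2)) against t with n-2 df,
    which is what ``scipy.stats.pearsonr`` evaluates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def rm_anova(data: np.ndarray) -> AnovaResult:
    """One-way within-subject (repeated-measures) ANOVA.

    Parameters
    ----------
    data : (n_subjects, n_conditions) ndarray
        Complete table, one within-subject factor.

    Notes
    -----
    Sum-of-squares decomposition SS_total = SS_subjects + SS_condition +
    SS_error; F = MS_condition / MS_error with (c-1, (c-1)(n-1)) df; the
    reported effect size is partial eta squared
    SS_condition / (SS_condition + SS_error).  No sphericity correction is
    applied (uncorrected dfs are the convention emulated here).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("data must be (>=2 subjects, >=2 conditions)")
    if not np.isfinite(data).all():
        raise ValueError("missing or non-finite cells")
    n, c = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    ss_subj = c * ((subj_means - grand) ** 2).sum()
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_cond
    df_effect = c - 1
    df_error = (c - 1) * (n - 1)
    ms_cond = ss_cond / df_effect
    ms_err = ss_err / df_error
    if ms_err <= 0:
        F = 0.0 if ss_cond == 0 else np.inf
    else:
        F = ms_cond / ms_err
    p = float(sps.f.sf(F, df_effect, df_error)) if np.isfinite(F) else 0.0
    eta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return AnovaResult(F=float(F), df_effect=df_effect, df_error=df_error, p=p,
                       eta_sq_partial=float(eta))


def posthoc_bonferroni(data: np.ndarray, labels: list[str] | None = None) -> list[dict]:
    """All pairwise paired t tests, Bonferroni-corrected by the pair count."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("data must be (>=2 subjects, >=2 conditions)")
    if not np.isfinite(data).all():
        raise ValueError("missing or non-finite cells")
    c = data.shape[1]
    if labels is None:
        labels = [f"cond{j}" for j in range(c)]
    pairs = [(a, b) for a in range(c) for b in range(a + 1, c)]
    m = len(pairs)
    out = []
    for a, b in pairs:
        diff = data[:, a] - data[:, b]
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(data[:, a], data[:, b])
        out.append({
            "pair": (labels[a], labels[b]),
            "t": float(t),
            "p": float(p),
            "p_corrected": bonferroni(float(p), m),
        })
    return out


def power_correlation(n: int, r: float = 0.3, alpha: float = 0.05) -> float:
    """Two-sided power of the Pearson correlation test (Fisher-z approximation)."""
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z_alpha = sps.norm.isf(alpha / 2)
    delta = np.arctanh(r) * np.sqrt(n - 3)
    return float(sps.norm.sf(z_alpha - delta) + sps.norm.cdf(-z_alpha - delta))


def power_two_sample_t(n1: int, n2: int, d: float = 0.5, alpha: float = 0.05) -> float:
    """Two-sided power of the independent-samples t test (noncentral t)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    t_crit = sps.t.isf(alpha / 2, df)
    return float(sps.nct.sf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp))


def min_power(
    n_total: int,
    group_sizes: tuple[int, int],
    alpha: float = 0.05,
    r: float = 0.3,
    d: float = 0.5,
) -> float:
    """Minimum achieved power over the study's test families.

    The two families bounding every test used in the pipeline are the
    Pearson correlation on the full sample (medium effect r = 0.3) and the
    independent-samples t test on the two subgroups (medium effect
    d = 0.5); both at two-sided ``alpha``.
    """
    if sum(group_sizes) > n_total:
        raise ValueError("group sizes exceed total n")
    return min(
        power_correlation(n_total, r=r, alpha=alpha),
        power_two_sample_t(group_sizes[0], group_sizes[1], d=d, alpha=alpha),
    )
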