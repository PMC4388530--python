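"""Velocity-distribution summaries and stage comparisons.

A sample's motility is summarized over its individual frame-to-frame
velocity vectors (not per-track means): mean +/- SEM and the vector count.
Growth stages (before / during / after the diauxic shift, onset of
sporulation) are compared with the two-sided Mann-Whitney U test, since
swimming-speed distributions are typically non-normal; normality itself is
screened with the Shapiro-Wilk, Anderson-Darling and Cramer-von-Mises
tests against the normal family with estimated mean and sd.  The motile
fraction of a sample set is the unweighted mean percentage of moving cells
with its sample standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad


@dataclass
class StageSummary:
    label: str
    mean_velocity: float    # um/s
    sem: float              # um/s
    n_vectors: int

    def to_dict(self) -> dict:
        return {"label": self.label, "mean_velocity": self.mean_velocity,
                "sem": self.sem, "n_vectors": self.n_vectors}


@dataclass
class StageComparison:
    labels: tuple[str, str]
    u_statistic: float
    p_value: float
    test: str = "mann-whitney-u two-sided"


def summarize_stage(velocities, label: str = "") -> StageSummary:
    """Mean, SEM (sd/sqrt(n)) and n of a stage's velocity vectors."""
    v = np.asarray(velocities, float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty velocity sample")
    sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
    return StageSummary(label=label, mean_velocity=float(v.mean()),
                        sem=sem, n_vectors=int(v.size))


def compare_stages(v1, v2, labels: tuple[str, str] = ("a", "b")
                   ) -> StageComparison:
    """Two-sided Mann-Whitney U test between two velocity samples.

    Uses the exact null distribution when the combined sample size is at
    most 20 (and no ties), the tie-corrected normal approximation with
    continuity correction otherwise.
    """
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    if v1.size == 0 or v2.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if v1.size + v2.size <= 20 else "asymptotic"
    if method == "exact" and np.union1d(v1, v2).size < v1.size + v2.size:
        method = "asymptotic"   # ties: exact null unavailable
    res = stats.mannwhitneyu(v1, v2, alternative="two-sided", method=method)
    return StageComparison(labels=labels, u_statistic=float(res.statistic),
                           p_value=float(res.pvalue))


def _cvm_normality(v: np.ndarray) -> tuple[float, float]:
    """Cramer-von-Mises test against the normal family (estimated params).

    Statistic W^2 from the probability-integral transform of the sorted
    sample; p-value from the small-sample-modified statistic via the
    standard piecewise-exponential approximation used for the composite
    normal hypothesis.
    """
    n = v.size
    z = (np.sort(v) - v.mean()) / v.std(ddof=1)
    p = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    w2 = 1.0 / (12 * n) + np.sum((p - (2 * i - 1) / (2 * n)) ** 2)
    ww = w2 * (1.0 + 0.5 / n)
    if ww < 0.0275:
        pval = 1 - math.exp(-13.953 + 775.5 * ww - 12542.61 * ww ** 2)
    elif ww < 0.051:
        pval = 1 - math.exp(-5.903 + 179.546 * ww - 1515.29 * ww ** 2)
    elif ww < 0.092:
        pval = math.exp(0.886 - 31.62 * ww + 10.897 * ww ** 2)
    elif ww < 1.1:
        pval = math.exp(1.111 - 34.242 * ww + 12.832 * ww ** 2)
    else:
        pval = 7.37e-10
    return float(w2), float(min(max(pval, 0.0), 1.0))


def normality_tests(v) -> dict[str, tuple[float, float]]:
    """Shapiro-Wilk, Anderson-Darling and Cramer-von-Mises normality tests.

    All three test the composite hypothesis that the data come from some
    normal distribution (mean and sd estimated).  Returns
    {test_name: (statistic, p_value)}.  Requires n >= 8; the tests are
    unreliable below that.
    """
    v = np.asarray(v, float)
    if v.size < 8:
        raise ValueError("normality tests need at least 8 observations")
    sw_stat, sw_p = stats.shapiro(v)
    ad_stat, ad_p = normal_ad(v)
    cvm_stat, cvm_p = _cvm_normality(v)
    return {"shapiro_wilk": (float(sw_stat), float(sw_p)),
            "anderson_darling": (float(ad_stat), float(ad_p)),
            "cramer_von_mises": (cvm_stat, cvm_p)}


def velocity_histogram(v, bin_width: float = 5.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of individual velocities with half-open bins [lo, hi).

    Bins cover [0, max(v)] in steps of ``bin_width``; a value exactly on
    an edge falls in the upper bin, and the counts sum to n.  An empty
    input yields an empty histogram.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = np.asarray(v, float)
    if v.size == 0:
        return np.array([0.0]), np.array([], dtype=int)
    n_bins = int(math.floor(v.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.floor(v / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return edges, counts


def motile_fraction(counts: list[tuple[int, int]]) -> tuple[float, float]:
    """Mean percentage of motile bacteria across samples, +/- sample sd.

    ``counts`` holds (n_motile, n_total) per sample; each sample
    contributes its percentage, aggregated unweighted.
    """
    if not counts:
        raise ValueError("need at least one sample")
    pcts = []
    for n_motile, n_total in counts:
        if n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 <= n_motile <= n_total:
            raise ValueError("need 0 <= n_motile <= n_total")
        pcts.append(100.0 * n_motile / n_total)
    pcts = np.asarray(pcts)
    sd = float(pcts.std(ddof=1)) if pcts.size > 1 else 0.0
    return float(pcts.mean()), sd
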