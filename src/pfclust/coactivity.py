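"""Population co-activation statistics against the independent-activation
null (binomial counts, χ² goodness of fit, pair-distance comparisons).

If fibres respond independently, the number of co-active fibres in a
field of view (FOV) with n labelled fibres is Binomial(n, p_response);
the pooled expectation across FOVs is the FOV-wise mixture of those
binomials. Deviations towards higher counts indicate that neighbouring
fibres tend to respond together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

from .core import PointPattern, ResponseRaster

__all__ = [
    "FieldOfView",
    "CoactivityNull",
    "CoactivityTestResult",
    "DistanceComparison",
    "CdfEnvelope",
    "binomial_null",
    "observed_coactive_counts",
    "coactivity_test",
    "coactive_pair_distances",
    "compare_distance_distributions",
    "distance_cdf_envelope",
]

#: sample-size bound below which the Mann–Whitney U null is enumerated
#: exactly (only without ties); larger samples use the normal
#: approximation with tie correction
EXACT_MWU_MAX_N = 25


@dataclass
class FieldOfView:
    """One imaging window: fibre geometry plus response outcomes."""

    pattern: PointPattern
    responder: np.ndarray  # bool per fibre
    raster: Optional[ResponseRaster] = None
    fov_id: int = 0

    def __post_init__(self) -> None:
        self.responder = np.asarray(self.responder, dtype=bool)
        if self.responder.size != self.pattern.n_points:
            raise ValueError("responder flags must match the number of fibres")

    @property
    def n_labelled(self) -> int:
        return self.pattern.n_points

    @property
    def n_responding(self) -> int:
        return int(self.responder.sum())


@dataclass(frozen=True)
class CoactivityNull:
    """Binomial null for the number of co-active fibres per FOV."""

    p_response: float
    n_labelled: Tuple[int, ...]
    pmfs: Tuple[np.ndarray, ...]  # per-FOV Binomial(n_i, p) over k=0..n_i
    expected_histogram: np.ndarray  # expected #FOVs with k responders

    @property
    def n_fovs(self) -> int:
        return len(self.n_labelled)

    @property
    def expected_total_responders(self) -> float:
        """Conservation of expectation: Σ n_i · p."""
        return float(sum(self.n_labelled) * self.p_response)


@dataclass(frozen=True)
class CoactivityTestResult:
    chi2: float
    p_value: float
    df: int
    observed_binned: np.ndarray
    expected_binned: np.ndarray
    bin_upper_edges: np.ndarray  # last bin pools the tail

    def summary(self) -> str:
        return (
            f"co-activation χ² test: χ²={self.chi2:.3f}, df={self.df}, "
            f"p={self.p_value:.3g}"
        )


@dataclass(frozen=True)
class DistanceComparison:
    statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    method: str  # "exact" | "asymptotic"


@dataclass(frozen=True)
class CdfEnvelope:
    grid_um: np.ndarray
    expected_cdf: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    coverage: float
    n_boot: int


def binomial_null(
    n_labelled_list: Sequence[int], p_response: float
) -> CoactivityNull:
    """Per-FOV Binomial(n, p) nulls and the pooled expected count histogram."""
    if not 0 <= p_response <= 1:
        raise ValueError("p_response must be a probability")
    ns = [int(n) for n in n_labelled_list]
    if any(n < 1 for n in ns):
        raise ValueError("every FOV must contain at least one labelled fibre")
    pmfs = tuple(
        stats.binom.pmf(np.arange(n + 1), n, p_response) for n in ns
    )
    kmax = max(ns)
    expected = np.zeros(kmax + 1)
    for pmf in pmfs:
        expected[: pmf.size] += pmf
    return CoactivityNull(
        p_response=float(p_response),
        n_labelled=tuple(ns),
        pmfs=pmfs,
        expected_histogram=expected,
    )


def observed_coactive_counts(fovs: Sequence[FieldOfView]) -> np.ndarray:
    """Number of responding fibres in each FOV."""
    return np.array([f.n_responding for f in fovs], dtype=int)


def coactivity_test(
    observed_counts: Sequence[int],
    null: CoactivityNull,
    min_expected: float = 3.0,
) -> CoactivityTestResult:
    """χ² goodness-of-fit of observed co-active counts against the null.

    Counts are histogrammed over k = 0..max(n); high-k bins are pooled
    into the tail until the tail's expected count reaches
    ``min_expected``. A threshold of 3 keeps the informative ≥2 tail bin
    separate at realistic response probabilities while leaving the χ²
    approximation well calibrated (tail expectations ≥1 suffice when the
    remaining bins are large); pooling all the way to 5 would merge the
    tail into the k=1 bin and discard most of the clustering signal.
    Degrees of freedom = bins − 1. Observations from all FOVs are pooled
    into a single histogram, so the result is invariant to FOV order.
    """
    obs_counts = np.asarray(observed_counts, dtype=int)
    if obs_counts.size != null.n_fovs:
        raise ValueError("one observed count per FOV in the null is required")
    kmax = len(null.expected_histogram) - 1
    if np.any(obs_counts < 0) or np.any(obs_counts > kmax):
        raise ValueError("observed count outside 0..max(n_labelled)")
    observed = np.bincount(obs_counts, minlength=kmax + 1).astype(float)
    expected = null.expected_histogram.copy()

    # pool the tail (expected counts are decreasing in k out there)
    upper = np.arange(kmax + 1)
    while expected.size > 2 and expected[-1] < min_expected:
        expected[-2] += expected[-1]
        observed[-2] += observed[-1]
        expected, observed, upper = expected[:-1], observed[:-1], upper[:-1]
    if expected.size < 2 or expected[-1] < min_expected:
        if expected.size > 1 and expected[-1] < min_expected:
            expected[-2] += expected[-1]
            observed[-2] += observed[-1]
            expected, observed, upper = expected[:-1], observed[:-1], upper[:-1]
    if expected.size < 2:
        raise ValueError("fewer than 2 bins remain after pooling")
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    df = expected.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return CoactivityTestResult(
        chi2=chi2,
        p_value=p,
        df=df,
        observed_binned=observed,
        expected_binned=expected,
        bin_upper_edges=upper,
    )


def coactive_pair_distances(
    fovs: Sequence[FieldOfView],
) -> Tuple[np.ndarray, np.ndarray]:
    """Within-FOV pair distances: (active pairs, all labelled pairs), μm.

    Distances are 2-D Euclidean in the sagittal plane; only pairs inside
    one FOV are formed. FOVs with ≥2 responders contribute active pairs;
    every FOV with ≥2 fibres contributes all-pairs.
    """
    active: List[np.ndarray] = []
    all_pairs: List[np.ndarray] = []
    for f in fovs:
        if f.n_labelled >= 2:
            all_pairs.append(pdist(f.pattern.points))
        if f.n_responding >= 2:
            active.append(pdist(f.pattern.points[f.responder]))
    cat = lambda xs: np.concatenate(xs) if xs else np.empty(0)
    return cat(active), cat(all_pairs)


def compare_distance_distributions(
    sample_a: np.ndarray, sample_b: np.ndarray
) -> DistanceComparison:
    """Two-sided Mann–Whitney U comparison of two distance samples.

    The exact null is used when both samples have ≤25 values and no ties
    span the samples; otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = (
        "exact"
        if (a.size <= EXACT_MWU_MAX_N and b.size <= EXACT_MWU_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return DistanceComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=int(a.size),
        n_b=int(b.size),
        method=method,
    )


def distance_cdf_envelope(
    all_pair_distances: np.ndarray,
    n_active_pairs: int,
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    coverage: float = 0.999,
) -> CdfEnvelope:
    """Pointwise confidence envelope for the active-pair distance CDF.

    The expected CDF comes from the pooled all-pair distances; the
    envelope is the pointwise (1−coverage)/2 and 1−(1−coverage)/2
    quantiles of empirical CDFs of ``n_boot`` subsets of size
    ``n_active_pairs`` drawn without replacement from the pool. An active
    CDF escaping the envelope at short distances indicates closer spacing
    than chance. For 99.9% coverage use n_boot ≥ 10,000.
    """
    pool = np.sort(np.asarray(all_pair_distances, dtype=float))
    if n_active_pairs > pool.size:
        raise ValueError("n_active_pairs exceeds the available pairs")
    if n_active_pairs < 1:
        raise ValueError("need at least one active pair")
    rng = np.random.default_rng(seed)
    grid = np.unique(pool)
    expected = np.searchsorted(pool, grid, side="right") / pool.size
    boot = np.empty((n_boot, grid.size))
    for i in range(n_boot):
        sub = np.sort(rng.choice(pool, size=n_active_pairs, replace=False))
        boot[i] = np.searchsorted(sub, grid, side="right") / n_active_pairs
    alpha = (1.0 - coverage) / 2.0
    return CdfEnvelope(
        grid_um=grid,
        expected_cdf=expected,
        lower=np.quantile(boot, alpha, axis=0),
        upper=np.quantile(boot, 1.0 - alpha, axis=0),
        coverage=coverage,
        n_boot=n_boot,
    )
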