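"""Trial-to-trial coupling analysis of simultaneously imaged fibre pairs.

For each within-FOV pair, the Pearson correlation between the two
fibres' binary response rasters is computed together with its two-sided
p-value — the pair's "probability of independence". Pairs with p < 0.05
are classified as significantly coupled, the signature expected of
fibres sharing a common presynaptic (mossy-fibre) driver. On binary data
the Pearson coefficient coincides with the φ coefficient of the 2×2
contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .coactivity import DistanceComparison, FieldOfView, compare_distance_distributions

__all__ = [
    "CouplingResult",
    "CoupledFraction",
    "DistanceIndependenceResult",
    "pair_coupling",
    "fov_pair_couplings",
    "coupled_fraction",
    "independence_vs_distance",
    "independent_pair_clustering",
]

ALPHA_COUPLED = 0.05


@dataclass(frozen=True)
class CouplingResult:
    """Coupling classification for one fibre pair."""

    pair: Tuple[int, int]
    pearson_r: float
    p_independence: float
    coupled: bool
    indeterminate: bool
    distance_um: Optional[float] = None
    fov_id: int = 0


@dataclass(frozen=True)
class CoupledFraction:
    fraction: float
    n_coupled: int
    n_determinate: int
    n_indeterminate: int
    n_tests: int  # no multiplicity correction is applied; surfaced instead

    def summary(self) -> str:
        return (
            f"{self.n_coupled} of {self.n_determinate} determinate pairs "
            f"coupled ({100 * self.fraction:.1f}%); "
            f"{self.n_indeterminate} indeterminate pairs excluded; "
            f"{self.n_tests} uncorrected tests"
        )


@dataclass(frozen=True)
class DistanceIndependenceResult:
    spearman_rho: Optional[float]
    spearman_p: Optional[float]
    coupled_vs_independent: Optional[DistanceComparison]
    flagged: Optional[str] = None


def pair_coupling(
    responses_i: np.ndarray,
    responses_j: np.ndarray,
    pair: Tuple[int, int] = (0, 1),
    distance_um: Optional[float] = None,
    fov_id: int = 0,
    method: str = "t",
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
) -> CouplingResult:
    """Pearson correlation of two binary response rasters and its p-value.

    ``method="t"`` uses the t-distribution on n−2 degrees of freedom;
    ``method="permutation"`` shuffles one raster ``n_permutations`` times
    (seeded) for an exact-style p, useful at small trial counts. A fibre
    responding on none or all trials makes r undefined; such pairs are
    flagged indeterminate and excluded from coupled-fraction denominators
    rather than counted as independent.
    """
    a = np.asarray(responses_i, dtype=float).ravel()
    b = np.asarray(responses_j, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("pair rasters must have the same trial count")
    if a.size < 3:
        raise ValueError("need at least 3 trials")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return CouplingResult(
            pair=pair,
            pearson_r=np.nan,
            p_independence=np.nan,
            coupled=False,
            indeterminate=True,
            distance_um=distance_um,
            fov_id=fov_id,
        )
    if method == "t":
        r, p = stats.pearsonr(a, b)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        r = float(stats.pearsonr(a, b).statistic)
        null = np.empty(n_permutations)
        for k in range(n_permutations):
            null[k] = stats.pearsonr(a, rng.permutation(b)).statistic
        p = (1 + np.sum(np.abs(null) >= abs(r) - 1e-12)) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CouplingResult(
        pair=pair,
        pearson_r=float(r),
        p_independence=float(p),
        coupled=bool(p < ALPHA_COUPLED),
        indeterminate=False,
        distance_um=distance_um,
        fov_id=fov_id,
    )


def fov_pair_couplings(
    fov: FieldOfView,
    responders_only: bool = True,
    method: str = "t",
    seed: Optional[int] = None,
) -> List[CouplingResult]:
    """Coupling results for all (responder) pairs within one FOV.

    The analysis requires simultaneous imaging, so only pairs contained
    within a single field of view are formed.
    """
    if fov.raster is None:
        raise ValueError("FOV carries no response raster")
    idx = np.where(fov.responder)[0] if responders_only else np.arange(fov.n_labelled)
    dmat = squareform(pdist(fov.pattern.points))
    out = []
    for u in range(len(idx)):
        for v in range(u + 1, len(idx)):
            i, j = int(idx[u]), int(idx[v])
            out.append(
                pair_coupling(
                    fov.raster.responses[i],
                    fov.raster.responses[j],
                    pair=(i, j),
                    distance_um=float(dmat[i, j]),
                    fov_id=fov.fov_id,
                    method=method,
                    seed=seed,
                )
            )
    return out


def coupled_fraction(results: Sequence[CouplingResult]) -> CoupledFraction:
    """Fraction of determinate pairs classified as coupled."""
    det = [r for r in results if not r.indeterminate]
    if not det:
        raise ValueError("no determinate pairs")
    n_coupled = sum(r.coupled for r in det)
    return CoupledFraction(
        fraction=n_coupled / len(det),
        n_coupled=n_coupled,
        n_determinate=len(det),
        n_indeterminate=len(results) - len(det),
        n_tests=len(det),
    )


def independence_vs_distance(
    results: Sequence[CouplingResult],
) -> DistanceIndependenceResult:
    """Does coupling depend on pair separation?

    Spearman rank correlation between the probability of independence and
    the pair distance, plus a Mann–Whitney comparison of distances for
    coupled vs independent pairs.
    """
    det = [r for r in results if not r.indeterminate]
    if any(r.distance_um is None for r in det):
        raise ValueError("all pairs need distances")
    if not det:
        raise ValueError("no determinate pairs")
    p_ind = np.array([r.p_independence for r in det])
    dist = np.array([r.distance_um for r in det])
    if np.unique(dist).size < 2:
        return DistanceIndependenceResult(
            None, None, None, flagged="all distances identical; rho undefined"
        )
    if np.unique(p_ind).size < 2:
        return DistanceIndependenceResult(
            None, None, None, flagged="p_independence constant; rho undefined"
        )
    rho, p = stats.spearmanr(p_ind, dist)
    d_coupled = dist[[r.coupled for r in det]]
    d_indep = dist[[not r.coupled for r in det]]
    comp = (
        compare_distance_distributions(d_coupled, d_indep)
        if d_coupled.size and d_indep.size
        else None
    )
    return DistanceIndependenceResult(
        spearman_rho=float(rho), spearman_p=float(p), coupled_vs_independent=comp
    )


def independent_pair_clustering(
    results: Sequence[CouplingResult],
    all_labelled_distances: np.ndarray,
) -> DistanceComparison:
    """Are even the non-coupled ("independent") pairs clustered in space?

    Compares the distances of determinate-but-independent pairs against
    all labelled-pair distances from the same FOVs.
    """
    d_indep = np.array(
        [
            r.distance_um
            for r in results
            if not r.indeterminate and not r.coupled
        ],
        dtype=float,
    )
    if d_indep.size == 0:
        raise ValueError("no independent pairs")
    return compare_distance_distributions(d_indep, np.asarray(all_labelled_distances))
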