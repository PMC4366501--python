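"""Labelling-density calibration from bouton maps.

A thin (1 μm) sagittal section cuts each labelled parallel fibre at most
once between boutons spaced ~3.7 μm apart, so the areal density of
labelled boutons times ``bouton_spacing / section_thickness`` estimates
the areal density of labelled fibres; dividing by the known total
parallel-fibre density (5–6 per μm², default midpoint 5.5) gives the
labelled fraction. Multiplying the fraction by the ~150,000 fibres
crossing one Purkinje-cell dendritic tree (~200 μm wide) predicts the
labelled-fibre count per Purkinje cell, which can be checked against
direct counts with a one-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import PointPattern

__all__ = [
    "DensityParams",
    "FractionEstimate",
    "PlausibilityResult",
    "estimate_labelled_fraction",
    "expected_pf_count_per_pc",
    "plausibility_check",
]


@dataclass(frozen=True)
class DensityParams:
    """Anatomical constants for the density calculation (all lengths μm)."""

    bouton_spacing_um: float = 3.7
    pf_density_per_um2: float = 5.5  # published range 5–6; midpoint default
    pfs_per_pc: int = 150_000
    pc_width_um: float = 200.0
    section_thickness_um: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "bouton_spacing_um",
            "pf_density_per_um2",
            "pfs_per_pc",
            "pc_width_um",
            "section_thickness_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FractionEstimate:
    labelled_fraction: float
    bouton_density_per_um2: float
    fibre_density_per_um2: float
    n_boutons: int
    area_um2: float

    def summary(self) -> str:
        return (
            f"{self.n_boutons} boutons over {self.area_um2:.0f} μm² → "
            f"bouton density {self.bouton_density_per_um2:.2e}/μm², "
            f"fibre density {self.fibre_density_per_um2:.2e}/μm², "
            f"labelled fraction {100 * self.labelled_fraction:.3f}%"
        )


@dataclass(frozen=True)
class PlausibilityResult:
    t_statistic: float
    p_value: float
    observed_mean: float
    expected: float
    n: int


def estimate_labelled_fraction(
    bouton_map: PointPattern, params: DensityParams = DensityParams()
) -> FractionEstimate:
    """Estimate the labelled fraction of parallel fibres from a bouton map."""
    if params.section_thickness_um > params.bouton_spacing_um:
        raise ValueError(
            "section thickness exceeds bouton spacing; a section would cut "
            "a fibre at several boutons"
        )
    n = bouton_map.n_points
    area = bouton_map.region.area
    if n == 0:
        warnings.warn("empty bouton map: labelled fraction estimated as 0")
    bouton_density = n / area
    fibre_density = (
        bouton_density * params.bouton_spacing_um / params.section_thickness_um
    )
    fraction = fibre_density / params.pf_density_per_um2
    if fraction >= 1:
        raise ValueError(
            f"estimated labelled fraction {fraction:.2f} ≥ 1 is implausible; "
            "check units or the density parameters"
        )
    return FractionEstimate(
        labelled_fraction=float(fraction),
        bouton_density_per_um2=float(bouton_density),
        fibre_density_per_um2=float(fibre_density),
        n_boutons=n,
        area_um2=float(area),
    )


def expected_pf_count_per_pc(
    fraction: float, params: DensityParams = DensityParams()
) -> int:
    """Expected labelled parallel fibres crossing one Purkinje-cell tree."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    return int(round(fraction * params.pfs_per_pc))


def plausibility_check(
    observed_counts: Sequence[float], expected: float
) -> PlausibilityResult:
    """One-sample t-test of directly counted labelled fibres vs expectation."""
    obs = np.asarray(observed_counts, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    if np.std(obs, ddof=1) == 0:
        if np.allclose(obs, expected):
            return PlausibilityResult(0.0, 1.0, float(obs.mean()), expected, obs.size)
        raise ValueError("zero variance among observations differing from expected")
    t, p = stats.ttest_1samp(obs, expected)
    return PlausibilityResult(
        t_statistic=float(t),
        p_value=float(p),
        observed_mean=float(obs.mean()),
        expected=float(expected),
        n=int(obs.size),
    )
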