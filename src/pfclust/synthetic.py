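"""Ground-truthed simulators for parallel-fibre imaging experiments.

Every downstream stage of the pipeline (event detection, co-activation
statistics, spatial tests, coupling analysis, density calibration) is
exercised against data produced here, with the generating truth retained.

The default parameters emulate in vivo population imaging of cerebellar
parallel fibres: ~19% of fibres spontaneously active at ~0.4 Hz, a
per-fibre sensory response probability of 0.028, evoked bursts of 2–3
events at up to ~172 Hz, bimodal response latencies peaking near 10 and
22 ms, ΔF/F event amplitudes around 0.5 over ~0.07 noise (event SNR ≈ 7),
and 4–21 labelled fibres per 56 μm field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import PointPattern, Region, ResponseRaster, Trace

__all__ = [
    "SimulationConfig",
    "ClusterParams",
    "CouplingStructure",
    "GroundTruth",
    "FovExperiment",
    "simulate_point_pattern",
    "simulate_spike_times",
    "simulate_traces",
    "simulate_population_experiment",
    "simulate_bouton_map",
]

#: smallest admissible event amplitude (ΔF/F); draws below are clipped here
#: so every simulated transient remains detectable in principle
AMPLITUDE_FLOOR_DFF = 0.05


@dataclass(frozen=True)
class ClusterParams:
    """Thomas cluster-process parameters.

    ``n_parents`` parent points are placed uniformly in the region; each
    receives ``offspring_per_parent`` children displaced by an isotropic
    Gaussian with s.d. ``sigma_um``. Children landing outside the region
    are re-drawn from the same parent, which keeps the point count exact
    at the cost of a slight inward bias for parents near the border.
    """

    n_parents: int = 5
    offspring_per_parent: int = 3
    sigma_um: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma_um <= 0:
            raise ValueError("offspring dispersion sigma_um must be positive")
        if self.n_parents < 1 or self.offspring_per_parent < 1:
            raise ValueError("cluster process needs >=1 parent and offspring")


def _shared_driver_rates(
    p: float, reliability: float, drive_p: Optional[float]
) -> Tuple[float, float]:
    """Solve ``(drive_p, background_p)`` for a shared-driver channel.

    A unit fires through the shared channel with probability q·r
    (drive × reliability) or through an independent background channel
    with probability b, so the marginal is

        p = q·r + b·(1 − q·r)   ⇒   b = (p − q·r)/(1 − q·r).

    With ``drive_p`` unspecified, q = p/r and b = 0: the whole marginal
    flows through the shared channel. q·r ≤ p is required.
    """
    r = reliability
    if drive_p is None:
        q = p / r
        if q > 1:
            raise ValueError(f"marginal p={p} unreachable at reliability {r}")
        return q, 0.0
    q = drive_p
    if q * r > p + 1e-12:
        raise ValueError("drive_p × reliability exceeds the requested marginal")
    b = (p - q * r) / (1.0 - q * r)
    return q, b


@dataclass(frozen=True)
class CouplingStructure:
    """Shared-driver grouping of the fibres in one field of view.

    Fibres are partitioned into groups of ``group_size`` (any remainder
    becomes singletons). The shared driver — a common mossy fibre — acts
    at two levels:

    * fibre level: whether a fibre responds to the sensory stimulus at
      all. A group is recruited with probability ``drive_p``; a fibre in
      a recruited group becomes a responder with probability
      ``reliability``, with the background channel solved so the
      marginal equals the experiment's ``p_response``
      (see ``_shared_driver_rates``).
    * trial level: responders in the same group share trial-to-trial
      variability. On each trial the group's driver fires with
      probability ``trial_drive_p``; responders follow it with
      probability ``trial_reliability``, marginal ``trial_response_p``.

    Defaults route each marginal entirely through the shared channel.
    """

    group_size: int = 1
    reliability: float = 1.0
    drive_p: Optional[float] = None
    trial_reliability: float = 0.8
    trial_drive_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError("group_size must be >=1")
        if not 0 < self.reliability <= 1:
            raise ValueError("reliability must be in (0, 1]")
        if not 0 < self.trial_reliability <= 1:
            raise ValueError("trial_reliability must be in (0, 1]")

    def fibre_rates(self, p_response: float) -> Tuple[float, float]:
        return _shared_driver_rates(p_response, self.reliability, self.drive_p)

    def trial_rates(self, trial_response_p: float) -> Tuple[float, float]:
        return _shared_driver_rates(
            trial_response_p, self.trial_reliability, self.trial_drive_p
        )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic experiment, fully determined by ``seed``."""

    seed: int = 0
    region_width_um: float = 56.0
    region_height_um: float = 150.0
    n_fibres_per_fov: Union[int, Tuple[int, int]] = (4, 21)
    p_response: float = 0.028
    spontaneous_rate_hz: float = 0.4
    frac_spontaneously_active: float = 0.19
    burst_size_dist: Tuple[Tuple[int, float], ...] = (
        (1, 0.05),
        (2, 0.40),
        (3, 0.45),
        (4, 0.10),
    )
    max_intraburst_freq_hz: float = 172.0
    latency_mixture: Tuple[Tuple[float, float, float], ...] = (
        (10.0, 2.0, 0.5),
        (22.0, 3.0, 0.5),
    )
    event_amplitude_dff: Tuple[float, float] = (0.50, 0.25)
    noise_sd_dff: float = 0.07
    frame_rate_hz: float = 32.0
    decay_tau_s: float = 0.4
    pattern_kind: str = "csr"
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    regular_jitter_frac: float = 0.1
    coupling_structure: Optional[CouplingStructure] = None
    #: per-trial response probability of a responder fibre; not
    #: constrained by the recordings, so exposed as a free parameter
    trial_response_p: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_response", "frac_spontaneously_active", "trial_response_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in (
            "region_width_um",
            "region_height_um",
            "spontaneous_rate_hz",
            "max_intraburst_freq_hz",
            "noise_sd_dff",
            "frame_rate_hz",
            "decay_tau_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        w = sum(p for _, p in self.burst_size_dist)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("burst_size_dist probabilities must sum to 1")
        w = sum(wt for _, _, wt in self.latency_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("latency mixture weights must sum to 1")
        if self.pattern_kind not in ("csr", "regular", "thomas_cluster"):
            raise ValueError(f"unknown pattern_kind {self.pattern_kind!r}")

    @property
    def region(self) -> Region:
        return Region(0.0, 0.0, self.region_width_um, self.region_height_um)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def draw_n_fibres(self, rng: np.random.Generator) -> int:
        if isinstance(self.n_fibres_per_fov, tuple):
            lo, hi = self.n_fibres_per_fov
            return int(rng.integers(lo, hi + 1))
        return int(self.n_fibres_per_fov)


@dataclass
class GroundTruth:
    """Generating truth emitted alongside every synthetic object."""

    spike_times: Optional[List[np.ndarray]] = None
    responses: Optional[np.ndarray] = None  # fibre × trial booleans
    responder: Optional[np.ndarray] = None  # fibre-level responsiveness
    pattern_kind: Optional[str] = None
    cluster_assignments: Optional[np.ndarray] = None
    group_ids: Optional[np.ndarray] = None
    labelled_fraction: Optional[float] = None
    latencies_s: Optional[np.ndarray] = None
    burst_sizes: Optional[np.ndarray] = None


@dataclass
class FovExperiment:
    """One simulated field of view: geometry plus its response raster."""

    pattern: PointPattern
    raster: ResponseRaster
    truth: GroundTruth


# --------------------------------------------------------------------------
# spatial point patterns
# --------------------------------------------------------------------------

def simulate_point_pattern(
    config: SimulationConfig,
    n_points: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[PointPattern, GroundTruth]:
    """Draw one spatial pattern of fibre cross-sections.

    ``pattern_kind`` selects complete spatial randomness (i.i.d. uniform),
    a jittered square lattice ("regular"), or a Thomas cluster process.
    For the cluster process ``n_points`` is ignored and the count is
    ``n_parents × offspring_per_parent``.
    """
    rng = config.rng() if rng is None else rng
    region = config.region
    kind = config.pattern_kind

    if kind == "thomas_cluster":
        pts, parents = _thomas_points(config.cluster_params, region, rng)
        truth = GroundTruth(pattern_kind=kind, cluster_assignments=parents)
        return PointPattern(pts, region), truth

    n = config.draw_n_fibres(rng) if n_points is None else int(n_points)
    if n == 0:
        return (
            PointPattern(np.empty((0, 2)), region),
            GroundTruth(pattern_kind=kind),
        )
    if kind == "csr":
        pts = _uniform_points(n, region, rng)
        return PointPattern(pts, region), GroundTruth(pattern_kind=kind)

    # regular: square-ish lattice filling the region, uniform jitter.
    # Density cap: one point per 1 μm² cell keeps the lattice spacing
    # physically meaningful for fibre cross-sections.
    if n > region.area:
        raise ValueError(
            f"regular pattern of {n} points exceeds the 1 point/μm² density cap"
        )
    pts = _lattice_points(n, region, config.regular_jitter_frac, rng)
    return PointPattern(pts, region), GroundTruth(pattern_kind=kind)


def _uniform_points(n: int, region: Region, rng: np.random.Generator) -> np.ndarray:
    xy = rng.random((n, 2))
    xy[:, 0] = region.x0 + xy[:, 0] * region.width
    xy[:, 1] = region.y0 + xy[:, 1] * region.height
    return xy


def _lattice_points(
    n: int, region: Region, jitter_frac: float, rng: np.random.Generator
) -> np.ndarray:
    nx = max(1, int(round(np.sqrt(n * region.width / region.height))))
    ny = int(np.ceil(n / nx))
    sx, sy = region.width / nx, region.height / ny
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    centres = np.column_stack(
        [
            region.x0 + (ix.ravel() + 0.5) * sx,
            region.y0 + (iy.ravel() + 0.5) * sy,
        ]
    )[:n]
    if jitter_frac > 0:
        jit = rng.uniform(-jitter_frac, jitter_frac, size=(n, 2))
        centres = centres + jit * np.array([sx, sy])
        centres[:, 0] = np.clip(centres[:, 0], region.x0, region.x0 + region.width)
        centres[:, 1] = np.clip(centres[:, 1], region.y0, region.y0 + region.height)
    return centres


def _thomas_points(
    params: ClusterParams, region: Region, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    parents = _uniform_points(params.n_parents, region, rng)
    pts = np.empty((params.n_parents * params.offspring_per_parent, 2))
    assign = np.repeat(np.arange(params.n_parents), params.offspring_per_parent)
    k = 0
    for i in range(params.n_parents):
        for _ in range(params.offspring_per_parent):
            while True:  # resample until inside; keeps n exact
                p = parents[i] + rng.normal(0.0, params.sigma_um, size=2)
                if region.contains(p[None, :])[0]:
                    pts[k] = p
                    k += 1
                    break
    return pts, assign


# --------------------------------------------------------------------------
# spike trains and fluorescence traces
# --------------------------------------------------------------------------

def _draw_burst(
    config: SimulationConfig, t0: float, rng: np.random.Generator
) -> np.ndarray:
    """Spike times of one evoked burst starting at ``t0``.

    Inter-event intervals are uniform in ``[1/f_max, 3/f_max]``, so the
    shortest interval realises the maximum intraburst frequency.
    """
    sizes = np.array([s for s, _ in config.burst_size_dist])
    probs = np.array([p for _, p in config.burst_size_dist])
    n = int(rng.choice(sizes, p=probs))
    if n == 1:
        return np.array([t0])
    lo = 1.0 / config.max_intraburst_freq_hz
    isis = rng.uniform(lo, 3.0 * lo, size=n - 1)
    return t0 + np.concatenate([[0.0], np.cumsum(isis)])


def _draw_latency(config: SimulationConfig, rng: np.random.Generator) -> float:
    """One response latency (seconds) from the two-component mixture."""
    weights = np.array([w for _, _, w in config.latency_mixture])
    k = int(rng.choice(len(weights), p=weights))
    mu, sd, _ = config.latency_mixture[k]
    return max(0.0, rng.normal(mu, sd)) / 1000.0


def simulate_spike_times(
    config: SimulationConfig,
    duration_s: float,
    n_fibres: int,
    responses: Optional[np.ndarray] = None,
    stimulus_times: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> GroundTruth:
    """Generate per-fibre spike trains: spontaneous Poisson activity in a
    ``frac_spontaneously_active`` subset plus evoked bursts on trials where
    ``responses[fibre, trial]`` is true."""
    rng = config.rng() if rng is None else rng
    spont = rng.random(n_fibres) < config.frac_spontaneously_active
    spikes: List[np.ndarray] = []
    latencies = []
    burst_sizes = []
    for i in range(n_fibres):
        t: List[np.ndarray] = []
        if spont[i]:
            n_sp = rng.poisson(config.spontaneous_rate_hz * duration_s)
            t.append(np.sort(rng.uniform(0.0, duration_s, size=n_sp)))
        if responses is not None and stimulus_times is not None:
            for j, stim in enumerate(stimulus_times):
                if responses[i, j]:
                    lat = _draw_latency(config, rng)
                    burst = _draw_burst(config, stim + lat, rng)
                    latencies.append(lat)
                    burst_sizes.append(len(burst))
                    t.append(burst)
        all_t = np.sort(np.concatenate(t)) if t else np.empty(0)
        spikes.append(all_t[all_t < duration_s])
    return GroundTruth(
        spike_times=spikes,
        responses=responses,
        latencies_s=np.asarray(latencies),
        burst_sizes=np.asarray(burst_sizes, dtype=int),
    )


def simulate_traces(
    config: SimulationConfig,
    truth: GroundTruth,
    duration_s: float,
    stimulus_times: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[Trace]:
    """Render spike trains as ΔF/F traces.

    Each spike contributes a transient with an instantaneous rise and an
    exponential decay (time constant ``decay_tau_s``); the amplitude is
    drawn from ``event_amplitude_dff`` and clipped at the 0.05 ΔF/F floor.
    Gaussian noise of s.d. ``noise_sd_dff`` is added throughout.
    """
    rng = config.rng() if rng is None else rng
    if truth.spike_times is None:
        raise ValueError("ground truth carries no spike times")
    fs = config.frame_rate_hz
    n_samp = int(round(duration_s * fs))
    t = np.arange(n_samp) / fs
    mu, sd = config.event_amplitude_dff
    stims = np.empty(0) if stimulus_times is None else np.asarray(stimulus_times)
    traces = []
    for spikes in truth.spike_times:
        sig = np.zeros(n_samp)
        for t0 in spikes:
            amp = max(AMPLITUDE_FLOOR_DFF, rng.normal(mu, sd))
            after = t >= t0
            sig[after] += amp * np.exp(-(t[after] - t0) / config.decay_tau_s)
        if config.noise_sd_dff > 0:
            sig = sig + rng.normal(0.0, config.noise_sd_dff, size=n_samp)
        traces.append(
            Trace(sig, sampling_rate=fs, stimulus_times=stims, units="dff")
        )
    return traces


# --------------------------------------------------------------------------
# population experiments (fields of view)
# --------------------------------------------------------------------------

def _simulate_raster(
    config: SimulationConfig,
    n_fibres: int,
    n_trials: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(raster, responder flags, group ids) under the coupling model.

    Responder status is drawn first (marginal ``p_response``, correlated
    within shared-driver groups); responders then respond trial-to-trial
    with marginal ``trial_response_p``, again correlated within groups.
    Non-responders contribute all-false raster rows.
    """
    cs = config.coupling_structure
    if cs is None or cs.group_size == 1:
        responder = rng.random(n_fibres) < config.p_response
        resp = responder[:, None] & (
            rng.random((n_fibres, n_trials)) < config.trial_response_p
        )
        return resp, responder, np.arange(n_fibres)
    q_f, b_f = cs.fibre_rates(config.p_response)
    q_t, b_t = cs.trial_rates(config.trial_response_p)
    group_ids = np.arange(n_fibres) // cs.group_size
    n_groups = int(group_ids.max()) + 1
    recruited = rng.random(n_groups) < q_f
    responder = (recruited[group_ids] & (rng.random(n_fibres) < cs.reliability)) | (
        rng.random(n_fibres) < b_f
    )
    trial_drive = rng.random((n_groups, n_trials)) < q_t
    follows = rng.random((n_fibres, n_trials)) < cs.trial_reliability
    background = rng.random((n_fibres, n_trials)) < b_t
    resp = responder[:, None] & ((trial_drive[group_ids] & follows) | background)
    return resp, responder, group_ids


def simulate_population_experiment(
    config: SimulationConfig,
    n_fovs: int = 85,
    n_trials: int = 40,
    stimulus_interval_s: float = 5.0,
    rng: Optional[np.random.Generator] = None,
) -> List[FovExperiment]:
    """Simulate a multi-FOV population imaging experiment.

    Defaults mirror the in vivo design: 85 fields of view, 40 airpuff
    trials at 0.2 Hz. Each FOV gets fibre positions from the configured
    point process and a response raster from the coupling model; when the
    positions come from the Thomas process and a shared-driver structure
    is set, co-driven fibres are placed within the same spatial cluster.
    """
    rng = config.rng() if rng is None else rng
    stims = np.arange(n_trials) * stimulus_interval_s
    fovs = []
    for _ in range(n_fovs):
        n = config.draw_n_fibres(rng)
        cs = config.coupling_structure
        if config.pattern_kind == "thomas_cluster" and cs is not None:
            n_groups = int(np.ceil(n / cs.group_size))
            params = ClusterParams(
                n_parents=n_groups,
                offspring_per_parent=cs.group_size,
                sigma_um=config.cluster_params.sigma_um,
            )
            pts, parents = _thomas_points(params, config.region, rng)
            pts, parents = pts[:n], parents[:n]
        else:
            pattern, truth0 = simulate_point_pattern(config, n_points=n, rng=rng)
            pts, parents = pattern.points, truth0.cluster_assignments
        resp, responder, group_ids = _simulate_raster(config, n, n_trials, rng)
        truth = GroundTruth(
            responses=resp,
            responder=responder,
            pattern_kind=config.pattern_kind,
            cluster_assignments=parents,
            group_ids=group_ids,
        )
        fovs.append(
            FovExperiment(
                pattern=PointPattern(pts, config.region),
                raster=ResponseRaster(resp, stimulus_times=stims),
                truth=truth,
            )
        )
    return fovs


# --------------------------------------------------------------------------
# bouton maps for density calibration
# --------------------------------------------------------------------------

def simulate_bouton_map(
    true_labelled_fraction: float,
    region: Region,
    pf_density_per_um2: float = 5.5,
    bouton_spacing_um: float = 3.7,
    section_thickness_um: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[PointPattern, GroundTruth]:
    """Simulate labelled-bouton positions in a thin sagittal section.

    The labelled-fibre density is ``fraction × pf_density``; a section of
    thickness *t* along fibres with boutons every *s* μm intersects a
    fraction *t/s* of boutons, so the expected count in the section is
    ``fraction × pf_density × area × t / s`` — Poisson-sampled, positions
    uniform. Sections thicker than the bouton spacing would intersect
    multiple boutons per fibre and are not supported.
    """
    if not 0 <= true_labelled_fraction < 1:
        raise ValueError("labelled fraction must be in [0, 1)")
    if pf_density_per_um2 <= 0 or bouton_spacing_um <= 0 or section_thickness_um <= 0:
        raise ValueError("densities, spacings and thickness must be positive")
    if section_thickness_um > bouton_spacing_um:
        raise ValueError(
            "section thickness exceeds bouton spacing; one section would cut "
            "a fibre at several boutons, which this model does not support"
        )
    rng = np.random.default_rng() if rng is None else rng
    expected = (
        true_labelled_fraction
        * pf_density_per_um2
        * region.area
        * section_thickness_um
        / bouton_spacing_um
    )
    n = int(rng.poisson(expected))
    pts = _uniform_points(n, region, rng) if n else np.empty((0, 2))
    return (
        PointPattern(pts, region),
        GroundTruth(labelled_fraction=true_labelled_fraction),
    )
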