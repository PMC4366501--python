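"""Shared domain containers for the parallel-fibre imaging analysis.

Conventions used throughout the package:

* lengths are micrometres (the sagittal imaging plane),
* times are seconds, intervals are half-open ``[start, end)``,
* fluorescence is either raw counts or ΔF/F (dimensionless),
* coordinates live in a right-handed frame with the origin at the
  lower-left corner of the bounded region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Trace",
    "EventList",
    "ResponseRaster",
    "PointPattern",
    "Region",
]


@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangle ``(x0, y0, width, height)`` in μm."""

    x0: float
    y0: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"region must have positive area, got {self.width}×{self.height} μm"
            )

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return (
            (pts[:, 0] >= self.x0 - atol)
            & (pts[:, 0] <= self.x0 + self.width + atol)
            & (pts[:, 1] >= self.y0 - atol)
            & (pts[:, 1] <= self.y0 + self.height + atol)
        )

    def scaled(self, area_multiplier: float) -> "Region":
        """Return a concentric region with area scaled by ``area_multiplier``.

        Both side lengths are multiplied by ``sqrt(area_multiplier)`` so the
        aspect ratio is preserved exactly.
        """
        if area_multiplier <= 0:
            raise ValueError("area_multiplier must be positive")
        s = float(np.sqrt(area_multiplier))
        cx = self.x0 + self.width / 2.0
        cy = self.y0 + self.height / 2.0
        w, h = self.width * s, self.height * s
        return Region(cx - w / 2.0, cy - h / 2.0, w, h)


@dataclass
class Trace:
    """A single ROI fluorescence time series.

    Parameters
    ----------
    samples : array of float
        Fluorescence samples, raw counts or ΔF/F depending on ``units``.
    sampling_rate : float
        Acquisition rate in Hz (32 Hz framing for population imaging,
        1 kHz for linescans).
    stimulus_times : array of float
        Stimulus onset times in seconds; may be empty.
    units : {"raw", "dff"}
    """

    samples: np.ndarray
    sampling_rate: float
    stimulus_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    units: str = "dff"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.units not in ("raw", "dff"):
            raise ValueError(f"units must be 'raw' or 'dff', got {self.units!r}")
        if self.stimulus_times.size:
            if np.any(np.diff(self.stimulus_times) <= 0):
                raise ValueError("stimulus_times must be strictly increasing")
            if (
                self.stimulus_times[0] < 0
                or self.stimulus_times[-1] >= self.duration
            ):
                raise ValueError("stimulus_times must lie within the trace duration")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def with_samples(self, samples: np.ndarray, units: Optional[str] = None) -> "Trace":
        return replace(
            self,
            samples=np.asarray(samples, dtype=float),
            units=self.units if units is None else units,
        )


@dataclass
class EventList:
    """Detected calcium events for one fibre.

    ``snr`` is the per-event peak amplitude divided by the RMS of the
    baseline-subtracted trace immediately preceding the event.
    """

    onset_times: np.ndarray
    peak_amplitudes: np.ndarray
    snr: np.ndarray
    baseline_rms: float

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (
            self.onset_times.shape
            == self.peak_amplitudes.shape
            == self.snr.shape
        ):
            raise ValueError("onset_times, peak_amplitudes and snr must align")
        if self.onset_times.size > 1 and np.any(np.diff(self.onset_times) < 0):
            raise ValueError("onset_times must be non-decreasing")

    def __len__(self) -> int:
        return int(self.onset_times.size)


@dataclass
class ResponseRaster:
    """Boolean fibre × trial matrix of stimulus-locked responses."""

    responses: np.ndarray
    stimulus_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    fov_id: int = 0

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=bool)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.responses.ndim != 2:
            raise ValueError("responses must be 2-D (fibre × trial)")
        if self.responses.shape[1] < 1:
            raise ValueError("raster needs at least one trial")
        if self.stimulus_times.size and self.stimulus_times.size != self.n_trials:
            raise ValueError("stimulus_times must match the trial count")

    @property
    def n_fibres(self) -> int:
        return int(self.responses.shape[0])

    @property
    def n_trials(self) -> int:
        return int(self.responses.shape[1])


@dataclass
class PointPattern:
    """2-D fibre cross-section coordinates inside a bounded region.

    ``labels`` is an optional per-point categorical array (for example
    ``"responding"`` vs ``"labelled"``).
    """

    points: np.ndarray
    region: Region
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.n_points:
                raise ValueError("labels must have one entry per point")
        if self.n_points and not np.all(self.region.contains(self.points)):
            raise ValueError("all points must lie inside the region")

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def subset(self, mask: Sequence[bool]) -> "PointPattern":
        mask = np.asarray(mask, dtype=bool)
        return PointPattern(
            self.points[mask],
            self.region,
            None if self.labels is None else self.labels[mask],
        )
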