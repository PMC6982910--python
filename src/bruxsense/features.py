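"""Monitoring statistics and network-input feature assembly.

Per tumbling monitoring window this module computes, channel by channel,
the average, maximum, minimum, standard deviation and variance of the
quantized bite forces, plus the cross-channel covariance matrix of the
window's samples.  From detected events and their clinical covariates it
assembles the five characteristics consumed by the classifier — mean force
magnitude, mean force duration, mean contact area, contact points and pain
level — and packs time-ordered frames into the fixed-size 16-channel input
block the network expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquire import CountTrace, OcclusionEvent

__all__ = [
    "MonitoringSummary",
    "FeatureVector",
    "Standardizer",
    "window_statistics",
    "build_feature_vector",
    "frames_to_tensor",
    "N_FRAMES",
    "N_INPUT_CHANNELS",
]

N_FRAMES = 128
N_INPUT_CHANNELS = 16
_N_SENSOR_CHANNELS = 6
_N_FEATURES = 5


@dataclass
class MonitoringSummary:
    """The six per-window statistics of the quantized bite forces.

    ``avg``/``max``/``min``/``sd``/``variance`` are per-channel vectors;
    ``covariance`` is the (population) cross-channel covariance matrix of the
    window's samples, whose diagonal equals ``variance``.
    """

    avg: np.ndarray
    max: np.ndarray
    min: np.ndarray
    sd: np.ndarray
    variance: np.ndarray
    covariance: np.ndarray
    window_start: float  # seconds
    window_end: float

    def __post_init__(self) -> None:
        if np.any(self.min > self.avg) or np.any(self.avg > self.max):
            raise ValueError("window statistics violate min <= avg <= max")
        if not np.allclose(self.variance, self.sd ** 2):
            raise ValueError("variance must equal sd**2")


@dataclass(frozen=True)
class FeatureVector:
    """The five classifier inputs for one monitoring window."""

    mean_force_magnitude: float  # counts
    mean_force_duration: float  # seconds
    mean_contact_area: float  # mm^2
    contact_points: int
    pain_level: int
    quiet: bool = False  # no events in the window

    def __post_init__(self) -> None:
        if min(self.mean_force_magnitude, self.mean_force_duration,
               self.mean_contact_area, self.contact_points) < 0:
            raise ValueError("feature values must be non-negative")
        if not (isinstance(self.pain_level, (int, np.integer))
                and 0 <= self.pain_level <= 10):
            raise ValueError("pain_level must be an integer in [0, 10]")

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_force_magnitude, self.mean_force_duration,
                         self.mean_contact_area, float(self.contact_points),
                         float(self.pain_level)])


def window_statistics(counts: CountTrace, window: float) -> list[MonitoringSummary]:
    """Tumbling-window statistics over a quantized trace.

    The final partial window is kept when it covers at least half the
    window length.  All second moments use population (1/n) normalization.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    w = int(round(window * counts.sampling_rate))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if counts.n_samples == 0:
        raise ValueError("counts trace is empty")

    x = counts.counts.astype(float)
    fs = counts.sampling_rate
    out: list[MonitoringSummary] = []
    start = 0
    while start < counts.n_samples:
        end = min(start + w, counts.n_samples)
        if end - start < max(2, w // 2) and start > 0:
            break
        seg = x[:, start:end]
        mean = seg.mean(axis=1)
        centered = seg - mean[:, None]
        cov = centered @ centered.T / seg.shape[1]
        var = np.diag(cov).copy()
        out.append(MonitoringSummary(
            avg=mean, max=seg.max(axis=1), min=seg.min(axis=1),
            sd=np.sqrt(var), variance=var, covariance=cov,
            window_start=start / fs, window_end=end / fs))
        start += w
    return out


def build_feature_vector(events: list[OcclusionEvent],
                         covariates: list[dict],
                         window: float,
                         last_pain_level: int = 0) -> FeatureVector:
    """Fuse one window's events with their aligned per-event covariates.

    Covariates must be one record per event (``contact_area``,
    ``contact_points``, ``pain_level``).  A window without events yields
    zero force/duration/area features, flagged quiet, carrying the last
    known pain level.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(events) != len(covariates):
        raise ValueError(
            f"covariate/event misalignment: {len(events)} events vs "
            f"{len(covariates)} covariate records")
    if not events:
        return FeatureVector(0.0, 0.0, 0.0, 0, int(last_pain_level), quiet=True)

    mean_force = float(np.mean([e.mean_force for e in events]))
    mean_dur = float(np.mean([e.duration for e in events]))
    mean_area = float(np.mean([c["contact_area"] for c in covariates]))
    pts = [int(c["contact_points"]) for c in covariates]
    vals, counts_ = np.unique(pts, return_counts=True)
    modal_points = int(vals[np.argmax(counts_)])
    pain = int(covariates[-1]["pain_level"])
    return FeatureVector(mean_force, mean_dur, mean_area, modal_points, pain)


@dataclass
class Standardizer:
    """Per-channel z-scoring fitted on a training set of input blocks."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(N_INPUT_CHANNELS))
    sd: np.ndarray = field(default_factory=lambda: np.ones(N_INPUT_CHANNELS))

    def fit(self, blocks: np.ndarray) -> "Standardizer":
        # blocks: (n, channels, frames); constant channels keep sd 1
        self.mean = blocks.mean(axis=(0, 2))
        sd = blocks.std(axis=(0, 2))
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, blocks: np.ndarray) -> np.ndarray:
        return (blocks - self.mean[None, :, None]) / self.sd[None, :, None]

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(mean=np.asarray(d["mean"], float), sd=np.asarray(d["sd"], float))


def frames_to_tensor(features: list[FeatureVector],
                     per_channel_forces: np.ndarray,
                     n_frames: int = N_FRAMES) -> np.ndarray:
    """Pack time-ordered frames into a (16, n_frames) network input block.

    Channel layout: 6 per-sensor mean forces, then the 5 feature values,
    then 5 zero-padding channels.  Shorter sequences are zero-padded at the
    end; longer ones keep the most recent ``n_frames`` frames.
    Standardization is applied separately (see :class:`Standardizer`) with
    training-set statistics.
    """
    if not features:
        raise ValueError("need at least one frame")
    forces = np.asarray(per_channel_forces, dtype=float)
    if forces.ndim != 2 or forces.shape != (len(features), _N_SENSOR_CHANNELS):
        raise ValueError(
            f"per_channel_forces must have shape ({len(features)}, "
            f"{_N_SENSOR_CHANNELS})")

    frames = np.concatenate(
        [forces, np.stack([f.as_array() for f in features])], axis=1)
    frames = np.concatenate(
        [frames, np.zeros((len(features), _N_FEATURES))], axis=1)
    if frames.shape[0] >= n_frames:
        frames = frames[-n_frames:]
    else:
        frames = np.concatenate(
            [frames, np.zeros((n_frames - frames.shape[0], N_INPUT_CHANNELS))])
    return frames.T.copy()  # (channels, frames)
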