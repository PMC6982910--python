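"""Synthetic multichannel occlusal-force voltage traces with ground-truth episodes.

A splint carries several piezoresistive sensors whose bridge voltage rises
with bite force.  This module emulates that front end: bite episodes arrive
as a Poisson process, each episode is a smooth force pulse (clench) or an
amplitude-modulated pulse (grind) on top of a constant baseline, plus
additive Gaussian sensor noise.  Every episode carries ground-truth bounds,
per-channel peaks and clinical covariates (contact area, contact points,
pain level) so that downstream detection and classification can be scored
against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimulationParams",
    "EpisodeLabel",
    "SensorTrace",
    "default_params_for_class",
    "schedule_episodes",
    "render_trace",
    "simulate_trace",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs for one simulated monitoring session.

    ``severity_class`` selects an ordered regime: higher classes produce
    larger-amplitude, longer and more frequent episodes, and correlated
    covariates (larger contact area, more contact points, higher pain).
    """

    n_channels: int = 6
    sampling_rate: float = 100.0  # Hz
    duration: float = 120.0  # seconds
    episode_rate: float = 30.0  # events per hour
    amplitude_range: tuple[float, float] = (0.3, 0.8)  # volts above baseline
    episode_duration_range: tuple[float, float] = (0.5, 2.5)  # seconds
    noise_sigma: float = 0.02  # volts
    baseline: float = 0.2  # volts
    severity_class: int = 0
    grind_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.episode_rate < 0:
            raise ValueError("episode_rate must be non-negative")
        lo, hi = self.amplitude_range
        if not lo < hi:
            raise ValueError("amplitude_range must satisfy min < max")
        dlo, dhi = self.episode_duration_range
        if not 0 < dlo <= dhi:
            raise ValueError("episode_duration_range must satisfy 0 < min <= max")
        if self.severity_class not in (0, 1, 2):
            raise ValueError("severity_class must be one of {0, 1, 2}")
        if not 0.0 <= self.grind_fraction <= 1.0:
            raise ValueError("grind_fraction must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass(frozen=True)
class EpisodeLabel:
    """Ground truth for one bite episode (sample-index bounds, end exclusive)."""

    start: int
    end: int
    peak_per_channel: tuple[float, ...] = ()
    kind: str = "clench"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("episode must satisfy 0 <= start < end")
        if self.kind not in ("clench", "grind"):
            raise ValueError(f"unknown episode kind {self.kind!r}")


@dataclass
class SensorTrace:
    """Multichannel voltage series with sampling metadata and optional labels."""

    values: np.ndarray  # (n_channels, n_samples), volts
    sampling_rate: float
    labels: list[EpisodeLabel] = field(default_factory=list)
    covariates: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_channels, n_samples)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for lab in self.labels:
            if lab.end > self.n_samples:
                raise ValueError("episode label exceeds trace length")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


# Ordered severity regimes: mean amplitude, rate and duration all increase
# with class, as do the covariate means used by the feature extractor.
_CLASS_REGIMES = {
    0: dict(amplitude_range=(0.2, 0.5), episode_rate=20.0,
            episode_duration_range=(0.4, 1.5)),
    1: dict(amplitude_range=(0.8, 1.3), episode_rate=45.0,
            episode_duration_range=(1.0, 2.5)),
    2: dict(amplitude_range=(1.8, 2.6), episode_rate=90.0,
            episode_duration_range=(2.0, 4.0)),
}

_COVARIATE_MEANS = {  # (contact_area mm^2, contact_points, pain_level)
    0: (25.0, 3.0, 1.5),
    1: (50.0, 6.0, 4.5),
    2: (80.0, 9.0, 7.5),
}


def default_params_for_class(severity_class: int, *, seed: int = 0,
                             **overrides) -> SimulationParams:
    """Reference :class:`SimulationParams` for one severity regime."""
    if severity_class not in _CLASS_REGIMES:
        raise ValueError(f"severity_class must be 0, 1 or 2, got {severity_class}")
    kw = dict(_CLASS_REGIMES[severity_class])
    kw.update(overrides)
    return SimulationParams(severity_class=severity_class, seed=seed, **kw)


def schedule_episodes(params: SimulationParams,
                      rng: np.random.Generator | None = None) -> list[EpisodeLabel]:
    """Draw non-overlapping episode bounds from a homogeneous Poisson process.

    Arrival times follow exponential gaps at ``episode_rate``; an episode
    whose span would overlap the previous one or run past the end of the
    trace is dropped.  Deterministic for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.episode_rate == 0:
        return []
    fs = params.sampling_rate
    n = params.n_samples
    rate_per_s = params.episode_rate / 3600.0
    dlo, dhi = params.episode_duration_range

    episodes: list[EpisodeLabel] = []
    t = rng.exponential(1.0 / rate_per_s)
    prev_end = -1
    while t < params.duration:
        dur = rng.uniform(dlo, dhi)
        kind = "grind" if rng.uniform() < params.grind_fraction else "clench"
        start = int(round(t * fs))
        end = start + max(2, int(round(dur * fs)))
        if start > prev_end and end <= n:
            episodes.append(EpisodeLabel(start=start, end=end, kind=kind))
            prev_end = end
        t += rng.exponential(1.0 / rate_per_s)
    return episodes


def _pulse_envelope(length: int) -> np.ndarray:
    """Raised-cosine pulse normalized to unit peak for any length >= 2."""
    env = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(length) / (length - 1)))
    return env / env.max()


def _draw_covariates(rng: np.random.Generator, severity_class: int) -> dict:
    area_mu, pts_mu, pain_mu = _COVARIATE_MEANS[severity_class]
    area = float(np.clip(rng.normal(area_mu, 5.0), 1.0, 150.0))
    points = int(np.clip(round(rng.normal(pts_mu, 1.0)), 1, 16))
    pain = int(np.clip(round(rng.normal(pain_mu, 1.0)), 0, 10))
    return {"contact_area": area, "contact_points": points, "pain_level": pain}


def render_trace(schedule: list[EpisodeLabel], params: SimulationParams,
                 rng: np.random.Generator | None = None) -> SensorTrace:
    """Render a schedule into a noisy multichannel voltage trace.

    Each episode is a raised-cosine force pulse; grind episodes are further
    amplitude-modulated at 1-2 Hz.  One randomly chosen primary channel
    receives the full pulse amplitude, the remaining channels attenuated
    copies.  Labels are re-emitted with the realized per-channel peaks and
    covariates correlated with the severity class.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    n, c, fs = params.n_samples, params.n_channels, params.sampling_rate
    clean = np.full((c, n), params.baseline, dtype=float)
    amp_lo, amp_hi = params.amplitude_range

    labels: list[EpisodeLabel] = []
    covariates: list[dict] = []
    for ep in schedule:
        if ep.end > n:
            raise ValueError("schedule extends past the trace duration")
        length = ep.end - ep.start
        amp = rng.uniform(amp_lo, amp_hi)
        env = _pulse_envelope(length) * amp
        if ep.kind == "grind":
            f_mod = rng.uniform(1.0, 2.0)
            tt = np.arange(length) / fs
            mod = 1.0 - 0.25 * (1.0 - np.cos(2.0 * np.pi * f_mod * tt))
            env = env * mod
        gains = rng.uniform(0.3, 0.9, size=c)
        gains[rng.integers(c)] = 1.0
        pulse = gains[:, None] * env[None, :]
        clean[:, ep.start:ep.end] += pulse
        peaks = tuple(float(v) for v in clean[:, ep.start:ep.end].max(axis=1))
        labels.append(replace(ep, peak_per_channel=peaks))
        covariates.append(_draw_covariates(rng, params.severity_class))

    values = clean
    if params.noise_sigma > 0:
        values = clean + rng.normal(0.0, params.noise_sigma, size=clean.shape)
    return SensorTrace(values=values, sampling_rate=fs,
                       labels=labels, covariates=covariates)


def simulate_trace(params: SimulationParams) -> SensorTrace:
    """Schedule and render one session with a single seed."""
    rng = np.random.default_rng(params.seed)
    schedule = schedule_episodes(params, rng)
    return render_trace(schedule, params, rng)


def generate_dataset(
    n_per_class: int,
    params_by_class: dict[int, SimulationParams] | None = None,
    seed: int = 0,
) -> list[tuple[SensorTrace, int]]:
    """Balanced labeled set of traces, ``n_per_class`` per severity class.

    Per-trace seeds are spawned reproducibly from the master seed.
    """
    if params_by_class is None:
        params_by_class = {k: default_params_for_class(k) for k in (0, 1, 2)}
    missing = [k for k in (0, 1, 2) if k not in params_by_class]
    if missing:
        raise ValueError(f"missing SimulationParams for class(es) {missing}")
    if n_per_class < 0:
        raise ValueError("n_per_class must be non-negative")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3 * n_per_class)
    out: list[tuple[SensorTrace, int]] = []
    i = 0
    for cls in (0, 1, 2):
        base = params_by_class[cls]
        for _ in range(n_per_class):
            sub_seed = int(children[i].generate_state(1)[0])
            i += 1
            p = replace(base, severity_class=cls, seed=sub_seed)
            out.append((simulate_trace(p), cls))
    return out
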