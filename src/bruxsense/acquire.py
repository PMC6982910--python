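"""ADC coding and threshold-triggered occlusion event detection.

The front-end MCU digitizes the sensor voltages with a 10-bit converter
referenced at 3.6 V (count = floor(v * 1024 / 3.6), clamped to full scale;
the inverse transfer is volts = counts * 3.6 / 1024).  Detection follows a
sleep/wake workflow: the system sleeps until the across-channel maximum
exceeds a dentist-set threshold for a debounced number of samples, stays
active until the signal has been at or below threshold for a debounced
number of samples, and merges events separated by less than a refractory
gap.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .simulate import SensorTrace

__all__ = [
    "AdcConfig",
    "CountTrace",
    "DetectorConfig",
    "OcclusionEvent",
    "adc_encode",
    "counts_to_voltage",
    "detect_events",
    "update_threshold",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdcConfig:
    """Analog-to-digital converter transfer parameters."""

    reference_voltage: float = 3.6
    resolution_bits: int = 10
    per_channel: bool = False

    def __post_init__(self) -> None:
        if self.reference_voltage <= 0:
            raise ValueError("reference_voltage must be positive")
        if self.resolution_bits < 1:
            raise ValueError("resolution_bits must be >= 1")

    @property
    def full_scale(self) -> int:
        return 2 ** self.resolution_bits


@dataclass
class CountTrace:
    """Quantized integer sample series with its converter configuration."""

    counts: np.ndarray  # (n_channels, n_samples), integer counts
    adc: AdcConfig
    sampling_rate: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (n_channels, n_samples)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be an integer array")
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.adc.full_scale:
            raise ValueError("counts out of ADC range")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class DetectorConfig:
    """Sleep/wake detector parameters (all in counts/samples)."""

    threshold: int = 100
    debounce_on: int = 3
    debounce_off: int = 3
    refractory: int = 50  # samples (0.5 s at 100 Hz)
    audit_log: tuple = field(default_factory=tuple, compare=False)

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.debounce_on < 1 or self.debounce_off < 1:
            raise ValueError("debounce values must be >= 1")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")


@dataclass(frozen=True)
class OcclusionEvent:
    """One detected bite episode (end exclusive)."""

    start: int
    end: int
    duration: float  # seconds
    peak_per_channel: tuple[int, ...]
    mean_force: float  # mean across-channel-max count inside the event

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("event must satisfy start < end")


def adc_encode(trace: SensorTrace, adc: AdcConfig | None = None) -> CountTrace:
    """Quantize a voltage trace to integer counts.

    count = clamp(floor(v * 2^bits / reference), 0, 2^bits).  Saturation
    clamps to full scale rather than raising (hardware-faithful).
    """
    if adc is None:
        adc = AdcConfig()
    raw = np.floor(trace.values * adc.full_scale / adc.reference_voltage)
    counts = np.clip(raw, 0, adc.full_scale).astype(np.int64)
    return CountTrace(counts=counts, adc=adc, sampling_rate=trace.sampling_rate)


def counts_to_voltage(counts, adc: AdcConfig | None = None):
    """Inverse transfer: volts = counts * reference / 2^bits."""
    if adc is None:
        adc = AdcConfig()
    if isinstance(counts, CountTrace):
        counts = counts.counts
    return np.asarray(counts, dtype=float) * adc.reference_voltage / adc.full_scale


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal constant runs of a boolean array as (start, end, value)."""
    n = mask.size
    if n == 0:
        return []
    change = np.flatnonzero(mask[1:] != mask[:-1]) + 1
    bounds = np.concatenate(([0], change, [n]))
    return [(int(bounds[i]), int(bounds[i + 1]), bool(mask[bounds[i]]))
            for i in range(len(bounds) - 1)]


def detect_events(counts: CountTrace, cfg: DetectorConfig) -> list[OcclusionEvent]:
    """Run the sleep/wake state machine over the across-channel maximum.

    ACTIVE is entered after ``debounce_on`` consecutive samples strictly above
    threshold; SLEEP resumes after ``debounce_off`` consecutive samples at or
    below threshold.  An open event at end-of-trace is closed with trailing
    sub-threshold samples stripped.  Events whose gap is smaller than
    ``refractory`` are merged.  Implemented on maximal runs of the
    supra-threshold mask, which is equivalent to the per-sample machine.
    """
    if counts.n_samples == 0:
        raise ValueError("counts trace is empty")
    if cfg.threshold >= counts.adc.full_scale:
        logger.warning("threshold %d >= ADC full scale %d: detector can never fire",
                       cfg.threshold, counts.adc.full_scale)
        return []

    resultant = counts.counts.max(axis=0)
    supra = resultant > cfg.threshold

    raw: list[tuple[int, int]] = []
    active = False
    ev_start = 0
    ev_end = 0
    for start, end, val in _runs(supra):
        length = end - start
        if val:
            if not active and length >= cfg.debounce_on:
                active = True
                ev_start = start
            if active:
                ev_end = end
        else:
            if active and length >= cfg.debounce_off:
                active = False
                raw.append((ev_start, ev_end))
    if active:
        raw.append((ev_start, ev_end))

    merged: list[tuple[int, int]] = []
    for s, e in raw:
        if merged and s - merged[-1][1] < cfg.refractory:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    events = []
    for s, e in merged:
        window = counts.counts[:, s:e]
        events.append(OcclusionEvent(
            start=s, end=e,
            duration=(e - s) / counts.sampling_rate,
            peak_per_channel=tuple(int(v) for v in window.max(axis=1)),
            mean_force=float(window.max(axis=0).mean()),
        ))
    return events


def update_threshold(cfg: DetectorConfig, new_threshold: int,
                     full_scale: int = 1024) -> DetectorConfig:
    """Return a config with the threshold reset, recording an audit entry."""
    if not 0 <= new_threshold <= full_scale:
        raise ValueError(
            f"threshold {new_threshold} outside [0, {full_scale}]")
    entry = (time.time(), int(new_threshold))
    logger.info("detector threshold %d -> %d", cfg.threshold, new_threshold)
    return replace(cfg, threshold=int(new_threshold),
                   audit_log=cfg.audit_log + (entry,))
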