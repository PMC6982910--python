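"""End-to-end session orchestration and the threshold-feedback loop.

``run_session`` chains the analysis stages — denoise (analog domain by
default), ADC coding, event detection, monitoring statistics, feature
assembly and classification — into one :class:`SessionReport`.
``feedback_step`` closes the biofeedback loop: a declarative rule inspects
the report's event rate and raises the detector threshold remotely, exactly
as a clinician would between appointments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .acquire import (
    AdcConfig,
    DetectorConfig,
    adc_encode,
    detect_events,
    update_threshold,
)
from .classify.data import match_covariates
from .classify.train import load_checkpoint, predict_level
from .denoise import WaveletConfig, cycle_spin_denoise
from .features import build_feature_vector, frames_to_tensor, window_statistics
from .simulate import SensorTrace

__all__ = ["PipelineConfig", "SessionReport", "ThresholdRule",
           "run_session", "feedback_step"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    adc: AdcConfig = field(default_factory=AdcConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    window: float = 10.0  # seconds
    model_path: str | None = None
    denoise_domain: str = "analog"  # or "digital" (after ADC coding)
    denoise_enabled: bool = True

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.denoise_domain not in ("analog", "digital"):
            raise ValueError("denoise_domain must be 'analog' or 'digital'")

    def config_hash(self) -> str:
        payload = {
            "adc": dataclasses.asdict(self.adc),
            "detector": {"threshold": self.detector.threshold,
                         "debounce_on": self.detector.debounce_on,
                         "debounce_off": self.detector.debounce_off,
                         "refractory": self.detector.refractory},
            "wavelet": dataclasses.asdict(self.wavelet),
            "window": self.window,
            "denoise_domain": self.denoise_domain,
            "denoise_enabled": self.denoise_enabled,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SessionReport:
    """Everything one monitoring session produced, JSON-serializable."""

    n_events: int
    event_rate_per_hour: float
    duration: float
    summaries: list[dict]
    feature_frames: list[dict]
    predicted_level: dict | None
    threshold_history: list[tuple[float, int]]
    flags: list[str]
    config_hash: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionReport":
        d = dict(d)
        d["threshold_history"] = [tuple(t) for t in d["threshold_history"]]
        return cls(**d)


def _summary_record(s) -> dict:
    return {"window_start": s.window_start, "window_end": s.window_end,
            "avg": s.avg.tolist(), "max": s.max.tolist(),
            "min": s.min.tolist(), "sd": s.sd.tolist(),
            "variance": s.variance.tolist(),
            "covariance": s.covariance.tolist()}


def run_session(config: PipelineConfig, trace: SensorTrace) -> SessionReport:
    """Run the full analysis chain over one trace and assemble the report.

    Without a model the report stops after feature assembly (degraded, with
    a warning flag).  The whole run is deterministic for a fixed trace and
    configuration.
    """
    flags: list[str] = []
    work = trace
    if config.denoise_enabled and config.denoise_domain == "analog":
        den = np.stack([cycle_spin_denoise(ch, config.wavelet)
                        for ch in trace.values])
        work = SensorTrace(values=den, sampling_rate=trace.sampling_rate,
                           labels=trace.labels, covariates=trace.covariates)
    counts = adc_encode(work, config.adc)
    if config.denoise_enabled and config.denoise_domain == "digital":
        den = np.stack([cycle_spin_denoise(ch.astype(float), config.wavelet)
                        for ch in counts.counts])
        counts.counts = np.clip(np.round(den), 0,
                                config.adc.full_scale).astype(np.int64)
    if np.any(counts.counts >= config.adc.full_scale):
        flags.append("saturated")

    events = detect_events(counts, config.detector)
    covs = match_covariates(events, trace)
    summaries = window_statistics(counts, config.window)

    feats, forces = [], []
    last_pain = 0
    fs = counts.sampling_rate
    quiet_windows = 0
    for summ in summaries:
        s0 = int(round(summ.window_start * fs))
        s1 = int(round(summ.window_end * fs))
        in_win = [i for i, e in enumerate(events) if s0 <= e.start < s1]
        fv = build_feature_vector([events[i] for i in in_win],
                                  [covs[i] for i in in_win],
                                  config.window, last_pain_level=last_pain)
        last_pain = fv.pain_level
        quiet_windows += int(fv.quiet)
        feats.append(fv)
        forces.append(summ.avg[: min(6, len(summ.avg))])
    if quiet_windows:
        flags.append(f"quiet_windows:{quiet_windows}")

    predicted = None
    if config.model_path is not None and Path(config.model_path).exists():
        network, std = load_checkpoint(config.model_path)
        forces_arr = np.zeros((len(feats), 6))
        for i, fr in enumerate(forces):
            forces_arr[i, : len(fr)] = fr
        block = frames_to_tensor(feats, forces_arr)
        if std is not None:
            block = std.transform(block[None])[0]
        level = predict_level(network, block)
        predicted = {"level": level.level, "altitude": level.altitude,
                     "confidence": level.confidence}
    else:
        if config.model_path is not None:
            logger.warning("model %s not found; reporting without a "
                           "prediction", config.model_path)
        flags.append("no_model")

    duration = counts.n_samples / fs
    return SessionReport(
        n_events=len(events),
        event_rate_per_hour=len(events) / duration * 3600.0,
        duration=duration,
        summaries=[_summary_record(s) for s in summaries],
        feature_frames=[dataclasses.asdict(f) for f in feats],
        predicted_level=predicted,
        threshold_history=[(0.0, config.detector.threshold)],
        flags=flags,
        config_hash=config.config_hash(),
    )


@dataclass(frozen=True)
class ThresholdRule:
    """Raise the threshold by ``increment`` while the event rate exceeds
    ``max_rate_per_hour``; the threshold is clamped to full scale."""

    max_rate_per_hour: float = 60.0
    increment: int = 50

    def __post_init__(self) -> None:
        if self.max_rate_per_hour < 0 or self.increment < 0:
            raise ValueError("rule parameters must be non-negative")


def feedback_step(report: SessionReport, cfg: DetectorConfig,
                  rule: ThresholdRule,
                  full_scale: int = 1024) -> DetectorConfig:
    """Apply one remote threshold-update step based on a session report."""
    if report.event_rate_per_hour <= rule.max_rate_per_hour:
        return cfg
    new = cfg.threshold + rule.increment
    if new > full_scale:
        logger.warning("rule pushed threshold to %d; clamping to %d",
                       new, full_scale)
        new = full_scale
    return update_threshold(cfg, new, full_scale=full_scale)
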