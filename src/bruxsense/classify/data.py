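"""Labeled network-input blocks built from simulated monitoring sessions.

Runs the front half of the analysis chain (simulate -> ADC -> detect ->
window statistics -> feature vectors -> input block) to produce training
data for the classifier.  The ``separable_params_for_class`` regimes widen
the gaps between severity classes (amplitude, rate, duration) so that class
recovery is guaranteed by construction, which is what the desk-scale
training checks rely on.
"""

from __future__ import annotations

import numpy as np

from ..acquire import AdcConfig, DetectorConfig, adc_encode, detect_events
from ..features import (
    Standardizer,
    build_feature_vector,
    frames_to_tensor,
    window_statistics,
)
from ..simulate import SensorTrace, SimulationParams, default_params_for_class, simulate_trace

__all__ = [
    "separable_params_for_class",
    "trace_to_block",
    "make_session_blocks",
]


def separable_params_for_class(severity_class: int, *, seed: int = 0,
                               duration: float = 60.0) -> SimulationParams:
    """Severity regimes with widened inter-class gaps and busier sessions."""
    widened = {
        0: dict(amplitude_range=(0.15, 0.35), episode_rate=120.0,
                episode_duration_range=(0.4, 1.0)),
        1: dict(amplitude_range=(0.9, 1.2), episode_rate=240.0,
                episode_duration_range=(1.0, 2.0)),
        2: dict(amplitude_range=(2.0, 2.6), episode_rate=480.0,
                episode_duration_range=(2.0, 3.5)),
    }
    return default_params_for_class(severity_class, seed=seed,
                                    duration=duration,
                                    **widened[severity_class])


def match_covariates(events, trace: SensorTrace) -> list[dict]:
    """Covariate record per detected event, matched to the ground-truth
    episode with the largest sample overlap (zeros when nothing matches)."""
    out = []
    last_pain = 0
    for ev in events:
        best, best_ov = None, 0
        for lab, cov in zip(trace.labels, trace.covariates):
            ov = min(ev.end, lab.end) - max(ev.start, lab.start)
            if ov > best_ov:
                best, best_ov = cov, ov
        if best is None:
            best = {"contact_area": 0.0, "contact_points": 0,
                    "pain_level": last_pain}
        last_pain = best["pain_level"]
        out.append(best)
    return out


def trace_to_block(trace: SensorTrace, *, window: float = 10.0,
                   detector: DetectorConfig | None = None,
                   adc: AdcConfig | None = None) -> np.ndarray:
    """One session -> one (16, 128) unstandardized network-input block."""
    if detector is None:
        detector = DetectorConfig(threshold=80)
    counts = adc_encode(trace, adc)
    events = detect_events(counts, detector)
    covs = match_covariates(events, trace)
    summaries = window_statistics(counts, window)

    feats, forces = [], []
    last_pain = 0
    fs = counts.sampling_rate
    for summ in summaries:
        s0, s1 = int(round(summ.window_start * fs)), int(round(summ.window_end * fs))
        in_win = [i for i, e in enumerate(events) if s0 <= e.start < s1]
        fv = build_feature_vector([events[i] for i in in_win],
                                  [covs[i] for i in in_win],
                                  window, last_pain_level=last_pain)
        last_pain = fv.pain_level
        feats.append(fv)
        forces.append(summ.avg[:6])
    return frames_to_tensor(feats, np.stack(forces))


def make_session_blocks(
    n_per_class: int, seed: int = 0, *, duration: float = 60.0,
    window: float = 10.0, standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray, Standardizer]:
    """Balanced labeled block set from the widened-gap severity regimes.

    Returns (blocks (n, 16, 128), labels, fitted standardizer); blocks are
    standardized in place when requested.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3 * n_per_class)
    blocks, labels = [], []
    i = 0
    for cls in (0, 1, 2):
        for _ in range(n_per_class):
            sub_seed = int(children[i].generate_state(1)[0])
            i += 1
            params = separable_params_for_class(cls, seed=sub_seed,
                                                duration=duration)
            blocks.append(trace_to_block(simulate_trace(params), window=window))
            labels.append(cls)
    x = np.stack(blocks) if blocks else np.zeros((0, 16, 128))
    y = np.asarray(labels, dtype=np.int64)
    std = Standardizer().fit(x) if len(x) else Standardizer()
    if standardize and len(x):
        x = std.transform(x)
    return x, y, std
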