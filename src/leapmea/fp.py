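"""Field-potential endpoints: spike amplitude, FPD and Fridericia correction.

The FP depolarization spike is the sharp biphasic deflection at the beat
start; its amplitude (AMP) is the peak-to-trough range in a ±10 ms window
around the spike extremum. FPD runs from the spike extremum to the extremum
of the repolarization feature (T-wave analogue), searched polarity-agnostic
in a configurable post-spike window; strong triangulation can shrink the
feature below the noise floor, in which case FPD is reported as not
detected. FPDc applies the Fridericia cube-root rate correction,
``fpdc = fpd / (bp_s)^(1/3)`` with the beat period in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AnalysisConfig

_MAD_SCALE = 1.4826


@dataclass
class FPMetrics:
    fp_amp_uV: float | None
    fpd_ms: float | None
    fpdc_ms: float | None
    bp_ms: float | None


def compute_fp_amplitude(
    trace: np.ndarray, sampling_rate_hz: float, spike_idx: int, window_ms: float = 10.0
) -> float:
    """Spike peak-to-trough within ±window_ms of the spike extremum."""
    x = np.asarray(trace, dtype=float)
    half = int(round(window_ms * sampling_rate_hz / 1000.0))
    a = max(0, spike_idx - half)
    b = min(x.size, spike_idx + half + 1)
    w = x[a:b]
    if w.size == 0:
        raise ValueError("empty spike window")
    return float(np.max(w) - np.min(w))


def compute_fpd(
    trace: np.ndarray,
    sampling_rate_hz: float,
    spike_idx: int,
    bp_ms: float,
    config: AnalysisConfig | None = None,
) -> float | None:
    """Spike-to-repolarization-feature time in ms, or None when not found.

    The repolarization feature is the largest absolute deflection from the
    local baseline in ``[spike + fpd_min_ms, spike + 0.9·BP]``; ties break
    toward the earlier time. The feature must exceed ``fpd_noise_mult``
    robust noise SDs, otherwise None is returned (obscured repolarization).
    """
    config = config or AnalysisConfig()
    x = np.asarray(trace, dtype=float)
    a = spike_idx + int(round(config.fpd_min_ms * sampling_rate_hz / 1000.0))
    b = spike_idx + int(round(0.9 * bp_ms * sampling_rate_hz / 1000.0))
    b = min(b, x.size)
    if a >= b:
        return None
    window = x[a:b]
    baseline = float(np.median(window))
    dev = np.abs(window - baseline)
    # noise floor from the first difference: insensitive to genuine slow
    # repolarization structure, which would otherwise inflate the estimate
    diff = np.diff(window)
    noise = _MAD_SCALE * float(np.median(np.abs(diff - np.median(diff)))) / np.sqrt(2.0)
    i = int(np.argmax(dev))
    if dev[i] <= config.fpd_noise_mult * noise or dev[i] <= 0:
        return None
    return (a + i - spike_idx) * 1000.0 / sampling_rate_hz


def fridericia_correct(fpd_ms: float, bp_ms: float) -> float:
    """Rate-corrected FPD via the Fridericia cube-root convention."""
    if fpd_ms <= 0 or bp_ms <= 0:
        raise ValueError("fpd and bp must be > 0")
    return fpd_ms / (bp_ms / 1000.0) ** (1.0 / 3.0)


def percent_change(baseline: float, post: float) -> float:
    if baseline == 0:
        raise ValueError("zero baseline")
    return 100.0 * (post - baseline) / baseline
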