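"""AP morphology metrics and automated EAD detection on LEAP beats.

Conventions (all durations in ms):

* APD_x is measured from beat start to x% voltage repolarization, where full
  repolarization runs from the beat's peak (0%) to its trough (100%).
  Threshold crossings are linearly interpolated between samples.
* Rise time runs from the take-off point (last time before the maximum-slope
  point at which the smoothed dV/dt falls below a configurable fraction of
  the beat's maximum slope, default 10%) to the peak.
* The triangulation ratio is APD50/APD90: 1 for a perfectly square plateau
  and ~0.55 for a perfectly triangular (linear) repolarization; a lower
  ratio means stronger triangulation and higher arrhythmic risk.
* An EAD is a local maximum strictly between the depolarization peak and 90%
  repolarization whose topographic prominence within the repolarization limb
  is at least 20 µV and greater than 2.5% of the LEAP amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .beats import BeatTrain, moving_average, smoothed_slope
from .model import AnalysisConfig


@dataclass
class EADEvent:
    time_ms: float          # relative to the beat's start sample
    prominence_uV: float
    index: int              # sample index within the beat array


@dataclass
class APMetrics:
    """Per-electrode AP morphology summary (fixed output column names)."""

    apd30_ms: float
    apd50_ms: float
    apd90_ms: float
    rise_ms: float
    bp_ms: float
    bp_cov_pct: float
    tri_ratio: float
    ead_pct: float
    leap_amp_uV: float
    n_beats: int
    ead_count: int = 0
    apd_curve_ms: dict[int, float] = field(default_factory=dict)


def _repolarization_fraction(samples: np.ndarray, peak_idx: int, trough_uV: float) -> np.ndarray:
    v_peak = samples[peak_idx]
    denom = v_peak - trough_uV
    if denom <= 0:
        raise ValueError("beat has no repolarization range (peak <= trough)")
    return (v_peak - samples) / denom


def _crossing_time_ms(
    r: np.ndarray, peak_idx: int, frac: float, sampling_rate_hz: float
) -> float:
    """First post-peak time (ms) at which r >= frac, linearly interpolated."""
    post = r[peak_idx:]
    above = np.nonzero(post >= frac)[0]
    if above.size == 0:
        raise ValueError(f"repolarization never reaches {100 * frac:g}%")
    i = int(above[0])
    if i == 0:
        t = float(peak_idx)
    else:
        r0, r1 = post[i - 1], post[i]
        t = peak_idx + (i - 1) + (frac - r0) / (r1 - r0)
    return t * 1000.0 / sampling_rate_hz


def compute_apd(
    samples: np.ndarray,
    sampling_rate_hz: float,
    percentages=(30, 50, 90),
    start_idx: int = 0,
    peak_idx: int | None = None,
    trough_uV: float | None = None,
) -> dict[int, float]:
    """APD at the requested repolarization percentages, from beat start.

    ``samples`` is one aligned beat (or averaged template); ``start_idx`` is
    the beat-start sample (0 for a template aligned at beat start).
    """
    x = np.asarray(samples, dtype=float)
    if peak_idx is None:
        peak_idx = int(np.argmax(x))
    if trough_uV is None:
        trough_uV = float(np.min(x[peak_idx:]))
    r = _repolarization_fraction(x, peak_idx, trough_uV)
    t_start_ms = start_idx * 1000.0 / sampling_rate_hz
    out: dict[int, float] = {}
    for p in percentages:
        if not (0 <= p < 100):
            raise ValueError(f"percentage {p} outside [0, 100)")
        if p == 0:
            out[0] = peak_idx * 1000.0 / sampling_rate_hz - t_start_ms
        else:
            out[p] = _crossing_time_ms(r, peak_idx, p / 100.0, sampling_rate_hz) - t_start_ms
    return out


def apd_curve(
    samples: np.ndarray,
    sampling_rate_hz: float,
    step: int = 10,
    start_idx: int = 0,
) -> dict[int, float]:
    """Full APD0–90 repolarization curve (used for cell-type comparisons)."""
    return compute_apd(samples, sampling_rate_hz, range(0, 91, step), start_idx=start_idx)


def compute_rise_time(
    samples: np.ndarray,
    sampling_rate_hz: float,
    takeoff_fraction: float = 0.10,
    smooth_ms: float = 0.4,
) -> float:
    """Time from the take-off point to the peak of the upstroke, in ms.

    The upstroke end is the first point after the maximum-slope sample at
    which the smoothed slope returns to zero: on a flat-topped AP the
    literal argmax wanders over the plateau under noise, while the
    flattening point stays pinned to the end of the rise. An upstroke that
    completes within two raw samples is returned directly (its slope
    structure is below the sampling scale).
    """
    x = np.asarray(samples, dtype=float)
    rng = float(np.max(x) - np.min(x))
    if rng <= 0:
        raise ValueError("beat has no upstroke before its peak")
    argmax = int(np.argmax(x))
    if argmax == 0:
        raise ValueError("beat has no upstroke before its peak")
    # degenerate near-instantaneous upstroke
    j = argmax
    while j > 0 and x[j - 1] < x[j]:
        j -= 1
    if argmax - j <= 2 and x[argmax] - x[j] >= 0.9 * rng:
        return (argmax - j) * 1000.0 / sampling_rate_hz

    slope = smoothed_slope(x, sampling_rate_hz, smooth_ms)
    up = slope[: argmax + 1]
    ms_idx = int(np.argmax(up))
    max_slope = up[ms_idx]
    if max_slope <= 0:
        raise ValueError("non-rising upstroke")
    flat = np.nonzero(slope[ms_idx:] <= 0)[0]
    peak_idx = ms_idx + int(flat[0]) if flat.size else argmax
    thr = takeoff_fraction * max_slope
    below = np.nonzero(up[:ms_idx] < thr)[0]
    if below.size == 0:
        takeoff = 0.0
    else:
        k = int(below[-1])
        # linear interpolation of the upward threshold crossing
        s0, s1 = up[k], up[k + 1]
        takeoff = k + (thr - s0) / (s1 - s0) if s1 > s0 else float(k)
    return (peak_idx - takeoff) * 1000.0 / sampling_rate_hz


def compute_bp_cov(train_or_starts) -> tuple[float, float] | None:
    """(mean beat period ms, CoV %) from beat starts; None below 3 beats.

    The CoV uses the sample SD (n−1 denominator).
    """
    if isinstance(train_or_starts, BeatTrain):
        starts = train_or_starts.starts_ms
    else:
        starts = np.asarray(train_or_starts, dtype=float)
    if starts.size < 3:
        return None
    bp = np.diff(starts)
    mean = float(np.mean(bp))
    cov = 100.0 * float(np.std(bp, ddof=1)) / mean
    return mean, cov


def triangulation_ratio(apd50_ms: float, apd90_ms: float) -> float:
    if apd90_ms <= 0:
        raise ValueError("apd90 must be > 0")
    if apd50_ms > apd90_ms * (1 + 1e-12):
        raise ValueError("apd50 > apd90 violates APD monotonicity")
    return apd50_ms / apd90_ms


def detect_eads(
    samples_uV: np.ndarray,
    sampling_rate_hz: float,
    leap_amplitude_uV: float,
    config: AnalysisConfig | None = None,
) -> list[EADEvent]:
    """EAD events on one un-normalized (µV) beat.

    Candidate peaks are local maxima strictly between the depolarization peak
    and the time of 90% repolarization; each must have topographic prominence
    (height above the greater of its two flanking minima, evaluated within
    the repolarization limb) ≥ 20 µV and > 2.5% of the LEAP amplitude.
    """
    config = config or AnalysisConfig()
    x = np.asarray(samples_uV, dtype=float)
    # mild moving-average smoothing: white noise can otherwise fake
    # prominences near the 20 µV floor, while genuine EAD bumps (tens of
    # ms wide) pass through essentially unattenuated; a moving average,
    # unlike a local polynomial, cannot overshoot at sharp corners
    w = int(round(config.ead_smooth_ms * sampling_rate_hz / 1000.0))
    if w >= 3:
        x = moving_average(x, w)
    # the depolarization peak is re-located on the smoothed signal: smoothing
    # smears the upstroke, and a search segment opened at the raw peak index
    # would start mid-smear and misread the plateau as a prominent peak
    peak_idx = int(np.argmax(x))
    post = x[peak_idx:]
    if post.size < 3:
        raise ValueError("beat lacks a repolarization limb")
    trough = float(np.min(post))
    r = _repolarization_fraction(x, peak_idx, trough)
    above = np.nonzero(r[peak_idx:] >= 0.9)[0]
    end = peak_idx + (int(above[0]) if above.size else post.size - 1)
    segment = x[peak_idx + 1 : end]  # strictly between peak and 90% repol
    if segment.size < 3:
        return []
    idx, props = sps.find_peaks(segment, prominence=0)
    events = []
    for i, prom in zip(idx, props["prominences"]):
        if prom >= config.ead_abs_uV and prom > config.ead_frac * leap_amplitude_uV:
            abs_idx = peak_idx + 1 + int(i)
            events.append(
                EADEvent(
                    time_ms=abs_idx * 1000.0 / sampling_rate_hz,
                    prominence_uV=float(prom),
                    index=abs_idx,
                )
            )
    return events


def percent_beats_with_eads(n_beats: int, events_per_beat: list[list[EADEvent]]) -> float:
    if n_beats <= 0:
        raise ValueError("empty beat train")
    flagged = sum(1 for ev in events_per_beat if ev)
    return 100.0 * flagged / n_beats
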