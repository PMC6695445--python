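"""Filtering, signal classification, beat detection and beat averaging.

The classification rule distinguishes high-coupling AP-shaped (LEAP) signals
from ordinary field potentials: a LEAP trace must show a standard deviation
above 100 µV *and* a beat amplitude above 350 µV (most genuine LEAP signals
are 1–10 mV). An electrode with no detectable beats is quiescent.

Beat starts are defined at the maximum slope of the rising edge. The slope is
estimated with a Savitzky–Golay local-polynomial derivative (~2 ms window):
raw single-sample differencing at 12.5 kHz is noise-dominated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .model import AnalysisConfig, ElectrodeID

# Robust Gaussian SD from the median absolute deviation.
_MAD_SCALE = 1.4826
# Detection floor in robust-noise SDs; keeps the false-positive rate on pure
# noise negligible even over millions of samples.
_NOISE_FLOOR_MULT = 6.0


class SignalClass(enum.Enum):
    LEAP = "LEAP"
    FP = "FP"
    QUIESCENT = "QUIESCENT"


@dataclass
class Beat:
    """One detected beat: start sample, window bounds, peak/trough stats."""

    start_idx: int
    window_start: int
    window_stop: int
    peak_idx: int
    trough_idx: int
    peak_uV: float
    trough_uV: float

    @property
    def amplitude_uV(self) -> float:
        return self.peak_uV - self.trough_uV


@dataclass
class BeatTrain:
    sampling_rate_hz: float
    beats: list[Beat] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.beats)

    @property
    def starts_ms(self) -> np.ndarray:
        return np.array([b.start_idx for b in self.beats]) * 1000.0 / self.sampling_rate_hz

    @property
    def bp_ms(self) -> np.ndarray:
        """Beat periods: time between consecutive beat starts."""
        return np.diff(self.starts_ms)

    @property
    def amplitudes_uV(self) -> np.ndarray:
        return np.array([b.amplitude_uV for b in self.beats])

    def median_amplitude_uV(self) -> float:
        if not self.beats:
            return 0.0
        return float(np.median(self.amplitudes_uV))


@dataclass
class WaveformTemplate:
    """Amplitude-normalized (trough = 0, peak = 1) beat-averaged waveform.

    ``start_offset`` is the number of samples between the template's first
    sample and the beat start (windows open slightly before the beat start
    so the take-off point is visible).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    n_beats: int
    source_amplitude_uV: float
    start_offset: int = 0


@dataclass
class SignalClassification:
    label: SignalClass
    sd_uV: float
    amplitude_uV: float
    train: BeatTrain


def bandpass(trace: np.ndarray, low_hz: float, high_hz: float, sampling_rate_hz: float) -> np.ndarray:
    """Zero-phase band-pass (cascaded 2nd-order Butterworth high- and low-pass).

    Zero-phase filtering (forward-backward) preserves fiducial timing; with
    ``low_hz > 0`` the DC component is removed.
    """
    nyq = sampling_rate_hz / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ValueError(f"high edge {high_hz} Hz is at or above Nyquist ({nyq} Hz)")
    x = np.asarray(trace, dtype=float)
    sos_hp = sps.butter(2, low_hz, btype="highpass", fs=sampling_rate_hz, output="sos")
    sos_lp = sps.butter(2, high_hz, btype="lowpass", fs=sampling_rate_hz, output="sos")
    y = sps.sosfiltfilt(sos_hp, x)
    y = sps.sosfiltfilt(sos_lp, y)
    return y


def condition_trace(
    trace: np.ndarray,
    sampling_rate_hz: float,
    config: AnalysisConfig,
    leap: bool,
) -> np.ndarray:
    """Band-limit a trace with the configured band for its signal kind.

    When the trace is shorter than one period of the low band edge (the
    0.01 Hz LEAP edge has a ~16 s time constant), the high-pass stage has
    nothing to remove and would only inject edge transients that bow the
    baseline — it is skipped and only the low-pass is applied. All
    morphology metrics are offset-invariant, so DC is harmless there.
    """
    x = np.asarray(trace, dtype=float)
    lo, hi = config.band_for(leap=leap, sampling_rate_hz=sampling_rate_hz)
    duration_s = x.size / sampling_rate_hz
    if lo * duration_s < 1.0:
        sos_lp = sps.butter(2, hi, btype="lowpass", fs=sampling_rate_hz, output="sos")
        return sps.sosfiltfilt(sos_lp, x)
    return bandpass(x, lo, hi, sampling_rate_hz)


def _odd_window(ms: float, sampling_rate_hz: float, minimum: int = 5) -> int:
    w = max(minimum, int(round(ms * sampling_rate_hz / 1000.0)))
    return w + 1 if w % 2 == 0 else w


def smoothed_slope(trace: np.ndarray, sampling_rate_hz: float, window_ms: float) -> np.ndarray:
    """Savitzky–Golay first derivative, in µV/ms."""
    x = np.asarray(trace, dtype=float)
    w = _odd_window(window_ms, sampling_rate_hz)
    if x.size <= w:
        return np.gradient(x) * sampling_rate_hz / 1000.0
    return sps.savgol_filter(x, w, polyorder=3, deriv=1, delta=1000.0 / sampling_rate_hz)


def moving_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred moving average with edge replication (never overshoots)."""
    w = int(window_samples)
    if w < 2 or x.size <= w:
        return np.asarray(x, dtype=float)
    kernel = np.ones(w) / w
    pad = np.concatenate([np.full(w, x[0]), x, np.full(w, x[-1])])
    return np.convolve(pad, kernel, mode="same")[w:-w]


def _robust_sigma(x: np.ndarray) -> float:
    med = np.median(x)
    return _MAD_SCALE * float(np.median(np.abs(x - med)))


def _adaptive_event_indices(
    score: np.ndarray,
    sigma: float,
    sampling_rate_hz: float,
    refractory_ms: float,
    slope_fraction: float,
) -> np.ndarray:
    """Two-pass adaptive peak picking on a non-negative score signal.

    ``sigma`` is the robust noise SD of the *unclipped* underlying signal
    (a clipped or rectified score would underestimate it). Pass 1 finds
    prominent events above max(half the global maximum, the noise floor);
    the final threshold is ``slope_fraction`` of the 95th percentile of
    those event heights (never below the noise floor).
    """
    if score.size == 0:
        return np.array([], dtype=int)
    floor = _NOISE_FLOOR_MULT * sigma
    peak = float(np.max(score))
    if peak <= floor or peak <= 0:
        return np.array([], dtype=int)
    distance = max(1, int(round(refractory_ms * sampling_rate_hz / 1000.0)))
    idx0, props0 = sps.find_peaks(score, height=max(0.5 * peak, floor), distance=distance)
    if idx0.size == 0:
        return np.array([], dtype=int)
    robust_height = float(np.percentile(props0["peak_heights"], 95))
    thr = max(slope_fraction * robust_height, floor)
    idx, _ = sps.find_peaks(score, height=thr, distance=distance)
    return idx


def _build_beats(
    trace: np.ndarray,
    starts: np.ndarray,
    sampling_rate_hz: float,
    pre_window_ms: float = 0.0,
) -> BeatTrain:
    """Segment beats at the detected starts; drop partial edge beats.

    Each window opens ``pre_window_ms`` before its beat start (so the
    take-off point and full upstroke are inside it) and closes the same
    margin before the next start; the peak is the window maximum and the
    trough the post-peak minimum (complete repolarization). A first beat
    without room for the pre-margin, or a final beat whose window is shorter
    than 90% of the median beat period, is discarded as partial.
    """
    train = BeatTrain(sampling_rate_hz)
    if starts.size == 0:
        return train
    pre = int(round(pre_window_ms * sampling_rate_hz / 1000.0))
    keep_last = True
    if starts.size >= 2:
        median_bp = float(np.median(np.diff(starts)))
        if (trace.size - starts[-1]) < 0.9 * median_bp:
            keep_last = False
    n = starts.size if keep_last else starts.size - 1
    for i in range(n):
        s = int(starts[i])
        a = max(0, s - pre)  # clamped at the trace edge
        b = int(starts[i + 1]) - pre if i + 1 < starts.size else trace.size
        window = trace[a:b]
        if window.size < 2:
            continue
        peak_rel = int(np.argmax(window))
        trough_rel = peak_rel + int(np.argmin(window[peak_rel:]))
        train.beats.append(
            Beat(
                start_idx=s,
                window_start=a,
                window_stop=b,
                peak_idx=a + peak_rel,
                trough_idx=a + trough_rel,
                peak_uV=float(window[peak_rel]),
                trough_uV=float(window[trough_rel]),
            )
        )
    return train


def detect_beats_ap(
    trace: np.ndarray, sampling_rate_hz: float, config: AnalysisConfig | None = None
) -> BeatTrain:
    """Detect AP-shaped beats; beat start = time of maximum upstroke slope."""
    config = config or AnalysisConfig()
    x = np.asarray(trace, dtype=float)
    slope = smoothed_slope(x, sampling_rate_hz, config.detect_smooth_ms)
    starts = _adaptive_event_indices(
        np.clip(slope, 0, None),
        _robust_sigma(slope),
        sampling_rate_hz,
        config.refractory_ms,
        config.slope_fraction,
    )
    # refine each start to the centre of its near-maximal slope region: on a
    # linear upstroke the slope plateau is flat and the argmax wanders under
    # noise, while the plateau midpoint stays at the middle of the rise
    refined = []
    for idx in starts:
        peak = slope[idx]
        lo = idx
        while lo > 0 and slope[lo - 1] >= 0.8 * peak:
            lo -= 1
        hi = idx
        while hi + 1 < slope.size and slope[hi + 1] >= 0.8 * peak:
            hi += 1
        refined.append((lo + hi) // 2)
    return _build_beats(x, np.asarray(refined, dtype=int), sampling_rate_hz, config.pre_window_ms)


def detect_beats_fp(
    trace: np.ndarray, sampling_rate_hz: float, config: AnalysisConfig | None = None
) -> BeatTrain:
    """Detect FP beats at depolarization spikes; beat start = spike extremum."""
    config = config or AnalysisConfig()
    x = np.asarray(trace, dtype=float)
    centered = x - np.median(x)
    starts = _adaptive_event_indices(
        np.abs(centered),
        _robust_sigma(centered),
        sampling_rate_hz,
        config.refractory_ms,
        config.slope_fraction,
    )
    return _build_beats(x, starts, sampling_rate_hz, config.pre_window_ms)


def class_rule(sd_uV: float, amplitude_uV: float, config: AnalysisConfig | None = None) -> SignalClass:
    """The published LEAP/FP decision rule on SD and beat amplitude."""
    config = config or AnalysisConfig()
    if sd_uV > config.sd_threshold_uV and amplitude_uV > config.amp_threshold_uV:
        return SignalClass.LEAP
    return SignalClass.FP


def classify_signal(
    trace: np.ndarray, sampling_rate_hz: float, config: AnalysisConfig | None = None
) -> SignalClassification:
    """Classify an electrode trace as LEAP, FP or quiescent.

    The SD/amplitude rule is applied to the LEAP-band filtered trace; the
    amplitude is the median per-beat peak-to-trough (global max−min when beat
    segmentation yields nothing usable). No beats at all ⇒ quiescent.
    """
    config = config or AnalysisConfig()
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    if x.size < sampling_rate_hz:
        raise ValueError("trace shorter than 1 s cannot be classified")
    filt = condition_trace(x, sampling_rate_hz, config, leap=True)
    train = detect_beats_ap(filt, sampling_rate_hz, config)
    if len(train) == 0:
        train = detect_beats_fp(filt, sampling_rate_hz, config)
    if len(train) == 0:
        return SignalClassification(SignalClass.QUIESCENT, float(np.std(filt)), 0.0, train)
    # classification amplitude: full-window peak-to-peak per beat (robust to
    # the spike polarity of FP signals), median across beats
    p2p = [
        float(np.max(filt[b.window_start : b.window_stop]))
        - float(np.min(filt[b.window_start : b.window_stop]))
        for b in train.beats
    ]
    amp = float(np.median(p2p)) if p2p else 0.0
    if amp <= 0:
        amp = float(np.max(filt) - np.min(filt))
    sd = float(np.std(filt))
    return SignalClassification(class_rule(sd, amp, config), sd, amp, train)


def segment_normalize_average(
    trace: np.ndarray,
    train: BeatTrain,
    n_beats: int = 5,
) -> WaveformTemplate:
    """Normalize each beat trough→0 / peak→1, align at beat start, average.

    The first ``min(n_beats, available)`` beats with a full pre-start margin
    are used (an edge-clamped first beat is skipped when others exist).
    Beats are aligned at their start sample; the post-start length is the
    shortest available, capped at the median beat period. The averaged
    waveform is re-normalized so its own trough is exactly 0 and peak
    exactly 1.
    """
    if len(train) == 0:
        raise ValueError("no beats to average")
    offsets = [b.start_idx - b.window_start for b in train.beats]
    pre = max(offsets)
    eligible = [b for b in train.beats if b.start_idx - b.window_start == pre]
    if not eligible:
        pre = min(offsets)
        eligible = train.beats
    m = min(n_beats, len(eligible))
    beats = eligible[:m]
    post = min(b.window_stop - b.start_idx for b in beats)
    if len(train) >= 2:
        bp = train.bp_ms
        median_bp_samples = int(np.median(bp) * train.sampling_rate_hz / 1000.0)
        post = min(post, median_bp_samples)
    stack = []
    amps = []
    for b in beats:
        w = np.asarray(trace[b.start_idx - pre : b.start_idx + post], dtype=float)
        peak = w.max()
        peak_rel = int(np.argmax(w))
        trough = w[peak_rel:].min()
        if peak == trough:
            raise ValueError("constant (zero-amplitude) beat window")
        stack.append((w - trough) / (peak - trough))
        amps.append(peak - trough)
    avg = np.mean(stack, axis=0)
    peak_rel = int(np.argmax(avg))
    trough = avg[peak_rel:].min()
    avg = (avg - trough) / (avg.max() - trough)
    return WaveformTemplate(
        samples=avg,
        sampling_rate_hz=train.sampling_rate_hz,
        n_beats=m,
        source_amplitude_uV=float(np.median(amps)),
        start_offset=pre,
    )


def select_best_electrode(
    traces: dict[str, np.ndarray],
    sampling_rate_hz: float,
    config: AnalysisConfig | None = None,
    classifications: dict[str, SignalClassification] | None = None,
) -> str | None:
    """Largest, most robust LEAP electrode in a well.

    Among LEAP-class electrodes, returns the one with the largest median beat
    amplitude; amplitude ties break toward the lowest electrode index.
    Returns ``None`` when no electrode is LEAP-class.
    """
    if not traces:
        raise ValueError("empty well")
    config = config or AnalysisConfig()
    best: tuple[float, int] | None = None
    best_key = None
    for key, trace in traces.items():
        cls = (
            classifications[key]
            if classifications is not None
            else classify_signal(trace, sampling_rate_hz, config)
        )
        if cls.label is not SignalClass.LEAP:
            continue
        amp = cls.train.median_amplitude_uV()
        rank = (-amp, ElectrodeID.parse(key).index)
        if best is None or rank < best:
            best = rank
            best_key = key
    return best_key
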