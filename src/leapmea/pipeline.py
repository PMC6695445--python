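"""Well- and plate-level orchestration.

Per-well analysis composes classification, beat detection, beat averaging
and the AP/FP metric modules: AP morphology comes from the best (largest
median-amplitude) LEAP electrode in the well, FP endpoints are averaged over
the FP-class electrodes, and a well with no beating electrode is flagged
quiescent and carries no morphology metrics. On top sit the assay-level
summaries: signal-stability time-courses over post-induction checkpoints,
endpoint-style dose-response tables, pacing analysis per rate block and a
thin two-sided rank-sum comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import ap as ap_mod
from . import fp as fp_mod
from .beats import (
    BeatTrain,
    SignalClass,
    SignalClassification,
    classify_signal,
    condition_trace,
    detect_beats_ap,
    moving_average,
    segment_normalize_average,
    select_best_electrode,
)
from .model import AnalysisConfig, ElectrodeID, PlateMap, Recording

AP_METRIC_NAMES = [
    "apd30_ms", "apd50_ms", "apd90_ms", "rise_ms", "bp_ms", "bp_cov_pct",
    "tri_ratio", "ead_pct", "leap_amp_uV",
]
FP_METRIC_NAMES = ["fp_amp_uV", "fpd_ms", "fpdc_ms", "fp_bp_ms"]


@dataclass
class WellResult:
    well: str
    electrode_classes: dict[str, SignalClass]
    chosen_electrode: str | None
    ap: ap_mod.APMetrics | None
    fp: fp_mod.FPMetrics | None
    n_beats: int
    quiescent: bool

    def to_row(self) -> dict:
        row: dict = {"well": self.well, "quiescent": self.quiescent,
                     "chosen_electrode": self.chosen_electrode, "n_beats": self.n_beats}
        for name in AP_METRIC_NAMES:
            row[name] = getattr(self.ap, name) if self.ap is not None else np.nan
        if self.fp is not None:
            row["fp_amp_uV"] = self.fp.fp_amp_uV
            row["fpd_ms"] = self.fp.fpd_ms
            row["fpdc_ms"] = self.fp.fpdc_ms
            row["fp_bp_ms"] = self.fp.bp_ms
        else:
            for name in FP_METRIC_NAMES:
                row[name] = np.nan
        return row


@dataclass
class StabilityTimecourse:
    checkpoints_min: list[float]
    fractions: list[float]
    n_wells: int


def _ap_metrics_from_trace(
    trace: np.ndarray,
    sampling_rate_hz: float,
    train: BeatTrain,
    config: AnalysisConfig,
) -> ap_mod.APMetrics | None:
    """AP morphology from a LEAP-class filtered trace and its beat train."""
    if len(train) == 0:
        return None
    template = segment_normalize_average(trace, train, config.beats_to_average)
    apds = ap_mod.compute_apd(
        template.samples, sampling_rate_hz, (30, 50, 90), start_idx=template.start_offset
    )
    # rise time per beat, then the median: averaging jittered beats smears
    # the upstroke corner and would bias a template-based measurement
    rises = []
    for b in train.beats[: config.beats_to_average]:
        try:
            rises.append(
                ap_mod.compute_rise_time(
                    trace[b.window_start : b.window_stop],
                    sampling_rate_hz,
                    config.takeoff_fraction,
                    config.rise_smooth_ms,
                )
            )
        except ValueError:
            pass
    rise = float(np.median(rises)) if rises else np.nan
    bp_stats = ap_mod.compute_bp_cov(train)
    bp_mean, bp_cov = bp_stats if bp_stats is not None else (np.nan, np.nan)
    # amplitude from lightly smoothed windows: the raw per-window max-min
    # carries an extreme-value noise bias of a few percent
    w_ma = max(2, int(round(config.ead_smooth_ms * sampling_rate_hz / 1000.0)))
    amps = []
    for b in train.beats:
        sm = moving_average(trace[b.window_start : b.window_stop], w_ma)
        amps.append(float(np.max(sm) - np.min(sm)))
    leap_amp = float(np.median(amps)) if amps else 0.0
    events_per_beat = []
    for b in train.beats:
        window = trace[b.window_start : b.window_stop]
        try:
            events = ap_mod.detect_eads(window, sampling_rate_hz, leap_amp, config)
        except ValueError:
            events = []
        events_per_beat.append(events)
    ead_pct = ap_mod.percent_beats_with_eads(len(train), events_per_beat)
    return ap_mod.APMetrics(
        apd30_ms=apds[30],
        apd50_ms=apds[50],
        apd90_ms=apds[90],
        rise_ms=rise,
        bp_ms=bp_mean,
        bp_cov_pct=bp_cov,
        tri_ratio=ap_mod.triangulation_ratio(apds[50], apds[90]),
        ead_pct=ead_pct,
        leap_amp_uV=leap_amp,
        n_beats=len(train),
        ead_count=sum(len(e) for e in events_per_beat),
    )


def _fp_metrics_from_trace(
    trace: np.ndarray, sampling_rate_hz: float, train: BeatTrain, config: AnalysisConfig
) -> fp_mod.FPMetrics | None:
    if len(train) == 0:
        return None
    amps, fpds, fpdcs = [], [], []
    bp = ap_mod.compute_bp_cov(train)
    bp_mean = bp[0] if bp is not None else (
        float(np.mean(train.bp_ms)) if len(train) >= 2 else np.nan
    )
    for b in train.beats:
        spike = b.start_idx
        amps.append(fp_mod.compute_fp_amplitude(trace, sampling_rate_hz, spike))
        if math.isfinite(bp_mean):
            d = fp_mod.compute_fpd(trace, sampling_rate_hz, spike, bp_mean, config)
            if d is not None:
                fpds.append(d)
                fpdcs.append(fp_mod.fridericia_correct(d, bp_mean))
    return fp_mod.FPMetrics(
        fp_amp_uV=float(np.median(amps)) if amps else None,
        fpd_ms=float(np.median(fpds)) if fpds else None,
        fpdc_ms=float(np.median(fpdcs)) if fpdcs else None,
        bp_ms=bp_mean if math.isfinite(bp_mean) else None,
    )


def analyze_well(
    traces: dict[str, np.ndarray],
    sampling_rate_hz: float,
    config: AnalysisConfig | None = None,
    well: str | None = None,
) -> WellResult:
    """Classify every electrode in a well and extract AP and FP metrics."""
    if not traces:
        raise ValueError("empty well")
    config = config or AnalysisConfig()
    if well is None:
        well = ElectrodeID.parse(next(iter(traces))).well
    classifications: dict[str, SignalClassification] = {
        key: classify_signal(tr, sampling_rate_hz, config) for key, tr in traces.items()
    }
    classes = {key: c.label for key, c in classifications.items()}
    quiescent = all(c is SignalClass.QUIESCENT for c in classes.values())

    chosen = select_best_electrode(traces, sampling_rate_hz, config, classifications)
    ap_metrics = None
    n_beats = 0
    if chosen is not None:
        filt = condition_trace(traces[chosen], sampling_rate_hz, config, leap=True)
        train = classifications[chosen].train
        ap_metrics = _ap_metrics_from_trace(filt, sampling_rate_hz, train, config)
        n_beats = len(train)

    fp_list = []
    for key, c in classifications.items():
        if c.label is not SignalClass.FP:
            continue
        filt = condition_trace(traces[key], sampling_rate_hz, config, leap=False)
        m = _fp_metrics_from_trace(filt, sampling_rate_hz, c.train, config)
        if m is not None:
            fp_list.append(m)
            n_beats = max(n_beats, len(c.train))
    fp_metrics = None
    if fp_list:
        def _mean(vals):
            vals = [v for v in vals if v is not None]
            return float(np.mean(vals)) if vals else None
        fp_metrics = fp_mod.FPMetrics(
            fp_amp_uV=_mean([m.fp_amp_uV for m in fp_list]),
            fpd_ms=_mean([m.fpd_ms for m in fp_list]),
            fpdc_ms=_mean([m.fpdc_ms for m in fp_list]),
            bp_ms=_mean([m.bp_ms for m in fp_list]),
        )
    return WellResult(
        well=well,
        electrode_classes=classes,
        chosen_electrode=chosen,
        ap=ap_metrics if not quiescent else None,
        fp=fp_metrics if not quiescent else None,
        n_beats=n_beats,
        quiescent=quiescent,
    )


def analyze_plate(
    recording: Recording, config: AnalysisConfig | None = None
) -> list[WellResult]:
    config = config or AnalysisConfig()
    results = []
    for well, keys in recording.wells().items():
        traces = {k: recording.traces[k] for k in keys}
        results.append(analyze_well(traces, recording.sampling_rate_hz, config, well=well))
    return results


def metrics_table(results: list[WellResult]) -> pd.DataFrame:
    """Per-well metric table with the fixed column names.

    Absent values are kept as NaN; :func:`write_metrics` serializes them as
    "Q" (quiescent well) or "ND" (feature not detected).
    """
    return pd.DataFrame([r.to_row() for r in results])


def write_metrics(results: list[WellResult], path) -> None:
    df = metrics_table(results).copy()
    metric_cols = AP_METRIC_NAMES + FP_METRIC_NAMES
    df[metric_cols] = df[metric_cols].astype(object)
    for i, r in enumerate(results):
        for col in metric_cols:
            if pd.isna(df.at[i, col]):
                df.at[i, col] = "Q" if r.quiescent else "ND"
    df.to_csv(path, index=False)


def stability_timecourse(
    recordings: list[Recording],
    checkpoints_min: list[float] | None = None,
    config: AnalysisConfig | None = None,
) -> StabilityTimecourse:
    """Fraction of wells whose originally chosen electrode stays LEAP-class.

    One recording per checkpoint, same plate layout throughout. The electrode
    chosen at the first checkpoint (the best LEAP electrode per well) defines
    well membership; a well with no LEAP electrode at the first checkpoint is
    excluded from the denominator.
    """
    if checkpoints_min is None:
        checkpoints_min = [0, 2, 5, 10, 20]
    if len(recordings) != len(checkpoints_min):
        raise ValueError("one recording required per checkpoint")
    config = config or AnalysisConfig()
    first = recordings[0]
    layout = first.wells()
    for rec in recordings[1:]:
        if rec.wells().keys() != layout.keys():
            missing = set(layout) ^ set(rec.wells())
            raise ValueError(f"checkpoint recording is missing wells: {sorted(missing)}")
    chosen: dict[str, str] = {}
    for well, keys in layout.items():
        traces = {k: first.traces[k] for k in keys}
        best = select_best_electrode(traces, first.sampling_rate_hz, config)
        if best is not None:
            chosen[well] = best
    if not chosen:
        raise ValueError("no well has a LEAP electrode at the first checkpoint")
    fractions = []
    for rec in recordings:
        stable = 0
        for well, key in chosen.items():
            c = classify_signal(rec.traces[key], rec.sampling_rate_hz, config)
            if c.label is SignalClass.LEAP:
                stable += 1
        fractions.append(stable / len(chosen))
    return StabilityTimecourse(list(checkpoints_min), fractions, len(chosen))


def dose_response_summary(results: list[WellResult], platemap: PlateMap) -> pd.DataFrame:
    """Per-group mean ± SD of each metric over non-quiescent wells.

    Groups are compound × dose (plus the plate-map group label); quiescent
    wells are excluded from the morphology means and tallied separately.
    SDs use the sample (n−1) denominator.
    """
    rows = []
    for r in results:
        if r.well not in platemap.wells:
            raise ValueError(f"well {r.well} missing from the plate map")
        info = platemap.wells[r.well]
        rows.append(
            {**r.to_row(), "group": info.get("group"), "compound": info.get("compound"),
             "dose": info.get("dose")}
        )
    df = pd.DataFrame(rows)
    metric_cols = [c for c in AP_METRIC_NAMES + FP_METRIC_NAMES if c in df.columns]
    out = []
    for (group, compound, dose), sub in df.groupby(
        ["group", "compound", "dose"], dropna=False, sort=False
    ):
        active = sub[~sub["quiescent"]]
        rec: dict = {
            "group": group, "compound": compound, "dose": dose,
            "n_wells": len(sub), "n_quiescent": int(sub["quiescent"].sum()),
        }
        for col in metric_cols:
            vals = active[col].astype(float).dropna()
            rec[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            rec[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        out.append(rec)
    return pd.DataFrame(out)


def pacing_analysis(
    trace: np.ndarray,
    sampling_rate_hz: float,
    stimulus_times_ms: np.ndarray,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Capture fraction and steady-state BP/APD90 per pacing-rate block.

    Stimuli are grouped into constant-rate blocks (interval change > 1%
    starts a new block). A stimulus is captured when a detected beat start
    falls within ±100 ms of it; steady-state BP and APD90 are averaged over
    the final third of each block.
    """
    config = config or AnalysisConfig()
    st = np.asarray(stimulus_times_ms, dtype=float)
    if st.size < 2:
        raise ValueError("need at least two stimuli")
    intervals = np.diff(st)
    block_edges = [0]
    for i in range(1, intervals.size):
        if abs(intervals[i] - intervals[i - 1]) > 0.01 * intervals[i - 1]:
            block_edges.append(i + 1)
    block_edges.append(st.size)

    filt = condition_trace(trace, sampling_rate_hz, config, leap=True)
    train = detect_beats_ap(filt, sampling_rate_hz, config)
    starts = train.starts_ms
    rows = []
    for a, b in zip(block_edges[:-1], block_edges[1:]):
        block = st[a:b]
        if block.size < 2:
            continue
        interval = float(np.mean(np.diff(block)))
        captured = 0
        for s in block:
            if starts.size and np.min(np.abs(starts - s)) <= config.capture_window_ms:
                captured += 1
        t_lo = block[0] + 2.0 / 3.0 * (block[-1] - block[0])
        idx = [i for i, t in enumerate(starts) if t_lo <= t <= block[-1]]
        bp_vals = [starts[i] - starts[i - 1] for i in idx if i > 0]
        apd_vals = []
        for i in idx:
            beat = train.beats[i]
            window = filt[beat.window_start : beat.window_stop]
            try:
                apd_vals.append(
                    ap_mod.compute_apd(
                        window, sampling_rate_hz, (90,),
                        start_idx=beat.start_idx - beat.window_start,
                    )[90]
                )
            except ValueError:
                pass
        rows.append(
            {
                "rate_hz": 1000.0 / interval,
                "stimulus_interval_ms": interval,
                "n_stimuli": int(block.size),
                "capture_fraction": captured / block.size,
                "bp_ms": float(np.mean(bp_vals)) if bp_vals else np.nan,
                "apd90_ms": float(np.mean(apd_vals)) if apd_vals else np.nan,
            }
        )
    return pd.DataFrame(rows)


def group_compare(a, b) -> float:
    """Two-sided Mann–Whitney rank-sum p-value (midranks under ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
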