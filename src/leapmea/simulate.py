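"""Synthetic multiwell MEA plate generator with analytically known truth.

Generates coupled AP/FP recordings: phenomenological action-potential
templates (no ionic model) with a linear upstroke and one of three
repolarization laws, spontaneous or paced beat schedules, per-electrode
coupling modes (high-coupling AP-scale "leap", ordinary field potential,
decaying post-electroporation, quiescent), injected early
afterdepolarizations, rate-dependent APD restitution, and additive
white noise plus sinusoidal baseline wander.

Repolarization families (closed forms measured from repolarization onset):

* ``hill``: V(τ) = 1 / (1 + (τ/θ)^h); APD_x = θ·(x/(100−x))^(1/h).
* ``linear``: V falls linearly over ``repol_ms``; APD_x = (x/100)·repol_ms.
* ``square``: flat plateau, one-sample drop; APD_x = plateau_ms for all x.

The field potential derives from the underlying AP: the depolarization
spike is the band-passed negative time-derivative of the AP; the
repolarization wave is the negative derivative weighted by r⁴(1−r), where
r is the repolarized fraction. The weight emulates repolarization
dispersion building across the syncytium and then collapsing as the tissue
returns to rest: its extremum falls at r* = (5h−1)/(7h) for the hill
family — between 50% and 90% repolarization for every h ≥ 1 — so the FPD
lies between APD50 and APD90, as observed on real plates. (The unweighted
derivative peaks at r = (h−1)/(2h) < 50%, which contradicts that
observation.)
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .beats import bandpass
from .model import ElectrodeID, Recording

_HILL_CUTOFF = 0.96        # repolarized fraction at which the hill tail is closed out
_HILL_CLOSEOUT_FRAC = 0.2  # close-out duration as a fraction of the hill support
_BP_FLOOR_MS = 100.0       # refractory floor for spontaneous beat intervals
_TWAVE_REL = 0.2           # T-wave amplitude relative to the FP spike


# --------------------------------------------------------------------------
# parameter types


@dataclass
class APShapeParams:
    """Phenomenological AP morphology parameters (one repolarization family)."""

    family: str = "hill"
    rise_time_ms: float = 2.0
    plateau_ms: float = 0.0      # square/linear families
    theta_ms: float = 250.0      # hill half-repolarization time
    h: float = 2.0               # hill steepness
    repol_ms: float = 450.0      # linear family total decay
    diastolic_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.family not in ("hill", "linear", "square"):
            raise ValueError(f"unknown repolarization family {self.family!r}")
        for name in ("rise_time_ms", "plateau_ms", "theta_ms", "repol_ms", "diastolic_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.h <= 0:
            raise ValueError("h must be > 0")

    def apd_from_onset(self, x: float) -> float:
        """Closed-form APD_x measured from repolarization onset, in ms."""
        if not (0 <= x < 100):
            raise ValueError("x outside [0, 100)")
        if x == 0:
            return 0.0
        if self.family == "hill":
            return self.theta_ms * (x / (100.0 - x)) ** (1.0 / self.h)
        if self.family == "linear":
            return (x / 100.0) * self.repol_ms
        return self.plateau_ms  # square: step repolarization

    @property
    def plateau_effective_ms(self) -> float:
        return self.plateau_ms if self.family in ("linear", "square") else 0.0

    def twave_fraction(self) -> float:
        """Repolarized fraction at which the synthetic T-wave peaks."""
        if self.family == "hill":
            return (5.0 * self.h - 1.0) / (7.0 * self.h)
        if self.family == "linear":
            return 0.8  # max of r^4(1-r)
        return 1.0  # square: the step itself

    def scaled(self, factor: float) -> "APShapeParams":
        """Time-scale the repolarization (restitution); the upstroke is kept."""
        s = dataclasses.replace(self)
        s.theta_ms *= factor
        s.repol_ms *= factor
        s.plateau_ms *= factor
        return s


@dataclass
class BeatSchedule:
    mode: str = "spontaneous"  # or "paced"
    mean_bp_ms: float = 1000.0
    cov_percent: float = 0.0
    stimulus_times_ms: Sequence[float] | None = None
    adaptation_beats: int = 25

    def __post_init__(self) -> None:
        if self.mode not in ("spontaneous", "paced"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.mean_bp_ms <= 0:
            raise ValueError("mean_bp_ms must be > 0")
        if self.cov_percent < 0:
            raise ValueError("cov_percent must be >= 0")
        if self.mode == "paced":
            if self.stimulus_times_ms is None or len(self.stimulus_times_ms) == 0:
                raise ValueError("paced schedule requires stimulus_times_ms")
            st = np.asarray(self.stimulus_times_ms, dtype=float)
            if np.any(np.diff(st) <= 0):
                raise ValueError("stimulus_times_ms must be strictly increasing")


@dataclass
class CouplingParams:
    mode: str = "leap"  # leap | fp | electroporation | quiescent
    amplitude_uV: float = 1000.0
    decay_tau_s: float | None = None
    fp_residual_uV: float = 0.0  # FP-scale signal persisting after electroporation decay

    def __post_init__(self) -> None:
        if self.mode not in ("leap", "fp", "electroporation", "quiescent"):
            raise ValueError(f"unknown coupling mode {self.mode!r}")
        if self.amplitude_uV < 0:
            raise ValueError("amplitude_uV must be >= 0")
        if self.mode == "electroporation" and (self.decay_tau_s is None or self.decay_tau_s <= 0):
            raise ValueError("electroporation mode requires decay_tau_s > 0")


@dataclass
class EADInjection:
    onset_fraction: float = 0.3   # position within repolarization (0=peak, 1=trough)
    amplitude_uV: float = 50.0    # target topographic prominence
    width_ms: float = 40.0
    probability: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.onset_fraction < 1):
            raise ValueError("onset_fraction must be in (0, 1)")
        if self.amplitude_uV < 0:
            raise ValueError("amplitude_uV must be >= 0")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be > 0")
        if not (0 <= self.probability <= 1):
            raise ValueError("probability must be in [0, 1]")


@dataclass
class NoiseParams:
    white_sigma_uV: float = 0.0
    drift_amp_uV: float = 0.0
    drift_period_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_sigma_uV < 0 or self.drift_amp_uV < 0 or self.drift_period_s <= 0:
            raise ValueError("noise parameters must be non-negative (period > 0)")


@dataclass
class RestitutionMap:
    """Steady-state APD90 as a monotone-increasing function of beat period:
    APD_ss(BP) = apd_max_ms − k_ms · exp(−BP/tau_r_ms)."""

    apd_max_ms: float = 400.0
    k_ms: float = 150.0
    tau_r_ms: float = 500.0

    def apd_ss(self, bp_ms: float) -> float:
        return self.apd_max_ms - self.k_ms * float(np.exp(-bp_ms / self.tau_r_ms))


@dataclass
class ElectrodeSpec:
    id: str
    shape: APShapeParams = field(default_factory=APShapeParams)
    schedule: BeatSchedule = field(default_factory=BeatSchedule)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    eads: EADInjection | None = None
    noise: NoiseParams = field(default_factory=NoiseParams)


@dataclass
class SimulationConfig:
    duration_s: float = 30.0
    sampling_rate_hz: float = 12500.0
    start_time_s: float = 0.0
    seed: int = 0
    restitution: RestitutionMap | None = None
    electrodes: list[ElectrodeSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    # -- serialization (YAML mirror of the field names) --------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        resti = d.get("restitution")
        electrodes = []
        for e in d.get("electrodes", []):
            electrodes.append(
                ElectrodeSpec(
                    id=e["id"],
                    shape=APShapeParams(**e.get("shape", {})),
                    schedule=BeatSchedule(**e.get("schedule", {})),
                    coupling=CouplingParams(**e.get("coupling", {})),
                    eads=EADInjection(**e["eads"]) if e.get("eads") else None,
                    noise=NoiseParams(**e.get("noise", {})),
                )
            )
        return cls(
            duration_s=d.get("duration_s", 30.0),
            sampling_rate_hz=d.get("sampling_rate_hz", 12500.0),
            start_time_s=d.get("start_time_s", 0.0),
            seed=d.get("seed", 0),
            restitution=RestitutionMap(**resti) if resti else None,
            electrodes=electrodes,
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def uniform_plate(
    n_rows: int,
    n_cols: int,
    electrodes_per_well: int,
    duration_s: float,
    shape: APShapeParams | None = None,
    schedule: BeatSchedule | None = None,
    coupling: CouplingParams | None = None,
    eads: EADInjection | None = None,
    noise: NoiseParams | None = None,
    **config_kwargs,
) -> SimulationConfig:
    """Convenience builder: every electrode shares the same parameters."""
    electrodes = []
    for r in range(n_rows):
        for c in range(n_cols):
            for e in range(electrodes_per_well):
                electrodes.append(
                    ElectrodeSpec(
                        id=f"W{chr(ord('A') + r)}{c + 1}_E{e + 1}",
                        shape=dataclasses.replace(shape) if shape else APShapeParams(),
                        schedule=dataclasses.replace(schedule) if schedule else BeatSchedule(),
                        coupling=dataclasses.replace(coupling) if coupling else CouplingParams(),
                        eads=dataclasses.replace(eads) if eads else None,
                        noise=dataclasses.replace(noise) if noise else NoiseParams(),
                    )
                )
    return SimulationConfig(duration_s=duration_s, electrodes=electrodes, **config_kwargs)


# --------------------------------------------------------------------------
# waveform construction


def generate_ap_template(shape: APShapeParams, sampling_rate_hz: float) -> np.ndarray:
    """Normalized AP waveform: 0 → linear rise to exactly 1 → family decay → 0.

    The hill decay is followed analytically until 96% repolarization, then
    closed out to exactly zero with a smooth half-cosine ramp (APD values up
    to 90% are unaffected). A trailing rest interval of ``diastolic_ms``
    zeros completes the template.
    """
    if sampling_rate_hz <= 0:
        raise ValueError("sampling rate must be > 0")
    fs = float(sampling_rate_hz)
    dt_ms = 1000.0 / fs

    n_rise = max(1, int(round(shape.rise_time_ms / dt_ms)))
    rise = np.arange(n_rise + 1) / n_rise  # ends exactly at 1 (the peak sample)

    parts = [rise]
    if shape.family == "square":
        n_plat = max(0, int(round(shape.plateau_ms / dt_ms)) - 1)
        parts.append(np.ones(n_plat))
        parts.append(np.zeros(1))
    elif shape.family == "linear":
        n_plat = int(round(shape.plateau_ms / dt_ms))
        parts.append(np.ones(n_plat))
        n_rep = max(1, int(round(shape.repol_ms / dt_ms)))
        parts.append(1.0 - np.arange(1, n_rep + 1) / n_rep)
    else:  # hill
        t_cut = shape.theta_ms * (_HILL_CUTOFF / (1 - _HILL_CUTOFF)) ** (1.0 / shape.h)
        n_hill = max(1, int(np.ceil(t_cut / dt_ms)))
        tau = np.arange(1, n_hill + 1) * dt_ms
        hill = 1.0 / (1.0 + (tau / shape.theta_ms) ** shape.h)
        parts.append(hill)
        v_last = hill[-1]
        n_close = max(2, int(round(_HILL_CLOSEOUT_FRAC * t_cut / dt_ms)))
        ramp = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, n_close + 1) / n_close))
        parts.append(v_last * ramp)

    n_dia = int(round(shape.diastolic_ms / dt_ms))
    parts.append(np.zeros(n_dia))
    return np.concatenate(parts)


def generate_beat_times(
    schedule: BeatSchedule, duration_s: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Strictly increasing beat-start times (ms) over the recording.

    Spontaneous intervals are truncated-normal (floor 100 ms, modelling
    refractoriness) with the requested mean and CoV; the first beat is at 0.
    Paced mode returns the stimulus train (capture assumed whenever the
    stimulus interval exceeds the refractory floor).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    dur_ms = duration_s * 1000.0
    if schedule.mode == "paced":
        st = np.asarray(schedule.stimulus_times_ms, dtype=float)
        keep = [st[0]]
        for t in st[1:]:
            if t - keep[-1] > _BP_FLOOR_MS:
                keep.append(t)
        return np.array([t for t in keep if t < dur_ms])

    mean = schedule.mean_bp_ms
    if schedule.cov_percent == 0:
        return np.arange(0.0, dur_ms, mean)
    rng = np.random.default_rng(rng)
    sd = schedule.cov_percent / 100.0 * mean
    times = [0.0]
    n_drawn = 0
    n_rejected = 0
    while times[-1] < dur_ms:
        draws = rng.normal(mean, sd, size=64)
        n_drawn += draws.size
        for iv in draws:
            if iv <= _BP_FLOOR_MS:
                n_rejected += 1
                continue
            times.append(times[-1] + iv)
            if times[-1] >= dur_ms:
                break
        if n_drawn >= 128 and n_rejected > 0.5 * n_drawn:
            raise ValueError(
                "cov_percent produces mostly non-positive intervals "
                f"(rejection rate {n_rejected / n_drawn:.0%})"
            )
    return np.array([t for t in times if t < dur_ms])


# --------------------------------------------------------------------------
# EAD injection


def _prominence_at(segment: np.ndarray, peak_idx: int) -> float:
    """Topographic prominence of ``segment[peak_idx]`` within the segment.

    Walks outward on each side to the first point higher than the peak (or
    the segment edge) and records the minimum encountered; the prominence is
    the height above the greater of the two flanking minima. Independent of
    scipy's implementation so it can serve as a truth oracle.
    """
    v = segment[peak_idx]
    left_min = v
    for x in segment[peak_idx - 1 :: -1] if peak_idx > 0 else []:
        if x > v:
            break
        left_min = min(left_min, x)
    right_min = v
    for x in segment[peak_idx + 1 :]:
        if x > v:
            break
        right_min = min(right_min, x)
    return float(v - max(left_min, right_min))


def inject_ead(
    beat: np.ndarray,
    sampling_rate_hz: float,
    onset_fraction: float,
    prominence: float,
    width_ms: float,
) -> tuple[np.ndarray, float, int]:
    """Add one raised-cosine EAD bump to a beat's repolarization limb.

    The bump is centred where the repolarized fraction first reaches
    ``onset_fraction``; its height is compensated for the local
    repolarization-trend drop so the realized topographic prominence matches
    ``prominence`` (same units as ``beat``). Returns the modified copy, the
    realized prominence and the index of the bump's local maximum.
    """
    x = np.asarray(beat, dtype=float).copy()
    peak_idx = int(np.argmax(x))
    post = x[peak_idx:]
    trough_rel = int(np.argmin(post))
    trough = post[trough_rel]
    if post[0] == trough:
        raise ValueError("beat has no repolarization limb")
    r = (x[peak_idx] - post[: trough_rel + 1]) / (x[peak_idx] - trough)
    above = np.nonzero(r >= onset_fraction)[0]
    if above.size == 0:
        raise ValueError("onset_fraction beyond the repolarization limb")
    center = peak_idx + int(above[0])
    half = max(2, int(round(width_ms / 2.0 * sampling_rate_hz / 1000.0)))
    lo, hi = center - half, center + half + 1
    if lo <= peak_idx or hi >= peak_idx + trough_rel:
        lo = max(lo, peak_idx + 1)
        hi = min(hi, peak_idx + trough_rel)
    k = np.arange(lo, hi)
    bump = 0.5 * (1.0 + np.cos(np.pi * (k - center) / half))
    limb = slice(peak_idx + 1, peak_idx + trough_rel + 1)

    def realized(height: float) -> tuple[float, int]:
        y = x.copy()
        y[lo:hi] += height * bump
        j = lo + int(np.argmax(y[lo:hi]))
        return _prominence_at(y[limb], j - limb.start), j

    # fixed-point compensation of the local repolarization-trend drop
    height = prominence
    got, j = realized(height)
    for _ in range(3):
        if abs(got - prominence) <= 0.005 * prominence:
            break
        height = max(height + (prominence - got), 0.25 * prominence)
        got, j = realized(height)
    x[lo:hi] += height * bump
    return x, got, j


# --------------------------------------------------------------------------
# trace synthesis


def _fp_from_train(
    clean: np.ndarray,
    starts_idx: np.ndarray,
    stops_idx: np.ndarray,
    peak_offsets: np.ndarray,
    sampling_rate_hz: float,
) -> np.ndarray:
    """Field potential derived from a clean normalized AP train (unit scale).

    Spike = −dV/dt around the upstroke; repolarization wave = −dV/dt
    weighted by r⁴(1−r) over the repolarization limb, scaled to ``_TWAVE_REL``
    of the spike amplitude. Band-passing (1–2000 Hz) happens downstream.
    """
    dt_ms = 1000.0 / sampling_rate_hz
    deriv = np.gradient(clean) / dt_ms
    spike = np.zeros_like(clean)
    twave = np.zeros_like(clean)
    margin = 2
    for a, b, off in zip(starts_idx, stops_idx, peak_offsets):
        p = a + off
        spike[a : min(p + margin + 1, b)] = -deriv[a : min(p + margin + 1, b)]
        limb = slice(min(p + margin + 1, b), b)
        seg = clean[limb]
        if seg.size == 0:
            continue
        r = np.clip(1.0 - seg, 0.0, 1.0)
        twave[limb] = -deriv[limb] * r**4 * (1.0 - r)
    spike_amp = float(np.max(np.abs(spike))) or 1.0
    twave_amp = float(np.max(np.abs(twave)))
    if twave_amp > 0:
        twave *= _TWAVE_REL * spike_amp / twave_amp
    return spike + twave


def synthesize_electrode_trace(
    shape: APShapeParams,
    schedule: BeatSchedule,
    coupling: CouplingParams,
    eads: EADInjection | None = None,
    noise: NoiseParams | None = None,
    restitution: RestitutionMap | None = None,
    sampling_rate_hz: float = 12500.0,
    duration_s: float = 30.0,
    start_time_s: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """One electrode's voltage trace (µV) plus its per-beat ground truth.

    Ground-truth beat starts use the max-upstroke-slope convention (the
    midpoint of the linear rise); APD values are the family closed forms
    offset accordingly. The truth list is empty for quiescent electrodes.
    """
    fs = float(sampling_rate_hz)
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(rng)
    noise = noise or NoiseParams()
    t_s = start_time_s + np.arange(n) / fs

    def add_noise(trace: np.ndarray) -> np.ndarray:
        if noise.white_sigma_uV > 0:
            trace = trace + rng.normal(0.0, noise.white_sigma_uV, size=n)
        if noise.drift_amp_uV > 0:
            trace = trace + noise.drift_amp_uV * np.sin(2 * np.pi * t_s / noise.drift_period_s)
        return trace

    if coupling.mode == "quiescent":
        return add_noise(np.zeros(n)), []

    beat_ms = generate_beat_times(schedule, duration_s, rng)
    if beat_ms.size == 0:
        raise ValueError("recording duration is shorter than one beat")

    # per-beat repolarization scale from the restitution map
    apd90_intrinsic = shape.apd_from_onset(90)
    scales = np.ones(beat_ms.size)
    if restitution is not None and apd90_intrinsic > 0:
        alpha = float(np.exp(-1.0 / max(1, schedule.adaptation_beats)))
        state = apd90_intrinsic
        prev = None
        for i, t in enumerate(beat_ms):
            bp = (t - prev) if prev is not None else schedule.mean_bp_ms
            target = restitution.apd_ss(bp)
            state = target + (state - target) * alpha
            scales[i] = state / apd90_intrinsic
            prev = t

    cache: dict[float, np.ndarray] = {}

    def template_for(scale: float) -> np.ndarray:
        key = round(scale, 4)
        if key not in cache:
            cache[key] = generate_ap_template(shape.scaled(key), fs)
        return cache[key]

    clean = np.zeros(n)
    rise = shape.rise_time_ms
    n_rise = max(1, int(round(rise * fs / 1000.0)))
    truth: list[dict] = []
    warned = False
    prev_t = None
    n_dia = int(round(shape.diastolic_ms * fs / 1000.0))
    for i, t in enumerate(beat_ms):
        tpl = template_for(scales[i])
        active_len = tpl.size - n_dia  # waveform length excluding the rest interval
        a = int(round(t * fs / 1000.0))
        b_next = int(round(beat_ms[i + 1] * fs / 1000.0)) if i + 1 < beat_ms.size else n
        avail = min(tpl.size, b_next - a, n - a)
        if avail <= 0:
            continue
        if (
            not warned
            and i + 1 < beat_ms.size
            and b_next - a < active_len  # the next beat, not the trace end, cuts it
        ):
            warnings.warn(
                "beat period shorter than the AP waveform; repolarization truncated",
                stacklevel=2,
            )
            warned = True
        clean[a : a + avail] = tpl[:avail]
        complete = avail >= active_len
        sh = shape.scaled(scales[i])
        onset = rise  # repolarization onset time after upstroke start
        start_true = t + rise / 2.0  # max-slope (mid-rise) convention
        row = {
            "beat_index": i,
            "beat_start_ms": start_true,
            "true_bp_ms": (t - prev_t) if prev_t is not None else np.nan,
            "true_apd30_ms": rise / 2.0 + sh.plateau_effective_ms + sh.apd_from_onset(30),
            "true_apd50_ms": rise / 2.0 + sh.plateau_effective_ms + sh.apd_from_onset(50),
            "true_apd90_ms": rise / 2.0 + sh.plateau_effective_ms + sh.apd_from_onset(90),
            "true_rise_ms": rise,
            "ead_flag": False,
            "ead_prominence_uV": np.nan,
            "complete": complete,
        }
        prev_t = t
        # amplitude seen by this beat (decay evaluated at the beat start)
        if coupling.mode == "electroporation":
            amp_i = coupling.amplitude_uV * float(
                np.exp(-(start_time_s + t / 1000.0) / coupling.decay_tau_s)
            )
        else:
            amp_i = coupling.amplitude_uV
        row["amplitude_uV"] = amp_i
        row["class"] = coupling.mode
        # T-wave truth (FP modes): spike at mid-rise, extremum at r*
        r_star = sh.twave_fraction()
        if sh.family == "hill":
            u = (r_star / (1.0 - r_star)) ** (1.0 / sh.h)
            t_rep = sh.theta_ms * u
        elif sh.family == "linear":
            t_rep = sh.plateau_ms + r_star * sh.repol_ms
        else:
            t_rep = sh.plateau_ms
        row["true_fpd_ms"] = rise / 2.0 + t_rep
        # EAD injection (into the clean normalized train, so FP inherits it)
        if (
            eads is not None
            and eads.probability > 0
            and complete
            and amp_i > 0
            and rng.random() < eads.probability
        ):
            beat_slice = clean[a : a + avail]
            try:
                modified, realized_norm, _ = inject_ead(
                    beat_slice,
                    fs,
                    eads.onset_fraction,
                    eads.amplitude_uV / amp_i,
                    eads.width_ms,
                )
            except ValueError:
                modified, realized_norm = beat_slice, 0.0
            clean[a : a + avail] = modified
            if realized_norm > 0:
                row["ead_flag"] = True
                row["ead_prominence_uV"] = realized_norm * amp_i
        truth.append(row)

    starts_idx = np.round(beat_ms * fs / 1000.0).astype(int)
    stops_idx = np.append(starts_idx[1:], n)
    peak_offsets = np.full(starts_idx.size, n_rise, dtype=int)

    if coupling.mode == "leap":
        trace = coupling.amplitude_uV * clean
    elif coupling.mode == "electroporation":
        env = coupling.amplitude_uV * np.exp(-t_s / coupling.decay_tau_s)
        trace = env * clean
        if coupling.fp_residual_uV > 0:
            fp = _fp_from_train(clean, starts_idx, stops_idx, peak_offsets, fs)
            trace = trace + _scale_fp(fp, starts_idx, peak_offsets, fs, coupling.fp_residual_uV)
    else:  # fp
        fp = _fp_from_train(clean, starts_idx, stops_idx, peak_offsets, fs)
        trace = _scale_fp(fp, starts_idx, peak_offsets, fs, coupling.amplitude_uV)
    return add_noise(trace), truth


def _scale_fp(
    fp: np.ndarray,
    starts_idx: np.ndarray,
    peak_offsets: np.ndarray,
    sampling_rate_hz: float,
    amplitude_uV: float,
) -> np.ndarray:
    """Band-limit the raw FP and scale its median spike peak-to-trough."""
    nyq = sampling_rate_hz / 2.0
    filt = bandpass(fp, 1.0, min(2000.0, 0.9 * nyq), sampling_rate_hz)
    half = int(round(10e-3 * sampling_rate_hz))
    amps = []
    for a, off in zip(starts_idx, peak_offsets):
        c = a + off
        w = filt[max(0, c - half) : min(filt.size, c + half + 1)]
        if w.size:
            amps.append(np.max(w) - np.min(w))
    p2p = float(np.median(amps)) if amps else 0.0
    if p2p <= 0:
        return filt
    return filt * (amplitude_uV / p2p)


def synthesize_plate(config: SimulationConfig) -> tuple[Recording, pd.DataFrame]:
    """Full plate: one trace per electrode plus a per-beat ground-truth table.

    Deterministic under a fixed config (the RNG stream of each electrode is
    derived from the plate seed, the electrode's noise seed and its position).
    """
    ids = [e.id for e in config.electrodes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate electrode IDs: {dupes}")
    if not ids:
        raise ValueError("config has no electrodes")
    traces: dict[str, np.ndarray] = {}
    rows = []
    for k, espec in enumerate(config.electrodes):
        eid = ElectrodeID.parse(espec.id)
        rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, espec.noise.seed, k))
        )
        trace, truth = synthesize_electrode_trace(
            espec.shape,
            espec.schedule,
            espec.coupling,
            eads=espec.eads,
            noise=espec.noise,
            restitution=config.restitution,
            sampling_rate_hz=config.sampling_rate_hz,
            duration_s=config.duration_s,
            start_time_s=config.start_time_s,
            rng=rng,
        )
        traces[espec.id] = trace
        for row in truth:
            rows.append({"well": eid.well, "electrode": eid.index, **row})
    recording = Recording(traces, config.sampling_rate_hz, config.start_time_s)
    columns = [
        "well", "electrode", "beat_index", "beat_start_ms", "true_bp_ms",
        "true_apd30_ms", "true_apd50_ms", "true_apd90_ms", "true_rise_ms",
        "ead_flag", "ead_prominence_uV", "true_fpd_ms", "amplitude_uV",
        "class", "complete",
    ]
    truth_df = pd.DataFrame(rows, columns=columns)
    return recording, truth_df
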