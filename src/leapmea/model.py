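"""Core data model for multiwell MEA recordings.

A recording is a set of equal-length voltage traces (microvolts) sampled at a
common rate, one per planar electrode. Electrodes are addressed by a compact
token ``W<row><col>_E<n>`` (e.g. ``WA1_E3`` = well A1, electrode 3), which is
also the column-header grammar used by the CSV reader/writer in
:mod:`leapmea.io`.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

ELECTRODE_ID_RE = re.compile(r"^W([A-Z])(\d+)_E(\d+)$")


@dataclass(frozen=True)
class ElectrodeID:
    """Electrode address: well row letter, well column number, electrode index."""

    well_row: str
    well_col: int
    index: int

    @property
    def well(self) -> str:
        return f"{self.well_row}{self.well_col}"

    def __str__(self) -> str:
        return f"W{self.well_row}{self.well_col}_E{self.index}"

    @classmethod
    def parse(cls, token: str) -> "ElectrodeID":
        m = ELECTRODE_ID_RE.match(token)
        if m is None:
            raise ValueError(
                f"electrode ID {token!r} does not match the W<row><col>_E<n> grammar"
            )
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))


class Recording:
    """Equal-length µV voltage traces keyed by electrode ID token.

    Parameters
    ----------
    traces
        Mapping from electrode ID token (``"WA1_E1"``) to a 1-D float array of
        voltages in microvolts. All traces must have the same length.
    sampling_rate_hz
        Sampling rate, > 0. The study platform samples at 12.5 kHz.
    start_time_s
        Absolute start time of the recording (0-based seconds); relevant when
        a plate is recorded repeatedly, e.g. at post-induction checkpoints.
    """

    def __init__(
        self,
        traces: Mapping[str, np.ndarray],
        sampling_rate_hz: float,
        start_time_s: float = 0.0,
    ) -> None:
        if sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if not traces:
            raise ValueError("no electrodes")
        self.traces: dict[str, np.ndarray] = {}
        n = None
        for key, arr in traces.items():
            ElectrodeID.parse(key)  # validates the grammar
            a = np.asarray(arr, dtype=float)
            if a.ndim != 1:
                raise ValueError(f"trace {key!r} is not 1-D")
            if n is None:
                n = a.size
            elif a.size != n:
                raise ValueError(
                    f"trace {key!r} has {a.size} samples, expected {n} (ragged recording)"
                )
            self.traces[key] = a
        self.sampling_rate_hz = float(sampling_rate_hz)
        self.start_time_s = float(start_time_s)

    @classmethod
    def from_arrays(
        cls,
        ids: Iterable[str],
        arrays: Iterable[np.ndarray],
        sampling_rate_hz: float,
        start_time_s: float = 0.0,
    ) -> "Recording":
        ids = list(ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate electrode IDs: {dupes}")
        return cls(dict(zip(ids, arrays)), sampling_rate_hz, start_time_s)

    @property
    def electrode_ids(self) -> list[str]:
        return list(self.traces)

    @property
    def n_samples(self) -> int:
        return next(iter(self.traces.values())).size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def wells(self) -> dict[str, list[str]]:
        """Group electrode tokens by well ID, preserving order."""
        out: dict[str, list[str]] = {}
        for key in self.traces:
            out.setdefault(ElectrodeID.parse(key).well, []).append(key)
        return out


@dataclass
class PlateMap:
    """Well-level experiment layout: group label, compound and dose per well.

    ``wells`` maps well ID (e.g. ``"A1"``) to a dict with keys ``group``,
    ``compound``, ``dose``, ``dose_units``. Group labels must be non-empty.
    """

    wells: dict[str, dict]
    plate_format: int | None = None
    electrodes_per_well: int | None = None

    def __post_init__(self) -> None:
        for well, info in self.wells.items():
            if not str(info.get("group", "")).strip():
                raise ValueError(f"well {well!r} has an empty group label")

    def group_of(self, well: str) -> str:
        return self.wells[well]["group"]

    def to_records(self) -> list[dict]:
        recs = []
        for well, info in self.wells.items():
            recs.append(
                {
                    "well": well,
                    "group": info.get("group"),
                    "compound": info.get("compound"),
                    "dose": info.get("dose"),
                    "dose_units": info.get("dose_units"),
                }
            )
        return recs

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "PlateMap":
        wells = {}
        for rec in records:
            well = rec["well"]
            if well in wells:
                raise ValueError(f"duplicate well {well!r} in plate map")
            wells[well] = {
                "group": rec.get("group"),
                "compound": rec.get("compound"),
                "dose": rec.get("dose"),
                "dose_units": rec.get("dose_units"),
            }
        return cls(wells)


@dataclass
class AnalysisConfig:
    """All tunable analysis thresholds, with the platform defaults.

    Band edges follow the acquisition settings: 1–2000 Hz for FP-only
    recordings and 0.01–2000 Hz for LEAP recordings (the lower LEAP edge
    preserves the slow plateau content of the AP). The LEAP classification
    rule (SD > 100 µV and amplitude > 350 µV) and the EAD rule (prominence
    at least 20 µV and greater than 2.5% of the LEAP amplitude) are the
    published operating points.
    """

    fp_band_hz: tuple[float, float] = (1.0, 2000.0)
    leap_band_hz: tuple[float, float] = (0.01, 2000.0)
    sd_threshold_uV: float = 100.0
    amp_threshold_uV: float = 350.0
    ead_abs_uV: float = 20.0
    ead_frac: float = 0.025
    ead_smooth_ms: float = 5.0
    beats_to_average: int = 5
    pre_window_ms: float = 20.0
    refractory_ms: float = 250.0
    slope_fraction: float = 0.30
    takeoff_fraction: float = 0.10
    detect_smooth_ms: float = 2.0
    rise_smooth_ms: float = 0.4
    fpd_min_ms: float = 100.0
    fpd_noise_mult: float = 4.0
    capture_window_ms: float = 100.0

    def __post_init__(self) -> None:
        for name in ("fp_band_hz", "leap_band_hz"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ValueError(f"{name}: need 0 <= low < high, got ({lo}, {hi})")
        for name in (
            "sd_threshold_uV",
            "amp_threshold_uV",
            "ead_abs_uV",
            "ead_frac",
            "refractory_ms",
            "slope_fraction",
            "takeoff_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def band_for(self, leap: bool, sampling_rate_hz: float) -> tuple[float, float]:
        """Band edges for the given signal kind, clamped below Nyquist."""
        lo, hi = self.leap_band_hz if leap else self.fp_band_hz
        nyq = sampling_rate_hz / 2.0
        return lo, min(hi, 0.9 * nyq)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fp_band_hz"] = list(self.fp_band_hz)
        d["leap_band_hz"] = list(self.leap_band_hz)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        kwargs = dict(d)
        for name in ("fp_band_hz", "leap_band_hz"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
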