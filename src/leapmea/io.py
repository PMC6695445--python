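"""Recording and plate-map file I/O.

A recording on disk is a CSV with a ``time_s`` column plus one µV column per
electrode (headers in the ``W<row><col>_E<n>`` grammar), accompanied by a JSON
sidecar with the same basename holding the sampling rate, units and start
time. The round trip is lossless: floats are written in shortest
round-trip representation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ELECTRODE_ID_RE, ElectrodeID, PlateMap, Recording


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(recording: Recording, path) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": recording.time_s()})
    for key, trace in recording.traces.items():
        df[key] = trace
    # 17 significant digits guarantee a lossless float64 round trip
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "sampling_rate_hz": recording.sampling_rate_hz,
        "start_time_s": recording.start_time_s,
        "units": "uV",
        "n_samples": recording.n_samples,
        "electrodes": recording.electrode_ids,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_recording(path) -> Recording:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sampling-rate metadata: sidecar {sidecar} not found"
        )
    with open(sidecar) as fh:
        meta = json.load(fh)
    if "sampling_rate_hz" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks 'sampling_rate_hz'")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError("no electrodes") from None
    cols = [c for c in df.columns if c != "time_s"]
    if not cols:
        raise ValueError("no electrodes")
    traces = {}
    for c in cols:
        ElectrodeID.parse(c)
        vals = df[c]
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError(f"non-numeric samples in column {c!r}")
        if vals.isna().any():
            raise ValueError(f"column {c!r} has missing samples (ragged recording)")
        traces[c] = vals.to_numpy(dtype=float)
    return Recording(
        traces,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        start_time_s=float(meta.get("start_time_s", 0.0)),
    )


def write_platemap(platemap: PlateMap, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(platemap.to_records(), fh, indent=1)
    else:
        pd.DataFrame(platemap.to_records()).to_csv(path, index=False)


def read_platemap(path) -> PlateMap:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            records = json.load(fh)
    else:
        records = pd.read_csv(path).to_dict("records")
    return PlateMap.from_records(records)


def validate_plate(recording_or_ids, platemap: PlateMap) -> list[str]:
    """Consistency report between a recording and a plate map.

    Accepts a :class:`Recording` or a raw iterable of electrode ID tokens
    (the latter allows duplicate-ID checking before deduplication). Returns a
    list of human-readable issues; an empty list means consistent.
    """
    if isinstance(recording_or_ids, Recording):
        ids = recording_or_ids.electrode_ids
    else:
        ids = list(recording_or_ids)
    issues: list[str] = []

    seen: set[str] = set()
    for token in ids:
        if token in seen:
            issues.append(f"duplicate electrode ID {token}")
        seen.add(token)

    wells_with_electrodes: set[str] = set()
    for token in seen:
        m = ELECTRODE_ID_RE.match(token)
        if m is None:
            issues.append(f"malformed electrode ID {token}")
            continue
        well = f"{m.group(1)}{m.group(2)}"
        wells_with_electrodes.add(well)
        if well not in platemap.wells:
            issues.append(f"electrode {token} maps to no well in the plate map")

    for well in platemap.wells:
        if well not in wells_with_electrodes:
            issues.append(f"well {well} has no electrodes in the recording")
    return issues
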