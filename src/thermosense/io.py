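"""On-disk cohort and feature-table formats.

A cohort directory holds one ``trials.csv`` metadata table plus one CSV per
trial and modality under ``traces/``:

* sampled modalities: header ``time_s,value``;
* RR series: header ``index,rr_ms``.

All files are UTF-8 with '.' decimal separator; floats are written with
``repr`` precision so a regenerated cohort is byte-identical for equal seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    EnvironmentSetting,
    SignalTrace,
    SubjectProfile,
    TrialRecord,
)

_UNITS = {
    "ECG_RR": "ms", "EMG": "mV", "EEG": "uV", "GSR": "uS",
    "TEMP_CHEST": "degC", "TEMP_FOREARM": "degC", "TEMP_CALF": "degC",
}


def _trial_stem(record: TrialRecord, idx: int) -> str:
    s = record.setting
    return f"{record.subject.subject_id}_t{s.air_temp:g}_rh{s.rh:g}_{s.fan_level}_{idx:03d}"


def write_cohort(cohort: list, out_dir, write_traces: bool = True) -> Path:
    """Serialize a cohort: trials.csv plus per-trial per-modality trace CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    traces_dir = out / "traces"
    if write_traces:
        traces_dir.mkdir(exist_ok=True)
    for i, rec in enumerate(cohort):
        stem = _trial_stem(rec, i)
        rows.append({
            "trial": stem,
            "subject_id": rec.subject.subject_id,
            "sex": rec.subject.sex,
            "air_temp": rec.setting.air_temp,
            "rh": rec.setting.rh,
            "fan_level": rec.setting.fan_level,
            "wind_speed": rec.setting.wind_speed,
            "reported_ts": rec.reported_ts,
            "quality_ok": rec.quality_ok,
            "corrupted_modality": rec.corrupted_modality or "",
        })
        if write_traces:
            for modality, trace in sorted(rec.traces.items()):
                path = traces_dir / f"{stem}_{modality}.csv"
                with open(path, "w", encoding="utf-8", newline="\n") as fh:
                    if modality == "ECG_RR":
                        fh.write("index,rr_ms\n")
                        for j, v in enumerate(trace.samples):
                            fh.write(f"{j},{float(v)!r}\n")
                    else:
                        fh.write("time_s,value\n")
                        dt = 1.0 / trace.sampling_rate
                        for j, v in enumerate(trace.samples):
                            fh.write(f"{j * dt!r},{float(v)!r}\n")
    pd.DataFrame(rows).to_csv(out / "trials.csv", index=False, lineterminator="\n")
    return out


def read_cohort(in_dir, sampling_rates: dict | None = None) -> list:
    """Load a cohort directory back into :class:`TrialRecord` objects.

    Subject-level simulator internals (thermal offsets, gains) are not stored
    on disk; loaded profiles carry neutral values, which is all downstream
    analysis needs.
    """
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "trials.csv")
    traces_dir = in_dir / "traces"
    cohort = []
    for _, row in meta.iterrows():
        traces = {}
        for path in sorted(traces_dir.glob(f"{row['trial']}_*.csv")):
            modality = path.stem[len(str(row["trial"])) + 1:]
            df = pd.read_csv(path)
            if modality == "ECG_RR":
                trace = SignalTrace("ECG_RR", df["rr_ms"].to_numpy(), None, "ms")
            else:
                t = df["time_s"].to_numpy()
                fs = 1.0 / (t[1] - t[0]) if t.size > 1 else 1.0
                trace = SignalTrace(modality, df["value"].to_numpy(), round(fs, 6),
                                    _UNITS.get(modality, ""))
            traces[modality] = trace
        subject = SubjectProfile(
            subject_id=row["subject_id"], sex=row["sex"],
            thermal_offset=0.0, signal_gain={}, temp_offset={},
        )
        setting = EnvironmentSetting(
            air_temp=float(row["air_temp"]), rh=float(row["rh"]),
            fan_level=row["fan_level"], wind_speed=float(row["wind_speed"]),
        )
        corrupted = row.get("corrupted_modality", "")
        cohort.append(TrialRecord(
            subject=subject, setting=setting, traces=traces,
            reported_ts=int(row["reported_ts"]),
            latent_ts=float("nan"),
            quality_ok=bool(row["quality_ok"]),
            corrupted_modality=corrupted if isinstance(corrupted, str) and corrupted else None,
        ))
    return cohort


def write_features(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, lineterminator="\n")
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, frozenset):
            return sorted(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n",
                    encoding="utf-8")
    return path
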