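"""On-disk dataset format: one CSV trace per utterance plus a JSON manifest.

Layout of a dataset directory::

    manifest.json            # config echo + ordered record index with labels
    record_00000.csv         # columns: time_s, ch1..ch8 (dR/R)
    record_00001.csv
    ...

Floats are written with 17 significant digits, so a write/read round trip
reproduces every sample bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import SimConfig, StrainRecord, N_CHANNELS

__all__ = ["write_dataset", "read_dataset"]

_COLUMNS = ["time_s"] + [f"ch{i}" for i in range(1, N_CHANNELS + 1)]


def write_dataset(records: Sequence[StrainRecord], path,
                  config: Optional[SimConfig] = None,
                  sampling_rate: Optional[float] = None) -> Path:
    """Write records and manifest to ``path`` (created if needed)."""
    if not records:
        raise ValueError("refusing to write an empty dataset")
    rate = sampling_rate if sampling_rate is not None else (
        config.sampling_rate if config is not None else 300.0)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    index = []
    for i, rec in enumerate(records):
        fname = f"record_{i:05d}.csv"
        t = np.arange(rec.waveform.shape[1]) / rate
        df = pd.DataFrame(
            np.column_stack([t, rec.waveform.T]), columns=_COLUMNS)
        df.to_csv(path / fname, index=False, float_format="%.17g")
        index.append({
            "file": fname,
            "class_id": int(rec.class_id),
            "subject_id": int(rec.subject_id),
            "session_id": int(rec.session_id),
            "rep_index": int(rec.rep_index),
        })
    manifest = {
        "sampling_rate": float(rate),
        "config": config.to_dict() if config is not None else None,
        "records": index,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def read_dataset(path) -> tuple[list[StrainRecord], dict]:
    """Load a dataset directory; returns (records in manifest order, manifest).

    Fails loudly: a missing manifest or an empty record list is a
    ValueError, a record file named by the manifest but absent on disk is a
    FileNotFoundError naming it, and a malformed trace (wrong columns,
    non-finite values) is a ValueError naming the file.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.is_file():
        raise ValueError(f"no manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    entries = manifest.get("records", [])
    if not entries:
        raise ValueError(f"manifest in {path} lists no records")
    records = []
    for entry in entries:
        fpath = path / entry["file"]
        if not fpath.is_file():
            raise FileNotFoundError(f"record file missing: {fpath}")
        df = pd.read_csv(fpath, float_precision="round_trip")
        if list(df.columns) != _COLUMNS:
            raise ValueError(f"unexpected columns in {fpath}: {list(df.columns)}")
        waveform = df[_COLUMNS[1:]].to_numpy().T
        if not np.all(np.isfinite(waveform)):
            raise ValueError(f"non-finite samples in {fpath}")
        records.append(StrainRecord(
            waveform=waveform,
            class_id=int(entry["class_id"]),
            subject_id=int(entry.get("subject_id", 0)),
            session_id=int(entry.get("session_id", 0)),
            rep_index=int(entry.get("rep_index", 0)),
        ))
    return records, manifest
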