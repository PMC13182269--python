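"""CSV reading/writing for long-format datasets.

Each dataset is a directory of three UTF-8 comma-separated files with
mandatory headers: ``measurements.csv`` (subject_id,time,feature_id,value),
``subjects.csv`` (subject_id,event_time,status,group) and
``features.csv`` (feature_id,n_peptides,n_missing).
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .datasets import (
    FEATURE_COLUMNS,
    MEASUREMENT_COLUMNS,
    SUBJECT_COLUMNS,
    LongitudinalDataset,
    ValidationError,
)

__all__ = ["write_dataset", "read_long_table"]

_NUMERIC = {
    "measurements.csv": ["time", "value"],
    "subjects.csv": ["event_time", "status"],
    "features.csv": ["n_peptides", "n_missing"],
}
_SCHEMAS = {
    "measurements.csv": MEASUREMENT_COLUMNS,
    "subjects.csv": SUBJECT_COLUMNS,
    "features.csv": FEATURE_COLUMNS,
}


def write_dataset(data: LongitudinalDataset, outdir: str | Path) -> Path:
    """Write the three CSV tables; atomic per file (tmp + rename)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in [
        ("measurements.csv", data.measurements),
        ("subjects.csv", data.subjects),
        ("features.csv", data.features),
    ]:
        tmp = outdir / (name + ".tmp")
        frame.to_csv(tmp, index=False)
        os.replace(tmp, outdir / name)
    return outdir


def _read_table(path: Path, name: str) -> pd.DataFrame:
    f = path / name
    if not f.exists():
        raise ValidationError(f"{f}: file missing")
    df = pd.read_csv(f)
    expected = _SCHEMAS[name]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"{f}: missing column(s) {missing}")
    for col in _NUMERIC[name]:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            line = int(bad.idxmax()) + 2 if bad.any() else "?"
            raise ValidationError(
                f"{f}: line {line}, column {col!r}: non-numeric value"
            ) from exc
    return df[expected]


def read_long_table(path: str | Path) -> LongitudinalDataset:
    """Read and validate a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    meas = _read_table(path, "measurements.csv")
    subj = _read_table(path, "subjects.csv")
    feat = _read_table(path, "features.csv")
    meas["time"] = meas["time"].astype(float)
    subj["event_time"] = subj["event_time"].astype(float)
    subj["status"] = subj["status"].astype(int)
    data = LongitudinalDataset(meas, subj, feat)
    data.validate()
    return data
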