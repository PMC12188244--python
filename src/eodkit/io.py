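"""File formats: recording CSV + JSON sidecar, TSV tables."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .waveform import Recording


def write_recording(rec: Recording, path) -> None:
    """Single-column voltage CSV plus a JSON sidecar with sampling metadata."""
    path = Path(path)
    pd.DataFrame({"voltage": rec.samples}).to_csv(path, index=False)
    sidecar = {
        "sample_rate": 1.0 / rec.dt,
        "npts": int(rec.npts),
        **{k: rec.meta[k] for k in sorted(rec.meta)},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path) -> Recording:
    path = Path(path)
    samples = pd.read_csv(path)["voltage"].to_numpy()
    sidecar = json.loads(path.with_suffix(".json").read_text())
    meta = {k: v for k, v in sidecar.items() if k not in ("sample_rate", "npts")}
    return Recording(samples=samples, dt=1.0 / sidecar["sample_rate"], meta=meta)


def read_recording_dir(directory) -> dict:
    """All ``*.csv`` recordings in a directory, grouped by (fish, day)."""
    out: dict = {}
    for path in sorted(Path(directory).glob("*.csv")):
        rec = read_recording(path)
        key = (rec.meta.get("fish", path.stem), int(rec.meta.get("day", 0)))
        out.setdefault(key, []).append(rec)
    return out


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
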