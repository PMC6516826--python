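"""Plain-text I/O: sweep TSVs with a manifest, labeled point fields, and
profile tables.

Sweep files are columnar TSV (``time_ms``, ``voltage_mV``, ``current_pA``),
one file per sweep, indexed by a manifest table carrying per-sweep metadata.
Point fields are TSV with ``x_um, y_um, z_um, labeled``.  SWC I/O lives in
:mod:`icvip.morphometry`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ephys import SweepRecording
from .errors import FormatError

MANIFEST_NAME = "sweep_manifest.tsv"
MANIFEST_COLUMNS = ["neuron_id", "sweep_file", "step_pa", "step_onset_ms",
                    "step_offset_ms", "sampling_khz", "group"]


def write_sweeps(sweeps: Sequence[SweepRecording], outdir, group: str = "main",
                 manifest_path=None) -> pd.DataFrame:
    """Write one TSV per sweep plus (append to) a manifest; returns the
    manifest rows written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(manifest_path) if manifest_path else outdir / MANIFEST_NAME
    rows = []
    for k, s in enumerate(sweeps):
        current = np.where((s.time >= s.step_onset) & (s.time < s.step_offset),
                           s.command_current, 0.0)
        name = f"{s.neuron_id or 'cell'}_{group}_{k:03d}.tsv"
        pd.DataFrame({"time_ms": s.time, "voltage_mV": s.voltage,
                      "current_pA": current}).to_csv(
            outdir / name, sep="\t", index=False, float_format="%.6g")
        rows.append({"neuron_id": s.neuron_id or "cell", "sweep_file": name,
                     "step_pa": s.command_current,
                     "step_onset_ms": s.step_onset,
                     "step_offset_ms": s.step_offset,
                     "sampling_khz": s.sampling_rate, "group": group})
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    header = not manifest_path.exists()
    df.to_csv(manifest_path, sep="\t", index=False, mode="a", header=header)
    return df


def read_sweeps(manifest_path, group=None) -> dict:
    """Read sweeps back as ``{neuron_id: [SweepRecording, ...]}``."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FormatError(f"manifest not found: {manifest_path}")
    mf = pd.read_csv(manifest_path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in mf.columns]
    if missing:
        raise FormatError(f"manifest missing columns {missing}")
    if group is not None:
        mf = mf[mf["group"] == group]
    out: dict = {}
    for row in mf.itertuples(index=False):
        table = pd.read_csv(manifest_path.parent / row.sweep_file, sep="\t")
        sweep = SweepRecording(
            time=table["time_ms"].to_numpy(),
            voltage=table["voltage_mV"].to_numpy(),
            command_current=float(row.step_pa),
            step_onset=float(row.step_onset_ms),
            step_offset=float(row.step_offset_ms),
            sampling_rate=float(row.sampling_khz),
            neuron_id=str(row.neuron_id))
        out.setdefault(str(row.neuron_id), []).append(sweep)
    return out


def write_point_field(points: pd.DataFrame, path) -> None:
    points.to_csv(path, sep="\t", index=False)


def read_point_field(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("x_um", "y_um", "z_um", "labeled")
               if c not in df.columns]
    if missing:
        raise FormatError(f"point field missing columns {missing}")
    df["labeled"] = df["labeled"].astype(bool)
    return df


def read_mask(path) -> np.ndarray:
    """Section mask polygon vertices from a 2-column TSV (x_um, y_um)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("mask file needs two columns of vertex coordinates")
    return df.iloc[:, :2].to_numpy(dtype=float)
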