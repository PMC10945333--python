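"""Readers and writers for RF recordings, event tables and frame stacks.

Formats:

- RF: raw little-endian float32 samples (``<stem>.bin``) or 2-column CSV
  (time s, amplitude; ``<stem>.csv``), both with a JSON sidecar
  (``<stem>.json``) holding ``sampling_rate``, ``onset_time``,
  ``pulse_length`` and ``f0``.
- Event tables: CSV with the documented column dictionary
  (:data:`mbcav.simulate.events.EVENT_COLUMNS`); rows violating the event
  invariants are rejected individually with a report.
- Frame stacks: multi-page float32 TIFF with a JSON ground-truth sidecar.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from mbcav.core import FrameSequence, RFRecording
from mbcav.simulate.events import EVENT_COLUMNS

log = logging.getLogger("mbcav")

RF_SIDECAR_FIELDS = ("sampling_rate", "onset_time", "pulse_length", "f0")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_rf(rec: RFRecording, stem: str | Path, fmt: str = "binary") -> Path:
    """Write an RF recording plus JSON sidecar; returns the sample-file path."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "binary":
        out = stem.with_suffix(".bin")
        rec.samples.astype("<f4").tofile(out)
    elif fmt == "csv":
        out = stem.with_suffix(".csv")
        pd.DataFrame(
            {"time_s": rec.times, "amplitude": rec.samples.astype(np.float32)}
        ).to_csv(out, index=False)
    else:
        raise ValueError("fmt must be 'binary' or 'csv'")
    sidecar = {
        "sampling_rate": rec.sampling_rate,
        "onset_time": rec.onset_time,
        "pulse_length": rec.pulse_length,
        "f0": rec.f0,
        "format": fmt,
        "metadata": _jsonable(rec.metadata),
    }
    _sidecar_path(stem).write_text(json.dumps(sidecar, indent=1))
    return out


def read_rf(path: str | Path) -> RFRecording:
    """Read an RF recording written by :func:`write_rf`.

    ``path`` may be the ``.bin``/``.csv`` sample file or the bare stem.
    Missing sidecar header fields are rejected by name.
    """
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    for fld in RF_SIDECAR_FIELDS:
        if fld not in sidecar:
            raise ValueError(f"sidecar {sidecar_file} missing field {fld!r}")
    if path.suffix in ("", ".json"):
        fmt = sidecar.get("format", "binary")
        path = path.with_suffix(".bin" if fmt == "binary" else ".csv")
    if path.suffix == ".bin":
        samples = np.fromfile(path, dtype="<f4").astype(np.float64)
    elif path.suffix == ".csv":
        samples = pd.read_csv(path)["amplitude"].to_numpy(dtype=np.float64)
    else:
        raise ValueError(f"unrecognized RF sample file {path}")
    return RFRecording(
        samples=samples,
        sampling_rate=float(sidecar["sampling_rate"]),
        onset_time=float(sidecar["onset_time"]),
        pulse_length=float(sidecar["pulse_length"]),
        f0=float(sidecar["f0"]),
        metadata=sidecar.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# event tables

def write_event_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def _row_violations(row: pd.Series) -> list[str]:
    problems = []
    activation = bool(row["activation"])
    fate = row["fate"]
    has_time = pd.notna(row["extravasation_time_s"])
    if fate != "n/a" and not activation:
        problems.append("fate recorded without activation")
    if activation and fate == "n/a":
        problems.append("activation without a fate")
    if has_time != (fate == "extravasated"):
        problems.append(
            "extravasation time must be present exactly for extravasated fate"
        )
    if row["rbc_leakage"] != "none" and not activation:
        problems.append("RBC leakage without activation")
    if row["flow_reversal"] != "none" and not activation:
        problems.append("flow reversal without activation")
    return problems


def read_event_table(path: str | Path) -> pd.DataFrame:
    """Read and validate an event CSV.

    Rows violating the event-record invariants (e.g. leakage without
    activation) are dropped; the per-row report is attached as
    ``DataFrame.attrs['rejected_rows']``.  An empty file yields an empty
    table with a warning.
    """
    path = Path(path)
    try:
        # keep_default_na=False: the literal fate label "n/a" must survive
        table = pd.read_csv(path, keep_default_na=False)
        for col in ("diameter_um", "bifurcation_distance_um",
                    "extravasation_time_s", "pressure_mpa"):
            if col in table.columns:
                table[col] = pd.to_numeric(table[col], errors="coerce")
        if "activation" in table.columns and table["activation"].dtype == object:
            table["activation"] = table["activation"].map(
                {"True": True, "False": False, "true": True, "false": False}
            )
    except pd.errors.EmptyDataError:
        log.warning("event table %s is empty", path)
        return pd.DataFrame(columns=EVENT_COLUMNS)
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table {path} missing columns {missing}")
    if table.empty:
        log.warning("event table %s has no rows", path)
        table.attrs["rejected_rows"] = []
        return table
    table["activation"] = table["activation"].astype(bool)
    report = []
    keep = np.ones(len(table), dtype=bool)
    for i, (_, row) in enumerate(table.iterrows()):
        problems = _row_violations(row)
        if problems:
            keep[i] = False
            report.append(
                f"row {i} (vessel_id={row['vessel_id']}): " + "; ".join(problems)
            )
    if report:
        log.warning("rejected %d invalid event rows in %s", len(report), path)
    out = table[keep].reset_index(drop=True)
    out.attrs["rejected_rows"] = report
    return out


# ---------------------------------------------------------------------------
# frame stacks

def write_frames(seq: FrameSequence, stem: str | Path) -> Path:
    """Write frames as a multi-page float32 TIFF plus JSON sidecar."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    out = stem.with_suffix(".tif")
    tifffile.imwrite(out, seq.frames.astype(np.float32), photometric="minisblack")
    sidecar = {
        "times": seq.times.tolist(),
        "frame_rate": seq.frame_rate,
        "pixel_pitch": seq.pixel_pitch,
        "onset_time": seq.onset_time,
        "metadata": _jsonable(seq.metadata),
    }
    _sidecar_path(stem).write_text(json.dumps(sidecar, indent=1))
    return out


def read_frames(path: str | Path) -> FrameSequence:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    for fld in ("times", "frame_rate", "pixel_pitch"):
        if fld not in sidecar:
            raise ValueError(f"sidecar {sidecar_file} missing field {fld!r}")
    frames = tifffile.imread(path.with_suffix(".tif")).astype(np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    return FrameSequence(
        frames=frames,
        times=np.asarray(sidecar["times"], dtype=float),
        frame_rate=float(sidecar["frame_rate"]),
        pixel_pitch=float(sidecar["pixel_pitch"]),
        onset_time=float(sidecar.get("onset_time", 0.0)),
        metadata=sidecar.get("metadata", {}),
    )


def write_report(payload: dict, path: str | Path, seed: int | None = None,
                 config: Any = None) -> Path:
    """Write a JSON report with seed/config provenance attached."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = {"provenance": {"seed": seed, "config": _jsonable(config)}}
    body.update(_jsonable(payload))
    path.write_text(json.dumps(body, indent=1))
    return path
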