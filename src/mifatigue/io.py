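"""Reading and writing recordings.

Two containers are supported:

* an **internal container**: a ``.npz`` array file plus a JSON sidecar
  (``<path>.json``) carrying sampling rate, channel labels and events —
  lossless round trip;
* **EDF** (European Data Format): samples are quantized to 16-bit
  integers against a per-channel symmetric physical range.  Events and
  the exact sample count travel in the same JSON sidecar; reading uses
  MNE's EDF parser.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import numpy as np

from .containers import Event, Recording
from .errors import ParseError

_SIDECAR_SUFFIX = ".json"


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + _SIDECAR_SUFFIX)


def _events_to_json(rec: Recording) -> dict:
    return {
        "fs": rec.fs,
        "labels": list(rec.labels),
        "n_samples": int(rec.n_samples),
        "events": [
            {"sample": int(e.sample), "trial": int(e.trial), "label": e.label}
            for e in rec.events
        ],
    }


def _events_from_json(meta: dict) -> list[Event]:
    try:
        return [
            Event(sample=int(e["sample"]), trial=int(e["trial"]), label=e["label"])
            for e in meta["events"]
        ]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed events in sidecar: missing field {exc}") from exc


# ---------------------------------------------------------------- internal

def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write the internal container (lossless): ``.npz`` + JSON sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    np.savez(path, data=rec.data)
    _sidecar_path(path).write_text(json.dumps(_events_to_json(rec), indent=1))
    return path


def load_recording(path: str | Path) -> Recording:
    """Read the internal container written by :func:`save_recording`."""
    path = Path(path)
    try:
        with np.load(path) as npz:
            data = npz["data"]
    except KeyError as exc:
        raise ParseError(f"container {path} lacks the 'data' array") from exc
    except Exception as exc:  # zipfile/OS errors on truncated files
        raise ParseError(f"cannot read array container {path}: {exc}") from exc
    try:
        meta = json.loads(_sidecar_path(path).read_text())
    except FileNotFoundError as exc:
        raise ParseError(f"missing sidecar {_sidecar_path(path)}") from exc
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed sidecar JSON: {exc}") from exc
    for fieldname in ("fs", "labels", "events"):
        if fieldname not in meta:
            raise ParseError(f"sidecar lacks required field {fieldname!r}")
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        labels=tuple(meta["labels"]),
        events=_events_from_json(meta),
    )


# --------------------------------------------------------------------- EDF

def _edf_ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a 16-bit EDF file plus the JSON sidecar.

    Record duration is 1 s (fs samples per record); the tail is
    zero-padded to a whole record and the true sample count is recorded
    in the sidecar so a round trip restores the exact length.  Physical
    range is symmetric per channel, so the quantization step is
    ``2 * max|x| / 65535``.
    """
    path = Path(path)
    if rec.fs != int(rec.fs):
        raise ParseError("EDF export requires an integer sampling rate")
    spr = int(rec.fs)  # samples per 1 s record
    n_rec = int(np.ceil(rec.n_samples / spr))
    ns = rec.n_channels

    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    dig_min, dig_max = -32768, 32767

    now = datetime(2000, 1, 1)
    header = b"".join([
        _edf_ascii("0", 8),
        _edf_ascii("X", 80),
        _edf_ascii("synthetic MI session", 80),
        _edf_ascii(now.strftime("%d.%m.%y"), 8),
        _edf_ascii(now.strftime("%H.%M.%S"), 8),
        _edf_ascii(256 * (ns + 1), 8),
        _edf_ascii("", 44),
        _edf_ascii(n_rec, 8),
        _edf_ascii(1, 8),
        _edf_ascii(ns, 4),
    ])
    fields = [
        (16, rec.labels),
        (80, [""] * ns),
        (8, ["uV"] * ns),
        (8, [f"{-m:.6g}"[:8] for m in phys_max]),
        (8, [f"{m:.6g}"[:8] for m in phys_max]),
        (8, [dig_min] * ns),
        (8, [dig_max] * ns),
        (80, [""] * ns),
        (8, [spr] * ns),
        (32, [""] * ns),
    ]
    for width, values in fields:
        header += b"".join(_edf_ascii(v, width) for v in values)

    padded = np.zeros((ns, n_rec * spr), dtype=np.float64)
    padded[:, : rec.n_samples] = rec.data
    # re-derive physical extremes from the rounded header strings so the
    # reader's scaling matches ours exactly
    pmax = np.array([float(f"{m:.6g}"[:8]) for m in phys_max])
    scale = (dig_max - dig_min) / (2.0 * pmax)
    # EDF readers decode as (dig - dig_min) * step + phys_min, which with
    # a symmetric physical range places value 0 half a step above digital
    # 0 -- encode against the same convention
    digital = np.clip(
        np.round(padded * scale[:, None] - 0.5), dig_min, dig_max
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    _sidecar_path(path).write_text(json.dumps(_events_to_json(rec), indent=1))
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file (via MNE) and its JSON sidecar back to a Recording."""
    import mne

    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise ParseError(f"cannot parse EDF {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # MNE stores EEG in volts
    fs = float(raw.info["sfreq"])
    labels = tuple(raw.ch_names)
    sidecar = _sidecar_path(path)
    events: list[Event] = []
    if sidecar.exists():
        try:
            meta = json.loads(sidecar.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed sidecar JSON: {exc}") from exc
        events = _events_from_json(meta)
        n = int(meta.get("n_samples", data.shape[1]))
        if data.shape[1] < n:
            raise ParseError(
                f"EDF {path} holds {data.shape[1]} samples but the sidecar "
                f"records {n}: file truncated"
            )
        data = data[:, :n]
    return Recording(
        data=data.astype(np.float32), fs=fs, labels=labels, events=events
    )


def quantization_step(rec: Recording) -> np.ndarray:
    """Per-channel EDF quantization step for ``rec``'s physical range."""
    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    pmax = np.array([float(f"{m:.6g}"[:8]) for m in phys_max])
    return 2.0 * pmax / 65535.0
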