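"""File formats: EDF recordings, TSV/CSV tables, JSON sidecars.

Recordings are written as plain 16-bit EDF with a BioSemi-style integer
``Status`` channel carrying event codes, and read back through mne's EDF/BDF
reader (events are recovered from the status channel).  Tables are TSV with
documented column names; every pipeline output can carry a JSON sidecar with
the config hash and seed for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import Recording
from .synthetic import GroundTruth

__all__ = [
    "write_edf",
    "read_recording",
    "write_table",
    "read_table",
    "write_ground_truth",
    "read_ground_truth",
    "write_bad_segments",
    "write_sidecar",
]

_STATUS = "Status"


# --------------------------------------------------------------------------
# EDF writing (16-bit, one fixed-length record per second)
# --------------------------------------------------------------------------


def _ascii(value: str, width: int) -> bytes:
    b = value.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path: str | Path, record_s: float = 1.0) -> Path:
    """Write a recording as EDF.

    Signals are scaled to the 16-bit digital range from their physical
    extrema (microvolts); events are encoded on an appended integer ``Status``
    channel (code held for 8 samples from each event onset).  The recording
    is zero-padded to a whole number of records.
    """
    path = Path(path)
    spr = int(round(record_s * rec.rate))
    if abs(spr - record_s * rec.rate) > 1e-9:
        raise ValueError("record duration must be an integer number of samples")
    n_records = -(-rec.n_samples // spr)
    total = n_records * spr

    status = np.zeros(total, dtype=np.int16)
    for sample, code in rec.events:
        if not 0 <= sample < total:
            raise ValueError(f"event sample {sample} outside recording")
        if not -32768 <= code <= 32767:
            raise ValueError(f"event code {code} does not fit 16 bits")
        status[sample : min(sample + 8, total)] = code

    n_sig = rec.n_channels + 1
    labels = list(rec.labels) + [_STATUS]

    data = np.zeros((rec.n_channels, total))
    data[:, : rec.n_samples] = rec.data
    phys_max = np.maximum(np.abs(data).max(axis=1) * 1.01, 1.0)
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767

    header = bytearray()
    header += _ascii("0", 8)
    header += _ascii("X X X X", 80)
    header += _ascii("Startdate 01-JAN-2000 X X X", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(str(256 * (1 + n_sig)), 8)
    header += _ascii("", 44)
    header += _ascii(str(n_records), 8)
    header += _ascii(f"{record_s:g}", 8)
    header += _ascii(str(n_sig), 4)

    def field(values: list[str], width: int) -> bytes:
        return b"".join(_ascii(v, width) for v in values)

    header += field(labels, 16)
    header += field([""] * n_sig, 80)
    header += field(["uV"] * rec.n_channels + [""], 8)
    header += field([f"{v:.6g}"[:8] for v in phys_min] + [str(dig_min)], 8)
    header += field([f"{v:.6g}"[:8] for v in phys_max] + [str(dig_max)], 8)
    header += field([str(dig_min)] * n_sig, 8)
    header += field([str(dig_max)] * n_sig, 8)
    header += field([""] * n_sig, 80)
    header += field([str(spr)] * n_sig, 8)
    header += field([""] * n_sig, 32)

    # physical -> digital (EDF stores digital values; readers invert this map)
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + dig_min).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            sl = slice(r * spr, (r + 1) * spr)
            fh.write(digital[:, sl].astype("<i2").tobytes())
            fh.write(status[sl].astype("<i2").tobytes())
    return path


# --------------------------------------------------------------------------
# reading (via mne)
# --------------------------------------------------------------------------


def read_recording(path: str | Path) -> Recording:
    """Read an EDF/BDF file into a :class:`Recording` (microvolts).

    Events are extracted from the status/annotation channel when present.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix not in (".edf", ".bdf"):
        raise ValueError(f"unsupported recording format {suffix!r} (expected .edf or .bdf)")
    reader = mne.io.read_raw_bdf if suffix == ".bdf" else mne.io.read_raw_edf
    try:
        raw = reader(path, preload=True, verbose="error")
    except Exception as exc:  # unreadable/truncated file
        raise OSError(f"could not read {path}: {exc}") from exc

    events: list[tuple[int, int]] = []
    stim_picks = mne.pick_types(raw.info, stim=True, eeg=False)
    if len(stim_picks):
        found = mne.find_events(raw, shortest_event=1, verbose="error")
        events = [(int(s), int(code)) for s, _, code in found]

    eeg_picks = mne.pick_types(raw.info, eeg=True, stim=False, misc=True)
    labels = [raw.ch_names[i] for i in eeg_picks]
    data = raw.get_data(picks=eeg_picks) * 1e6  # volts -> microvolts
    return Recording(data=data, rate=float(raw.info["sfreq"]), labels=labels, events=events)


# --------------------------------------------------------------------------
# tables and sidecars
# --------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "B": truth.B.tolist(),
        "I0": truth.I0,
        "I": truth.I.tolist(),
        "b": truth.b.tolist(),
        "sigma_g": truth.sigma_g,
        "nu": truth.nu,
        "sigma_I": truth.sigma_I,
        "slope_sd": truth.slope_sd,
        "conditions": list(truth.conditions),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        B=np.array(d["B"]),
        I0=d["I0"],
        I=np.array(d["I"]),
        b=np.array(d["b"]),
        sigma_g=d["sigma_g"],
        nu=d["nu"],
        sigma_I=d["sigma_I"],
        slope_sd=d["slope_sd"],
        conditions=tuple(d["conditions"]),
    )


def write_bad_segments(rec: Recording, path: str | Path) -> Path:
    """Bad segments as a two-column TSV of start/stop seconds."""
    df = pd.DataFrame(
        [(start / rec.rate, stop / rec.rate) for start, stop in rec.bad_segments],
        columns=["start_s", "stop_s"],
    )
    return write_table(df, path)


def write_sidecar(path: str | Path, config_hash: str, seed: int, **extra) -> Path:
    """JSON provenance sidecar (``<output>.meta.json``) for an output file."""
    out = Path(str(path) + ".meta.json")
    out.write_text(json.dumps({"config_hash": config_hash, "seed": seed, **extra}, indent=1))
    return out
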