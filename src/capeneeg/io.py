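"""Recording and cohort-metadata I/O.

Two recording formats are supported:

* **EDF** (European Data Format): read through :mod:`mne`; written by a
  small built-in EDF+ writer (16-bit samples, one-second data records) so
  round trips work without any EDF-writing dependency.
* **tabular**: a plain CSV with one header row of channel labels and one
  column per channel, plus a YAML sidecar (``<file>.meta.yaml``) holding the
  sampling rate, condition and patient id.  Human-readable; used for small
  fixtures.

Cohort metadata travel as a UTF-8 CSV with columns ``patient_id, age, sex,
lesion, duration_days, crsr, group, mgos`` (plus ``affected_side``, which
the relabeling step needs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, MontageError
from .montage import EEGRecording, to_canonical_order

_EDF_RESERVED = "capeneeg"


@dataclass(frozen=True)
class PatientRecord:
    """One patient's clinical metadata and 12-month outcome."""

    patient_id: str
    age: float
    sex: str  # male | female
    lesion: str  # TBI | hemorrhage
    duration: float  # days since onset
    crsr: float  # CRS-R total at admission
    group: str  # control | tDCS
    mgos: int  # modified Glasgow Outcome Scale, 1-6

    def __post_init__(self) -> None:
        if not 1 <= self.mgos <= 6:
            raise ValueError(f"mgos must be in [1, 6], got {self.mgos}")

    @property
    def improved(self) -> bool:
        """Recovery at 12 months, defined as mGOS >= 3."""
        return self.mgos >= 3


# ---------------------------------------------------------------------------
# EDF writing (minimal EDF+ compatible subset)
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, recording: EEGRecording) -> None:
    """Write a recording as EDF with 16-bit physical scaling.

    Uses one-second data records; the signal is zero-padded to a whole
    number of seconds if needed (the pad is dropped again on read via the
    sample count stored in the reserved header field).
    """
    path = Path(path)
    sig = recording.signal
    fs = int(round(recording.fs))
    if abs(recording.fs - fs) > 1e-9:
        raise DataError(f"EDF writer requires an integer sampling rate, got {recording.fs}")
    n_ch, n_samp = sig.shape
    n_rec = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = sig

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    # avoid zero physical span on constant channels
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((padded - phys_min[:, None]) / scale[:, None] + dig_min).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(f"X X X {recording.patient_id or 'X'}", 80))
        fh.write(_pad(f"Startdate X X X X cond {recording.condition}", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (n_ch + 1)), 8))
        fh.write(_pad(f"{_EDF_RESERVED} n={n_samp}", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_ch), 4))
        for lbl in recording.channel_labels:
            fh.write(_pad(f"EEG {lbl}", 16))
        for _ in range(n_ch):
            fh.write(_pad("", 80))
        for _ in range(n_ch):
            fh.write(_pad("uV", 8))
        for v in phys_min:
            fh.write(_pad(f"{v:.8g}"[:8], 8))
        for v in phys_max:
            fh.write(_pad(f"{v:.8g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dig_min), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dig_max), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 80))
        for _ in range(n_ch):
            fh.write(_pad(str(fs), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 32))
        for rec in range(n_rec):
            block = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(block.tobytes())


def _read_edf(path: Path, condition: str | None, patient_id: str | None) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sig = raw.get_data() * 1e6  # volts -> microvolts
    labels = tuple(raw.ch_names)
    fs = float(raw.info["sfreq"])
    # recover metadata stashed in the headers by write_edf, if present
    with open(path, "rb") as fh:
        header = fh.read(256)
    reserved = header[192:236].decode("ascii", "replace")
    if reserved.startswith(_EDF_RESERVED) and "n=" in reserved:
        n_samp = int(reserved.split("n=")[1].split()[0])
        sig = sig[:, :n_samp]
    rec_field = header[88:168].decode("ascii", "replace")
    if condition is None and "cond " in rec_field:
        condition = rec_field.split("cond ")[1].split()[0]
    pat_field = header[8:88].decode("ascii", "replace").split()
    if patient_id is None and len(pat_field) >= 4 and pat_field[3] != "X":
        patient_id = pat_field[3]
    return _finalize(sig, labels, fs, condition, patient_id)


# ---------------------------------------------------------------------------
# Tabular format
# ---------------------------------------------------------------------------

def write_tabular(path: str | Path, recording: EEGRecording) -> None:
    """Write samples-in-rows CSV plus a YAML sidecar with fs and labels."""
    path = Path(path)
    df = pd.DataFrame(recording.signal.T, columns=list(recording.channel_labels))
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "fs": float(recording.fs),
        "condition": recording.condition,
        "patient_id": recording.patient_id,
    }
    Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(meta))


def _read_tabular(path: Path, condition: str | None, patient_id: str | None) -> EEGRecording:
    df = pd.read_csv(path)
    meta_path = Path(str(path) + ".meta.yaml")
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    fs = float(meta.get("fs", 0.0))
    if fs <= 0:
        raise DataError(f"no sampling rate: sidecar {meta_path} missing or lacks 'fs'")
    return _finalize(
        df.to_numpy(dtype=float).T,
        tuple(df.columns),
        fs,
        condition or meta.get("condition"),
        patient_id or meta.get("patient_id"),
    )


def _finalize(sig, labels, fs, condition, patient_id) -> EEGRecording:
    sig, labels = to_canonical_order(sig, labels)
    return EEGRecording(
        signal=sig,
        fs=fs,
        channel_labels=labels,
        condition=condition or "closed_eyes",
        patient_id=patient_id or "",
    )


def read_recording(
    path: str | Path,
    format: str | None = None,
    condition: str | None = None,
    patient_id: str | None = None,
) -> EEGRecording:
    """Read an EDF or tabular recording, normalizing to the canonical montage.

    Channel labels are normalized to canonical 10-20 names and the signal
    rows permuted into canonical order.  ``format`` is inferred from the
    file suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "tabular"
    if format == "edf":
        return _read_edf(path, condition, patient_id)
    if format == "tabular":
        return _read_tabular(path, condition, patient_id)
    raise ValueError(f"unknown recording format {format!r}")


def write_recording(path: str | Path, recording: EEGRecording, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "tabular"
    if format == "edf":
        write_edf(path, recording)
    elif format == "tabular":
        write_tabular(path, recording)
    else:
        raise ValueError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# Cohort metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "patient_id", "age", "sex", "lesion", "duration_days", "crsr", "group", "mgos",
]


def write_cohort_csv(path: str | Path, table: pd.DataFrame, header_lines: list[str] | None = None) -> None:
    """Write cohort metadata, optionally with ``#``-prefixed provenance lines."""
    missing = [c for c in _META_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"cohort table lacks columns {missing}")
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cohort CSV {path} lacks columns {missing}")
    bad = df[(df["mgos"] < 1) | (df["mgos"] > 6)]
    if len(bad):
        raise DataError(f"mgos outside [1,6] for patients {list(bad['patient_id'])}")
    df["improved"] = df["mgos"] >= 3
    return df
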