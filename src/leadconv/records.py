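"""Multi-lead ECG record container and on-disk formats.

The central I/O unit is :class:`EcgRecord`: a fixed-rate signal matrix with
one column per lead, plus subject/record identifiers and optional diagnostic
labels.  Two on-disk formats are supported:

* a CSV dialect (first row lead names, one column per lead, amplitudes in
  the file's native units; sampling rate supplied by the caller or a JSON
  sidecar), and
* a minimal subset of the WFDB format — a text ``.hea`` header plus a single
  interleaved 16-bit little-endian ``.dat`` signal file (format "16"),
  which covers the layout used by the common PhysioNet 12-lead databases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: The twelve standard leads in conventional order.
STANDARD_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

_CANONICAL = {name.upper(): name for name in STANDARD_LEADS}


def canonical_lead_name(name: str) -> str:
    """Map a lead label to its canonical spelling, case-insensitively.

    Raises ``ValueError`` for labels outside the standard 12-lead set.
    """
    key = name.strip().upper()
    if key not in _CANONICAL:
        raise ValueError(f"unknown ECG lead name: {name!r}")
    return _CANONICAL[key]


@dataclass
class EcgRecord:
    """A multi-lead, fixed-rate ECG signal with metadata.

    Parameters
    ----------
    signals:
        Array of shape ``(n_samples, n_leads)``; amplitudes in millivolts
        or arbitrary units.
    fs:
        Sampling rate in Hz.
    lead_names:
        Ordered lead labels, a duplicate-free subset of the standard twelve.
    subject_id, record_id:
        Opaque identifiers; ``subject_id`` drives subject-disjoint splits.
    labels:
        Optional diagnostic tags (e.g. NORM / MI / STTC / CD / HYP).
    """

    signals: np.ndarray
    fs: float
    lead_names: tuple[str, ...]
    subject_id: str
    record_id: str
    labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (n_samples, n_leads)")
        if self.signals.shape[0] < 1:
            raise ValueError("record must contain at least one sample")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        names = tuple(canonical_lead_name(n) for n in self.lead_names)
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate lead names in {names}")
        if self.signals.shape[1] != len(names):
            raise ValueError(
                f"signals has {self.signals.shape[1]} columns but "
                f"{len(names)} lead names were given"
            )
        self.lead_names = names
        self.labels = frozenset(self.labels)

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return the signal vector of one lead."""
        name = canonical_lead_name(name)
        try:
            idx = self.lead_names.index(name)
        except ValueError:
            raise KeyError(f"record {self.record_id} has no lead {name}") from None
        return self.signals[:, idx]

    def has_leads(self, names) -> bool:
        return all(canonical_lead_name(n) in self.lead_names for n in names)

    def with_signals(self, signals: np.ndarray, fs: float | None = None) -> "EcgRecord":
        return replace(self, signals=signals, fs=self.fs if fs is None else fs)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def write_csv_record(record: EcgRecord, path: str | Path) -> None:
    """Write a record as CSV (header row = lead names) plus a JSON sidecar
    carrying fs, subject/record ids and labels."""
    path = Path(path)
    df = pd.DataFrame(record.signals, columns=list(record.lead_names))
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "fs": record.fs,
        "subject_id": record.subject_id,
        "record_id": record.record_id,
        "labels": sorted(record.labels),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_csv_record(
    path: str | Path,
    fs: float | None = None,
    subject_id: str | None = None,
    record_id: str | None = None,
) -> EcgRecord:
    """Read a CSV record; metadata comes from the JSON sidecar when present,
    otherwise ``fs`` (and optionally ids) must be supplied."""
    path = Path(path)
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fs = fs if fs is not None else meta.get("fs")
    if fs is None:
        raise ValueError(f"no sampling rate for {path}: pass fs= or provide a sidecar")
    df = pd.read_csv(path)
    return EcgRecord(
        signals=df.to_numpy(dtype=np.float64),
        fs=float(fs),
        lead_names=tuple(df.columns),
        subject_id=subject_id or meta.get("subject_id", path.stem),
        record_id=record_id or meta.get("record_id", path.stem),
        labels=frozenset(meta.get("labels", ())),
    )


# ---------------------------------------------------------------------------
# Minimal WFDB subset (format 16, single signal file)
# ---------------------------------------------------------------------------

_WFDB_FMT = "16"


def write_wfdb_record(record: EcgRecord, directory: str | Path) -> Path:
    """Write ``<record_id>.hea`` + ``<record_id>.dat`` (WFDB format 16).

    Amplitudes are quantised with a gain of 1000 ADC units per signal unit
    (the PTB convention of 1000/mV), clipped to the int16 range.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    gain = 1000.0
    adc = np.clip(np.round(record.signals * gain), -32768, 32767).astype("<i2")
    (directory / f"{name}.dat").write_bytes(adc.tobytes(order="C"))
    fs_txt = f"{record.fs:g}"
    lines = [f"{name} {len(record.lead_names)} {fs_txt} {record.n_samples}"]
    for i, lead in enumerate(record.lead_names):
        first = int(adc[0, i])
        lines.append(f"{name}.dat {_WFDB_FMT} {gain:g}(0)/mV 16 0 {first} 0 0 {lead}")
    lines.append(f"# subject_id: {record.subject_id}")
    if record.labels:
        lines.append(f"# labels: {','.join(sorted(record.labels))}")
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    return directory / f"{name}.hea"


def read_wfdb_record(header_path: str | Path) -> EcgRecord:
    """Read a WFDB record written in the supported subset (format 16,
    one interleaved ``.dat`` file, per-signal gain, optional baseline)."""
    header_path = Path(header_path)
    if header_path.suffix != ".hea":
        header_path = header_path.with_suffix(".hea")
    lines = [ln.strip() for ln in header_path.read_text().splitlines() if ln.strip()]
    comments = [ln[1:].strip() for ln in lines if ln.startswith("#")]
    body = [ln for ln in lines if not ln.startswith("#")]
    rec_fields = body[0].split()
    name, n_sig = rec_fields[0], int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else None

    gains = np.ones(n_sig)
    baselines = np.zeros(n_sig)
    leads: list[str] = []
    dat_files = set()
    for i, ln in enumerate(body[1 : 1 + n_sig]):
        parts = ln.split()
        dat_files.add(parts[0])
        fmt = parts[1]
        if fmt != _WFDB_FMT:
            raise NotImplementedError(f"unsupported WFDB signal format {fmt!r}")
        gain_spec = parts[2] if len(parts) > 2 else "200"
        g = gain_spec.split("/")[0]
        if "(" in g:
            g, base = g.split("(")
            baselines[i] = float(base.rstrip(")"))
        gains[i] = float(g) if float(g) != 0 else 200.0
        leads.append(parts[-1])
    if len(dat_files) != 1:
        raise NotImplementedError("only single-.dat WFDB records are supported")

    raw = np.frombuffer(
        (header_path.parent / dat_files.pop()).read_bytes(), dtype="<i2"
    )
    raw = raw[: (len(raw) // n_sig) * n_sig].reshape(-1, n_sig).astype(np.float64)
    if n_samples is not None:
        raw = raw[:n_samples]
    signals = (raw - baselines) / gains

    subject_id = name
    labels: frozenset[str] = frozenset()
    for c in comments:
        if c.lower().startswith("subject_id:"):
            subject_id = c.split(":", 1)[1].strip()
        elif c.lower().startswith("labels:"):
            labels = frozenset(t for t in c.split(":", 1)[1].strip().split(",") if t)
    return EcgRecord(
        signals=signals,
        fs=fs,
        lead_names=tuple(leads),
        subject_id=subject_id,
        record_id=name,
        labels=labels,
    )


def load_record_dir(directory: str | Path, fs: float | None = None) -> list[EcgRecord]:
    """Load every record in a directory (``.hea`` WFDB subset or ``.csv``)."""
    directory = Path(directory)
    records: list[EcgRecord] = []
    for hea in sorted(directory.glob("*.hea")):
        records.append(read_wfdb_record(hea))
    for csv in sorted(directory.glob("*.csv")):
        records.append(read_csv_record(csv, fs=fs))
    if not records:
        raise FileNotFoundError(f"no .hea or .csv records found in {directory}")
    return records
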