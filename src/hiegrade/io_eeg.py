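"""Reading, writing and montage handling for neonatal EEG recordings.

Recordings are held as :class:`EegRecord` objects: a channels-by-time matrix
of potentials in microvolts plus the sampling rate and montage labels.  Two
on-disk formats are supported: EDF (read through MNE; a minimal EDF+ writer
is provided for fixture generation and round-tripping) and a plain-text
"matrix" format — one delimited samples file with a header row of channel
labels and a small JSON sidecar holding rate / patient / grade metadata — so
that desk-scale tests and synthetic datasets need no binary files.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EegRecord",
    "MontageError",
    "DEFAULT_BIPOLAR_PAIRS",
    "read_recording",
    "write_recording",
    "to_bipolar",
    "standardize_rate",
    "read_label_table",
    "write_label_table",
    "grade_proportions",
]

#: Common neonatal 8-channel bipolar derivation set.  The montage is
#: configuration, not a constant of the method: pass your own pairs to
#: :func:`to_bipolar` when the recording uses different electrode names.
DEFAULT_BIPOLAR_PAIRS: tuple[tuple[str, str], ...] = (
    ("F4", "C4"),
    ("C4", "O2"),
    ("F3", "C3"),
    ("C3", "O1"),
    ("T4", "C4"),
    ("C4", "Cz"),
    ("Cz", "C3"),
    ("C3", "T3"),
)


class MontageError(KeyError):
    """A requested electrode label is absent from the recording."""


@dataclass
class EegRecord:
    """A multichannel EEG recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Potentials in microvolts.
    rate : float
        Sampling rate in Hz, > 0.
    channel_labels : sequence of str
        Montage names, one per row of ``samples``.
    patient_id : str, optional
        Opaque patient identifier (groups recordings for patient-wise splits).
    grade : int, optional
        Background severity grade in 1..4 (1 normal/mild, 4 isoelectric).
    """

    samples: np.ndarray
    rate: float
    channel_labels: tuple[str, ...] = field(default_factory=tuple)
    patient_id: str | None = None
    grade: int | None = None
    start_time: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not self.channel_labels:
            self.channel_labels = tuple(
                f"ch{i}" for i in range(self.samples.shape[0])
            )
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if self.grade is not None and self.grade not in (1, 2, 3, 4):
            raise ValueError(f"grade must be in 1..4, got {self.grade}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.rate

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise MontageError(label) from None
        return self.samples[idx]


# ---------------------------------------------------------------------------
# EDF I/O.  Reading goes through MNE's EDF reader; writing uses a minimal
# EDF+ encoder (16-bit integers, one data record per second) sufficient for
# fixtures and round-tripping — the environment offers no EDF writer.
# ---------------------------------------------------------------------------

def _read_edf(path: Path) -> EegRecord:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE holds EEG in volts; we keep microvolts
    return EegRecord(
        samples=data,
        rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )


def _write_edf(path: Path, record: EegRecord) -> None:
    """Minimal EDF+ writer: int16 samples, per-channel physical scaling."""
    n_ch = record.n_channels
    rate = record.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    rate = int(round(rate))
    # pad to a whole number of 1 s data records
    n_records = int(np.ceil(record.n_times / rate))
    padded = np.zeros((n_ch, n_records * rate))
    padded[:, : record.n_times] = record.samples

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    # avoid degenerate physical ranges (flat channels)
    flat = phys_max - phys_min < 1e-12
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"field too long for EDF header: {text!r}")
        return b.ljust(width)

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256 * n_ch), 8),
            pad("EDF+C", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    header += b"".join(pad(lbl, 16) for lbl in record.channel_labels)
    header += b"".join(pad("", 80) for _ in range(n_ch))
    header += b"".join(pad("uV", 8) for _ in range(n_ch))
    header += b"".join(pad(f"{v:.8g}"[:8], 8) for v in phys_min)
    header += b"".join(pad(f"{v:.8g}"[:8], 8) for v in phys_max)
    header += b"".join(pad(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(pad(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(pad("", 80) for _ in range(n_ch))
    header += b"".join(pad(str(rate), 8) for _ in range(n_ch))
    header += b"".join(pad("", 32) for _ in range(n_ch))

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            chunk = padded[:, rec * rate : (rec + 1) * rate]
            for ch in range(n_ch):
                dig = np.round(
                    (chunk[ch] - phys_min[ch]) / gain[ch] + dig_min
                ).astype(np.int16)
                fh.write(struct.pack(f"<{rate}h", *dig))


# ---------------------------------------------------------------------------
# Matrix (plain-text) format
# ---------------------------------------------------------------------------

def _matrix_paths(path: Path) -> tuple[Path, Path]:
    return path, path.with_suffix(path.suffix + ".meta.json")


def _write_matrix(path: Path, record: EegRecord) -> None:
    data_path, meta_path = _matrix_paths(path)
    df = pd.DataFrame(record.samples.T, columns=list(record.channel_labels))
    df.to_csv(data_path, sep="\t", index=False, float_format="%.6f")
    meta = {
        "rate": record.rate,
        "patient_id": record.patient_id,
        "grade": record.grade,
        "start_time": record.start_time,
    }
    meta_path.write_text(json.dumps(meta))


def _read_matrix(path: Path) -> EegRecord:
    data_path, meta_path = _matrix_paths(path)
    df = pd.read_csv(data_path, sep="\t")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return EegRecord(
        samples=df.to_numpy().T,
        rate=float(meta.get("rate", 256.0)),
        channel_labels=tuple(df.columns),
        patient_id=meta.get("patient_id"),
        grade=meta.get("grade"),
        start_time=meta.get("start_time"),
    )


def read_recording(path: str | Path, format: str | None = None) -> EegRecord:
    """Read an EEG recording from ``path``.

    ``format`` is ``"edf"`` or ``"matrix"``; when omitted it is inferred from
    the file extension (``.edf`` vs anything else).
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return _read_edf(path)
    if format == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown format {format!r}")


def write_recording(
    path: str | Path, record: EegRecord, format: str | None = None
) -> None:
    """Write ``record`` to ``path`` in EDF or the plain-text matrix format."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        _write_edf(path, record)
    elif format == "matrix":
        _write_matrix(path, record)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Montage and rate handling
# ---------------------------------------------------------------------------

def to_bipolar(
    record: EegRecord,
    pairs: Sequence[tuple[str, str]] = DEFAULT_BIPOLAR_PAIRS,
) -> EegRecord:
    """Derive a bipolar montage: channel i = anode_i − cathode_i.

    Raises :class:`MontageError` naming the first electrode label that is
    missing from the recording.
    """
    derived = []
    labels = []
    for anode, cathode in pairs:
        derived.append(record.channel(anode) - record.channel(cathode))
        labels.append(f"{anode}-{cathode}")
    return replace(
        record,
        samples=np.vstack(derived),
        channel_labels=tuple(labels),
    )


def standardize_rate(record: EegRecord, target_rate: float) -> EegRecord:
    """Resample every channel to ``target_rate`` (polyphase filtering).

    Duration is preserved to within one sample period; a record already at
    the target rate is returned unchanged.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if abs(target_rate - record.rate) < 1e-9:
        return record
    from fractions import Fraction

    frac = Fraction(target_rate / record.rate).limit_denominator(1000)
    resampled = sps.resample_poly(record.samples, frac.numerator,
                                  frac.denominator, axis=1)
    return replace(record, samples=resampled, rate=float(target_rate))


# ---------------------------------------------------------------------------
# Label tables
# ---------------------------------------------------------------------------

def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read a recording_id,patient_id,grade CSV and validate it."""
    df = pd.read_csv(path, dtype={"recording_id": str, "patient_id": str})
    return validate_label_table(df)


def write_label_table(path: str | Path, table: pd.DataFrame) -> None:
    validate_label_table(table).to_csv(path, index=False)


def validate_label_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"recording_id", "patient_id", "grade"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    if table["recording_id"].duplicated().any():
        dupes = table.loc[table["recording_id"].duplicated(), "recording_id"]
        raise ValueError(f"duplicate recording ids: {list(dupes)[:5]}")
    bad = ~table["grade"].isin([1, 2, 3, 4])
    if bad.any():
        raise ValueError(f"grades outside 1..4: {sorted(table.loc[bad, 'grade'].unique())}")
    return table


def grade_proportions(table: pd.DataFrame) -> pd.Series:
    """Fraction of recordings per grade (index 1..4), summing to 1."""
    counts = table["grade"].value_counts().reindex([1, 2, 3, 4], fill_value=0)
    return counts / counts.sum()
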