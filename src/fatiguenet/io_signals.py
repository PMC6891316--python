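"""Recording and study-table I/O.

Canonical data model for one EEG epoch (``Recording``) and for the aggregated
per-subject / per-condition / per-stage result table (``StudyTable``), with
CSV and 16-bit EDF readers/writers.

Conventions
-----------
* Samples are microvolts, channels x time, 0-based sample indexing.
* CSV layout: one row per channel, first column is the channel label.
* Epoch metadata (subject, condition, stage, sampling rate) lives in a JSON
  sidecar with the same basename (``epoch.csv`` -> ``epoch.json``), for both
  CSV and EDF files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The study montage: 14 scalp electrodes of the 10-10 system covering
#: frontal, central and posterior regions.
STUDY_CHANNELS = (
    "F3", "F4", "F7", "F8", "FT7", "FT8", "C3", "C4",
    "TP7", "TP8", "P3", "P4", "O1", "O2",
)

CONDITIONS = ("normal", "mrm")

STUDY_TABLE_COLUMNS = (
    "subject", "condition", "stage",
    "C", "G", "power_ratio", "eye_rate", "sq_score", "error_rate",
)


class FormatError(ValueError):
    """Malformed on-disk data (labels, shapes, non-numeric samples)."""


class ValidationError(ValueError):
    """Violated invariant of a domain object."""


@dataclass
class Recording:
    """One epoch of multichannel EEG.

    Parameters
    ----------
    subject_id : str
        Subject identifier (the study numbers subjects 1..12).
    condition : str
        ``"normal"`` or ``"mrm"`` (man-machine response mode).
    stage : int
        Measurement stage 1..7 (half-hourly 3-minute windows).
    fs : float
        Sampling rate in Hz, > 0.
    channel_labels : list of str
        Ordered, unique channel labels.
    samples : ndarray
        channels x time array, microvolts.
    """

    subject_id: str
    condition: str
    stage: int
    fs: float
    channel_labels: list[str]
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = [str(c) for c in self.channel_labels]
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if not (1 <= int(self.stage) <= 7):
            raise ValidationError(f"stage must be in 1..7, got {self.stage}")
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise FormatError(
                f"{self.samples.shape[0]} sample rows but "
                f"{len(self.channel_labels)} channel labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise FormatError("duplicate channel labels")
        if self.samples.shape[1] == 0:
            raise ValidationError("empty recording (0 samples)")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Epoch length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise ValidationError(f"channel {label!r} not present") from None
        return self.samples[idx]

    def has_channels(self, labels: Iterable[str]) -> bool:
        return set(labels).issubset(self.channel_labels)


# ---------------------------------------------------------------------------
# CSV epoch I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_sidecar(rec: Recording, path: Path) -> None:
    meta = {
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "stage": int(rec.stage),
        "fs": float(rec.fs),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("subject_id", "condition", "stage", "fs"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} missing field {key!r}")
    return meta


def write_recording(rec: Recording, path: str | Path, format: str = "csv") -> None:
    """Write a Recording (and its JSON metadata sidecar) to disk.

    ``format="csv"`` stores the full-precision text matrix; ``format="edf"``
    stores 16-bit EDF with per-channel physical scaling (quantization error is
    bounded by the channel's (max-min)/(2^16-1) step).
    """
    path = Path(path)
    if format == "csv":
        with open(path, "w") as fh:
            for label, row in zip(rec.channel_labels, rec.samples):
                fh.write(label + "," + ",".join(repr(float(v)) for v in row)
                         + "\n")
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise ValidationError(f"unknown format {format!r}")
    _write_sidecar(rec, path)


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a Recording written by :func:`write_recording`.

    The format is inferred from the file extension when not given.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    meta = _read_sidecar(path)
    if format == "csv":
        labels: list[str] = []
        rows: list[np.ndarray] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split(",")
                labels.append(parts[0])
                try:
                    rows.append(np.array([float(v) for v in parts[1:]]))
                except ValueError as exc:
                    raise FormatError(
                        f"non-numeric sample on line {lineno} of {path}") from exc
        if not rows:
            raise FormatError(f"no channels found in {path}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged channel lengths {sorted(lengths)} in {path}")
        samples = np.vstack(rows)
    elif format == "edf":
        labels, samples, fs_edf = _read_edf(path)
        if abs(fs_edf - float(meta["fs"])) > 1e-6 * float(meta["fs"]):
            raise FormatError(
                f"EDF sampling rate {fs_edf} disagrees with sidecar {meta['fs']}")
    else:
        raise ValidationError(f"unknown format {format!r}")
    return Recording(
        subject_id=str(meta["subject_id"]),
        condition=str(meta["condition"]),
        stage=int(meta["stage"]),
        fs=float(meta["fs"]),
        channel_labels=labels,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# EDF (16-bit European Data Format)
# ---------------------------------------------------------------------------
# The writer emits a minimal EDF+ -compatible plain EDF file with a single
# data record holding the whole epoch.  No EDF *writer* is available in the
# dependency set (mne only reads), so the fixed-layout header is assembled
# here; reading goes through mne for independence.

def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValidationError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def edf_quantization_step(physical_min: float, physical_max: float) -> float:
    """Size of one digital unit for a 16-bit EDF channel."""
    return (physical_max - physical_min) / 65535.0


def _write_edf(rec: Recording, path: Path) -> None:
    n_sig = rec.n_channels
    n_samp = rec.n_samples
    record_duration = rec.duration

    # physical range per channel, padded so flat channels stay representable
    pmins, pmaxs, digital = [], [], []
    for row in rec.samples:
        lo, hi = float(np.min(row)), float(np.max(row))
        if hi - lo < 1e-6:
            lo, hi = lo - 1.0, hi + 1.0
        step = edf_quantization_step(lo, hi)
        dig = np.round((row - lo) / step).astype(np.int64) - 32768
        digital.append(np.clip(dig, -32768, 32767).astype("<i2"))
        pmins.append(lo)
        pmaxs.append(hi)

    header_bytes = 256 * (1 + n_sig)
    with open(path, "wb") as fh:
        fh.write(_ascii_field("0", 8))                      # version
        fh.write(_ascii_field("X X X X", 80))               # patient id
        fh.write(_ascii_field("Startdate X X X X", 80))     # recording id
        fh.write(_ascii_field("01.01.00", 8))               # start date
        fh.write(_ascii_field("00.00.00", 8))               # start time
        fh.write(_ascii_field(header_bytes, 8))
        fh.write(_ascii_field("", 44))                      # reserved
        fh.write(_ascii_field(1, 8))                        # n data records
        fh.write(_ascii_field(f"{record_duration:.6g}", 8))
        fh.write(_ascii_field(n_sig, 4))
        for lab in rec.channel_labels:
            fh.write(_ascii_field(f"EEG {lab}", 16))
        for _ in range(n_sig):
            fh.write(_ascii_field("AgAgCl electrode", 80))
        for _ in range(n_sig):
            fh.write(_ascii_field("uV", 8))
        for lo in pmins:
            fh.write(_ascii_field(f"{lo:.7g}"[:8], 8))
        for hi in pmaxs:
            fh.write(_ascii_field(f"{hi:.7g}"[:8], 8))
        for _ in range(n_sig):
            fh.write(_ascii_field(-32768, 8))
        for _ in range(n_sig):
            fh.write(_ascii_field(32767, 8))
        for _ in range(n_sig):
            fh.write(_ascii_field("", 80))                  # prefiltering
        for _ in range(n_sig):
            fh.write(_ascii_field(n_samp, 8))
        for _ in range(n_sig):
            fh.write(_ascii_field("", 32))                  # reserved
        for dig in digital:
            fh.write(dig.tobytes())


def _read_edf(path: Path) -> tuple[list[str], np.ndarray, float]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = [lab.removeprefix("EEG ") for lab in raw.ch_names]
    samples = raw.get_data() * 1e6  # mne returns volts
    return labels, np.asarray(samples, dtype=float), float(raw.info["sfreq"])


# ---------------------------------------------------------------------------
# Study table
# ---------------------------------------------------------------------------

@dataclass
class StudyTable:
    """Aggregated per (subject, condition, stage) metrics.

    Wraps a DataFrame with the fixed column set
    ``subject, condition, stage, C, G, power_ratio, eye_rate, sq_score,
    error_rate``.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=list(STUDY_TABLE_COLUMNS)))

    def __post_init__(self) -> None:
        missing = set(STUDY_TABLE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValidationError(f"StudyTable missing columns {sorted(missing)}")
        self.data = self.data[list(STUDY_TABLE_COLUMNS)].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            return
        if not df["condition"].isin(CONDITIONS).all():
            bad = sorted(set(df["condition"]) - set(CONDITIONS))
            raise ValidationError(f"unknown condition(s) {bad}")
        if not df["stage"].between(1, 7).all():
            raise ValidationError("stage values must be in 1..7")
        sq = df["sq_score"].dropna()
        if len(sq) and not sq.isin(range(1, 8)).all():
            raise ValidationError("sq_score must be an integer in 1..7")
        for col in ("C", "G", "power_ratio", "eye_rate", "error_rate"):
            vals = df[col].dropna()
            if len(vals) and (vals < 0).any():
                raise ValidationError(f"negative values in column {col}")
        if df.duplicated(["subject", "condition", "stage"]).any():
            raise ValidationError("duplicate (subject, condition, stage) rows")

    def add_row(self, subject, condition, stage, **metrics) -> None:
        row = {"subject": subject, "condition": condition, "stage": stage}
        row.update({c: metrics.get(c, np.nan) for c in STUDY_TABLE_COLUMNS[3:]})
        new = pd.DataFrame([row])[list(STUDY_TABLE_COLUMNS)]
        if self.data.empty:
            self.data = new
        else:
            self.data = pd.concat([self.data, new], ignore_index=True)

    def completeness_gaps(self, stages: Sequence[int] = range(1, 8)) -> list[tuple]:
        """Missing (subject, condition, stage) triples over the observed
        subjects/conditions."""
        gaps = []
        present = set(map(tuple, self.data[["subject", "condition", "stage"]]
                          .itertuples(index=False, name=None)))
        for subj in sorted(self.data["subject"].unique()):
            for cond in sorted(self.data["condition"].unique()):
                for st in stages:
                    if (subj, cond, st) not in present:
                        gaps.append((subj, cond, st))
        return gaps

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StudyTable):
            return NotImplemented
        a = self.data.sort_values(["subject", "condition", "stage"]).reset_index(drop=True)
        b = other.data.sort_values(["subject", "condition", "stage"]).reset_index(drop=True)
        if a.shape != b.shape:
            return False
        num = ["stage", "C", "G", "power_ratio", "eye_rate", "sq_score", "error_rate"]
        return (
            (a["subject"].astype(str) == b["subject"].astype(str)).all()
            and (a["condition"] == b["condition"]).all()
            and np.allclose(a[num].astype(float), b[num].astype(float),
                            rtol=1e-12, atol=1e-12, equal_nan=True)
        )


def write_study_table(table: StudyTable, path: str | Path) -> None:
    table.validate()
    table.data.to_csv(path, index=False, columns=list(STUDY_TABLE_COLUMNS))


def read_study_table(path: str | Path) -> StudyTable:
    df = pd.read_csv(path)
    return StudyTable(df)
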