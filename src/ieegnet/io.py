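"""Readers, writers and domain containers for signals, contacts and manifests.

Signals travel as EDF/EDF+ files (the de facto interchange format for clinical
EEG), per-contact metadata as CSV, cohort manifests as JSON, and square labeled
matrices as CSV.  Contact/channel identity is by exact string match: silent
fuzzy matching of clinical label variants is worse than a hard error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "ContactTable",
    "SegmentRef",
    "PatientEntry",
    "CohortManifest",
    "read_recording",
    "write_recording_edf",
    "read_contact_table",
    "write_contact_table",
    "align_contacts",
    "write_matrix",
    "read_matrix",
]


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """A multichannel iEEG segment: ``channels x samples`` in physical units.

    Parameters
    ----------
    patient_id : str
        Identifier of the patient the segment belongs to.
    channel_ids : list of str
        One unique id per row of ``data``.
    fs : float
        Sampling rate in Hz (clinical data are typically 512 or 1024 Hz).
    data : ndarray, shape (n_channels, n_samples)
        Signal values; units are whatever the source file declares.  All
        downstream statistics are correlation based and scale invariant.
    t0 : float
        Segment start time in seconds from the recording origin.
    """

    patient_id: str
    channel_ids: list[str]
    fs: float
    data: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[0]} rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, t0: Optional[float] = None) -> "Recording":
        """Copy of this recording with new sample values (same channels)."""
        return Recording(
            patient_id=self.patient_id,
            channel_ids=list(self.channel_ids),
            fs=self.fs,
            data=data,
            t0=self.t0 if t0 is None else t0,
        )

    def select_channels(self, ids: Sequence[str]) -> "Recording":
        index = {c: i for i, c in enumerate(self.channel_ids)}
        missing = [c for c in ids if c not in index]
        if missing:
            raise KeyError(f"unknown channel id(s): {missing}")
        rows = [index[c] for c in ids]
        return Recording(
            patient_id=self.patient_id,
            channel_ids=list(ids),
            fs=self.fs,
            data=self.data[rows],
            t0=self.t0,
        )


@dataclass
class ContactTable:
    """Per-contact anatomy: mm coordinates plus removed/artifact flags.

    Coordinates are Cartesian millimetres in a patient-native space; only
    Euclidean differences are ever used, so origin and orientation conventions
    are irrelevant.  The removed flag records whether the contact lay within
    5 mm of the resected tissue (determined upstream from imaging).
    """

    contact_ids: list[str]
    coords: np.ndarray  # (n, 3) mm
    removed: np.ndarray  # bool
    artifact: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.contact_ids = list(self.contact_ids)
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.contact_ids), 3)
        self.removed = np.asarray(self.removed, dtype=bool).reshape(-1)
        self.artifact = np.asarray(self.artifact, dtype=bool).reshape(-1)
        n = len(self.contact_ids)
        if len(set(self.contact_ids)) != n:
            raise ValueError("contact_id must be unique")
        if self.removed.shape != (n,) or self.artifact.shape != (n,):
            raise ValueError("flag arrays must match the number of contacts")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("contact coordinates must be finite")

    def __len__(self) -> int:
        return len(self.contact_ids)

    @property
    def n_removed(self) -> int:
        return int(self.removed.sum())

    @property
    def n_spared(self) -> int:
        return int((~self.removed).sum())

    def subset(self, ids: Sequence[str]) -> "ContactTable":
        index = {c: i for i, c in enumerate(self.contact_ids)}
        missing = [c for c in ids if c not in index]
        if missing:
            raise KeyError(f"unknown contact id(s): {missing}")
        rows = [index[c] for c in ids]
        return ContactTable(
            contact_ids=list(ids),
            coords=self.coords[rows],
            removed=self.removed[rows],
            artifact=self.artifact[rows],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contact_id": self.contact_ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "removed": self.removed.astype(int),
                "artifact": self.artifact.astype(int),
            }
        )


class SegmentRef(BaseModel):
    """Pointer into a recording file: which time range of which EDF."""

    path: str
    offset_s: float = Field(default=0.0, ge=0.0)
    length_s: Optional[float] = Field(default=None, gt=0.0)


class PatientEntry(BaseModel):
    patient_id: str
    ilae_class: int = Field(ge=1)
    contact_table: str
    recordings: list[SegmentRef] = Field(min_length=1)

    @property
    def good_outcome(self) -> bool:
        """ILAE class 1 (seizure free) is good; class 2 and above is poor."""
        return self.ilae_class == 1


class CohortManifest(BaseModel):
    patients: list[PatientEntry]

    @model_validator(mode="after")
    def _unique_patients(self) -> "CohortManifest":
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_id must be unique in a manifest")
        return self

    @classmethod
    def load(cls, path: str | Path) -> "CohortManifest":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_DIG_MAX = 32767
_EDF_DIG_MIN = -32767


def _ascii_field(value, width: int) -> bytes:
    text = str(value)
    if len(text) > width:
        raise ValueError(f"EDF header field too wide: {text!r} > {width}")
    return text.ljust(width).encode("ascii")


def _phys_bounds(v: float) -> tuple[str, str, float]:
    """Symmetric physical bounds (+v, -v) as <= 8-char ASCII at equal precision."""
    for fmt in ("%.6g", "%.5g", "%.4g", "%.3g"):
        pos, neg = fmt % v, fmt % -v
        if len(pos) <= 8 and len(neg) <= 8:
            return pos, neg, float(pos)
    raise ValueError(f"cannot format {v} into 8 chars")


def write_recording_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as a 16-bit EDF file.

    The sampling rate must be a positive integer and the sample count a
    multiple of ``fs`` (whole 1-second data records), which every synthetic
    fixture satisfies.  Each channel is scaled to its own symmetric physical
    range, so the quantization step is ``2*max|x| / 65534`` per channel.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec, rem = divmod(rec.n_samples, fs)
    if rem or n_rec < 1:
        raise ValueError("sample count must be a positive multiple of fs")

    ns = rec.n_channels
    # pad the range slightly so the printed (rounded) bound still covers the data
    raw_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-9) * 1.001
    bounds = [_phys_bounds(v) for v in raw_max]
    phys_strs = [b[0] for b in bounds]
    neg_strs = [b[1] for b in bounds]
    phys_max = np.array([b[2] for b in bounds])

    start = datetime(2000, 1, 1)
    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field(rec.patient_id[:80], 80),
            _ascii_field("synthetic iEEG", 80),
            _ascii_field(start.strftime("%d.%m.%y"), 8),
            _ascii_field(start.strftime("%H.%M.%S"), 8),
            _ascii_field(256 * (1 + ns), 8),
            _ascii_field("", 44),
            _ascii_field(n_rec, 8),
            _ascii_field(1, 8),
            _ascii_field(ns, 4),
        ]
    )
    sig = b"".join(_ascii_field(c[:16], 16) for c in rec.channel_ids)
    sig += b"".join(_ascii_field("", 80) for _ in range(ns))
    sig += b"".join(_ascii_field("uV", 8) for _ in range(ns))
    sig += b"".join(_ascii_field(s, 8) for s in neg_strs)
    sig += b"".join(_ascii_field(s, 8) for s in phys_strs)
    sig += b"".join(_ascii_field(_EDF_DIG_MIN, 8) for _ in range(ns))
    sig += b"".join(_ascii_field(_EDF_DIG_MAX, 8) for _ in range(ns))
    sig += b"".join(_ascii_field("", 80) for _ in range(ns))
    sig += b"".join(_ascii_field(fs, 8) for _ in range(ns))
    sig += b"".join(_ascii_field("", 32) for _ in range(ns))

    scale = _EDF_DIG_MAX / phys_max  # digital per physical unit
    digital = np.rint(rec.data * scale[:, None])
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # records are 1 s long: for each record, all channels' fs samples
        blocks = digital.reshape(ns, n_rec, fs)
        for r in range(n_rec):
            fh.write(blocks[:, r, :].tobytes())


def read_recording(
    path: str | Path,
    channel_subset: Optional[Sequence[str]] = None,
    patient_id: Optional[str] = None,
) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (physical units).

    Channels come back in ``channel_subset`` order when given, file order
    otherwise.  Unknown channel ids raise ``KeyError``; EDF files mixing
    sampling rates within the requested subset are rejected.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = list(raw.ch_names)
    if channel_subset is not None:
        missing = [c for c in channel_subset if c not in names]
        if missing:
            raise KeyError(f"unknown channel id(s): {missing}")
        raw = raw.pick(list(channel_subset))
        raw = raw.reorder_channels(list(channel_subset))
        names = list(raw.ch_names)
    # MNE converts uV to volts internally; ask for the file's physical units back
    data = raw.get_data(units="uV")
    return Recording(
        patient_id=patient_id or path.stem,
        channel_ids=names,
        fs=float(raw.info["sfreq"]),
        data=data,
        t0=0.0,
    )


# ---------------------------------------------------------------------------
# Contact tables
# ---------------------------------------------------------------------------

_REQUIRED_CONTACT_COLUMNS = ("contact_id", "x", "y", "z", "removed", "artifact")
_BOOL_MAP = {"0": False, "1": True, "true": True, "false": False}


def _parse_bool_column(col: pd.Series, name: str) -> np.ndarray:
    out = []
    for v in col:
        key = str(v).strip().lower()
        if key not in _BOOL_MAP:
            raise ValueError(f"column {name!r}: cannot parse {v!r} as boolean")
        out.append(_BOOL_MAP[key])
    return np.array(out, dtype=bool)


def read_contact_table(path: str | Path) -> ContactTable:
    """Read and validate a contact CSV (contact_id,x,y,z,removed,artifact)."""
    df = pd.read_csv(path, dtype={"contact_id": str})
    missing = [c for c in _REQUIRED_CONTACT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"contact table missing column(s): {missing}")
    coords = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce").to_numpy()
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-numeric or non-finite coordinate in contact table")
    return ContactTable(
        contact_ids=df["contact_id"].tolist(),
        coords=coords,
        removed=_parse_bool_column(df["removed"], "removed"),
        artifact=_parse_bool_column(df["artifact"], "artifact"),
    )


def write_contact_table(tab: ContactTable, path: str | Path) -> None:
    tab.to_dataframe().to_csv(path, index=False)


def align_contacts(rec: Recording, tab: ContactTable) -> tuple[Recording, ContactTable]:
    """Restrict recording and table to their common ids, identically ordered.

    Contacts flagged as artifactual are dropped (visual artifact screening is
    consumed as an input, not recomputed).  Order follows the recording's
    channel order.  Idempotent.
    """
    keep = {c for c, a in zip(tab.contact_ids, tab.artifact) if not a}
    common = [c for c in rec.channel_ids if c in keep]
    if not common:
        raise ValueError(
            f"no usable common channels between recording {rec.patient_id!r} "
            "and its contact table"
        )
    dropped = [c for c in rec.channel_ids if c in set(tab.contact_ids) - keep]
    if dropped:
        logger.info("dropping %d artifact channel(s): %s", len(dropped), dropped)
    return rec.select_channels(common), tab.subset(common)


# ---------------------------------------------------------------------------
# Labeled square matrices
# ---------------------------------------------------------------------------


def write_matrix(path: str | Path, matrix: np.ndarray, row_labels: Sequence[str]) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if matrix.shape[0] != len(row_labels):
        raise ValueError("label count must match matrix size")
    df = pd.DataFrame(matrix, index=list(row_labels), columns=list(row_labels))
    df.to_csv(path, float_format="%.17g")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"matrix in {path} is not square: {df.shape}")
    labels = [str(c) for c in df.index]
    if [str(c) for c in df.columns] != labels:
        raise ValueError("row and column labels disagree")
    return df.to_numpy(dtype=float), labels
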