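"""Windowed-correlation functional networks.

One functional network per recording: Pearson correlation over consecutive
non-overlapping 2-second windows, averaged entrywise across windows.
Correlations are kept signed and averaged raw (no absolute value, no Fisher
transform); an ``absolute`` flag is available for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "SegmentSpec",
    "extract_segment",
    "window_partition",
    "window_correlation",
    "temporal_average_network",
]


@dataclass
class ConnectivityMatrix:
    """Temporally averaged (optionally distance-normalized) correlation matrix."""

    patient_id: str
    contact_ids: list[str]
    values: np.ndarray
    n_windows: int
    window_len_s: float = 2.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.contact_ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match contact_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValueError("connectivity matrix must be symmetric")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if not self.normalized:
            if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
                raise ValueError("unnormalized matrix must have unit diagonal")
            off = self.values[~np.eye(n, dtype=bool)]
            if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
                raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_contacts(self) -> int:
        return len(self.contact_ids)

    def save(self, path_prefix) -> None:
        """Write ``<prefix>.csv`` (labeled matrix) and ``<prefix>.json`` sidecar."""
        import json
        from pathlib import Path

        from .io import write_matrix

        prefix = Path(path_prefix)
        write_matrix(prefix.with_suffix(".csv"), self.values, self.contact_ids)
        sidecar = {
            "patient_id": self.patient_id,
            "n_windows": self.n_windows,
            "window_len_s": self.window_len_s,
            "normalized": self.normalized,
        }
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path_prefix) -> "ConnectivityMatrix":
        import json
        from pathlib import Path

        from .io import read_matrix

        prefix = Path(path_prefix)
        values, labels = read_matrix(prefix.with_suffix(".csv"))
        with open(prefix.with_suffix(".json")) as fh:
            meta = json.load(fh)
        return cls(
            patient_id=meta["patient_id"],
            contact_ids=labels,
            values=values,
            n_windows=meta["n_windows"],
            window_len_s=meta["window_len_s"],
            normalized=meta["normalized"],
        )


@dataclass(frozen=True)
class SegmentSpec:
    """A time slice of a recording: ``offset_s`` from its start, ``length_s`` long."""

    offset_s: float
    length_s: float

    def __post_init__(self) -> None:
        if self.offset_s < 0:
            raise ValueError("offset_s must be >= 0")
        if self.length_s <= 0:
            raise ValueError("length_s must be positive")


def extract_segment(rec: Recording, seg: SegmentSpec) -> Recording:
    """Sample-exact slice ``[offset, offset+length)``; ``t0`` is advanced."""
    i0 = int(round(seg.offset_s * rec.fs))
    i1 = i0 + int(round(seg.length_s * rec.fs))
    if i1 > rec.n_samples:
        raise ValueError(
            f"segment [{seg.offset_s}, {seg.offset_s + seg.length_s}) s exceeds "
            f"recording duration {rec.duration_s} s"
        )
    return rec.with_data(rec.data[:, i0:i1], t0=rec.t0 + seg.offset_s)


def window_partition(rec: Recording, window_len_s: float = 2.0) -> list[np.ndarray]:
    """Consecutive non-overlapping windows; a trailing partial window is dropped."""
    wlen = int(round(window_len_s * rec.fs))
    if wlen < 2:
        raise ValueError("window must contain at least 2 samples")
    n_win = rec.n_samples // wlen
    if n_win < 1:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{window_len_s} s window ({wlen} samples)"
        )
    return [rec.data[:, k * wlen : (k + 1) * wlen] for k in range(n_win)]


def window_correlation(window: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of one ``channels x samples`` window.

    Zero-variance (constant) channels cannot be correlated; their entries are
    set to 0 (diagonal stays 1) and a warning is logged.  Real data after
    bandpassing are never exactly constant, so this only guards degenerate
    synthetic or clipped input.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] < 2:
        raise ValueError("window must be 2-D with >= 2 samples")
    sd = window.std(axis=1)
    constant = sd == 0.0
    if constant.any():
        logger.warning(
            "window contains %d constant channel(s); their correlations set to 0",
            int(constant.sum()),
        )
        centered = window - window.mean(axis=1, keepdims=True)
        z = np.zeros_like(centered)
        z[~constant] = centered[~constant] / sd[~constant, None]
        c = z @ z.T / window.shape[1]
        np.fill_diagonal(c, 1.0)
    else:
        c = np.corrcoef(window)
    c = np.clip(c, -1.0, 1.0)
    return (c + c.T) / 2.0


def temporal_average_network(
    rec: Recording, window_len_s: float = 2.0, absolute: bool = False
) -> ConnectivityMatrix:
    """Entrywise mean of per-window correlation matrices.

    Parameters
    ----------
    rec : Recording
        Preprocessed, artifact-free segment.
    window_len_s : float
        Window length in seconds (2 s by default; exact in samples for
        512/1024 Hz data).
    absolute : bool
        Average ``|r|`` instead of signed ``r`` (sensitivity analysis only).
    """
    windows = window_partition(rec, window_len_s)
    acc = np.zeros((rec.n_channels, rec.n_channels))
    for w in windows:
        c = window_correlation(w)
        acc += np.abs(c) if absolute else c
    acc /= len(windows)
    np.fill_diagonal(acc, 1.0)
    return ConnectivityMatrix(
        patient_id=rec.patient_id,
        contact_ids=list(rec.channel_ids),
        values=acc,
        n_windows=len(windows),
        window_len_s=window_len_s,
        normalized=False,
    )
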