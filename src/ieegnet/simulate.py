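"""Synthetic iEEG cohorts with known ground truth.

The generator emulates the statistical structure the analysis relies on,
nothing more: (i) pairwise correlation decaying with Euclidean distance
following a rat11 curve f_true(d); (ii) a spatially contiguous epileptogenic
contact cluster whose mutual correlations are elevated by an additive effect
delta; (iii) a contiguous resection whose overlap with that cluster
determines the outcome label (complete overlap -> ILAE class 1, no overlap ->
poor outcome); (iv) stationary zero-mean Gaussian signals realizing the
target correlation matrix, with optional common-mode 50 Hz contamination.
Signals are Gaussian and white in time: windowed Pearson correlation only
sees the instantaneous covariance, so richer spectra would change effective
degrees of freedom but not the quantities under test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import (
    CohortManifest,
    ContactTable,
    PatientEntry,
    Recording,
    SegmentRef,
    write_contact_table,
    write_recording_edf,
)
from .spatial import BaselineFit

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "SynthPatient",
    "make_layout",
    "make_target_correlation",
    "sample_recording",
    "make_patient",
    "make_cohort",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults mirror a realistic clinical cohort.

    A subdural grid (8x8 at 10 mm pitch when geometry is not varied),
    hour-long interictal segments at 512 Hz, a 5-contact epileptogenic
    cluster whose mutual correlation is raised by ``epi_effect`` = 0.1 above
    the distance baseline, and a contiguous resection.  The true decay
    f_true(d) = (p1 d + p2)/(d + q1) with (0.015, 1.6, 10.0) runs from 0.16
    at contact-touching distances down to ~0.03 at 10 cm — the modest
    broadband correlation level of average-referenced interictal recordings,
    which keeps rereferencing from grossly distorting the planted structure.

    Cross-patient implantation variability — the spatial-sampling confound
    the analysis is designed to overcome — is emulated by sampling grid
    dimensions, contact pitch and resection extent per patient from the
    ``*_range`` fields (set a range to None to freeze that quantity).

    Channel amplitudes are heterogeneous, as in clinical recordings: a
    lognormal electrode-coupling gain (``gain_sd``) times a factor
    (local coherence)^(-amp_coherence_exp/2), emulating the empirical
    anti-correlation between recorded amplitude and local synchrony —
    contacts dominated by strong independent background run hot and
    correlate weakly, while hypersynchronous (e.g. epileptogenic) cortex
    shows an attenuated background.  With ``epi_effect = 0``, epileptogenic
    contacts carry no signature of any kind.
    """

    grid_shape: tuple[int, int] = (8, 8)
    pitch_mm: float = 10.0
    grid_rows_range: tuple[int, int] | None = (6, 8)
    grid_cols_range: tuple[int, int] | None = (6, 10)
    pitch_range_mm: tuple[float, float] | None = (7.0, 12.0)
    n_resected_range: tuple[int, int] | None = (12, 32)
    baseline_p1: float = 0.015
    baseline_p2: float = 1.6
    baseline_q1: float = 10.0
    epi_set_size: int = 5
    epi_effect: float = 0.1
    n_resected: int = 20
    resection_overlap_threshold: float = 1.0
    poor_overlap: float = 0.0
    duration_s: float = 3600.0
    fs: float = 512.0
    amp_coherence_exp: float = 6.0
    gain_sd: float = 0.1
    line_noise_amp: float = 0.0
    label_noise: float = 0.0
    max_psd_repair: float = 0.05

    @property
    def n_contacts(self) -> int:
        return int(np.prod(self.grid_shape))

    def f_true(self, d):
        d = np.asarray(d, dtype=float)
        return (self.baseline_p1 * d + self.baseline_p2) / (d + self.baseline_q1)

    def true_baseline(self) -> BaselineFit:
        """The generating decay packaged as a baseline-fit record."""
        return BaselineFit(
            p1=self.baseline_p1,
            p2=self.baseline_p2,
            q1=self.baseline_q1,
            n_pairs_fit=0,
            fit_rmse=0.0,
            distance_range_fit=(self.pitch_mm, self.pitch_mm * 20),
        )


@dataclass
class SynthPatient:
    """One generated patient plus its ground truth."""

    recording: Recording
    contacts: ContactTable
    epi_contact_ids: list[str]
    ilae_class: int
    resection_overlap: float
    target_correlation: np.ndarray
    amplitudes: np.ndarray | None = None
    extra_segments: list = field(default_factory=list)


def make_layout(cfg: SynthConfig) -> np.ndarray:
    """Deterministic grid coordinates in mm (z = 0 cortical sheet)."""
    rows, cols = cfg.grid_shape
    if rows < 1 or cols < 1:
        raise ValueError("grid shape must be positive")
    xx, yy = np.meshgrid(np.arange(cols), np.arange(rows))
    coords = np.column_stack(
        [xx.ravel() * cfg.pitch_mm, yy.ravel() * cfg.pitch_mm, np.zeros(rows * cols)]
    )
    return coords


def make_target_correlation(
    dist_values: np.ndarray, epi_mask: np.ndarray, cfg: SynthConfig
) -> tuple[np.ndarray, float]:
    """Distance-decay correlation plus the epileptogenic bump, PSD-repaired.

    C_ij = f_true(d_ij) + delta for epileptogenic-epileptogenic pairs, unit
    diagonal, then projected to the nearest valid correlation matrix by
    eigenvalue clipping and diagonal rescaling.  Returns the matrix and the
    largest entrywise move the repair made; a move beyond
    ``cfg.max_psd_repair`` means the requested structure is infeasible.
    """
    epi_mask = np.asarray(epi_mask, dtype=bool)
    c = cfg.f_true(dist_values)
    bump = np.outer(epi_mask, epi_mask).astype(float) * cfg.epi_effect
    c = c + bump
    np.fill_diagonal(c, 1.0)
    target = c.copy()  # pre-repair target; clipping counts as repair distance
    c = np.clip(c, -1.0, 1.0)
    for _ in range(50):
        w, v = np.linalg.eigh(c)
        if w.min() >= -1e-10:
            break
        w = np.clip(w, 1e-8, None)
        c = (v * w) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        c = (c + c.T) / 2.0
        np.fill_diagonal(c, 1.0)
    repair = float(np.abs(c - target).max())
    if repair > cfg.max_psd_repair:
        raise ValueError(
            f"PSD repair moved correlations by {repair:.3g} > {cfg.max_psd_repair}; "
            "requested epi_effect/decay configuration is infeasible"
        )
    return c, repair


def amplitude_profile(
    c: np.ndarray, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-channel amplitude: lognormal gain x (local coherence)^(-gamma/2).

    Local coherence of a channel is its mean correlation with all other
    channels under the target matrix ``c``; the negative exponent encodes
    the amplitude/synchrony anti-correlation described in
    :class:`SynthConfig`.
    """
    n = c.shape[0]
    local = (c.sum(axis=1) - 1.0) / (n - 1)
    local = np.clip(local, 1e-3, None)
    coh_factor = (local / local.mean()) ** (-cfg.amp_coherence_exp / 2.0)
    return coh_factor * np.exp(rng.normal(0.0, cfg.gain_sd, n))


def sample_recording(
    c: np.ndarray,
    cfg: SynthConfig,
    rng: np.random.Generator,
    patient_id: str,
    channel_ids: list[str],
    duration_s: float | None = None,
    amplitudes: np.ndarray | None = None,
) -> Recording:
    """Stationary Gaussian channels with population correlation ``c``.

    Channel amplitudes are scaled by ``amplitudes`` (heterogeneous in real
    recordings; pass ``None`` for unit-variance channels), and an optional
    common-mode 50 Hz line component of amplitude ``cfg.line_noise_amp`` is
    added, which the rereferencing/notch stages of the pipeline remove.
    """
    duration_s = cfg.duration_s if duration_s is None else duration_s
    n_samples = int(round(duration_s * cfg.fs))
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    w, v = np.linalg.eigh(np.asarray(c, dtype=float))
    if w.min() < -1e-8:
        raise ValueError("correlation matrix is not positive semidefinite")
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    data = factor @ rng.standard_normal((len(channel_ids), n_samples))
    if amplitudes is not None:
        data *= np.asarray(amplitudes, dtype=float)[:, None]
    if cfg.line_noise_amp > 0:
        t = np.arange(n_samples) / cfg.fs
        phase = rng.uniform(0, 2 * np.pi)
        data = data + cfg.line_noise_amp * np.sin(2 * np.pi * 50.0 * t + phase)
    return Recording(
        patient_id=patient_id, channel_ids=channel_ids, fs=cfg.fs, data=data
    )


def _nearest_cluster(
    coords: np.ndarray, center_idx: int, size: int, eligible: np.ndarray
) -> np.ndarray:
    """Indices of the ``size`` eligible contacts nearest the center contact."""
    d = np.linalg.norm(coords - coords[center_idx], axis=1)
    d[~eligible] = np.inf
    order = np.lexsort((np.arange(len(d)), d))  # stable tie-break by index
    chosen = order[:size]
    if np.isinf(d[chosen]).any():
        raise ValueError("not enough eligible contacts for the requested cluster")
    return np.sort(chosen)


def make_patient(
    cfg: SynthConfig,
    outcome: str,
    rng: np.random.Generator,
    patient_id: str = "synthetic",
    duration_s: float | None = None,
) -> SynthPatient:
    """Generate one patient with a planted epileptogenic cluster.

    ``outcome='good'`` places the cluster fully inside the resection
    (overlap 1, ILAE class 1); ``'poor'`` places it among spared contacts
    (overlap ``cfg.poor_overlap``, class 3).  Both the resection and the
    cluster are spatially contiguous, with locations randomized per patient —
    that variation is precisely what makes the raw (distance-confounded)
    node strengths inconsistent across patients.
    """
    if outcome not in ("good", "poor"):
        raise ValueError("outcome must be 'good' or 'poor'")

    # per-patient implantation geometry (the cross-patient sampling confound)
    patient_cfg = cfg
    if cfg.grid_rows_range is not None:
        rows = int(rng.integers(cfg.grid_rows_range[0], cfg.grid_rows_range[1] + 1))
        cols = int(rng.integers(cfg.grid_cols_range[0], cfg.grid_cols_range[1] + 1))
        pitch = float(rng.uniform(*cfg.pitch_range_mm))
        patient_cfg = replace(patient_cfg, grid_shape=(rows, cols), pitch_mm=pitch)
    n = patient_cfg.n_contacts
    n_resected = cfg.n_resected
    if cfg.n_resected_range is not None:
        hi = min(cfg.n_resected_range[1], n - cfg.epi_set_size)
        lo = min(cfg.n_resected_range[0], hi)
        n_resected = int(rng.integers(lo, hi + 1))
    if n_resected > n or cfg.epi_set_size > n:
        raise ValueError("cluster sizes exceed contact count")
    if outcome == "good" and cfg.epi_set_size > n_resected:
        raise ValueError("a good outcome needs epi_set_size <= n_resected")

    coords = make_layout(patient_cfg)
    everywhere = np.ones(n, dtype=bool)
    res_center = int(rng.integers(n))
    resected_idx = _nearest_cluster(coords, res_center, n_resected, everywhere)
    removed = np.zeros(n, dtype=bool)
    removed[resected_idx] = True

    if outcome == "good":
        epi_idx = _nearest_cluster(coords, res_center, cfg.epi_set_size, removed)
        overlap = 1.0
    else:
        spared = ~removed
        spared_idx = np.where(spared)[0]
        epi_center = int(spared_idx[rng.integers(len(spared_idx))])
        epi_idx = _nearest_cluster(coords, epi_center, cfg.epi_set_size, spared)
        overlap = float(np.isin(epi_idx, resected_idx).mean())

    epi_mask = np.zeros(n, dtype=bool)
    epi_mask[epi_idx] = True

    contact_ids = [f"E{i:03d}" for i in range(n)]
    contacts = ContactTable(
        contact_ids=contact_ids,
        coords=coords,
        removed=removed,
        artifact=np.zeros(n, dtype=bool),
    )
    from .spatial import pairwise_distances

    dist = pairwise_distances(contacts)
    c, repair = make_target_correlation(dist.values, epi_mask, patient_cfg)
    logger.debug("PSD repair moved correlations by %.3g", repair)
    amps = amplitude_profile(c, cfg, rng)
    rec = sample_recording(c, cfg, rng, patient_id, contact_ids, duration_s, amps)

    ilae = 1 if overlap >= cfg.resection_overlap_threshold else 3
    if cfg.label_noise > 0 and rng.uniform() < cfg.label_noise:
        ilae = 3 if ilae == 1 else 1
    return SynthPatient(
        recording=rec,
        contacts=contacts,
        epi_contact_ids=[contact_ids[i] for i in epi_idx],
        ilae_class=ilae,
        resection_overlap=overlap,
        target_correlation=c,
        amplitudes=amps,
    )


def make_cohort(
    n_good: int,
    n_poor: int,
    cfg: SynthConfig,
    seed: int,
    out_dir: str | Path | None = None,
    duration_s: float | None = None,
    segments_per_patient: int = 1,
) -> tuple[list[SynthPatient], CohortManifest | None]:
    """Generate a cohort; optionally write EDF + CSV + manifest to disk.

    Per-patient randomness is spawned from the master seed, so the cohort is
    reproducible patient-by-patient.  With ``segments_per_patient > 1`` the
    extra independent segments of each patient are appended to the manifest
    (on-disk mode) and returned as additional recordings on the patient
    object via ``SynthPatient.recording`` siblings in ``extra_segments``.
    """
    if n_good < 1 or n_poor < 1:
        raise ValueError("need at least one patient per outcome group")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_good + n_poor)
    patients: list[SynthPatient] = []
    outcomes = ["good"] * n_good + ["poor"] * n_poor
    for k, (outcome, child) in enumerate(zip(outcomes, children)):
        rng = np.random.default_rng(child)
        pid = f"P{k:03d}"
        patient = make_patient(cfg, outcome, rng, pid, duration_s)
        patient.extra_segments = [
            sample_recording(
                patient.target_correlation,
                cfg,
                rng,
                pid,
                list(patient.recording.channel_ids),
                duration_s,
                patient.amplitudes,
            )
            for _ in range(segments_per_patient - 1)
        ]
        patients.append(patient)

    manifest = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        truth = {}
        for p in patients:
            pid = p.recording.patient_id
            recs = [p.recording] + list(getattr(p, "extra_segments", []))
            seg_refs = []
            for si, rec in enumerate(recs):
                edf = out_dir / f"{pid}_seg{si}.edf"
                write_recording_edf(rec, edf)
                seg_refs.append(SegmentRef(path=edf.name))
            csv = out_dir / f"{pid}_contacts.csv"
            write_contact_table(p.contacts, csv)
            entries.append(
                PatientEntry(
                    patient_id=pid,
                    ilae_class=p.ilae_class,
                    contact_table=csv.name,
                    recordings=seg_refs,
                )
            )
            truth[pid] = {
                "epi_contact_ids": p.epi_contact_ids,
                "resection_overlap": p.resection_overlap,
                "ilae_class": p.ilae_class,
            }
        manifest = CohortManifest(patients=entries)
        manifest.save(out_dir / "manifest.json")
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return patients, manifest
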