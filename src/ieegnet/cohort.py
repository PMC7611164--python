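"""Cohort-level pipelines: per-patient D_RS, outcome AUC, coverage and time scans.

The per-patient pipeline is: align contacts/channels -> rereference and
filter -> windowed-correlation network -> pairwise distances -> residual
normalization against the cohort baseline -> node strength -> D_RS.  The
baseline is fitted once per analyzed segment on spared-spared pairs of
good-outcome patients and applied to everyone (including those patients; a
leave-one-patient-out variant is available for circularity checks).
Patients failing any stage are excluded with a machine-readable reason,
never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    CohortManifest,
    ContactTable,
    Recording,
    align_contacts,
    read_contact_table,
    read_recording,
)
from .network import ConnectivityMatrix, SegmentSpec, extract_segment, temporal_average_network
from .preprocess import FilterSpec, preprocess_pipeline
from .spatial import (
    BaselineFit,
    DistanceMatrix,
    collect_baseline_pairs,
    fit_baseline,
    normalize_matrix,
    pairwise_distances,
)
from .stats import (
    DrsResult,
    GroupAUCResult,
    NodeStrengthVector,
    auc_ci_logit,
    drs,
    mannwhitney_auc,
    node_strength,
    ranksum_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CohortPatient",
    "PatientNetwork",
    "CohortResult",
    "load_cohort",
    "from_synthetic",
    "build_networks",
    "run_cohort",
    "patient_pipeline",
    "group_auc",
    "coverage_scan",
    "segment_length_analysis",
    "multi_segment_analysis",
    "cross_validated_auc",
]

#: segment lengths (s) used in the timescale analysis
DEFAULT_SEGMENT_LENGTHS = (4.0, 10.0, 20.0, 40.0, 60.0, 180.0, 360.0, 600.0)


@dataclass
class CohortPatient:
    """One patient's inputs to the cohort pipeline."""

    patient_id: str
    recording: Recording
    contacts: ContactTable
    ilae_class: int

    @property
    def good_outcome(self) -> bool:
        return self.ilae_class == 1


@dataclass
class PatientNetwork:
    """Intermediate per-patient products (unnormalized)."""

    patient_id: str
    ilae_class: int
    conn: ConnectivityMatrix
    dist: DistanceMatrix
    table: ContactTable


@dataclass
class CohortResult:
    """Per-patient D_RS table plus the baseline used to normalize."""

    table: pd.DataFrame
    baseline: BaselineFit
    node_strengths: dict
    node_strengths_unnormalized: dict
    exclusions: list

    def drs_values(self, normalized: bool = True) -> tuple[np.ndarray, np.ndarray]:
        col = "drs" if normalized else "drs_unnormalized"
        return self.table[col].to_numpy(), self.table["ilae_class"].to_numpy()

    def write_csv(self, path: str | Path) -> None:
        cols = ["patient_id", "ilae_class", "n_removed", "n_spared", "drs", "drs_unnormalized"]
        self.table[cols].to_csv(path, index=False, float_format="%.17g")


def load_cohort(
    manifest: CohortManifest | str | Path,
    base_dir: str | Path | None = None,
    segment_index: int = 0,
) -> list[CohortPatient]:
    """Materialize manifest entries into memory (one chosen segment each)."""
    if not isinstance(manifest, CohortManifest):
        path = Path(manifest)
        if base_dir is None:
            base_dir = path.parent
        manifest = CohortManifest.load(path)
    base = Path(base_dir) if base_dir is not None else Path(".")
    out = []
    for entry in manifest.patients:
        seg = entry.recordings[segment_index]
        rec = read_recording(base / seg.path, patient_id=entry.patient_id)
        if seg.offset_s or seg.length_s is not None:
            length = seg.length_s if seg.length_s is not None else rec.duration_s - seg.offset_s
            rec = extract_segment(rec, SegmentSpec(seg.offset_s, length))
        tab = read_contact_table(base / entry.contact_table)
        out.append(CohortPatient(entry.patient_id, rec, tab, entry.ilae_class))
    return out


def from_synthetic(patients: Sequence, segment: int = 0) -> list[CohortPatient]:
    """Adapt :class:`ieegnet.simulate.SynthPatient` objects to the pipeline."""
    out = []
    for p in patients:
        rec = p.recording
        if segment > 0:
            rec = getattr(p, "extra_segments")[segment - 1]
        out.append(CohortPatient(rec.patient_id, rec, p.contacts, p.ilae_class))
    return out


def subsample_contacts(
    patient: CohortPatient,
    n_removed: int,
    n_spared: int,
    rng: np.random.Generator,
) -> CohortPatient:
    """Randomly restrict a patient to a fixed removed/spared contact budget.

    Used to study the effect of spatial coverage: the recording and contact
    table are both cut to ``n_removed`` + ``n_spared`` randomly chosen
    contacts (without replacement), emulating a sparser implantation.
    """
    tab = patient.contacts
    removed_ids = [c for c, r in zip(tab.contact_ids, tab.removed) if r]
    spared_ids = [c for c, r in zip(tab.contact_ids, tab.removed) if not r]
    if n_removed > len(removed_ids) or n_spared > len(spared_ids):
        raise ValueError("patient has too few contacts for the requested coverage")
    keep = sorted(
        list(rng.choice(removed_ids, size=n_removed, replace=False))
        + list(rng.choice(spared_ids, size=n_spared, replace=False))
    )
    keep = [c for c in patient.recording.channel_ids if c in set(keep)]
    return CohortPatient(
        patient_id=patient.patient_id,
        recording=patient.recording.select_channels(keep),
        contacts=tab.subset(keep),
        ilae_class=patient.ilae_class,
    )


def build_networks(
    patients: Sequence[CohortPatient],
    filter_spec: FilterSpec | None = None,
    window_len_s: float = 2.0,
    segment: SegmentSpec | None = None,
    preprocess: bool = True,
    car: bool = True,
) -> tuple[list[PatientNetwork], list]:
    """Per-patient unnormalized networks; failures become logged exclusions."""
    spec = filter_spec or FilterSpec()
    nets: list[PatientNetwork] = []
    exclusions: list[tuple[str, str]] = []
    for p in patients:
        try:
            rec, tab = align_contacts(p.recording, p.contacts)
            if preprocess:
                rec = preprocess_pipeline(rec, spec, car=car)
            if segment is not None:
                rec = extract_segment(rec, segment)
            conn = temporal_average_network(rec, window_len_s)
            dist = pairwise_distances(tab)
        except Exception as exc:
            logger.warning("excluding patient %s: %s", p.patient_id, exc)
            exclusions.append((p.patient_id, str(exc)))
            continue
        nets.append(PatientNetwork(p.patient_id, p.ilae_class, conn, dist, tab))
    return nets, exclusions


def _drs_of(conn: ConnectivityMatrix, tab: ContactTable, pid: str) -> tuple[DrsResult, NodeStrengthVector]:
    ns = node_strength(conn, removed=tab.removed)
    return drs(ns, patient_id=pid), ns


def run_cohort(
    patients: Sequence[CohortPatient] | None = None,
    networks: Sequence[PatientNetwork] | None = None,
    filter_spec: FilterSpec | None = None,
    window_len_s: float = 2.0,
    segment: SegmentSpec | None = None,
    baseline: BaselineFit | None = None,
    baseline_exclude_self: bool = False,
    preprocess: bool = True,
    car: bool = True,
) -> CohortResult:
    """Full cohort pipeline; returns normalized and raw D_RS per patient.

    Pass either raw ``patients`` or precomputed ``networks``.  ``baseline``
    may be a previously fitted curve; by default it is fitted on this
    cohort's good-outcome spared pairs.  ``baseline_exclude_self`` refits
    the baseline per good-outcome patient without that patient's own pairs.
    """
    if networks is None:
        if patients is None:
            raise ValueError("provide patients or networks")
        networks, exclusions = build_networks(
            patients, filter_spec, window_len_s, segment, preprocess, car
        )
    else:
        exclusions = []
    usable: list[PatientNetwork] = []
    for net in networks:
        if net.table.n_removed < 1:
            exclusions.append((net.patient_id, "no removed contacts"))
        elif net.table.n_spared < 1:
            exclusions.append((net.patient_id, "no spared contacts"))
        else:
            usable.append(net)
    if not usable:
        raise ValueError("no usable patients in cohort")

    pool = [(n.conn, n.dist, n.table, n.ilae_class) for n in usable]
    if baseline is None:
        d, r = collect_baseline_pairs(pool)
        fit = fit_baseline(d, r)
    else:
        fit = baseline

    rows = []
    strengths: dict = {}
    strengths_raw: dict = {}
    for net in usable:
        if baseline is None and baseline_exclude_self and net.ilae_class == 1:
            d_i, r_i = collect_baseline_pairs(
                [t for t in pool if t[0].patient_id != net.patient_id]
            )
            fit_i = fit_baseline(d_i, r_i)
        else:
            fit_i = fit
        raw_res, raw_ns = _drs_of(net.conn, net.table, net.patient_id)
        norm_conn = normalize_matrix(net.conn, net.dist, fit_i)
        norm_res, norm_ns = _drs_of(norm_conn, net.table, net.patient_id)
        strengths[net.patient_id] = norm_ns
        strengths_raw[net.patient_id] = raw_ns
        rows.append(
            {
                "patient_id": net.patient_id,
                "ilae_class": net.ilae_class,
                "n_removed": norm_res.n_removed,
                "n_spared": norm_res.n_spared,
                "drs": norm_res.drs,
                "drs_unnormalized": raw_res.drs,
            }
        )
    table = pd.DataFrame(rows)
    return CohortResult(
        table=table,
        baseline=fit,
        node_strengths=strengths,
        node_strengths_unnormalized=strengths_raw,
        exclusions=exclusions,
    )


def patient_pipeline(
    patient: CohortPatient,
    fit: BaselineFit,
    filter_spec: FilterSpec | None = None,
    window_len_s: float = 2.0,
) -> DrsResult:
    """Single-patient composition against a precomputed baseline."""
    nets, exclusions = build_networks([patient], filter_spec, window_len_s)
    if exclusions:
        raise ValueError(f"patient excluded: {exclusions[0][1]}")
    net = nets[0]
    if net.table.n_removed < 1:
        raise ValueError("patient excluded: no removed contacts")
    if net.table.n_spared < 1:
        raise ValueError("patient excluded: no spared contacts")
    norm = normalize_matrix(net.conn, net.dist, fit)
    res, _ = _drs_of(norm, net.table, net.patient_id)
    return res


def group_auc(
    drs_values: Sequence[float], ilae_classes: Sequence[int], alpha: float = 0.05
) -> GroupAUCResult:
    """Discrimination of poor (ILAE >= 2) from good (class 1) outcome by D_RS.

    Orientation: AUC = P(D_RS of a poor-outcome patient > D_RS of a
    good-outcome patient); the complementary convention is ``1 - auc``.
    """
    drs_values = np.asarray(drs_values, dtype=float)
    ilae = np.asarray(ilae_classes, dtype=int)
    good = ilae == 1
    n_good, n_poor = int(good.sum()), int((~good).sum())
    if n_good < 1 or n_poor < 1:
        raise ValueError("both outcome groups must be nonempty")
    auc = mannwhitney_auc(drs_values[~good], drs_values[good])
    lo, hi = auc_ci_logit(auc, n_poor, n_good, alpha)
    p = ranksum_test(drs_values[~good], drs_values[good])
    return GroupAUCResult(
        auc=float(auc), ci_low=lo, ci_high=hi, p_value=p, n_good=n_good, n_poor=n_poor
    )


def coverage_scan(
    result: CohortResult | pd.DataFrame, nx_min: int = 1, nx_max: int = 40
) -> pd.DataFrame:
    """Group AUC as a function of minimum per-compartment contact coverage.

    For each n_x, only patients with at least n_x removed AND n_x spared
    contacts are retained.  Rows where one outcome group empties carry NaN
    AUC and ``defined=False`` (they are still written, mirroring truncated
    confidence bands at high n_x).
    """
    table = result.table if isinstance(result, CohortResult) else result
    rows = []
    for nx in range(nx_min, nx_max + 1):
        kept = table[(table["n_removed"] >= nx) & (table["n_spared"] >= nx)]
        n_kept = len(kept)
        n_good = int((kept["ilae_class"] == 1).sum())
        row = {
            "n_x": nx,
            "n_patients_retained": n_kept,
            "pct_good_outcome": 100.0 * n_good / n_kept if n_kept else np.nan,
            "auc": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p_value": np.nan,
            "defined": False,
        }
        if n_good >= 1 and n_kept - n_good >= 1:
            res = group_auc(kept["drs"], kept["ilae_class"])
            row.update(
                auc=res.auc, ci_low=res.ci_low, ci_high=res.ci_high,
                p_value=res.p_value, defined=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def segment_length_analysis(
    patients: Sequence[CohortPatient],
    lengths: Sequence[float] = DEFAULT_SEGMENT_LENGTHS,
    filter_spec: FilterSpec | None = None,
    window_len_s: float = 2.0,
    max_segments_per_length: int = 20,
    nx_values: Sequence[int] = (1,),
    car: bool = True,
) -> pd.DataFrame:
    """Re-run the full analysis on nonoverlapping sub-segments of each length.

    The conditioning chain runs once on the full recordings (it is linear and
    time invariant); everything from windowing and the baseline refit onward
    is done per segment, blind to the other segments.  Returns one row per
    (length, segment index, n_x).
    """
    prepped = [
        CohortPatient(p.patient_id, rec, tab, p.ilae_class)
        for p in patients
        for rec, tab in [align_contacts(p.recording, p.contacts)]
    ]
    spec = filter_spec or FilterSpec()
    prepped = [
        CohortPatient(p.patient_id, preprocess_pipeline(p.recording, spec, car=car), p.contacts, p.ilae_class)
        for p in prepped
    ]
    min_duration = min(p.recording.duration_s for p in prepped)
    rows = []
    for length in lengths:
        n_seg = int(min_duration // length)
        if n_seg < 1:
            raise ValueError(f"recordings too short for {length} s segments")
        n_seg = min(n_seg, max_segments_per_length)
        for k in range(n_seg):
            seg = SegmentSpec(offset_s=k * length, length_s=length)
            res = run_cohort(
                prepped, window_len_s=window_len_s, segment=seg, preprocess=False
            )
            for nx in nx_values:
                tab = res.table
                kept = tab[(tab["n_removed"] >= nx) & (tab["n_spared"] >= nx)]
                if (kept["ilae_class"] == 1).sum() < 1 or (kept["ilae_class"] != 1).sum() < 1:
                    continue
                g = group_auc(kept["drs"], kept["ilae_class"])
                rows.append(
                    {
                        "length_s": length,
                        "segment_index": k,
                        "n_x": nx,
                        "auc": g.auc,
                        "ci_low": g.ci_low,
                        "ci_high": g.ci_high,
                        "p_value": g.p_value,
                        "n_good": g.n_good,
                        "n_poor": g.n_poor,
                    }
                )
    return pd.DataFrame(rows)


def multi_segment_analysis(
    segment_cohorts: Sequence[Sequence[CohortPatient]],
    filter_spec: FilterSpec | None = None,
    window_len_s: float = 2.0,
    car: bool = True,
) -> tuple[list[CohortResult], pd.DataFrame, float]:
    """Independent analyses of separate (e.g. hour-long) segments.

    Each element of ``segment_cohorts`` is one segment's cohort; patients
    are matched across segments by id, and missing segments are tolerated.
    Returns per-segment results, a per-segment AUC table, and the
    between-segment node-strength similarity: per patient, the Pearson
    correlation of normalized node-strength vectors between each segment
    pair, averaged over pairs and then patients.
    """
    if len(segment_cohorts) < 2:
        raise ValueError("need >= 2 segments")
    results = [
        run_cohort(list(cohort), filter_spec=filter_spec, window_len_s=window_len_s, car=car)
        for cohort in segment_cohorts
    ]
    auc_rows = []
    for si, res in enumerate(results):
        vals, ilae = res.drs_values()
        g = group_auc(vals, ilae)
        auc_rows.append(
            {
                "segment_index": si,
                "auc": g.auc,
                "ci_low": g.ci_low,
                "ci_high": g.ci_high,
                "p_value": g.p_value,
                "n_good": g.n_good,
                "n_poor": g.n_poor,
            }
        )

    per_patient: list[float] = []
    all_ids = sorted({pid for res in results for pid in res.node_strengths})
    for pid in all_ids:
        vectors = []
        for res in results:
            if pid in res.node_strengths:
                ns = res.node_strengths[pid]
                vectors.append(dict(zip(ns.contact_ids, ns.strengths)))
        if len(vectors) < 2:
            continue
        pair_corrs = []
        for i in range(len(vectors)):
            for j in range(i + 1, len(vectors)):
                common = [c for c in vectors[i] if c in vectors[j]]
                if len(common) < 3:
                    continue
                a = np.array([vectors[i][c] for c in common])
                b = np.array([vectors[j][c] for c in common])
                if a.std() == 0 or b.std() == 0:
                    continue
                pair_corrs.append(float(np.corrcoef(a, b)[0, 1]))
        if pair_corrs:
            per_patient.append(float(np.mean(pair_corrs)))
    similarity = float(np.mean(per_patient)) if per_patient else float("nan")
    return results, pd.DataFrame(auc_rows), similarity


def _youden_threshold(values: np.ndarray, is_poor: np.ndarray) -> float:
    """Threshold on D_RS maximizing TPR - FPR (poor = positive, score >= t)."""
    v = np.sort(np.unique(values))
    candidates = np.concatenate(
        [[v[0] - 1.0], (v[:-1] + v[1:]) / 2.0 if len(v) > 1 else [], [v[-1] + 1.0]]
    )
    n_pos = max(int(is_poor.sum()), 1)
    n_neg = max(int((~is_poor).sum()), 1)
    js = np.array(
        [
            (values[is_poor] >= t).sum() / n_pos - (values[~is_poor] >= t).sum() / n_neg
            for t in candidates
        ]
    )
    best = js == js.max()
    return float(candidates[best].mean())  # ties -> midpoint of tied thresholds


def cross_validated_auc(
    drs_values: Sequence[float], ilae_classes: Sequence[int], seed: int = 0
) -> float:
    """Leave-one-patient-out AUC with a Youden-J threshold per fold.

    For each held-out patient a threshold is chosen on the remaining
    patients; the held-out patient's score is its thresholded prediction
    (1 = poor).  The AUC of those held-out scores against the true outcome
    dichotomy is returned.  Deterministic given the input order; ``seed`` is
    accepted for interface stability (the construction uses no randomness).
    """
    values = np.asarray(drs_values, dtype=float)
    ilae = np.asarray(ilae_classes, dtype=int)
    is_poor = ilae >= 2
    if is_poor.sum() < 2 or (~is_poor).sum() < 2:
        raise ValueError("need >= 2 patients per outcome group")
    scores = np.empty(len(values))
    for i in range(len(values)):
        mask = np.ones(len(values), dtype=bool)
        mask[i] = False
        t = _youden_threshold(values[mask], is_poor[mask])
        scores[i] = 1.0 if values[i] >= t else 0.0
    return float(mannwhitney_auc(scores[is_poor], scores[~is_poor]))
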