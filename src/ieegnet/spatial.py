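"""Distance baseline and spatial normalization of connectivity matrices.

Nearby electrode contacts correlate strongly for purely volume-conduction /
proximity reasons, which biases any cross-patient comparison of functional
networks.  The remedy: fit the decay of correlation with Euclidean distance
on contact pairs known to be non-epileptogenic (spared contacts of
seizure-free patients), then replace every correlation by its residual to
that baseline.  Residuals quantify coupling beyond what spatial proximity
predicts.

The baseline is the degree-1/degree-1 rational function ("rat11")

    f(d) = (p1 * d + p2) / (d + q1),

fitted by unweighted nonlinear least squares with a deterministic multi-start
over q1 and a linear initialization of p1, p2 given q1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, RegressorMixin

from .io import ContactTable
from .network import ConnectivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "BaselineFit",
    "pairwise_distances",
    "collect_baseline_pairs",
    "fit_baseline",
    "evaluate_baseline",
    "normalize_matrix",
    "DistanceBaseline",
]

#: deterministic multi-start grid for the pole parameter q1 (mm)
Q1_STARTS = (5.0, 10.0, 20.0, 50.0, 100.0)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise Euclidean contact distances (mm)."""

    contact_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.contact_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square and match contact_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if (self.values < 0).any() or np.abs(np.diag(self.values)).max() > 1e-12:
            raise ValueError("distances must be nonnegative with zero diagonal")


@dataclass(frozen=True)
class BaselineFit:
    """Fitted rat11 correlation-vs-distance baseline."""

    p1: float
    p2: float
    q1: float
    n_pairs_fit: int
    fit_rmse: float
    distance_range_fit: tuple[float, float]

    def __call__(self, d) -> np.ndarray:
        return evaluate_baseline(self, d)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["distance_range_fit"] = list(self.distance_range_fit)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BaselineFit":
        with open(path) as fh:
            payload = json.load(fh)
        payload["distance_range_fit"] = tuple(payload["distance_range_fit"])
        return cls(**payload)


def pairwise_distances(tab: ContactTable) -> DistanceMatrix:
    """Euclidean inter-contact distances in mm."""
    if len(tab) < 2:
        raise ValueError("need >= 2 contacts for pairwise distances")
    dmat = squareform(pdist(tab.coords))
    off = dmat[~np.eye(len(tab), dtype=bool)]
    if off.size and off.min() == 0.0:
        logger.warning("coincident contacts found (zero pairwise distance)")
    return DistanceMatrix(contact_ids=list(tab.contact_ids), values=dmat)


def collect_baseline_pairs(
    cohort: Iterable[tuple[ConnectivityMatrix, DistanceMatrix, ContactTable, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Pool (distance, correlation) pairs from non-epileptogenic tissue.

    Only spared-spared contact pairs of good-outcome (ILAE class 1) patients
    enter the pool; any pair touching a removed contact is excluded.  Returns
    ``(distances_mm, correlations)`` over the pooled upper triangles.
    """
    ds: list[np.ndarray] = []
    rs: list[np.ndarray] = []
    n_good = 0
    for conn, dist, tab, ilae_class in cohort:
        if ilae_class != 1:
            continue
        if conn.contact_ids != dist.contact_ids or conn.contact_ids != tab.contact_ids:
            raise ValueError("connectivity/distance/table contact orderings differ")
        n_good += 1
        spared = ~tab.removed
        if spared.sum() < 2:
            continue
        sub = np.ix_(spared, spared)
        iu = np.triu_indices(int(spared.sum()), k=1)
        ds.append(dist.values[sub][iu])
        rs.append(conn.values[sub][iu])
    if n_good == 0:
        raise ValueError("baseline requires at least one good-outcome patient")
    if not ds or sum(len(d) for d in ds) == 0:
        raise ValueError("no spared-spared pairs available for the baseline")
    return np.concatenate(ds), np.concatenate(rs)


def _rat11(params: np.ndarray, d: np.ndarray) -> np.ndarray:
    p1, p2, q1 = params
    return (p1 * d + p2) / (d + q1)


def _linear_init(d: np.ndarray, r: np.ndarray, q1: float) -> np.ndarray:
    # given q1, the model is linear in (p1, p2)
    design = np.column_stack([d / (d + q1), 1.0 / (d + q1)])
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    return np.array([coef[0], coef[1], q1])


def fit_baseline(
    distances_mm: Sequence[float],
    correlations: Sequence[float],
    q1_starts: Sequence[float] = Q1_STARTS,
) -> BaselineFit:
    """Least-squares rat11 fit with a deterministic multi-start over q1.

    Zero-distance pairs (coincident contacts, a data error) are excluded:
    they sit next to the pole and dominate its leverage.  Requires >= 10
    pairs over a nondegenerate distance range.  The pole is constrained
    outside the data range (q1 > 0 since distances are positive).
    """
    d = np.asarray(distances_mm, dtype=float)
    r = np.asarray(correlations, dtype=float)
    if d.shape != r.shape:
        raise ValueError("distance and correlation arrays must match")
    keep = d > 0
    if keep.sum() < len(d):
        logger.warning("excluding %d zero-distance pair(s) from baseline fit", len(d) - keep.sum())
    d, r = d[keep], r[keep]
    if len(d) < 10:
        raise ValueError(f"need >= 10 positive-distance pairs, got {len(d)}")
    if np.ptp(d) <= 0:
        raise ValueError("degenerate distance range: all pairs at one distance")

    best = None
    diagnostics = []
    for q1 in q1_starts:
        x0 = _linear_init(d, r, q1)
        try:
            res = optimize.least_squares(
                lambda p: _rat11(p, d) - r,
                x0,
                bounds=([-np.inf, -np.inf, 1e-3], [np.inf, np.inf, np.inf]),
                method="trf",
            )
        except Exception as exc:  # pragma: no cover - numerical edge
            diagnostics.append(f"start q1={q1}: {exc}")
            continue
        diagnostics.append(f"start q1={q1}: cost={res.cost:.6g} success={res.success}")
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("baseline fit failed from every start: " + "; ".join(diagnostics))

    p1, p2, q1 = best.x
    resid = _rat11(best.x, d) - r
    if q1 <= -d.min():
        raise RuntimeError(f"fitted pole q1={q1:.3g} inside the data range")
    return BaselineFit(
        p1=float(p1),
        p2=float(p2),
        q1=float(q1),
        n_pairs_fit=int(len(d)),
        fit_rmse=float(np.sqrt(np.mean(resid**2))),
        distance_range_fit=(float(d.min()), float(d.max())),
    )


def evaluate_baseline(fit: BaselineFit, d) -> np.ndarray:
    """Evaluate f(d) = (p1 d + p2)/(d + q1); extrapolation is logged."""
    d = np.asarray(d, dtype=float)
    denom = d + fit.q1
    if np.any(np.abs(denom) < 1e-12):
        raise ZeroDivisionError("baseline evaluated at its pole")
    lo, hi = fit.distance_range_fit
    positive = d[d > 0]
    if positive.size and (positive.min() < lo - 1e-9 or d.max() > hi + 1e-9):
        logger.warning(
            "evaluating baseline outside fitted range [%.3g, %.3g] mm", lo, hi
        )
    return (fit.p1 * d + fit.p2) / denom


def normalize_matrix(
    conn: ConnectivityMatrix, dist: DistanceMatrix, fit: BaselineFit
) -> ConnectivityMatrix:
    """Residual-to-baseline normalization: off-diagonals become r - f(d).

    The diagonal is set to 0 and the result carries ``normalized=True``;
    entries then measure correlation beyond what proximity predicts.
    """
    if conn.contact_ids != dist.contact_ids:
        raise ValueError("connectivity and distance contact orderings differ")
    resid = conn.values - evaluate_baseline(fit, dist.values)
    np.fill_diagonal(resid, 0.0)
    resid = (resid + resid.T) / 2.0
    return ConnectivityMatrix(
        patient_id=conn.patient_id,
        contact_ids=list(conn.contact_ids),
        values=resid,
        n_windows=conn.n_windows,
        window_len_s=conn.window_len_s,
        normalized=True,
    )


class DistanceBaseline(RegressorMixin, BaseEstimator):
    """sklearn regressor interface to the rat11 distance baseline.

    ``fit(X, y)`` takes distances (mm) as a single feature column and
    correlations as target; ``predict(X)`` evaluates the fitted curve.

    Attributes (after fit)
    ----------------------
    p1_, p2_, q1_ : float
        Parameters of f(d) = (p1 d + p2)/(d + q1).
    baseline_ : BaselineFit
        Frozen, serializable fit record.
    """

    def __init__(self, q1_starts: tuple = Q1_STARTS):
        self.q1_starts = q1_starts

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("DistanceBaseline expects a single distance feature")
            X = X[:, 0]
        self.baseline_ = fit_baseline(X, np.asarray(y, dtype=float), self.q1_starts)
        self.p1_ = self.baseline_.p1
        self.p2_ = self.baseline_.p2
        self.q1_ = self.baseline_.q1
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "baseline_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return evaluate_baseline(self.baseline_, X)
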