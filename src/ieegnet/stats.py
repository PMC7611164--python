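"""Rank statistics linking node strength to resection and outcome.

D_RS — the distinguishability of removed vs spared node strengths — is the
normalized Mann-Whitney U statistic (equivalently, the area under the ROC
curve) comparing the node strengths of spared contacts against those of
removed contacts within one patient.  D_RS = 1 means every spared contact has
higher strength than every removed contact; 0 the reverse; 0.5 no separation.
Being purely rank based, it is invariant to any strictly increasing
transform of the strengths (so mean- vs sum-based node strength give the
same value) and robust to outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .network import ConnectivityMatrix

__all__ = [
    "NodeStrengthVector",
    "DrsResult",
    "GroupAUCResult",
    "node_strength",
    "mannwhitney_auc",
    "drs",
    "auc_ci_logit",
    "ranksum_test",
]


@dataclass
class NodeStrengthVector:
    contact_ids: list[str]
    strengths: np.ndarray
    removed: np.ndarray

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float).reshape(-1)
        self.removed = np.asarray(self.removed, dtype=bool).reshape(-1)
        n = len(self.contact_ids)
        if self.strengths.shape != (n,) or self.removed.shape != (n,):
            raise ValueError("strengths/removed must match contact_ids")
        if not np.all(np.isfinite(self.strengths)):
            raise ValueError("node strengths must be finite")


@dataclass(frozen=True)
class DrsResult:
    """Per-patient removed-vs-spared distinguishability."""

    patient_id: str
    drs: float
    n_removed: int
    n_spared: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.drs <= 1.0):
            raise ValueError("drs must lie in [0, 1]")
        if self.n_removed < 1 or self.n_spared < 1:
            raise ValueError("both contact groups must be nonempty")


@dataclass(frozen=True)
class GroupAUCResult:
    """Cohort-level discrimination of poor vs good outcome by D_RS."""

    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_good: int
    n_poor: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI must bracket the AUC")


def node_strength(
    conn: ConnectivityMatrix, removed: Sequence[bool] | None = None, mode: str = "mean"
) -> NodeStrengthVector:
    """Per-contact average (or sum) of off-diagonal connectivity.

    ``mode='mean'`` divides by (n-1); ``mode='sum'`` does not.  The two are
    rank-equivalent within a patient, so D_RS is identical under either.
    """
    n = conn.n_contacts
    if n < 2:
        raise ValueError("node strength needs >= 2 contacts")
    off = conn.values.copy()
    np.fill_diagonal(off, 0.0)
    totals = off.sum(axis=1)
    strengths = totals / (n - 1) if mode == "mean" else totals
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    if removed is None:
        removed = np.zeros(n, dtype=bool)
    return NodeStrengthVector(
        contact_ids=list(conn.contact_ids),
        strengths=strengths,
        removed=np.asarray(removed, dtype=bool),
    )


def _rank2(values: np.ndarray) -> np.ndarray:
    """Midranks times two, as exact integers."""
    ranks2 = 2.0 * sps.rankdata(values, method="average")
    return np.rint(ranks2).astype(np.int64)


def mannwhitney_auc(x: Sequence[float], y: Sequence[float]) -> float:
    """P(random x > random y), ties counted half: the normalized U statistic.

    Computed from midranks as exact integers (2U and 2nm), so the single
    float division is correctly rounded: the result is bit-identical to
    direct pair counting, and ``mannwhitney_auc(x, y) + mannwhitney_auc(y,
    x) == 1`` holds exactly (2U and 2nm - 2U share the denominator).
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    ranks2 = _rank2(np.concatenate([x, y]))
    two_u = int(ranks2[:n].sum()) - n * (n + 1)  # 2U as an exact integer
    return two_u / (2.0 * n * m)


def drs(ns: NodeStrengthVector, patient_id: str = "") -> DrsResult:
    """D_RS of one patient: AUC of spared vs removed node strengths."""
    removed = ns.removed
    n_removed = int(removed.sum())
    n_spared = int((~removed).sum())
    if n_removed < 1 or n_spared < 1:
        raise ValueError(
            f"D_RS needs both groups nonempty (removed={n_removed}, spared={n_spared})"
        )
    value = mannwhitney_auc(ns.strengths[~removed], ns.strengths[removed])
    return DrsResult(
        patient_id=patient_id,
        drs=float(value),
        n_removed=n_removed,
        n_spared=n_spared,
    )


def auc_ci_logit(
    auc: float, n1: int, n2: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Hanley-McNeil standard error, delta method on the logit scale.

    The back-transformed interval always lies inside (0, 1).  A degenerate
    AUC of exactly 0 or 1 is first pulled in by half a pair-count unit,
    1/(2 n1 n2), so the logit is defined.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0.0 <= auc <= 1.0):
        raise ValueError("auc must lie in [0, 1]")
    eps = 1.0 / (2.0 * n1 * n2)
    a = min(max(auc, eps), 1.0 - eps)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a)) / (n1 * n2)
    se = np.sqrt(max(var, 0.0))
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    logit = np.log(a / (1.0 - a))
    half = z * se / (a * (1.0 - a))
    lo, hi = logit - half, logit + half
    expit = lambda t: 1.0 / (1.0 + np.exp(-t))
    # a clamped boundary AUC (exactly 0 or 1) must still be inside its interval
    return float(min(expit(lo), auc)), float(max(expit(hi), auc))


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all C(n+m, n) group assignments.

    Uses the permutation distribution of U (half-credit ties, symmetric
    about nm/2): p = P(|U - nm/2| >= |u_obs - nm/2|).
    """
    n, m = x.size, y.size
    ranks2 = _rank2(np.concatenate([x, y]))
    total = ranks2.sum()
    nm2 = n * m  # 2 * (nm/2), in 2U units below
    u2_obs = int(ranks2[:n].sum()) - n * (n + 1)
    idx = np.array(list(combinations(range(n + m), n)), dtype=np.int64)
    u2_all = ranks2[idx].sum(axis=1) - n * (n + 1)
    dev_obs = abs(u2_obs - nm2)
    return float(np.mean(np.abs(u2_all - nm2) >= dev_obs))


def _asymptotic_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Edgeworth-corrected normal approximation to the permutation p-value.

    The permutation distribution of the midrank sum under label exchange is a
    finite-population sampling distribution; its variance, skewness and
    kurtosis have closed forms in the midrank power sums, and a two-term
    Edgeworth expansion with continuity correction tracks the exact tail far
    more closely than the plain tie-corrected normal (worst-case error
    ~5e-4 instead of ~1e-2 at n1 = n2 = 8).
    """
    n, m = x.size, y.size
    big = n + m
    ranks = sps.rankdata(np.concatenate([x, y]))
    centered = ranks - ranks.mean()
    s2 = float(np.sum(centered**2))
    s3 = float(np.sum(centered**3))
    s4 = float(np.sum(centered**4))
    if s2 == 0.0:
        return 1.0  # all observations tied: no evidence either way
    # falling-factorial sampling probabilities for 1..4 distinct indices
    p1, p2, p3, p4 = (
        np.prod([(n - i) / (big - i) for i in range(r)]) for r in (1, 2, 3, 4)
    )
    mu2 = s2 * (p1 - p2)
    mu3 = s3 * (p1 - 3 * p2 + 2 * p3)
    mu4 = s4 * (p1 - 7 * p2 + 12 * p3 - 6 * p4) + s2 * s2 * 3 * (p2 - 2 * p3 + p4)
    sigma = np.sqrt(mu2)
    g1 = mu3 / sigma**3
    g2 = mu4 / (mu2 * mu2) - 3.0
    dev = abs(float(ranks[:n].sum()) - n * float(ranks.mean()))
    zc = max(dev - 0.5, 0.0) / sigma
    if zc > 5.0:
        # deep tail: the polynomial correction is unstable and negligible
        return float(min(1.0, 2.0 * sps.norm.sf(zc)))

    def edgeworth_cdf(z: float) -> float:
        he2 = z * z - 1.0
        he3 = z**3 - 3.0 * z
        he5 = z**5 - 10.0 * z**3 + 15.0 * z
        corr = g1 / 6.0 * he2 + g2 / 24.0 * he3 + g1 * g1 / 72.0 * he5
        return sps.norm.cdf(z) - sps.norm.pdf(z) * corr

    p_val = edgeworth_cdf(-zc) + (1.0 - edgeworth_cdf(zc))
    return float(min(1.0, max(p_val, 0.0)))


def ranksum_test(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> float:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney p-value.

    ``method='exact'`` enumerates all group assignments (handles ties;
    feasible for small samples), ``'asymptotic'`` uses an Edgeworth-corrected
    tie-aware normal approximation with continuity correction, and ``'auto'``
    picks exact when the combined size is <= 12.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if method == "auto":
        method = "exact" if x.size + y.size <= 12 else "asymptotic"
    if method == "exact":
        return _exact_ranksum_p(x, y)
    if method == "asymptotic":
        return _asymptotic_ranksum_p(x, y)
    raise ValueError("method must be 'auto', 'exact' or 'asymptotic'")
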