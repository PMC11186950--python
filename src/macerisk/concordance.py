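"""Discrimination of a risk score under competing risks.

Two rank-based concordance indices are provided:

* ``harrell_c`` — cause-specific Harrell C: competing events (code 2)
  are censored at their event time, then the usual concordance over
  comparable pairs is computed.
* ``wolbers_c`` — the competing-risks adaptation: competing events are
  recoded as censored at ``tau``, the longest follow-up observed in the
  cohort, so a subject dying of a competing cause remains comparable
  (as a non-event) with every earlier cause-1 event.

A pair (i, j) is comparable iff subject i had a cause-1 event and
``T_i < T_j``, or ``T_i == T_j`` with only i an event; pairs tied in
both time and event status are excluded. A concordant pair has
``score_i > score_j``; score ties credit 1/2.

Confidence intervals and the paired score comparison use the jackknife
variance of Somers' D (``D = 2C - 1``), with a seeded bootstrap
fallback when the jackknife variance degenerates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ConcordanceResult", "harrell_c", "wolbers_c", "compare_c"]


@dataclass
class ConcordanceResult:
    method: str  # harrell_cause_specific | wolbers
    c: float
    ci95: tuple
    n_comparable_pairs: int
    somers_d: float
    somers_d_se: float


def _pair_matrices(time, status, score):
    """Boolean comparability and concordance-credit matrices.

    comparable[i, j]: i is the (earlier) event of the ordered pair.
    credit[i, j]: 1 concordant, 0.5 score tie, 0 discordant.
    """
    t_i = time[:, None]
    t_j = time[None, :]
    ev_i = status[:, None].astype(bool)
    ev_j = status[None, :].astype(bool)
    comparable = ev_i & ((t_i < t_j) | ((t_i == t_j) & ~ev_j))
    s_i = score[:, None]
    s_j = score[None, :]
    credit = np.where(s_i > s_j, 1.0, np.where(s_i == s_j, 0.5, 0.0))
    return comparable, credit


def _concordance(time, status, score, method: str) -> ConcordanceResult:
    time = np.asarray(time, float)
    status = np.asarray(status, int)
    score = np.asarray(score, float)
    if not np.all(np.isfinite(score)):
        raise ValueError("scores must be finite")
    n = time.size
    if np.unique(score).size == 1:
        warnings.warn("degenerate score: all values identical; C = 0.5")
        return ConcordanceResult(method, 0.5, (0.5, 0.5), 0, 0.0, 0.0)
    comparable, credit = _pair_matrices(time, status, score)
    ncomp = comparable.sum()
    if ncomp == 0:
        warnings.warn("no comparable pairs; C = 0.5")
        return ConcordanceResult(method, 0.5, (0.5, 0.5), 0, 0.0, 0.0)
    wins = np.where(comparable, credit, 0.0)
    c = wins.sum() / ncomp
    d = 2 * c - 1
    # jackknife over subjects via per-subject pair aggregates
    d_se, d_jack = _jackknife_d(comparable, wins, ncomp, wins.sum())
    half = 1.96 * d_se / 2  # C = (D+1)/2
    ci = (float(np.clip(c - half, 0, 1)), float(np.clip(c + half, 0, 1)))
    res = ConcordanceResult(method, float(c), ci, int(ncomp), float(d), float(d_se))
    res._d_jack = d_jack  # leave-one-out D values, reused by compare_c
    return res


def _jackknife_d(comparable, wins, ncomp, nwins):
    n = comparable.shape[0]
    comp_i = comparable.sum(axis=1) + comparable.sum(axis=0)
    wins_i = wins.sum(axis=1) + wins.sum(axis=0)
    denom = ncomp - comp_i
    with np.errstate(divide="ignore", invalid="ignore"):
        c_loo = np.where(denom > 0, (nwins - wins_i) / denom, 0.5)
    d_loo = 2 * c_loo - 1
    var = (n - 1) / n * np.sum((d_loo - d_loo.mean()) ** 2)
    return float(np.sqrt(var)), d_loo


def harrell_c(time, event, score) -> ConcordanceResult:
    """Cause-specific Harrell C (competing events censored at their time)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    status = (event == 1).astype(int)
    return _concordance(time, status, score, "harrell_cause_specific")


def wolbers_c(time, event, score) -> ConcordanceResult:
    """Wolbers C: competing events recoded as censored at max follow-up."""
    time = np.asarray(time, float).copy()
    event = np.asarray(event, int)
    tau = time.max()
    time[event == 2] = tau
    status = (event == 1).astype(int)
    return _concordance(time, status, score, "wolbers")


def compare_c(
    time,
    event,
    score_a,
    score_b,
    method: str = "harrell",
    n_boot: int = 1000,
    seed: int = 0,
):
    """Paired comparison of two scores' concordance on the same subjects.

    Returns ``(delta_c, p_value)`` for ``C_a - C_b`` using the jackknife
    covariance of the two Somers' D statistics (delta method, two-sided
    normal test). Falls back to a seeded bootstrap when the jackknife
    variance of the difference is non-positive.
    """
    score_a = np.asarray(score_a, float)
    score_b = np.asarray(score_b, float)
    fn = {"harrell": harrell_c, "wolbers": wolbers_c}[method]
    ra = fn(time, event, score_a)
    rb = fn(time, event, score_b)
    delta = ra.c - rb.c
    if np.array_equal(score_a, score_b):
        return 0.0, 1.0
    da = getattr(ra, "_d_jack", None)
    db = getattr(rb, "_d_jack", None)
    if da is not None and db is not None and da.size == db.size:
        n = da.size
        diff = da - db
        var = (n - 1) / n * np.sum((diff - diff.mean()) ** 2)
        if var > 0:
            se_delta_c = np.sqrt(var) / 2  # C = (D+1)/2
            z = delta / se_delta_c
            return float(delta), float(2 * stats.norm.sf(abs(z)))
    # bootstrap fallback
    rng = np.random.default_rng(seed)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = time.size
    deltas = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = fn(time[idx], event[idx], score_a[idx]).c - fn(
                time[idx], event[idx], score_b[idx]
            ).c
        deltas.append(d)
    deltas = np.asarray(deltas)
    se = deltas.std(ddof=1)
    if se == 0:
        return float(delta), 1.0
    z = delta / se
    return float(delta), float(2 * stats.norm.sf(abs(z)))
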