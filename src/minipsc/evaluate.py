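"""Detection/classification scoring: onset matching, confusion counts, ROC
metrics, Matthews correlation, inter-rater grids and the exact paired
permutation test.

Detected and reference event lists are aligned by greedy one-to-one
nearest-neighbour matching of onset times within a tolerance (default
1.2 ms). From the accepted/rejected partition of the candidates the usual
confusion counts follow: a true positive is an accepted candidate matching a
reference event; a false positive an accepted candidate matching none; a
true negative a rejected candidate matching none (a spurious detection
correctly discarded); a false negative a reference event with no accepted
match. Inter-rater consistency is summarised by the Matthews correlation
coefficient over the union of two raters' candidate pools, and differences
between conditions are tested with an exact paired permutation test that
enumerates all 2^n sign assignments of the per-subject differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "Matching",
    "RocMetrics",
    "match_events",
    "confusion",
    "roc_metrics",
    "mcc",
    "rater_mcc_grid",
    "paired_permutation_test",
    "PermutationResult",
]

DEFAULT_TOL_S = 1.2e-3  # onset-matching tolerance


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class Matching:
    pairs: list  # (detected_time, reference_time)
    unmatched_detected: list
    unmatched_reference: list


class RocMetrics(NamedTuple):
    """FPR/TPR/accuracy/FDR; a metric whose denominator is zero is None."""

    fpr: Optional[float]
    tpr: Optional[float]
    accuracy: Optional[float]
    fdr: Optional[float]


def match_events(detected: Sequence[float], reference: Sequence[float],
                 tol: float = DEFAULT_TOL_S) -> Matching:
    """Greedy one-to-one nearest-neighbour matching of onset times within
    ``tol`` seconds; candidate pairs are taken closest-first, ties broken by
    the earlier reference time."""
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    det = np.asarray(detected, dtype=float)
    ref = np.asarray(reference, dtype=float)
    pairs = []
    if det.size and ref.size:
        cand = []
        for i, d in enumerate(det):
            lo = np.searchsorted(ref, d - tol)
            hi = np.searchsorted(ref, d + tol, side="right")
            for j in range(lo, hi):
                cand.append((abs(d - ref[j]), ref[j], d, i, j))
        cand.sort()
        used_d: set = set()
        used_r: set = set()
        for _, _, _, i, j in cand:
            if i in used_d or j in used_r:
                continue
            used_d.add(i)
            used_r.add(j)
            pairs.append((float(det[i]), float(ref[j])))
    else:
        used_d, used_r = set(), set()
    pairs.sort(key=lambda p: p[1])
    return Matching(
        pairs=pairs,
        unmatched_detected=[float(det[i]) for i in range(det.size) if i not in used_d],
        unmatched_reference=[float(ref[j]) for j in range(ref.size) if j not in used_r],
    )


def confusion(candidates: Sequence[float], accepted: Sequence[float],
              reference: Sequence[float], tol: float = DEFAULT_TOL_S) -> ConfusionCounts:
    """Confusion counts for an accepted subset of candidate onsets against a
    reference event list.

    ``accepted`` must be a subset of ``candidates`` (by value). Rejected
    candidates that do fall within ``tol`` of a reference event count toward
    neither TN nor FP: the missed reference event surfaces in FN.
    """
    cand = np.asarray(candidates, dtype=float)
    acc = np.asarray(accepted, dtype=float)
    cand_round = set(np.round(cand, 12))
    if not set(np.round(acc, 12)) <= cand_round:
        raise ValueError("accepted is not a subset of candidates")
    ref = np.sort(np.asarray(reference, dtype=float))
    m = match_events(np.sort(acc), ref, tol)
    tp = len(m.pairs)
    fp = acc.size - tp
    fn = ref.size - tp
    # rejected candidates (multiset difference by value)
    acc_counts: dict = {}
    for t in np.round(acc, 12):
        acc_counts[t] = acc_counts.get(t, 0) + 1
    rejected = []
    for t, tr in zip(cand, np.round(cand, 12)):
        if acc_counts.get(tr, 0) > 0:
            acc_counts[tr] -= 1
        else:
            rejected.append(t)
    rejected = np.asarray(rejected, dtype=float)
    if rejected.size and ref.size:
        near = np.array([np.any(np.abs(ref - t) <= tol) for t in rejected])
        tn = int((~near).sum())
    else:
        tn = int(rejected.size)
    return ConfusionCounts(tp=int(tp), fp=int(fp), tn=tn, fn=int(fn))


def roc_metrics(c: ConfusionCounts) -> RocMetrics:
    """FPR = FP/(FP+TN), TPR = TP/(TP+FN), accuracy = (TP+TN)/total,
    FDR = FP/(FP+TP); None where the denominator is zero."""
    def ratio(num, den):
        return num / den if den > 0 else None
    return RocMetrics(
        fpr=ratio(c.fp, c.fp + c.tn),
        tpr=ratio(c.tp, c.tp + c.fn),
        accuracy=ratio(c.tp + c.tn, c.total),
        fdr=ratio(c.fp, c.fp + c.tp),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 by convention when a marginal is
    zero."""
    denom2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom2 == 0:
        return 0.0
    return float((c.tp * c.tn - c.fp * c.fn) / np.sqrt(float(denom2)))


def _pair_confusion(pool_a: np.ndarray, acc_a: np.ndarray,
                    pool_b: np.ndarray, acc_b: np.ndarray,
                    tol: float) -> ConfusionCounts:
    """2x2 agreement table for two raters over the union of their candidate
    pools, aligned by onset matching."""
    m = match_events(np.sort(pool_b), np.sort(pool_a), tol)
    b_to_a = {round(b, 12): round(a, 12) for b, a in m.pairs}
    set_a = set(np.round(acc_a, 12))
    set_b = set(np.round(acc_b, 12))
    tp = fp = tn = fn = 0
    # slots present in rater A's pool (possibly shared with B)
    matched_b = set(b_to_a.keys())
    a_of_b: dict = {v: k for k, v in b_to_a.items()}
    for t in np.round(pool_a, 12):
        in_a = t in set_a
        tb = a_of_b.get(round(t, 12))
        in_b = tb in set_b if tb is not None else False
        if in_a and in_b:
            tp += 1
        elif in_a and not in_b:
            fn += 1
        elif in_b:
            fp += 1
        else:
            tn += 1
    # slots only in rater B's pool
    for t in np.round(pool_b, 12):
        if round(t, 12) in matched_b:
            continue
        if t in set_b:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def rater_mcc_grid(accepted: Sequence[Sequence[float]],
                   pools: Sequence[Sequence[float]],
                   tol: float = DEFAULT_TOL_S) -> np.ndarray:
    """Symmetric matrix of pairwise MCCs between raters.

    ``accepted[i]`` is rater i's accepted onset times, a subset of that
    rater's candidate pool ``pools[i]``. The diagonal is 1.
    """
    r = len(accepted)
    if r < 2:
        raise ValueError("need at least two raters")
    if len(pools) != r:
        raise ValueError("one candidate pool per rater required")
    grid = np.eye(r)
    for i in range(r):
        for j in range(i + 1, r):
            c = _pair_confusion(np.asarray(pools[i], dtype=float),
                                np.asarray(accepted[i], dtype=float),
                                np.asarray(pools[j], dtype=float),
                                np.asarray(accepted[j], dtype=float), tol)
            grid[i, j] = grid[j, i] = mcc(c)
    return grid


class PermutationResult(NamedTuple):
    observed_diff: float
    p_value: float
    n_permutations: int


def paired_permutation_test(scores_a: Sequence[float], scores_b: Sequence[float],
                            mode: str = "exhaustive", n_mc: int = 100_000,
                            seed: Optional[int] = None) -> PermutationResult:
    """Two-tailed paired permutation test of mean(b - a).

    Exhaustive mode enumerates all 2^n sign assignments of the per-subject
    differences (n <= 25); the two-tailed p-value is the proportion of
    assignments with |statistic| >= |observed|, the observed assignment
    included. Monte-Carlo mode draws ``n_mc`` random assignments and adds the
    observed one.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("scores must be equal-length non-empty vectors")
    d = b - a
    n = d.size
    observed = float(d.mean())
    atol = 1e-12 * max(1.0, abs(observed))
    if mode == "exhaustive":
        if n > 25:
            raise ValueError("exhaustive enumeration limited to n <= 25 subjects")
        total = 1 << n
        codes = np.arange(total, dtype=np.int64)
        signs = ((codes[:, None] >> np.arange(n)) & 1) * 2 - 1  # (2^n, n) of +-1
        stats = signs @ d / n
        p = float(np.mean(np.abs(stats) >= abs(observed) - atol))
        return PermutationResult(observed, p, total)
    if mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        signs = rng.integers(0, 2, size=(n_mc, n)) * 2 - 1
        stats = signs @ d / n
        exceed = int(np.sum(np.abs(stats) >= abs(observed) - atol))
        p = (1 + exceed) / (1 + n_mc)
        return PermutationResult(observed, float(p), n_mc)
    raise ValueError(f"unknown mode {mode!r}")
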