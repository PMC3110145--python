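"""Optimal multilevel thresholding of positional intensity histograms.

A microarray row/column intensity profile is treated as an irregular
histogram on bins 1..n whose masses are normalized to probabilities.  A set
of k interior thresholds t_1 < ... < t_k partitions the bins into k+1
contiguous classes; the between-class variance criterion

    Psi_BC(T) = sum_j omega_j * mu_j**2

(omega_j: class probability mass, mu_j: mass-weighted mean bin position) is
maximized exactly by dynamic programming in O(k n^2) time.  An exhaustive
enumerator is provided as an independent oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from itertools import combinations
from math import comb

import numpy as np

from ._dp import dp_all_thresholds

__all__ = [
    "IntensityHistogram",
    "ThresholdSet",
    "class_moments",
    "between_class_score",
    "optimal_thresholds",
    "optimal_thresholds_upto",
    "brute_force_thresholds",
]


def _neumaier_cumsum(x: np.ndarray) -> np.ndarray:
    """Compensated (Neumaier) running sum; keeps prefix sums accurate enough
    that the DP and the exhaustive oracle agree bitwise on test instances."""
    out = np.empty(x.shape[0] + 1, dtype=np.float64)
    out[0] = 0.0
    s = 0.0
    c = 0.0
    for i, v in enumerate(np.asarray(x, dtype=np.float64)):
        t = s + v
        if abs(s) >= abs(v):
            c += (s - t) + v
        else:
            c += (v - t) + s
        s = t
        out[i + 1] = s + c
    return out


@dataclass(frozen=True)
class IntensityHistogram:
    """Positional histogram: bin i in 1..n carries nonnegative mass."""

    masses: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.masses, dtype=np.float64)
        if m.ndim != 1 or m.shape[0] < 2:
            raise ValueError("histogram needs at least 2 bins")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("histogram masses must be finite and nonnegative")
        if m.sum() <= 0:
            raise ValueError("histogram has zero total mass")
        object.__setattr__(self, "masses", m)

    @property
    def n(self) -> int:
        return self.masses.shape[0]

    @cached_property
    def probabilities(self) -> np.ndarray:
        return self.masses / self.masses.sum()

    @cached_property
    def _prefix(self) -> tuple[np.ndarray, np.ndarray]:
        """(P, S): compensated prefix sums of p_i and i * p_i, 1-based."""
        p = self.probabilities
        pos = np.arange(1, self.n + 1, dtype=np.float64)
        return _neumaier_cumsum(p), _neumaier_cumsum(pos * p)


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered interior thresholds with their between-class score."""

    thresholds: tuple[int, ...]
    score: float
    n: int = field(default=0)

    @property
    def k(self) -> int:
        return len(self.thresholds)

    def __post_init__(self):
        t = tuple(int(v) for v in self.thresholds)
        object.__setattr__(self, "thresholds", t)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if t and self.n and (t[0] < 1 or t[-1] > self.n - 1):
            raise ValueError("thresholds must be interior (1 <= t <= n-1)")

    def classes(self) -> list[tuple[int, int]]:
        """Closed 1-based (first, last) bin ranges of the k+1 classes."""
        bounds = (0, *self.thresholds, self.n)
        return [(a + 1, b) for a, b in zip(bounds, bounds[1:])]


def _validate_range(h: IntensityHistogram, a: int, b: int) -> None:
    if a > b:
        raise ValueError(f"empty bin range: a={a} > b={b}")
    if a < 1 or b > h.n:
        raise ValueError(f"bin range [{a}, {b}] outside 1..{h.n}")


def class_moments(h: IntensityHistogram, a: int, b: int) -> tuple[float, float]:
    """Probability mass and mean position of bins a..b (1-based, inclusive).

    O(1) after the histogram's prefix sums are built.  A zero-mass range has
    mean 0 by convention (it contributes nothing to any score).
    """
    _validate_range(h, a, b)
    P, S = h._prefix
    w = P[b] - P[a - 1]
    s = S[b] - S[a - 1]
    return float(w), float(s / w) if w > 0 else 0.0


def _psi(P: np.ndarray, S: np.ndarray, a: int, b: int) -> float:
    w = P[b] - P[a - 1]
    s = S[b] - S[a - 1]
    return (s * s / w) if w > 0.0 else 0.0


def _score(P, S, thresholds, n) -> float:
    """Right-associated Psi_BC so DP and oracle agree bitwise."""
    bounds = (0, *thresholds, n)
    acc = 0.0
    for a, b in zip(reversed(bounds[:-1]), reversed(bounds[1:])):
        acc = _psi(P, S, a + 1, b) + acc
    return acc


def between_class_score(h: IntensityHistogram, T: ThresholdSet) -> float:
    """Psi_BC(T) = sum_j omega_j mu_j^2 over the classes induced by T."""
    if T.k and (T.thresholds[0] < 1 or T.thresholds[-1] > h.n - 1):
        raise ValueError("thresholds outside interior range")
    P, S = h._prefix
    return _score(P, S, T.thresholds, h.n)


def _check_k(h: IntensityHistogram, k: int) -> None:
    if not 1 <= k <= h.n - 1:
        raise ValueError(f"k={k} outside valid range 1..{h.n - 1}")


def optimal_thresholds_upto(h: IntensityHistogram, kmax: int) -> list[ThresholdSet]:
    """Optimal threshold sets for every k = 1..kmax from a single DP run.

    The model-selection stage evaluates all candidate class counts, so
    sharing one O(kmax n^2) DP across them is what keeps the search cheap.
    """
    _check_k(h, kmax)
    P, S = h._prefix
    return [
        ThresholdSet(thresholds=t, score=s, n=h.n)
        for t, s in dp_all_thresholds(P, S, kmax)
    ]


def optimal_thresholds(h: IntensityHistogram, k: int) -> ThresholdSet:
    """Globally optimal k-threshold set under the between-class criterion.

    Deterministic: among score-equal optima, ties resolve toward the
    smaller t_1, then the larger remaining-suffix score, then the smaller
    t_2, and so on (see :func:`brute_force_thresholds`).
    """
    _check_k(h, k)
    return optimal_thresholds_upto(h, k)[k - 1]


def center_thresholds(h: IntensityHistogram, T: ThresholdSet) -> ThresholdSet:
    """Canonicalize a threshold set by centering each threshold in its
    empty valley.

    Every bin of a zero-mass run yields the same between-class score; the
    DP's deterministic tie-break returns the run's first bin, which hugs
    the preceding mass block.  The centered representative is
    score-equivalent but places the induced separating line in the middle
    of a clean gap, which is both what a human would draw and what the
    threshold-probability index A(K) should be charged with.
    """
    zero = h.masses <= 0.0
    n = h.n
    out = list(T.thresholds)
    for i, t in enumerate(out):
        left = t
        while left >= 1 and zero[left - 1]:
            left -= 1
        right = t
        while right < n and zero[right]:
            right += 1
        if right == t and left == t:
            continue
        center = (left + right) // 2
        lo = out[i - 1] + 1 if i > 0 else 1
        hi = out[i + 1] - 1 if i + 1 < len(out) else n - 1
        out[i] = min(max(center, lo), hi)
    return ThresholdSet(thresholds=tuple(out), score=T.score, n=n)


def brute_force_thresholds(
    h: IntensityHistogram, k: int, budget: int = 10**6
) -> ThresholdSet:
    """Exhaustive maximization over all C(n-1, k) threshold sets.

    Reference oracle for tests.  It enumerates every candidate, computes
    the same right-associated class-score sums as the DP, and applies the
    package's deterministic tie-break: maximize the total score; on bitwise
    ties prefer the smaller t_1, then the larger score of the remaining
    suffix (classes after t_1), then the smaller t_2, and so on.  This is
    the natural refinement order of score-equal optima (plain
    "lexicographically smallest" is not well defined once rounding can make
    distinct partitions score-equal at the top level but not in their
    sub-sums).
    """
    _check_k(h, k)
    n = h.n
    if comb(n - 1, k) > budget:
        raise ValueError(f"C({n - 1},{k}) exceeds enumeration budget {budget}")
    P, S = h._prefix
    cand = np.array(list(combinations(range(1, n), k)), dtype=np.int64)
    m = cand.shape[0]
    # class boundaries per candidate: 0, t_1..t_k, n
    bounds = np.concatenate(
        [np.zeros((m, 1), np.int64), cand, np.full((m, 1), n, np.int64)], axis=1
    )
    w = P[bounds[:, 1:]] - P[bounds[:, :-1]]
    s = S[bounds[:, 1:]] - S[bounds[:, :-1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = np.where(w > 0.0, s * s / np.where(w > 0.0, w, 1.0), 0.0)
    # right-associated suffix scores: suff[:, i] = psi_i + (psi_{i+1} + ...)
    suff = np.empty_like(psi)
    suff[:, -1] = psi[:, -1]
    for i in range(k - 1, -1, -1):
        suff[:, i] = psi[:, i] + suff[:, i + 1]
    # hierarchical selection: score, t_1, suffix score, t_2, ...
    alive = np.arange(m)
    for i in range(k + 1):
        vals = suff[alive, i]
        alive = alive[vals == vals.max()]
        if alive.size == 1 or i == k:
            break
        ts = cand[alive, i]
        alive = alive[ts == ts.min()]
        if alive.size == 1:
            break
    best = alive[0]
    return ThresholdSet(
        thresholds=tuple(int(t) for t in cand[best]),
        score=float(suff[best, 0]),
        n=n,
    )
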