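"""Cluster-validity indices for choosing the number of sub-grids/spots.

Multilevel thresholding needs the number of classes K as input; to stay
parameterless the pipeline evaluates every K = 2..delta and picks the one
maximizing the alpha index:

    I(K)     = ((1/K) * (E_1 / E_K) * D_K)^2     (Maulik-Bandyopadhyay I,
                                                  L1 dispersion, power 2)
    A(K)     = mean probability of the K-1 chosen thresholds
    alpha(K) = I(K) / (A(K) + eps),  eps = the profile's empty-bin level

E_K is the total L1 dispersion of bins around their class centers z_k
(mass-weighted), D_K the largest center separation, E_1 the one-class
dispersion.  A good partition has thresholds in near-empty valleys (small A)
and compact, well-separated classes (large I); alpha rewards both, and in
particular suppresses the I index's tendency to over-split, which the A
term detects as thresholds landing on spot mass.

The search bound is delta = ceil(sqrt(n)) for an n-bin histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mlt import (
    IntensityHistogram,
    ThresholdSet,
    center_thresholds,
    optimal_thresholds_upto,
)

__all__ = ["KRecord", "ValidityProfile", "i_index", "a_index", "alpha_index", "select_K"]

_EPS_REL = 1e-12


def _class_stats(h: IntensityHistogram, T: ThresholdSet):
    """Per positive-mass class: (center z_k, L1 dispersion around z_k)."""
    p = h.probabilities
    pos = np.arange(1, h.n + 1, dtype=np.float64)
    centers, disps = [], []
    for a, b in T.classes():
        w = p[a - 1 : b].sum()
        if w <= 0.0:
            continue  # empty stripe: contributes nothing to E_K or D_K
        z = float((pos[a - 1 : b] * p[a - 1 : b]).sum() / w)
        e = float((p[a - 1 : b] * np.abs(pos[a - 1 : b] - z)).sum())
        centers.append(z)
        disps.append(e)
    return np.array(centers), np.array(disps)


def _e1(h: IntensityHistogram) -> float:
    p = h.probabilities
    pos = np.arange(1, h.n + 1, dtype=np.float64)
    mu = float((pos * p).sum())
    return float((p * np.abs(pos - mu)).sum())


def i_index(h: IntensityHistogram, T: ThresholdSet) -> float:
    """I(K) for the K = k+1 class partition induced by T."""
    K = T.k + 1
    if K < 2:
        raise ValueError("I index needs at least 2 classes (D_K undefined for K=1)")
    centers, disps = _class_stats(h, T)
    if centers.size < 2:
        return 0.0
    e1 = _e1(h)
    ek = max(float(disps.sum()), _EPS_REL * e1) if e1 > 0 else _EPS_REL
    dk = float(centers.max() - centers.min())
    return ((1.0 / K) * (e1 / ek) * dk) ** 2


def a_index(h: IntensityHistogram, T: ThresholdSet) -> float:
    """Mean histogram probability at the thresholds; small in deep valleys."""
    if T.k < 1:
        raise ValueError("A index needs at least one threshold")
    p = h.probabilities
    return float(np.mean([p[t - 1] for t in T.thresholds]))


def alpha_index(h: IntensityHistogram, T: ThresholdSet) -> float:
    """alpha(K) = I(K) / (A(K) + eps); maximized at the true class count.

    eps is the histogram's empty-bin level (5th-percentile probability,
    floored at 1e-12 of the maximum): differences between threshold sets
    that all sit below the valley floor are noise and must not flip the
    index, while thresholds on real mass are penalized in full.
    """
    p = h.probabilities
    eps = max(float(np.percentile(p, 5.0)), _EPS_REL * float(p.max()))
    return i_index(h, T) / (a_index(h, T) + eps)


@dataclass(frozen=True)
class KRecord:
    K: int
    thresholds: ThresholdSet
    i_index: float
    a_index: float
    alpha_index: float


@dataclass(frozen=True)
class ValidityProfile:
    """alpha search over K = 2..delta with the winning class count."""

    records: tuple[KRecord, ...]
    delta: int
    best_K: int
    confident: bool

    def best_thresholds(self) -> ThresholdSet:
        return next(r.thresholds for r in self.records if r.K == self.best_K)

    def record(self, K: int) -> KRecord:
        return next(r for r in self.records if r.K == K)


def select_K(h: IntensityHistogram, delta: int | None = None) -> ValidityProfile:
    """Exhaustive alpha-index search for the best number of classes.

    Runs the thresholding DP once up to delta-1 thresholds and scores every
    resulting partition.  ``confident`` is False when the alpha curve has no
    pronounced peak (max < 2x median), i.e. no evidence of grid structure;
    callers treat that as "do not split".
    """
    if h.n < 4:
        raise ValueError("histogram too short for model selection (need n >= 4)")
    if delta is None:
        delta = math.ceil(math.sqrt(h.n))
    delta = int(min(delta, h.n))
    if delta < 2:
        raise ValueError(f"delta={delta} < 2: no candidate class counts")

    sets = optimal_thresholds_upto(h, delta - 1)
    records = []
    for T in sets:
        T = center_thresholds(h, T)  # score-equivalent, valley-centered
        K = T.k + 1
        records.append(
            KRecord(
                K=K,
                thresholds=T,
                i_index=i_index(h, T),
                a_index=a_index(h, T),
                alpha_index=alpha_index(h, T),
            )
        )
    alphas = np.array([r.alpha_index for r in records])
    best = int(np.argmax(alphas))  # first max -> smallest K on ties
    confident = bool(alphas[best] >= 2.0 * float(np.median(alphas)))
    return ValidityProfile(
        records=tuple(records),
        delta=delta,
        best_K=records[best].K,
        confident=confident,
    )
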