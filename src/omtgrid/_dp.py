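"""Dynamic-programming kernel for optimal multilevel thresholding.

The recurrence is a suffix DP over contiguous classes of a positional
histogram.  ``G[c][j]`` is the best achievable between-class score for bins
``j..n`` split into ``c`` classes; each class contributes ``s**2 / w`` where
``w`` and ``s`` are its probability mass and first moment (Otsu's
``omega * mu**2`` written on prefix sums).  Ties are broken toward the
smallest split point at every state, which with the left-to-right
reconstruction yields the hierarchical tie-break documented on
``omtgrid.mlt.brute_force_thresholds``.  Scores are
accumulated right-associated, ``psi_1 + (psi_2 + (... + psi_{c}))``, so the
exhaustive oracle in :mod:`omtgrid.mlt` can reproduce them bit-for-bit.

Worst-case work is O(kmax * n**2), memory O(kmax * n).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _dp_kernel(P, S, kmax):  # pragma: no cover - compiled
    n = P.shape[0] - 1
    ncls = kmax + 1
    choice = np.zeros((ncls + 1, n + 2), dtype=np.int32)
    scores = np.zeros(ncls + 1, dtype=np.float64)
    prev = np.zeros(n + 2, dtype=np.float64)
    cur = np.zeros(n + 2, dtype=np.float64)

    # one class: psi(j, n)
    for j in range(1, n + 1):
        w = P[n] - P[j - 1]
        s = S[n] - S[j - 1]
        prev[j] = (s * s / w) if w > 0.0 else 0.0
    scores[1] = prev[1]

    for c in range(2, ncls + 1):
        jmax = n - c + 1
        for j in range(1, jmax + 1):
            best = -1.0
            bt = -1
            for t in range(j, jmax + 1):
                w = P[t] - P[j - 1]
                s = S[t] - S[j - 1]
                psi = (s * s / w) if w > 0.0 else 0.0
                v = psi + prev[t + 1]
                if v > best:
                    best = v
                    bt = t
            cur[j] = best
            choice[c, j] = bt
        scores[c] = cur[1]
        prev, cur = cur, prev
    return scores, choice


def _dp_numpy(P, S, kmax):
    """Pure-NumPy twin of :func:`_dp_kernel` (same tie-break and op order)."""
    n = P.shape[0] - 1
    ncls = kmax + 1
    choice = np.zeros((ncls + 1, n + 2), dtype=np.int32)
    scores = np.zeros(ncls + 1, dtype=np.float64)
    prev = np.zeros(n + 2, dtype=np.float64)
    cur = np.zeros(n + 2, dtype=np.float64)

    w = P[n] - P[:n]
    s = S[n] - S[:n]
    with np.errstate(divide="ignore", invalid="ignore"):
        psi_tail = np.where(w > 0.0, s * s / np.where(w > 0.0, w, 1.0), 0.0)
    prev[1 : n + 1] = psi_tail
    scores[1] = prev[1]

    for c in range(2, ncls + 1):
        jmax = n - c + 1
        for j in range(1, jmax + 1):
            t = np.arange(j, jmax + 1)
            w = P[t] - P[j - 1]
            s = S[t] - S[j - 1]
            psi = np.where(w > 0.0, s * s / np.where(w > 0.0, w, 1.0), 0.0)
            v = psi + prev[j + 1 : jmax + 2]
            i = int(np.argmax(v))  # first max == smallest t
            cur[j] = v[i]
            choice[c, j] = j + i
        scores[c] = cur[1]
        prev, cur = cur, prev
    return scores, choice


def dp_all_thresholds(P: np.ndarray, S: np.ndarray, kmax: int):
    """Run the DP once and return, for every k in 1..kmax, the optimal
    threshold tuple and its score.

    Parameters
    ----------
    P, S:
        Prefix sums (length n+1, ``P[0] == 0``) of bin probabilities and of
        ``position * probability`` with 1-based positions.
    kmax:
        Largest number of thresholds wanted (``1 <= kmax <= n - 1``).
    """
    if _HAVE_NUMBA:
        scores, choice = _dp_kernel(P, S, int(kmax))
    else:
        scores, choice = _dp_numpy(P, S, int(kmax))
    out = []
    for k in range(1, kmax + 1):
        thresholds = []
        j = 1
        for c in range(k + 1, 1, -1):
            t = int(choice[c, j])
            thresholds.append(t)
            j = t + 1
        out.append((tuple(thresholds), float(scores[k + 1])))
    return out
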