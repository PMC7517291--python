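"""Independent brute-force oracles used to validate the implementations.

These deliberately re-derive the statistics by exhaustive enumeration,
without sharing any code with the package.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np


def sampen_bruteforce(x, m: int, r: float) -> Tuple[float, float, float]:
    """Sample Entropy by exhaustive template-pair enumeration.

    Lists every ordered template pair (j, k), j != k, over the common
    index range 1..N-m, computes Chebyshev distances at lengths m and
    m+1 and counts strict-inequality matches.  Returns (SE, A, B) with
    SE = nan when either count is zero.
    """
    x = list(map(float, x))
    n = len(x)
    nt = n - m
    assert nt >= 2, "series too short"
    b_total = 0
    a_total = 0
    for j in range(nt):
        for k in range(nt):
            if k == j:
                continue
            d_m = max(abs(x[j + i] - x[k + i]) for i in range(m))
            if d_m < r:
                b_total += 1
            d_m1 = max(abs(x[j + i] - x[k + i]) for i in range(m + 1))
            if d_m1 < r:
                a_total += 1
    denom = nt * (nt - 1)
    b = b_total / denom
    a = a_total / denom
    if a == 0 or b == 0:
        return float("nan"), a, b
    return -math.log(a / b), a, b


def auroc_pairs(pos, neg) -> float:
    """AROC by brute-force pair counting, ties counting one half."""
    pos = list(map(float, pos))
    neg = list(map(float, neg))
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def youden_scan(pos, neg):
    """Exhaustive scan of max(Se + Sp) over every real threshold.

    Evaluates Se/Sp (positive call: score >= threshold) at all candidate
    thresholds between and beyond the observed scores; returns the
    maximum of Se + Sp.
    """
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    allv = np.unique(np.concatenate([pos, neg]))
    cands = np.concatenate(
        ([-np.inf], (allv[:-1] + allv[1:]) / 2 if allv.size > 1 else [], [np.inf], allv)
    )
    best = -1.0
    for thr in cands:
        se = float(np.mean(pos >= thr))
        sp = float(np.mean(neg < thr))
        best = max(best, se + sp)
    return best
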