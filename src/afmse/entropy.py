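"""Sample Entropy with explicit template-match accounting.

Sample Entropy (SE) of a series of length N is the negative logarithm of
the conditional probability that two epochs matching within tolerance r
over m consecutive samples (Chebyshev distance, strict inequality, self
matches excluded) still match when extended to m+1 samples::

    SE(x, N, m, r) = -ln( A^m(r) / B^m(r) )

Both match probabilities are averaged over the same N-m templates; the
epoch at index j spans x[j..j+m], so extending every length-m template by
one sample is always possible.  This convention keeps the m and m+1 counts
over an identical index range, which makes A <= B hold exactly.

The O(N^2) pair scan is JIT-compiled with numba when available and falls
back to a blocked numpy implementation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "EntropyParams",
    "TemplateMatchCounts",
    "sample_entropy",
    "resolve_tolerance",
]

# diagnostics: full distance matrices are only materialized for short series
_DMAT_MAX_N = 256


@dataclass
class EntropyParams:
    """Embedding length and tolerance for Sample Entropy.

    Parameters
    ----------
    m : int
        Epoch (template) length in samples.
    r : float, optional
        Absolute tolerance, same units as the series.  Required when
        ``r_mode="absolute"``.
    r_mode : {"fraction_of_sd", "absolute"}
        How the tolerance is resolved.  The default follows the common
        practice of r = 0.2 standard deviations of the analyzed series.
    r_fraction : float
        Fraction of the series' standard deviation used when
        ``r_mode="fraction_of_sd"``.
    """

    m: int = 2
    r: Optional[float] = None
    r_mode: str = "fraction_of_sd"
    r_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_mode not in ("fraction_of_sd", "absolute"):
            raise ValueError(f"unknown r_mode {self.r_mode!r}")
        if self.r_mode == "absolute":
            if self.r is None or self.r <= 0:
                raise ValueError("absolute r_mode requires r > 0")
        elif self.r_fraction <= 0:
            raise ValueError("r_fraction must be > 0")


@dataclass
class TemplateMatchCounts:
    """Per-template match fractions underlying one SE evaluation.

    ``b_j``/``a_j`` are the per-template match fractions at lengths m and
    m+1 (each normalized by N-m-1 possible partners); ``b``/``a`` are their
    means.  ``d_metric`` holds the full Chebyshev distance matrix at length
    m for short series (None otherwise).
    """

    b_j: np.ndarray
    a_j: np.ndarray
    b: float
    a: float
    m: int
    r: float
    n: int
    d_metric: Optional[np.ndarray] = None

    @property
    def undefined(self) -> bool:
        """True when the entropy ratio A/B is undefined (zero matches)."""
        return self.b <= 0.0 or self.a <= 0.0


def resolve_tolerance(series: np.ndarray, params: EntropyParams) -> float:
    """Resolve the tolerance r for a concrete series.

    With ``fraction_of_sd`` the population standard deviation is used.  A
    constant series yields r = 0, which downstream produces the flagged
    undefined-entropy path rather than an exception.
    """
    if params.r_mode == "absolute":
        return float(params.r)
    return float(params.r_fraction * np.std(series))


try:  # pragma: no cover - import guard
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @njit(cache=True)
    def _pair_scan(x, m, r):  # pragma: no cover - compiled
        n = x.shape[0]
        nt = n - m
        bj = np.zeros(nt)
        aj = np.zeros(nt)
        for j in range(nt):
            for k in range(j + 1, nt):
                d = 0.0
                matched = True
                for i in range(m):
                    diff = abs(x[j + i] - x[k + i])
                    if diff > d:
                        d = diff
                    if d >= r:
                        matched = False
                        break
                if matched:
                    bj[j] += 1.0
                    bj[k] += 1.0
                    dm1 = abs(x[j + m] - x[k + m])
                    if dm1 > d:
                        d = dm1
                    if d < r:
                        aj[j] += 1.0
                        aj[k] += 1.0
        return bj, aj


def _pair_scan_numpy(x: np.ndarray, m: int, r: float):
    """Blocked numpy fallback for the pairwise template scan."""
    n = x.size
    nt = n - m
    emb = np.lib.stride_tricks.sliding_window_view(x, m + 1)  # (nt, m+1)
    bj = np.zeros(nt)
    aj = np.zeros(nt)
    block = max(1, int(4e6 // max(nt, 1)))
    for start in range(0, nt, block):
        stop = min(nt, start + block)
        diff = np.abs(emb[start:stop, None, :] - emb[None, :, :])
        d_m = diff[:, :, :m].max(axis=2)
        d_m1 = np.maximum(d_m, diff[:, :, m])
        match_m = d_m < r
        match_m1 = d_m1 < r
        rows = np.arange(start, stop)
        match_m[rows - start, rows] = False  # exclude self matches
        match_m1[rows - start, rows] = False
        bj[start:stop] += match_m.sum(axis=1)
        aj[start:stop] += match_m1.sum(axis=1)
    return bj, aj


def sample_entropy(series, params: Optional[EntropyParams] = None):
    """Sample Entropy of a numeric series.

    Parameters
    ----------
    series : array_like
        1-D numeric series, length N > m + 1.
    params : EntropyParams, optional
        Embedding and tolerance settings (defaults: m=2, r=0.2 SD).

    Returns
    -------
    value : float
        SE = -ln(A/B); ``nan`` when no matches exist at either length (the
        undefined-entropy case, flagged through ``counts.undefined``).
    counts : TemplateMatchCounts
        Per-template diagnostics.
    """
    if params is None:
        params = EntropyParams()
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    m = params.m
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series length {n} too short for m={m}")
    r = resolve_tolerance(x, params)

    nt = n - m
    if r <= 0:
        warnings.warn(
            "tolerance r resolved to 0 (constant series?); entropy undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        bj = np.zeros(nt)
        aj = np.zeros(nt)
    elif _HAVE_NUMBA:
        bj, aj = _pair_scan(x, m, r)
    else:
        bj, aj = _pair_scan_numpy(x, m, r)

    denom = nt - 1
    b_j = bj / denom
    a_j = aj / denom
    b = float(b_j.mean())
    a = float(a_j.mean())

    d_metric = None
    if n <= _DMAT_MAX_N:
        emb = np.lib.stride_tricks.sliding_window_view(x, m)[:nt]
        d_metric = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)

    counts = TemplateMatchCounts(
        b_j=b_j, a_j=a_j, b=b, a=a, m=m, r=r, n=n, d_metric=d_metric
    )
    if counts.undefined:
        return float("nan"), counts
    return float(-np.log(a / b)), counts
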