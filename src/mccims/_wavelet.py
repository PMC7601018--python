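"""Minimal orthogonal Daubechies wavelet transform (periodized).

Daubechies scaling filters are built by spectral factorization: the
half-band polynomial P(y) = sum_k C(N-1+k, k) y^k is rooted, each root kept
on its minimum-phase side, and the filter assembled from those roots plus a
zero of order N at z = -1, normalized to sum sqrt(2).  The 1-D transform
uses circular (periodization) boundary handling, so the analysis operator
is orthogonal and reconstruction is exact to machine precision.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import comb


@lru_cache(maxsize=None)
def daubechies_filter(n_moments: int) -> np.ndarray:
    """Orthonormal Daubechies scaling (low-pass) filter with 2*n taps."""
    n = n_moments
    if n < 1:
        raise ValueError("need at least one vanishing moment")
    if n == 1:  # Haar
        return np.array([1.0, 1.0]) / np.sqrt(2.0)
    # P(y), ascending powers
    p = np.array([comb(n - 1 + k, k, exact=True) for k in range(n)], dtype=float)
    roots_y = np.roots(p[::-1])
    z_roots = []
    for y in roots_y:
        # y = (2 - z - 1/z)/4  =>  z^2 - 2(1 - 2y) z + 1 = 0
        b = 2.0 * (1.0 - 2.0 * y)
        disc = np.sqrt(b * b - 4.0 + 0j)
        for z in ((b + disc) / 2.0, (b - disc) / 2.0):
            if abs(z) < 1.0 - 1e-12:
                z_roots.append(z)
    assert len(z_roots) == n - 1, "spectral factorization lost roots"
    poly = np.poly(np.concatenate([np.full(n, -1.0 + 0j), np.array(z_roots)]))
    h = np.real(poly)
    h *= np.sqrt(2.0) / h.sum()
    return h


def _filters(n_moments: int) -> tuple[np.ndarray, np.ndarray]:
    lo = daubechies_filter(n_moments)
    hi = lo[::-1].copy()
    hi[1::2] *= -1.0  # quadrature mirror
    return lo, hi


def _analysis_step(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One periodized decomposition level along the last axis (even length)."""
    n = x.shape[-1]
    half = n // 2
    idx = (2 * np.arange(half)[:, None] + np.arange(lo.size)[None, :]) % n
    seg = x[..., idx]  # (..., half, taps)
    return seg @ lo, seg @ hi


def _synthesis_step(a: np.ndarray, d: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_analysis_step` (transpose of the orthogonal map)."""
    half = a.shape[-1]
    n = 2 * half
    x = np.zeros(a.shape[:-1] + (n,))
    idx = (2 * np.arange(half)[:, None] + np.arange(lo.size)[None, :]) % n
    contrib = a[..., :, None] * lo + d[..., :, None] * hi
    np.add.at(x, (..., idx), contrib)
    return x


def wavedec_rows(x: np.ndarray, n_moments: int = 8, level: int | None = None):
    """Multilevel periodized DWT of each row of ``x``.

    Returns ``(approx, [detail_coarsest, ..., detail_finest], orig_len)``.
    Odd lengths are edge-padded by one sample before transforming.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = _filters(n_moments)
    orig_len = x.shape[-1]
    if orig_len < lo.size:
        raise ValueError(f"signal length {orig_len} shorter than filter support {lo.size}")
    max_level = int(np.floor(np.log2(orig_len / (lo.size - 1.0)))) if orig_len >= lo.size else 0
    max_level = max(max_level, 1)
    if level is None:
        level = max_level
    if level > max_level:
        raise ValueError(f"level {level} exceeds maximum decomposition depth {max_level}")
    a = x
    details: list[np.ndarray] = []
    for _ in range(level):
        if a.shape[-1] % 2:
            a = np.concatenate([a, a[..., -1:]], axis=-1)
        a, d = _analysis_step(a, lo, hi)
        details.append(d)
    details.reverse()  # coarsest first
    return a, details, orig_len


def waverec_rows(approx: np.ndarray, details, orig_len: int, n_moments: int = 8) -> np.ndarray:
    """Inverse of :func:`wavedec_rows`; truncates back to ``orig_len``."""
    lo, hi = _filters(n_moments)
    a = approx
    for d in details:  # coarsest -> finest
        if a.shape[-1] != d.shape[-1]:
            a = a[..., : d.shape[-1]]
        a = _synthesis_step(a, d, lo, hi)
    return a[..., :orig_len]
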