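"""Low-level simulation kernels.

Genotypes are drawn per variant as two allele indicators: an allele is
present when a fresh 16-bit integer falls below ``round(maf * 2**16)``.
The fused kernel and the materializing kernel consume the random stream
in exactly the same order (two length-``n`` uint16 arrays per variant,
column by column), so a cohort simulated through either path sees the
same genotypes for the same seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U16_SCALE = 65536


def maf_to_threshold(maf: np.ndarray) -> np.ndarray:
    """Map allele frequencies to uint16 comparison thresholds."""
    t = np.rint(np.asarray(maf, dtype=np.float64) * U16_SCALE)
    return np.clip(t, 0, U16_SCALE).astype(np.int64)


@njit(cache=True)
def _fill_genotypes(rng, thresh, n, out):
    m = thresh.shape[0]
    for j in range(m):
        t = thresh[j]
        a = rng.integers(0, U16_SCALE, size=n, dtype=np.uint16)
        b = rng.integers(0, U16_SCALE, size=n, dtype=np.uint16)
        for i in range(n):
            g = 0
            if a[i] < t:
                g += 1
            if b[i] < t:
                g += 1
            out[i, j] = g


@njit(cache=True)
def _accumulate_scores(rng, thresh, w_pb, w_pgs, n, special_j):
    """Draw all variant columns and accumulate PB / PGS inner products.

    ``w_pb`` and ``w_pgs`` are per-variant weights on the *raw* allele
    count scale (effect divided by the population dosage sd); centering
    is a constant shift applied by the caller.  When ``special_j >= 0``
    the haplotype indicators of that column are returned so the caller
    can couple an LEV to it or form an interaction term.
    """
    m = thresh.shape[0]
    pb = np.zeros(n, dtype=np.float64)
    pgs = np.zeros(n, dtype=np.float64)
    hap_a = np.zeros(n, dtype=np.uint8)
    hap_b = np.zeros(n, dtype=np.uint8)
    for j in range(m):
        t = thresh[j]
        a = rng.integers(0, U16_SCALE, size=n, dtype=np.uint16)
        b = rng.integers(0, U16_SCALE, size=n, dtype=np.uint16)
        wb = w_pb[j]
        wg = w_pgs[j]
        keep = j == special_j
        for i in range(n):
            g = 0
            if a[i] < t:
                g += 1
            if b[i] < t:
                g += 1
            if g:
                pb[i] += wb * g
                pgs[i] += wg * g
            if keep:
                hap_a[i] = 1 if a[i] < t else 0
                hap_b[i] = 1 if b[i] < t else 0
    return pb, pgs, hap_a, hap_b


def simulate_genotype_matrix(rng: np.random.Generator, maf: np.ndarray, n: int) -> np.ndarray:
    """Materialize an ``n x m`` raw allele-count matrix (int8)."""
    thresh = maf_to_threshold(maf)
    out = np.empty((n, thresh.shape[0]), dtype=np.int8)
    _fill_genotypes(rng, thresh, n, out)
    return out


def simulate_scores(
    rng: np.random.Generator,
    maf: np.ndarray,
    w_pb: np.ndarray,
    w_pgs: np.ndarray,
    n: int,
    special_j: int = -1,
):
    """Fused genotype draw + score accumulation (uncentred raw-scale sums)."""
    thresh = maf_to_threshold(maf)
    pb, pgs, hap_a, hap_b = _accumulate_scores(
        rng,
        thresh,
        np.ascontiguousarray(w_pb, dtype=np.float64),
        np.ascontiguousarray(w_pgs, dtype=np.float64),
        n,
        special_j,
    )
    if special_j < 0:
        return pb, pgs, None, None
    return pb, pgs, hap_a.astype(bool), hap_b.astype(bool)
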