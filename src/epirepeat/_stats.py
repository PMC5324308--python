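"""Small shared statistical helpers.

Everything here is a thin, vectorised wrapper over scipy/statsmodels so the
analysis modules agree on one multiple-testing procedure and one two-sided
binomial test.
"""
from __future__ import annotations

import zlib

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def binom_two_sided(k, n, p) -> np.ndarray:
    """Two-sided doubled-tail binomial p-value, vectorised.

    p = min(1, 2 * min(P(X <= k), P(X >= k))) for X ~ Binomial(n, p).
    Entries with n == 0 get p = 1.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    k, n = np.broadcast_arrays(k, n)
    lower = stats.binom.cdf(k, np.maximum(n, 1), p)
    upper = stats.binom.sf(k - 1, np.maximum(n, 1), p)
    out = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return np.where(n == 0, 1.0, out)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child random stream of a master seed.

    The stream identity is the CRC32 of the name, so independent stages of a
    pipeline draw from non-colliding streams of one user-facing seed.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])
    )
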