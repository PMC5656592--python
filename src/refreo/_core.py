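"""Shared vectorized kernels for within-sample order comparisons."""

from __future__ import annotations

import numpy as np

# pairs are processed in chunks of this many rows so that the pairs x samples
# work arrays stay small regardless of universe size
PAIR_CHUNK = 250_000


def pair_sign(values: np.ndarray, ia: np.ndarray, ib: np.ndarray,
              chunk: int = PAIR_CHUNK) -> np.ndarray:
    """Sign of E[ia] - E[ib] per (pair, sample): +1, -1, or 0 for a tie.

    ``values`` is genes x samples; ``ia``/``ib`` index its rows.  Returned
    int8 array has shape (n_pairs, n_samples).
    """
    n = len(ia)
    out = np.empty((n, values.shape[1]), dtype=np.int8)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d = values[ia[lo:hi], :] - values[ib[lo:hi], :]
        np.sign(d, out=d)
        out[lo:hi] = d.astype(np.int8)
    return out


def concordance_counts(values: np.ndarray, ia: np.ndarray, ib: np.ndarray,
                       orientation: np.ndarray,
                       chunk: int = PAIR_CHUNK) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair counts of samples concordant with / reversed against
    ``orientation`` (ties count as neither)."""
    n = len(ia)
    conc = np.empty(n, dtype=np.int64)
    rev = np.empty(n, dtype=np.int64)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        s = pair_sign(values, ia[lo:hi], ib[lo:hi], chunk=chunk)
        o = orientation[lo:hi, None]
        conc[lo:hi] = (s == o).sum(axis=1)
        rev[lo:hi] = (s == -o).sum(axis=1)
    return conc, rev
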