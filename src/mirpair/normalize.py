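"""Expression normalization: logCPM and quantile normalization.

logCPM uses the standard convention ``log2((count + c) / (libsize + 2c) * 1e6)``
with pseudocount ``c`` (default 0.5), which avoids log(0) while staying
monotone in the count within a sample.  Quantile normalization maps every
column onto the across-column mean of sorted values; within-column ties
receive the mean of the reference values spanned by the tie, which keeps the
transform deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, PairedCountMatrix

__all__ = ["log_cpm", "quantile_normalize"]


def log_cpm(counts: PairedCountMatrix, pseudocount: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million with a pseudocount.

    value = log2((count + pseudocount) / (libsize + 2*pseudocount) * 1e6)

    Raises
    ------
    ValueError
        If any sample has zero library size (named in the message).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    mat = counts.counts.to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    for sample, ls in zip(counts.sample_ids, libsize):
        if ls <= 0:
            raise ValueError(f"sample {sample!r} has zero library size")
    vals = np.log2((mat + pseudocount) / (libsize + 2.0 * pseudocount) * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)
    )


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the mean-of-sorted-columns reference distribution.

    After the transform each column's sorted values equal the reference, and
    within-column rank order is preserved.  A tie spanning ranks r..s is given
    the mean of reference[r..s].
    """
    arr = m.values.to_numpy(dtype=float)
    n_feat, n_samp = arr.shape
    if n_samp < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    reference = np.sort(arr, axis=0).mean(axis=1)
    # cumulative sums let us average reference values over a tied rank span
    ref_cumsum = np.concatenate(([0.0], np.cumsum(reference)))
    out = np.empty_like(arr)
    for j in range(n_samp):
        col = arr[:, j]
        # tie span of each value: [min_rank-1, max_rank) in 0-based rank space
        rmin = rankdata(col, method="min").astype(int) - 1
        rmax = rankdata(col, method="max").astype(int)
        out[:, j] = (ref_cumsum[rmax] - ref_cumsum[rmin]) / (rmax - rmin)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    )
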