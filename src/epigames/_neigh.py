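"""Vectorized closed-neighborhood reductions over a CSR adjacency matrix."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def neighbor_sum(adj: sp.csr_matrix, values: np.ndarray) -> np.ndarray:
    """Per-node sum of ``values`` over (open) neighbors."""
    return adj @ values


def neighbor_max_where(
    adj: sp.csr_matrix, values: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Per-node max of ``values[j]`` over neighbors ``j`` with ``mask[j]``.

    Nodes with no masked neighbor get ``-inf``.  Implemented as a segmented
    maximum over the CSR index array, which is O(nnz).
    """
    n = adj.shape[0]
    masked = np.where(mask, values, -np.inf)
    vals = masked[adj.indices]
    out = np.full(n, -np.inf)
    starts = adj.indptr[:-1]
    nonempty = starts < adj.indptr[1:]
    if np.any(nonempty):
        # reduceat over the starts of nonempty rows: empty rows have zero-width
        # segments and are skipped, so each reduction covers exactly one row
        out[nonempty] = np.maximum.reduceat(vals, starts[nonempty])
    return out
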