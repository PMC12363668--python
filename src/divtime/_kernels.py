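"""JIT-compiled inner loops for the bd/db simulators.

CSR layout: `indptr`/`indices` hold, per first-picked vertex, the candidate
second vertices (out-neighbours for bd, in-neighbours for db).  For bd the
type copies first->second; for db, second->first (`copy_from_second`).
Bookkeeping (type counts, number of distinct types) is O(1) per step.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def advance(x, counts, n_distinct, indptr, indices, copy_from_second, budget, gen):
    # Advance until absorbed or `budget` steps consumed; returns
    # (steps_used, n_distinct).  Mutates x and counts in place.
    n = x.shape[0]
    steps = 0
    while n_distinct > 1 and steps < budget:
        a = np.int64(gen.integers(0, n))
        lo = indptr[a]
        deg = indptr[a + 1] - lo
        b = indices[lo + np.int64(gen.integers(0, deg))]
        if copy_from_second:
            src, dst = b, a
        else:
            src, dst = a, b
        steps += 1
        ts = x[src]
        td = x[dst]
        if ts != td:
            counts[td] -= 1
            if counts[td] == 0:
                n_distinct -= 1
            counts[ts] += 1
            x[dst] = ts
    return steps, n_distinct
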