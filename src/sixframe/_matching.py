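"""One-to-one peak matching within an m/z tolerance.

Both the search-engine score and the synthetic-spectrum common-ion score
count how many peaks of one list can be paired, each at most once, with a
peak of the other list at most ``tol`` Th apart.  Because every m/z window
is an interval of equal width, the compatibility graph is convex bipartite
and a single sorted sweep (Glover's rule: assign each right-hand peak to
the lowest unmatched compatible left-hand peak) attains the true maximum
matching — no heuristic shortfall.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def max_common_count(a: Sequence[float], b: Sequence[float], tol: float) -> int:
    """Size of a maximum one-to-one matching between ``a`` and ``b`` where a
    pair is admissible iff ``|a_i - b_j| <= tol``.  Inputs need not be
    sorted."""
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    xs = np.sort(np.asarray(a, dtype=float))
    ys = np.sort(np.asarray(b, dtype=float))
    i = 0
    count = 0
    for y in ys:
        while i < len(xs) and xs[i] < y - tol:
            i += 1
        if i < len(xs) and xs[i] <= y + tol:
            count += 1
            i += 1
    return count
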