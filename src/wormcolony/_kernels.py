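"""Hot-loop kernels for the per-timepoint feeding pass.

Feeding is the only step that cannot be expressed as independent vector
operations: worms sharing a cell eat sequentially (all-or-nothing meals), so
whether one is fed depends on how much its predecessors left.  The loop runs
over individuals pre-sorted by cell in a randomized within-cell order and is
JIT-compiled with numba when available.

Modes: 0 = no demand (always fed), 1 = consume as larva, 2 = consume as
adult, 3 = probe only (arrested stages test whether resumption is possible
without eating).
"""

from __future__ import annotations

import numpy as np

MODE_NONE = 0
MODE_LARVA = 1
MODE_ADULT = 2
MODE_PROBE = 3


def _feed_loop_py(order, cell, demand, mode, food, fed, totals):
    for k in range(order.size):
        i = order[k]
        m = mode[i]
        d = demand[i]
        c = cell[i]
        if m == MODE_NONE or d == 0.0:
            fed[i] = 1
        elif m == MODE_PROBE:
            fed[i] = 1 if food[c] >= d else 0
        else:  # consume
            if food[c] >= d:
                food[c] -= d
                fed[i] = 1
                if m == MODE_LARVA:
                    totals[0] += d
                else:
                    totals[1] += d
            else:
                fed[i] = 0


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    feed_loop = njit(cache=False)(_feed_loop_py)
except ImportError:  # pragma: no cover
    feed_loop = _feed_loop_py
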