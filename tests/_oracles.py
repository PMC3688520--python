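"""Independent brute-force oracles used to cross-check the fast callers.

These deliberately re-derive the contracts by direct window scanning rather
than sharing any code with the package's segmentation routine.
"""

from __future__ import annotations

import numpy as np


def window_scan_runs(starts, passing, *, tile_width, max_gap, min_run, min_span):
    """All qualifying maximal runs, found by scanning every start position.

    A probe can start a run only if it passes and its left neighbour cannot
    extend the run to it; the run is then grown probe by probe to the right.
    Returns (start, end) genomic intervals.
    """
    starts = np.asarray(starts)
    passing = np.asarray(passing, dtype=bool)
    n = starts.size
    out = []
    for i in range(n):
        if not passing[i]:
            continue
        if i > 0 and passing[i - 1] and starts[i] - starts[i - 1] <= max_gap:
            continue  # not the leftmost probe of its maximal run
        j = i
        while (j + 1 < n and passing[j + 1]
               and starts[j + 1] - starts[j] <= max_gap):
            j += 1
        count = j - i + 1
        span = int(starts[j]) + tile_width - int(starts[i])
        if count >= min_run and span >= min_span:
            out.append((int(starts[i]), int(starts[j]) + tile_width))
    return out


def count_probes_in_null_runs(delta, median, sd, k_sd=2.0, min_run=3):
    """Probes inside qualifying same-sign runs on a regular grid.

    Direct run counting for the null-calibration Monte-Carlo: on a gap-free
    grid the span condition is implied by the run-length condition, so it is
    enough to count maximal stretches of >= min_run consecutive values beyond
    each threshold.  Returns (n_probes_in_runs, n_increase_runs, n_decrease_runs).
    """
    total = 0
    n_inc = n_dec = 0
    for sign in (1, -1):
        if sign > 0:
            beyond = delta >= median + k_sd * sd
        else:
            beyond = delta <= median - k_sd * sd
        run = 0
        for flag in np.append(beyond, False):  # sentinel flushes the last run
            if flag:
                run += 1
            else:
                if run >= min_run:
                    total += run
                    if sign > 0:
                        n_inc += 1
                    else:
                        n_dec += 1
                run = 0
    return total, n_inc, n_dec
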