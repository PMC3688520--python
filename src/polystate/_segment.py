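"""Run-length threshold segmentation on probe tracks.

The single primitive both callers share: find maximal runs of consecutive
track probes that all pass a predicate, where consecutive probes may be at
most ``max_gap`` bp apart (start-to-start).  A probe that is present but
fails the predicate always breaks a run; the gap allowance only bridges
positions where the array simply has no probe (masked/absent features).
A run is emitted when it contains at least ``min_run`` probes and its
tile-union span ``last_start + tile_width - first_start`` is at least
``min_span`` bp.
"""

from __future__ import annotations

import numpy as np


def threshold_runs(starts: np.ndarray, passing: np.ndarray, *, tile_width: int,
                   max_gap: int, min_run: int, min_span: int) -> list[tuple[int, int]]:
    """Return ``(i, j)`` index slices (half-open) of qualifying runs.

    ``starts`` must be sorted ascending; ``passing`` is a boolean mask of the
    same length.
    """
    n = starts.size
    if n == 0:
        return []
    idx = np.flatnonzero(passing)
    if idx.size == 0:
        return []
    # split the passing indices where they are non-consecutive in the track
    # or where the genomic spacing exceeds the gap allowance
    breaks = np.flatnonzero(
        (np.diff(idx) != 1) | (np.diff(starts[idx]) > max_gap)
    )
    runs = []
    lo = 0
    for b in np.append(breaks, idx.size - 1):
        i, j = int(idx[lo]), int(idx[b]) + 1
        count = j - i
        span = int(starts[j - 1]) + tile_width - int(starts[i])
        if count >= min_run and span >= min_span:
            runs.append((i, j))
        lo = b + 1
    return runs
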