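"""Shared sub-bin spectral peak refinement."""

from __future__ import annotations

import numpy as np


def parabolic_refine(grid: np.ndarray, amp: np.ndarray, j: int) -> float:
    """Refine a peak location by a three-point parabola on log-amplitude.

    Returns the refined coordinate of the maximum around index ``j`` of
    ``amp`` on ``grid``.  Falls back to ``grid[j]`` at array edges, on zero
    neighbours, or on a degenerate (non-concave) triple.  The offset is
    clamped to half a bin so refinement can never leave the winning bin.
    """
    n = amp.size
    if j <= 0 or j >= n - 1:
        return float(grid[j])
    y0, y1, y2 = amp[j - 1], amp[j], amp[j + 1]
    if min(y0, y1, y2) <= 0:
        return float(grid[j])
    l0, l1, l2 = np.log(y0), np.log(y1), np.log(y2)
    denom = l0 - 2 * l1 + l2
    if denom >= 0:  # not strictly concave in log-amplitude
        return float(grid[j])
    delta = 0.5 * (l0 - l2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = grid[j + 1] - grid[j] if delta >= 0 else grid[j] - grid[j - 1]
    return float(grid[j] + delta * step)
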