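"""SPXY calibration/prediction partitioning (joint x-y Kennard-Stone).

SPXY extends the Kennard-Stone maximin design to regression data: pairwise
Euclidean distances in spectral space and in response space are each
normalized by their maxima and summed,

    d(i, j) = d_x(i, j) / max d_x  +  d_y(i, j) / max d_y,

then samples are picked greedily — seed with the most distant pair, then
repeatedly add the sample whose minimum distance to the already-selected set
is largest — until the calibration set is full. The remainder forms the
prediction set. The procedure is deterministic; ties are broken toward the
smallest original sample index so the split is order-independent.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .containers import SpectraTable, SplitAssignment


def _joint_distance_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    max_dx = dx.max()
    max_dy = dy.max()
    if max_dx == 0 and max_dy == 0:
        raise ValueError("all samples identical in both x and y")
    # degenerate block (all-equal x or all-equal y): use the other alone
    d = np.zeros_like(dx)
    if max_dx > 0:
        d += dx / max_dx
    if max_dy > 0:
        d += dy / max_dy
    return d


def spxy_split(table: SpectraTable, n_calibration: int) -> SplitAssignment:
    """Deterministic SPXY split into ``n_calibration`` + remainder samples."""
    n = table.n_samples
    if not 2 <= n_calibration < n:
        raise ValueError("n_calibration must satisfy 2 <= n_calibration < n_samples")
    d = _joint_distance_matrix(table.X, table.y)

    # seed: the pair with maximal joint distance, lowest indices on ties
    flat = np.argmax(d)  # argmax scans row-major -> smallest (i, j) wins ties
    i0, j0 = np.unravel_index(flat, d.shape)
    selected = [min(i0, j0), max(i0, j0)]
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True

    # min distance from each candidate to the selected set, updated incrementally
    min_dist = np.minimum(d[:, selected[0]], d[:, selected[1]])
    min_dist[in_set] = -np.inf
    while len(selected) < n_calibration:
        nxt = int(np.argmax(min_dist))  # argmax -> smallest index on ties
        selected.append(nxt)
        in_set[nxt] = True
        min_dist = np.minimum(min_dist, d[:, nxt])
        min_dist[in_set] = -np.inf

    calibration = np.sort(np.array(selected, dtype=int))
    prediction = np.flatnonzero(~in_set)
    return SplitAssignment(calibration=calibration, prediction=prediction)
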