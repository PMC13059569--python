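"""Inter-channel spatial relationships between puncta of two markers.

Two families of metrics relate H3K27ac and CTCF foci:

* directional minimum centroid distances — for each source punctum, the
  Euclidean distance to its nearest target punctum, averaged over sources
  (the two directions differ and are never symmetrized);
* the effective-radius overlap ratio — the fraction of source puncta whose
  centroid lies within ``r_i + r_j`` of at least one target punctum, where
  ``r = (L_major + L_minor) / 4`` is the mean axis half-length.

Distances are in pixels throughout; conversion to nm via the pixel pitch is
left to the caller and never applied silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .puncta import PunctaSet

__all__ = ["ColocResult", "min_distances", "overlap_ratio", "colocalize"]

HIST_BIN_WIDTH = 10.0  # px


@dataclass
class ColocResult:
    """Directional minimum-distance summary from source to target puncta."""

    mean_min_distance: float | None
    min_distances: np.ndarray
    histogram: np.ndarray        # counts per [10k, 10(k+1)) px bin
    bin_edges: np.ndarray


def min_distances(source: PunctaSet, target: PunctaSet) -> ColocResult:
    """Mean minimum centroid distance from each source punctum to the target set.

    An empty source or target makes the metric missing (mean None, empty
    arrays) rather than zero. The histogram uses left-closed bins of width
    10 px starting at 0.
    """
    if source.n == 0 or target.n == 0:
        return ColocResult(mean_min_distance=None,
                           min_distances=np.empty(0),
                           histogram=np.empty(0, dtype=int),
                           bin_edges=np.array([0.0]))
    d = cdist(source.centroids, target.centroids)
    mins = d.min(axis=1)
    n_bins = int(np.floor(mins.max() / HIST_BIN_WIDTH)) + 1
    edges = np.arange(n_bins + 1) * HIST_BIN_WIDTH
    # left-closed right-open bins [10k, 10(k+1))
    counts = np.bincount((mins // HIST_BIN_WIDTH).astype(int), minlength=n_bins)
    return ColocResult(mean_min_distance=float(mins.mean()),
                       min_distances=mins, histogram=counts, bin_edges=edges)


def overlap_ratio(source: PunctaSet, target: PunctaSet) -> float | None:
    """Fraction of source puncta geometrically overlapping >= 1 target punctum.

    Overlap uses the effective-radius rule: centroid distance
    d_ij <= r_i + r_j (boundary inclusive). Empty source -> missing (None);
    empty target -> 0.0 with a warning (no overlap is possible).
    """
    if source.n == 0:
        return None
    if target.n == 0:
        warnings.warn("empty target puncta set: overlap ratio is 0",
                      stacklevel=2)
        return 0.0
    d = cdist(source.centroids, target.centroids)
    rsum = source.effective_radii[:, None] + target.effective_radii[None, :]
    has_overlap = (d <= rsum).any(axis=1)
    return float(has_overlap.mean())


def colocalize(source: PunctaSet, target: PunctaSet) -> dict[str, float]:
    """Both directional distance means and overlap ratios as a flat record."""
    fwd = min_distances(source, target)
    rev = min_distances(target, source)
    out = {
        "source_to_target_min_distance": _nan(fwd.mean_min_distance),
        "target_to_source_min_distance": _nan(rev.mean_min_distance),
        "source_overlap_ratio": _nan(overlap_ratio(source, target)),
        "target_overlap_ratio": _nan(overlap_ratio(target, source)),
    }
    return out


def _nan(x: float | None) -> float:
    return float("nan") if x is None else float(x)
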