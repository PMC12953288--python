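"""Audit segmentation output against generator ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphometry import SegmentedDroplet
from .simulate.images import GroundTruthDroplet

__all__ = ["MatchResult", "match_droplets"]


@dataclass
class MatchResult:
    """Centroid matching of segmented droplets to ground truth."""

    pairs: list[tuple[GroundTruthDroplet, SegmentedDroplet]]
    n_truth: int
    n_segmented: int

    @property
    def recall(self) -> float:
        return len(self.pairs) / self.n_truth if self.n_truth else 1.0

    @property
    def precision(self) -> float:
        return len(self.pairs) / self.n_segmented if self.n_segmented else 1.0

    def area_relative_errors(self) -> np.ndarray:
        return np.array(
            [abs(s.area_um2 - t.area_um2) / t.area_um2 for t, s in self.pairs]
        )


def match_droplets(
    truth: list[GroundTruthDroplet],
    segmented: list[SegmentedDroplet],
    max_dist_px: float = 5.0,
) -> MatchResult:
    """Greedily pair each ground-truth droplet with the nearest unmatched
    segmented droplet within ``max_dist_px`` (centroid distance)."""
    taken: set[int] = set()
    pairs = []
    for t in truth:
        best, best_d = None, max_dist_px
        for idx, s in enumerate(segmented):
            if idx in taken:
                continue
            d = float(np.hypot(s.centroid_xy[0] - t.center_xy[0],
                               s.centroid_xy[1] - t.center_xy[1]))
            if d <= best_d:
                best, best_d = idx, d
        if best is not None:
            taken.add(best)
            pairs.append((t, segmented[best]))
    return MatchResult(pairs=pairs, n_truth=len(truth), n_segmented=len(segmented))
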