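"""Temporal MNC descriptors, matching descriptions and antipodal frames.

Each frame of an ordered image sequence is summarized by the feature
vectors of its maximal nucleus clusters: the gradient-orientation angle of
the nucleus generating point and the adjacency degree (plus centroid and
area, which are carried for trajectory export but deliberately excluded
from matching — matching compares features, not positions).

Two frames carry a *matching description* when some MNC descriptor of one
agrees with some descriptor of the other: circular GO-angle agreement
within a tolerance (default 2 degrees on the 180-degree folded range) and,
by default, exact degree equality.

For antipodal analysis the frames are placed uniformly, in order, on a
circle; frames diametrically opposite are antipodal.  With an even number
of frames n the pure antipodal pairs are exactly (i, i + n/2); with odd n
no pair sits at exactly 180 degrees, so the deterministic completion pairs
frames to minimize the total deviation from 180 degrees, each frame used
at most once, ties broken lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tessellation import (
    NucleusCluster,
    VoronoiTiling,
    find_maximal_nucleus_clusters,
    region_area,
    region_centroid,
)

__all__ = [
    "MNCDescriptor",
    "FrameSequence",
    "describe_frame",
    "match_descriptions",
    "antipodal_pairs",
    "centroid_trajectory",
    "circular_angle_diff",
]


@dataclass(frozen=True)
class MNCDescriptor:
    """Feature vector of one maximal nucleus cluster in one frame."""

    frame_index: int
    nucleus_theta: float
    degree: int
    centroid: tuple[float, float]
    nucleus_area: float
    time_label: float | None = None


@dataclass(frozen=True)
class FrameSequence:
    """Ordered per-frame MNC descriptor lists."""

    frames: tuple[tuple[MNCDescriptor, ...], ...]
    frame_period: float | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a frame sequence needs at least 2 frames")

    def __len__(self) -> int:
        return len(self.frames)


def circular_angle_diff(a: float, b: float, period: float = 180.0) -> float:
    """Smallest absolute difference between two angles on a circle."""
    d = abs(a - b) % period
    return min(d, period - d)


def describe_frame(
    tiling: VoronoiTiling,
    mncs: list[NucleusCluster] | None = None,
    frame_index: int = 0,
    time_label: float | None = None,
) -> list[MNCDescriptor]:
    """One descriptor per maximal cluster, in MNC detection order.

    The nucleus GO angle is read from the tiling's generating-point set;
    tilings built from raw coordinates (no orientations) get NaN there.
    """
    if mncs is None:
        mncs = find_maximal_nucleus_clusters(tiling)
    out = []
    for c in mncs:
        theta = float("nan")
        if tiling.point_set is not None:
            theta = tiling.point_set.points[c.nucleus_id].theta
        out.append(
            MNCDescriptor(
                frame_index=frame_index,
                nucleus_theta=theta,
                degree=c.degree,
                centroid=region_centroid(tiling, c.nucleus_id),
                nucleus_area=region_area(tiling, c.nucleus_id),
                time_label=time_label,
            )
        )
    return out


def match_descriptions(
    seq: FrameSequence, tol: float = 2.0, degree_exact: bool = True
) -> list[tuple[int, int]]:
    """Frame pairs (i < j) whose MNC descriptors match.

    Frames match when some descriptor of i and some of j agree in nucleus
    GO angle within ``tol`` (circular difference on the folded range) and,
    if ``degree_exact``, have equal adjacency degree.  All matching pairs,
    ordered by (i, j).
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    n = len(seq)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if any(
                circular_angle_diff(a.nucleus_theta, b.nucleus_theta) <= tol
                and (not degree_exact or a.degree == b.degree)
                for a in seq.frames[i]
                for b in seq.frames[j]
            ):
                pairs.append((i, j))
    return pairs


def antipodal_pairs(seq: FrameSequence | int) -> list[tuple[int, int]]:
    """Antipodal frame pairs on the uniform temporal circle.

    Even n: the exact perfect matching (i, i + n/2).  Odd n: the matching
    minimizing the total |angular separation - 180 deg|, each frame in at
    most one pair (one frame stays unpaired), lexicographically smallest
    among the minimizers.  Deterministic in both cases.
    """
    n = seq if isinstance(seq, int) else len(seq)
    if n < 2:
        raise ValueError("need at least 2 frames")
    if n % 2 == 0:
        return [(i, i + n // 2) for i in range(n // 2)]
    # odd: every pair deviates from 180 by >= 180/n; offsets (n-1)/2 and
    # (n+1)/2 both attain it, so the lexicographically smallest optimal
    # matching is greedy: pair each unpaired i with i + (n-1)/2.
    step = (n - 1) // 2
    pairs = []
    used = set()
    for i in range(n):
        j = i + step
        if i in used or j >= n or j in used:
            continue
        pairs.append((i, j))
        used |= {i, j}
    return pairs


def frame_angles(n: int) -> np.ndarray:
    """Angular positions (degrees) of n frames placed uniformly in order."""
    return np.arange(n) * 360.0 / n


def centroid_trajectory(seq: FrameSequence) -> list[dict]:
    """Per-frame principal-MNC centroid table, in time order.

    The principal MNC of a frame is the first descriptor (highest degree,
    then lexicographic nucleus — the detection order).  Frames with no MNC
    descriptor are skipped.
    """
    rows = []
    for idx, frame in enumerate(seq.frames):
        if not frame:
            continue
        d = frame[0]
        rows.append(
            {
                "frame_index": idx,
                "time_label": d.time_label,
                "centroid_x": d.centroid[0],
                "centroid_y": d.centroid[1],
                "degree": d.degree,
            }
        )
    return rows
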