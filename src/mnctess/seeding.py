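"""Generating-point selection by gradient-orientation uniqueness.

The tessellation is seeded at pixels whose gradient-orientation (GO) angle
is *unique* in the image, so that every Voronoi region carries a distinct
descriptor.  On a discrete image, float angles are almost surely pairwise
distinct, so "unique angle" is made operational by quantizing the folded
orientation range [-90, 90) into ``bin_count`` equal bins:

* ``strict`` mode keeps exactly the pixels whose bin is occupied by no
  other defined pixel (the literal weeding rule);
* ``representative`` mode keeps, for every occupied bin, the single pixel
  with the largest gradient magnitude (the robust default: strict weeding
  can empty the set on smooth synthetic images).

Either way the selected points are one-per-bin, so the point -> bin map is
injective and every generating point has a unique quantized GO angle.
Everything here is deterministic: ties break on the smallest (y, x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import GradientField

__all__ = [
    "GeneratingPoint",
    "GeneratingPointSet",
    "SeedingConfig",
    "FewerThanMinPoints",
    "quantize_orientation",
    "select_generating_points",
]


class FewerThanMinPoints(ValueError):
    """Selection produced too few points to tessellate (degenerate image)."""


@dataclass(frozen=True)
class GeneratingPoint:
    """A seed pixel: location, orientation angle, bin and gradient magnitude."""

    x: int
    y: int
    theta: float
    bin: int
    magnitude: float


@dataclass(frozen=True)
class GeneratingPointSet:
    points: tuple[GeneratingPoint, ...]
    bin_count: int
    mode: str

    def __len__(self) -> int:
        return len(self.points)

    def coords(self, *, pixel_centers: bool = True) -> np.ndarray:
        """(n, 2) array of (x, y) seed coordinates.

        With ``pixel_centers`` (the default) pixel (x, y) maps to the point
        (x + 0.5, y + 0.5), so border-pixel seeds lie strictly inside the
        image rectangle [0, width] x [0, height].
        """
        off = 0.5 if pixel_centers else 0.0
        return np.array([(p.x + off, p.y + off) for p in self.points], dtype=float)


@dataclass(frozen=True)
class SeedingConfig:
    """Knobs for generating-point selection.

    bins: orientation quantization resolution over the 180-degree range
    (default 1024 — fine enough to emulate angle uniqueness, coarse enough
    that the weeding rule bites).  max_points caps Voronoi complexity,
    keeping the largest-magnitude seeds.  min_points guards against
    degenerate images (a tessellation needs at least 4 seeds).
    """

    bins: int = 1024
    mode: str = "representative"
    max_points: int = 300
    min_points: int = 4

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.mode not in ("strict", "representative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


def quantize_orientation(theta, bin_count: int):
    """Map folded orientation angles to bin indices.

    bin = floor((theta + 90) / 180 * bin_count), clamped to
    [0, bin_count - 1]; theta must lie in [-90, 90).
    """
    if bin_count < 2:
        raise ValueError("bin_count must be >= 2")
    theta = np.asarray(theta, dtype=float)
    if np.any(np.isnan(theta)):
        raise ValueError("theta is undefined (NaN) for some input")
    if np.any((theta < -90.0) | (theta >= 90.0)):
        raise ValueError("theta must lie in [-90, 90)")
    bins = np.floor((theta + 90.0) / 180.0 * bin_count).astype(int)
    return np.clip(bins, 0, bin_count - 1)


def select_generating_points(
    gfield: GradientField, config: SeedingConfig | None = None
) -> GeneratingPointSet:
    """Select the generating-point set S from a gradient field.

    Raises FewerThanMinPoints when the weeding rule leaves fewer than
    ``config.min_points`` pixels — the signal of an image too degenerate
    to tessellate (e.g. a pure linear ramp, where every pixel shares one
    orientation).
    """
    cfg = config or SeedingConfig()
    ys, xs = np.nonzero(gfield.defined)
    if ys.size == 0:
        raise FewerThanMinPoints("no pixel has a defined orientation")
    theta = gfield.theta[ys, xs]
    mag = gfield.magnitude[ys, xs]
    bins = quantize_orientation(theta, cfg.bins)

    counts = np.bincount(bins, minlength=cfg.bins)
    if cfg.mode == "strict":
        keep = counts[bins] == 1
        idx = np.nonzero(keep)[0]
    else:  # representative: best pixel per occupied bin
        # sort by (bin, -magnitude, y, x); first entry per bin wins
        order = np.lexsort((xs, ys, -mag, bins))
        b_sorted = bins[order]
        first = np.ones(order.size, dtype=bool)
        first[1:] = b_sorted[1:] != b_sorted[:-1]
        idx = order[first]

    if idx.size > cfg.max_points:
        # keep the max_points largest-magnitude seeds, ties -> smallest (y, x)
        order = np.lexsort((xs[idx], ys[idx], -mag[idx]))
        idx = idx[order[: cfg.max_points]]

    if idx.size < cfg.min_points:
        raise FewerThanMinPoints(
            f"selection yielded {idx.size} points (< min_points={cfg.min_points})"
        )

    # final ordering: (y, x) lexicographic
    order = np.lexsort((xs[idx], ys[idx]))
    idx = idx[order]
    points = tuple(
        GeneratingPoint(
            x=int(xs[i]),
            y=int(ys[i]),
            theta=float(theta[i]),
            bin=int(bins[i]),
            magnitude=float(mag[i]),
        )
        for i in idx
    )
    return GeneratingPointSet(points=points, bin_count=cfg.bins, mode=cfg.mode)
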