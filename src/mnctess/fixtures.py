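"""Seeded synthetic images and frame sequences for the MNC pipeline.

Real inputs are 2D grayscale frames extracted from fMRI videos, which are
not redistributable; the generator emulates their salient property for
this method — smooth intensity structure with a rich, predictable
gradient-orientation field — with sums of isotropic Gaussian bumps plus
seeded Gaussian noise.  A Gaussian bump has analytically radial gradients,
so orientation fields (and hence seed selection) are predictable, and the
added noise spreads orientations across quantization bins the way texture
in a real image does.

Sequence generators plant ground truth for the temporal analyses: repeated
frames at chosen index pairs (descriptor matching must recover exactly
those pairs) and a translating dominant blob (the centroid trajectory must
recover the planted velocity).

Everything is deterministic given the seed; per-frame randomness is drawn
from a single seed stream split by frame counter, so outputs do not depend
on call order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .raster import ScalarImage2D, compute_gradient
from .seeding import SeedingConfig, select_generating_points
from .tessellation import build_tessellation
from .temporal import MNCDescriptor, circular_angle_diff, describe_frame

__all__ = [
    "BlobSpec",
    "FixtureConfig",
    "make_blob_image",
    "make_repeat_sequence",
    "make_translating_sequence",
    "default_fixture_config",
    "default_trajectory_config",
]


@dataclass(frozen=True)
class BlobSpec:
    """One isotropic Gaussian bump: center (x, y), width sigma, amplitude."""

    center: tuple[float, float]
    sigma: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class FixtureConfig:
    """A deterministic synthetic-image recipe."""

    width: int = 64
    height: int = 64
    blobs: tuple[BlobSpec, ...] = ()
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for b in self.blobs:
            x, y = b.center
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(f"blob center {b.center} outside image bounds")


def default_fixture_config(seed: int = 0) -> FixtureConfig:
    """The canonical 64x64 three-blob fixture (noise sd 0.01)."""
    return FixtureConfig(
        width=64,
        height=64,
        blobs=(
            BlobSpec(center=(18.0, 20.0), sigma=6.0, amplitude=1.0),
            BlobSpec(center=(44.0, 16.0), sigma=5.0, amplitude=0.8),
            BlobSpec(center=(32.0, 46.0), sigma=8.0, amplitude=0.9),
        ),
        noise_sd=0.01,
        seed=seed,
    )


def default_trajectory_config(seed: int = 0) -> FixtureConfig:
    """Canonical base for translating sequences: one dominant blob, no noise.

    The maximal-degree nucleus is a discrete argmax over the tiling, and
    independent per-frame noise relocates it non-locally (it hops between
    near-tied cells anywhere in the seed cloud), which would swamp any
    planted translation.  The trajectory fixture therefore isolates the
    translation itself; sub-pixel translation steps still exercise real
    tessellation jitter because the blob is resampled at a different
    pixel phase each frame.
    """
    return FixtureConfig(
        width=64,
        height=64,
        blobs=(BlobSpec(center=(16.0, 32.0), sigma=6.0, amplitude=1.0),),
        noise_sd=0.0,
        seed=seed,
    )


def _frame_rng(config: FixtureConfig, counter: int = 0) -> np.random.Generator:
    """Per-frame generator split from the config seed by counter."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(counter,))
    )


def make_blob_image(config: FixtureConfig, frame_counter: int = 0) -> ScalarImage2D:
    """Render a sum of Gaussian bumps plus seeded Gaussian noise."""
    yy, xx = np.mgrid[0 : config.height, 0 : config.width].astype(float)
    img = np.zeros((config.height, config.width))
    for b in config.blobs:
        cx, cy = b.center
        img += b.amplitude * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * b.sigma**2)
        )
    if config.noise_sd > 0:
        img += _frame_rng(config, frame_counter).normal(
            0.0, config.noise_sd, img.shape
        )
    return ScalarImage2D(img, source=f"<fixture seed={config.seed}>")


def _jittered(config: FixtureConfig, rng: np.random.Generator) -> FixtureConfig:
    """Displace every blob center by a seeded offset of at least 3 px."""
    blobs = []
    for b in config.blobs:
        ang = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(3.0, 6.0)
        cx = float(np.clip(b.center[0] + r * np.cos(ang), 1, config.width - 2))
        cy = float(np.clip(b.center[1] + r * np.sin(ang), 1, config.height - 2))
        blobs.append(replace(b, center=(cx, cy)))
    return replace(config, blobs=tuple(blobs))


def _frame_descriptors(
    img: ScalarImage2D, idx: int, seeding: SeedingConfig
) -> list[MNCDescriptor]:
    g = compute_gradient(img)
    pts = select_generating_points(g, seeding)
    tiling = build_tessellation(pts, (img.width, img.height))
    return describe_frame(tiling, frame_index=idx)


def _frames_collide(
    a: list[MNCDescriptor], b: list[MNCDescriptor], tol: float
) -> bool:
    return any(
        circular_angle_diff(da.nucleus_theta, db.nucleus_theta) <= tol
        and da.degree == db.degree
        for da in a
        for db in b
    )


def make_repeat_sequence(
    n_frames: int,
    repeat_pairs: list[tuple[int, int]],
    base: FixtureConfig | None = None,
    *,
    tol: float = 2.0,
    ensure_distinct: bool = True,
    seeding: SeedingConfig | None = None,
    max_rejitter: int = 50,
) -> list[ScalarImage2D]:
    """Frame sequence with planted repeats at ``repeat_pairs``.

    Frames at the paired indices are byte-identical copies of the base
    image; all other frames are jitters of it (blob centers displaced by
    seeded offsets >= 3 px).  With ``ensure_distinct`` (the default) the
    generator verifies that no non-planted frame pair carries a matching
    MNC description at tolerance ``tol`` with exact degree equality,
    re-jittering colliding frames deterministically until the planted
    pairs are the only matches.
    """
    base = base or default_fixture_config()
    seeding = seeding or SeedingConfig()
    members: dict[int, set[int]] = {}
    for i, j in repeat_pairs:
        if not (0 <= i < n_frames and 0 <= j < n_frames) or i == j:
            raise ValueError(f"invalid repeat pair ({i}, {j})")
        group = members.setdefault(i, {i})
        if j in members and members[j] is not group and members[j] != {j}:
            raise ValueError(f"overlapping pair constraints at frame {j}")
        group.add(j)
        members[j] = group

    planted = {idx for g in members.values() for idx in g}
    frames: list[ScalarImage2D | None] = [None] * n_frames
    base_img = make_blob_image(base, frame_counter=0)
    for idx in planted:
        frames[idx] = base_img

    counter = 1
    for idx in range(n_frames):
        if frames[idx] is None:
            cfg = _jittered(base, _frame_rng(base, counter))
            frames[idx] = make_blob_image(cfg, frame_counter=counter)
            counter += 1

    if ensure_distinct:
        desc = [_frame_descriptors(f, i, seeding) for i, f in enumerate(frames)]
        same_group = {
            (min(i, j), max(i, j))
            for g in members.values()
            for i in g
            for j in g
            if i != j
        }
        for _ in range(max_rejitter):
            bad = None
            for i in range(n_frames):
                for j in range(i + 1, n_frames):
                    if (i, j) in same_group:
                        continue
                    if _frames_collide(desc[i], desc[j], tol):
                        bad = j if j not in planted else i
                        break
                if bad is not None:
                    break
            if bad is None:
                break
            if bad in planted:
                raise RuntimeError(
                    "a planted frame collides with another planted group"
                )
            cfg = _jittered(base, _frame_rng(base, counter))
            frames[bad] = make_blob_image(cfg, frame_counter=counter)
            desc[bad] = _frame_descriptors(frames[bad], bad, seeding)
            counter += 1
        else:
            raise RuntimeError("could not separate jittered frames beyond tol")
    return frames  # type: ignore[return-value]


def make_translating_sequence(
    n_frames: int,
    dx_per_frame: float,
    base: FixtureConfig | None = None,
) -> list[ScalarImage2D]:
    """Sequence whose dominant (first) blob translates dx px per frame.

    Noise (when the base config has any) is reseeded per frame from the
    shared stream.  Raises when the trajectory would leave the image.
    Defaults to the noise-free single-blob trajectory base (see
    default_trajectory_config for why).
    """
    base = base or default_trajectory_config()
    if not base.blobs:
        raise ValueError("base config needs at least one blob")
    x0, y0 = base.blobs[0].center
    x_end = x0 + dx_per_frame * (n_frames - 1)
    if not (0 <= x_end < base.width):
        raise ValueError("translated blob leaves the image bounds")
    frames = []
    for k in range(n_frames):
        blobs = (
            replace(base.blobs[0], center=(x0 + dx_per_frame * k, y0)),
        ) + base.blobs[1:]
        cfg = replace(base, blobs=blobs)
        frames.append(make_blob_image(cfg, frame_counter=k))
    return frames
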