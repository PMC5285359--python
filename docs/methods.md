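# Methods

This note records the modelling and numerical choices behind `mnctess`,
what the synthetic fixtures do and do not emulate, and the limitations we
know about.

## Coordinates and gradients

Pixel coordinates are `x` = column, `y` = row, 0-based, origin top-left.
A pixel `(x, y)` seeds geometry at its center `(x + 0.5, y + 0.5)`, so
border-pixel seeds lie strictly inside the image rectangle
`[0, W] × [0, H]`.

Partial derivatives are estimated by central differences on interior
pixels and one-sided differences at borders (the `np.gradient` stencil).
No smoothing or normalization is applied: the orientation angle is
invariant to intensity rescaling, and any pre-filtering belongs upstream
of this package. The orientation `θ = atan2(Gy, Gx)` is folded into
`[−90°, 90°)` — orientations are line-like with period 180°, and the
two-argument form extends `arctan(Gy/Gx)` continuously through `Gx = 0`.
Pixels with an exactly zero gradient vector carry no orientation
(`defined = False`); a constant image therefore has an empty seed pool
rather than being an error at the gradient stage.

## Seeding

"Unique gradient-orientation angle" is not decidable on float angles
(they are almost surely pairwise distinct), so uniqueness is made
operational by quantizing the 180° range into `bins` equal bins.

* `bins = 1024` by default: fine enough (≈0.18°/bin) that bin-uniqueness
  approximates angle-uniqueness, coarse enough that the weeding rule
  actually removes pixels.
* `strict` mode implements the literal weeding: keep pixels whose bin is
  occupied exactly once. On smooth synthetic images this can annihilate
  the seed set (a pure linear ramp occupies one bin with every pixel and
  raises `FewerThanMinPoints`).
* `representative` mode (default) keeps the largest-gradient-magnitude
  pixel of every occupied bin — still one seed per bin, hence still a
  unique descriptor per region, but robust on images with repeated
  structure.
* `max_points = 300` caps diagram complexity; the cap keeps the
  largest-magnitude seeds because strong gradients mark the
  structure-bearing parts of the image. All ties break on smallest
  `(y, x)`; seeding contains no randomness.

## Bounded Voronoï tiling

The diagram is computed by `scipy.spatial.Voronoi` on the seed set
augmented with its mirror images across the four boundary lines of the
image rectangle. The bisector between a seed and its mirror is the
boundary line itself, so the cells of the original seeds are *exactly*
the rectangle-clipped cells — no explicit polygon clipping, no
approximation. Cells are convex by construction; vertices are stored
counter-clockwise starting at the lexicographically smallest vertex so
exports are bit-stable.

Adjacency ("strongly near") requires a shared boundary edge longer than
`ε_edge = 1e−9` px, read directly off the Voronoï ridge between two
original seeds. Vertex-only contact — e.g. four co-circular seeds whose
bisectors meet in a point — is explicitly not adjacency. All geometric
point-equality tests use the same 1e−9 px tolerance. Areas are shoelace
sums; the areas of every tiling partition the rectangle to ≤1e−6
relative error (measured ≈1e−15 in practice).

Maximality ties are preserved: every nucleus attaining the maximum
degree is returned, ordered by `(y, x)` of the nucleus seed. Clusters
are reported separately even when they overlap; intersection of their
region-id sets is available as a plain set operation
(`NucleusCluster.region_ids`), with no further interpretation attached.

## Entropy model

`H_β(X) = (1/(1−β)) log₂ Σ pᵢ^β`, evaluated in log-space
(`logsumexp`) so large sets and large β cannot underflow. β must be
positive and ≠ 1; the Shannon limit is provided separately and the sweep
default is the grid 1.1 … 2.5 in steps of 0.1.

The occurrence probability of a polygon is modelled from its area `A`
in square pixels — area is the only polygon magnitude the profile
compares, and regions below one square pixel are rejected as degenerate.
Two variants exist:

* **`inverse-area` (default): `p = 1/A`, unnormalized.** The vector sums
  past 1 for large sets; that is intentional. Both the size of a polygon
  set and its area magnitudes then enter `H_β`, and the MNC set (few
  polygons, bounded total weight) scores consistently above the much
  larger non-MNC remainder — the directionality the profile is meant to
  exhibit, which holds at every β on every image of the canonical
  fixture suite.
* **`inverse-area-normalized`: `p = (1/A)/Σ(1/Aⱼ)` within the profiled
  set.** The textbook entropy properties hold only here (uniform vector
  → `log₂ n`; `H_β` non-increasing in β), so this variant backs the
  property tests. But normalization makes the vector invariant to
  rescaling all areas — area *magnitudes* cannot influence it, only the
  shape of the area distribution — and `H_β` is then dominated by set
  size: a ~10-polygon MNC set can essentially never out-score a
  ~290-polygon remainder. The normalized variant is therefore the wrong
  instrument for the MNC-vs-surround comparison and is not the default;
  it remains available and config-exposed.

## Temporal analysis

An MNC's feature vector is (nucleus orientation angle, adjacency degree,
centroid, nucleus area). Matching between frames deliberately uses only
the first two — features, not positions: two frames match when some MNC
of each agrees in angle within `tol` (default 2°, circular difference on
the folded 180° range) and, by default, exactly in degree. Matching is
symmetric and monotone in `tol`.

Antipodal pairing places the `n` frames uniformly on a circle in time
order. Even `n`: the exact matching `(i, i + n/2)`. Odd `n`: no pair
sits at 180°, so the completion minimizes total deviation from 180°
with each frame used at most once; all minimal pairs sit at circular
offset `(n±1)/2`, and the lexicographically smallest optimum — pair
each unpaired `i` with `i + (n−1)/2` — is returned deterministically
(verified against exhaustive search for odd `n ≤ 15`).

Trajectories report the principal MNC per frame (highest degree, then
lexicographic nucleus) in time order.

## Synthetic fixtures

Fixtures are sums of isotropic Gaussian bumps plus seeded Gaussian
noise, 64×64 px by default. Gaussian bumps have radial gradients, so the
orientation field and hence the seeding are analytically predictable,
and mild noise (`sd = 0.01` against unit-amplitude bumps) spreads
orientations over the quantization bins the way texture does in real
images. Randomness comes from one seed stream split per frame by
counter, so outputs are independent of call order. The canonical suite
is 20 three-blob images, seeds 0–19, default configuration.

Sequence fixtures plant ground truth:

* `make_repeat_sequence` copies the base frame to the planted index
  pairs and jitters every other frame's blob centers by ≥3 px; it then
  verifies (and deterministically re-jitters until) no non-planted frame
  pair matches at the default tolerance, so downstream matching must
  achieve precision = recall = 1 on the planted pairs.
* `make_translating_sequence` moves the first blob by `dx` px/frame.
  Its canonical base is a single noise-free blob: the maximal-degree
  nucleus is a discrete argmax, and independently reseeded per-frame
  noise relocates it non-locally between near-tied cells (observed
  displacement errors of ±10–25 px at any tested noise level), which
  would swamp a planted drift of a few px/frame. With the noise-free
  base the recovered trajectory is exact for integer `dx` and within
  the tessellation-jitter tolerance (±1.5 px median) for sub-pixel
  `dx`, where the blob is resampled at a different pixel phase each
  frame.

What passing these fixtures does **not** show: performance on real fMRI
frames — which have anisotropic anatomy, spatially correlated noise,
acquisition artifacts and registration error, none of which the
generator emulates. The fixtures validate the geometry, the entropy
arithmetic and the temporal bookkeeping, not the neuroscience.

## Known limitations

* **MNC stability.** The maximal-degree nucleus is sensitive to any
  perturbation that changes the seed set: degree is integer-valued, ties
  and near-ties are common, and the argmax can jump across the image
  between consecutive noisy frames. Trajectory analyses of real
  sequences should expect this and may need descriptor-based smoothing
  upstream; this package reports the raw argmax.
* **Strict seeding fragility.** Literal uniqueness weeding can leave too
  few seeds on synthetic or heavily quantized images; representative
  mode is the practical default.
* The Borsuk–Ulam motivation for antipodal analysis, 4D/quaternionic
  trajectory interpretation, and any comparison against BOLD activation
  maps are outside this package's scope: it computes and exports the
  tessellation, entropy and temporal quantities those interpretations
  would consume.
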