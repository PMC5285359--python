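"""Renyi entropy of MNC vs non-MNC polygon sets.

The information carried by a set of tessellation polygons is measured by
the Renyi entropy of order beta (beta > 0, beta != 1):

    H_beta(X) = 1 / (1 - beta) * log2( sum_i p(x_i)^beta )   [bits]

with the occurrence probability of a polygon modelled from its area A in
square pixels:

* ``inverse-area``             p = 1 / A  — the literal occurrence model
  (default).  The values need not sum to 1 across the set; that is
  intentional, and it is what lets both the set's size and its area
  magnitudes enter the comparison.  Under this model the MNC set is
  consistently the higher-entropy one.
* ``inverse-area-normalized``  p = (1/A) / sum_j (1/A_j) over the set
  being profiled.  The standard entropy properties (uniform vector gives
  log2 n; H non-increasing in beta) hold only here, so this variant backs
  the property checks — but note it is invariant to rescaling all areas,
  so it measures only the *shape* of the area distribution and is
  dominated by set size when the two sets differ greatly in count.

``entropy_profile`` sweeps beta over a grid (default 1.1 to 2.5, step 0.1)
for the MNC polygon set (every region belonging to any maximal cluster,
nucleus plus adjacent) against the complementary non-MNC set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .tessellation import NucleusCluster, VoronoiTiling, region_area

__all__ = [
    "ProbabilityVector",
    "EntropyProfile",
    "default_beta_grid",
    "region_probability",
    "renyi_entropy",
    "shannon_entropy",
    "entropy_profile",
    "mnc_region_ids",
]

PROB_MODELS = ("inverse-area", "inverse-area-normalized")


@dataclass(frozen=True)
class ProbabilityVector:
    """Occurrence probabilities p(x_i) in (0, 1], optionally summing to 1."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("probability vector must be non-empty and 1D")
        if np.any(v <= 0.0) or np.any(v > 1.0 + 1e-12):
            raise ValueError("probabilities must lie in (0, 1]")
        if self.normalized and abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("vector flagged normalized but does not sum to 1")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EntropyProfile:
    """H_beta curves (bits) for the MNC and non-MNC polygon sets."""

    betas: np.ndarray
    h_mnc: np.ndarray
    h_nonmnc: np.ndarray
    model: str
    n_mnc: int
    n_nonmnc: int
    mnc_areas: np.ndarray
    nonmnc_areas: np.ndarray


def default_beta_grid() -> np.ndarray:
    """The canonical sweep 1.1 <= beta <= 2.5, step 0.1 (15 values)."""
    return np.round(np.arange(11, 26) * 0.1, 10)


def region_probability(areas, model: str = "inverse-area"):
    """Occurrence probabilities for polygon areas under the chosen model.

    Areas below 1 square pixel signal a degenerate tiling and are
    rejected: the literal 1/A model would then exceed probability 1.
    """
    a = np.atleast_1d(np.asarray(areas, dtype=float))
    if np.any(a < 1.0):
        raise ValueError("region area < 1 square pixel: degenerate tiling")
    inv = 1.0 / a
    if model == "inverse-area":
        return ProbabilityVector(inv, normalized=False)
    if model == "inverse-area-normalized":
        return ProbabilityVector(inv / inv.sum(), normalized=True)
    raise ValueError(f"unknown probability model {model!r}")


def renyi_entropy(p: ProbabilityVector | np.ndarray, beta: float) -> float:
    """Renyi entropy of order beta, in bits, computed in log-space."""
    if not isinstance(p, ProbabilityVector):
        p = ProbabilityVector(np.asarray(p, dtype=float))
    if beta <= 0.0 or beta == 1.0:
        raise ValueError("beta must be > 0 and != 1 (use shannon_entropy at 1)")
    log_sum = logsumexp(beta * np.log(p.values))
    return float(log_sum / np.log(2.0) / (1.0 - beta))


def shannon_entropy(p: ProbabilityVector | np.ndarray) -> float:
    """Shannon entropy -sum p log2 p in bits; requires a normalized vector.

    This is the beta -> 1 limit of the Renyi entropy and serves as a
    property check for the sweep.
    """
    if not isinstance(p, ProbabilityVector):
        p = ProbabilityVector(np.asarray(p, dtype=float), normalized=True)
    if not p.normalized:
        raise ValueError("shannon_entropy requires a normalized vector")
    v = p.values
    return float(-(v * np.log2(v)).sum())


def mnc_region_ids(mncs: list[NucleusCluster]) -> frozenset[int]:
    """Union of region ids over all maximal clusters (nucleus + adjacent)."""
    ids: frozenset[int] = frozenset()
    for c in mncs:
        ids |= c.region_ids
    return ids


def entropy_profile(
    tiling: VoronoiTiling,
    mncs: list[NucleusCluster],
    betas=None,
    model: str = "inverse-area",
) -> EntropyProfile:
    """Sweep H_beta for the MNC region set against the non-MNC complement.

    Raises ValueError when every region belongs to an MNC (the comparison
    set would be empty) or when there is no maximal cluster.
    """
    if not mncs:
        raise ValueError("no maximal nucleus clusters supplied")
    if model not in PROB_MODELS:
        raise ValueError(f"unknown probability model {model!r}")
    betas = default_beta_grid() if betas is None else np.asarray(betas, dtype=float)
    if betas.size == 0 or np.any(np.diff(betas) <= 0):
        raise ValueError("betas must be non-empty and strictly increasing")
    if np.any(betas <= 0) or np.any(betas == 1.0):
        raise ValueError("betas must be > 0 and != 1")

    in_mnc = mnc_region_ids(mncs)
    all_ids = range(tiling.n_regions)
    mnc_areas = np.array([region_area(tiling, i) for i in sorted(in_mnc)])
    non_ids = [i for i in all_ids if i not in in_mnc]
    if not non_ids:
        raise ValueError("all regions belong to MNCs; non-MNC set is empty")
    non_areas = np.array([region_area(tiling, i) for i in non_ids])

    p_mnc = region_probability(mnc_areas, model)
    p_non = region_probability(non_areas, model)
    h_mnc = np.array([renyi_entropy(p_mnc, b) for b in betas])
    h_non = np.array([renyi_entropy(p_non, b) for b in betas])
    return EntropyProfile(
        betas=betas,
        h_mnc=h_mnc,
        h_nonmnc=h_non,
        model=model,
        n_mnc=len(mnc_areas),
        n_nonmnc=len(non_areas),
        mnc_areas=mnc_areas,
        nonmnc_areas=non_areas,
    )
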