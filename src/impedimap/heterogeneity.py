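"""Mixed-population composition scoring from pixel-level motility distributions.

A co-culture of an epithelial (low-motility) and a mesenchymal
(high-motility) population produces a per-pixel normalized-RMS distribution
that interpolates between the two pure-population distributions.  The
composition is scored by the first-order 1-D Wasserstein (earth mover's)
distance of the pooled experimental sample to each pure reference sample:

    s_a = d(exp, ref_b) / (d(exp, ref_a) + d(exp, ref_b)),   s_b = 1 - s_a

so that a sample identical to reference A scores ``s_a = 1`` and an
equidistant 50/50 mixture scores 0.5 for both.  Scores from the first hours
after plating are flagged: the attachment transient dominates motility there
and the model is not predictive until about +5 h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import wasserstein_distance

__all__ = [
    "PopulationDistribution",
    "SimilarityTrace",
    "wasserstein_1d",
    "similarity_scores",
    "mixture_trajectory",
    "pool_wells",
]

#: Default number of wells pooled per empirical condition distribution.
WELLS_PER_CONDITION = 3
#: Earliest trusted time after plating (hours).
DEFAULT_VALIDITY_START_H = 5.0


@dataclass
class PopulationDistribution:
    """Pooled per-pixel sample for one condition at one timepoint."""

    well_ids: tuple[str, ...]
    time_h: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError("population sample is empty")
        if np.any(v < 0):
            raise ValueError("normalized RMS samples must be non-negative")
        self.values = v


@dataclass
class SimilarityTrace:
    """Similarity scores of an experimental condition to two pure references
    over time; ``s_ref_a + s_ref_b = 1`` at every timepoint."""

    times_h: np.ndarray
    s_ref_a: np.ndarray
    s_ref_b: np.ndarray
    validity_start_h: float = DEFAULT_VALIDITY_START_H

    def valid(self) -> np.ndarray:
        return self.times_h >= self.validity_start_h


def wasserstein_1d(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """First-order 1-D Wasserstein distance between two empirical samples."""
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    return float(wasserstein_distance(a, b))


def similarity_scores(
    exp: np.ndarray | PopulationDistribution,
    ref_a: np.ndarray | PopulationDistribution,
    ref_b: np.ndarray | PopulationDistribution,
) -> tuple[float, float]:
    """Complement-of-ratio similarity of an experimental sample to two references.

    Returns ``(s_a, s_b)`` with ``s_a = d(exp, ref_b) / (d_a + d_b)`` and
    ``s_b = 1 - s_a``; degenerate zero-distance-to-both inputs return
    ``(0.5, 0.5)`` with a warning.
    """

    def _vals(x):
        return x.values if isinstance(x, PopulationDistribution) else x

    d_a = wasserstein_1d(_vals(exp), _vals(ref_a))
    d_b = wasserstein_1d(_vals(exp), _vals(ref_b))
    if d_a == 0.0 and d_b == 0.0:
        warnings.warn("experimental sample is identical to both references", stacklevel=2)
        return 0.5, 0.5
    s_a = d_b / (d_a + d_b)
    return float(s_a), float(1.0 - s_a)


def pool_wells(
    pixel_samples: dict[str, np.ndarray],
    wells: list[str],
    time_index: int,
) -> np.ndarray:
    """Concatenate one timepoint's pixel samples across wells (no weighting)."""
    parts = []
    for w in wells:
        arr = np.asarray(pixel_samples[w], dtype=float)
        vals = arr[time_index].ravel()
        parts.append(vals[np.isfinite(vals)])
    return np.concatenate(parts)


def mixture_trajectory(
    pixel_samples: dict[str, np.ndarray],
    exp_wells: list[str],
    ref_a_wells: list[str],
    ref_b_wells: list[str],
    times_h: np.ndarray,
    validity_start_h: float = DEFAULT_VALIDITY_START_H,
) -> SimilarityTrace:
    """Score an experimental condition against two pure-population references
    at every timepoint.

    ``pixel_samples`` maps well -> array of shape ``(n_times, n_pixels)`` of
    per-pixel normalized RMS values.  Reference wells must be disjoint from
    the experimental wells (no leakage).
    """
    overlap = set(exp_wells) & (set(ref_a_wells) | set(ref_b_wells))
    if overlap:
        raise ValueError(f"reference wells overlap experimental wells: {sorted(overlap)}")
    if set(ref_a_wells) & set(ref_b_wells):
        raise ValueError("the two reference conditions share wells")
    times_h = np.asarray(times_h, dtype=float)
    s_a = np.empty(len(times_h))
    s_b = np.empty(len(times_h))
    for i in range(len(times_h)):
        exp = pool_wells(pixel_samples, exp_wells, i)
        ra = pool_wells(pixel_samples, ref_a_wells, i)
        rb = pool_wells(pixel_samples, ref_b_wells, i)
        s_a[i], s_b[i] = similarity_scores(exp, ra, rb)
    return SimilarityTrace(
        times_h=times_h, s_ref_a=s_a, s_ref_b=s_b, validity_start_h=validity_start_h
    )
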