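"""Similarity and difference effect sizes for two groups on a bounded scale.

The central idea: Cohen's d, the standardized mean difference, can be
re-expressed as the overlap of two equal-variance normal densities shifted
by d standard deviations, OVL = 2*Phi(-|d|/2). Multiplied by 100 this is
the *percentage of common responses* (PCR), a similarity index on a 0-100
percent scale. Two companions cover what PCR misses:

* PCS (*percentage of common scores*) is the nonparametric analogue — the
  shared mass of the two empirical response distributions on a common
  category grid — and is robust to non-normality.
* AE (*absolute effect*) is the median difference expressed as a percentage
  of the maximum possible difference on the scale (a two-group
  generalization of the POMP rescaling), so it is sensitive to where on the
  scale both groups sit, which distribution-relative indices ignore.

All indices here are pure functions of the data; confidence intervals and
the similarity/difference decision rule live in :mod:`groupsim.inference`.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from scipy import stats

from .errors import DegenerateVarianceError
from .samples import GroupSample, ScaleSpec

__all__ = [
    "cohen_d",
    "pcr_from_d",
    "pcr",
    "pcs",
    "ae",
    "pomp",
    "probability_of_superiority",
]

Denominator = Literal["pooled", "average_sd"]


def _check_same_scale(a: GroupSample, b: GroupSample) -> None:
    if a.scale != b.scale:
        raise ValueError(
            f"groups {a.label!r} and {b.label!r} are on different scales"
        )


def cohen_d(a: GroupSample, b: GroupSample, denominator: Denominator = "pooled") -> float:
    """Standardized mean difference, signed as mean(a) - mean(b).

    Parameters
    ----------
    denominator
        ``"pooled"`` (default): pooled SD with n-1 weights, the Cohen (1988)
        convention. ``"average_sd"``: unweighted mean of the two SDs.

    Raises
    ------
    DegenerateVarianceError
        If both groups are constant, so the denominator is zero.
    """
    _check_same_scale(a, b)
    if a.n < 2 or b.n < 2:
        raise ValueError("cohen_d requires at least 2 observations per group")
    if denominator == "pooled":
        s = pooled_sd(a.sd, b.sd, a.n, b.n)
    elif denominator == "average_sd":
        s = (a.sd + b.sd) / 2.0
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if s == 0.0:
        raise DegenerateVarianceError(
            f"both groups ({a.label!r}, {b.label!r}) are constant; d is undefined"
        )
    return (a.mean - b.mean) / s


def pooled_sd(sd_a: float, sd_b: float, n_a: int, n_b: int) -> float:
    """Pooled standard deviation with n-1 weights."""
    return float(
        np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    )


def pcr_from_d(d):
    """Percentage of common responses implied by a standardized mean difference.

    For two normal densities with equal variance separated by ``d`` standard
    deviations, the overlapping coefficient is ``OVL = 2*Phi(-|d|/2)`` with
    ``Phi`` the standard normal CDF; PCR is ``100 * OVL``. Even in ``d``,
    strictly decreasing in ``|d|``, with ``pcr_from_d(0) == 100``.

    Accepts a scalar or array; returns a float for scalar input.
    """
    d = np.asarray(d, dtype=float)
    out = 100.0 * 2.0 * stats.norm.cdf(-np.abs(d) / 2.0)
    return float(out) if out.ndim == 0 else out


def pcr(a: GroupSample, b: GroupSample, denominator: Denominator = "pooled") -> float:
    """Percentage of common responses between two groups: ``pcr_from_d(cohen_d)``.

    Symmetric in argument order. Propagates the degenerate-variance error
    when both groups are constant.
    """
    return pcr_from_d(cohen_d(a, b, denominator=denominator))


def _relative_frequencies(values: np.ndarray, scale: ScaleSpec, n_bins: int) -> np.ndarray:
    counts, _ = np.histogram(values, bins=n_bins, range=(scale.minimum, scale.maximum))
    return counts / values.size


def pcs(a: GroupSample, b: GroupSample, n_bins: int | None = None) -> float:
    """Percentage of common scores: shared mass of the empirical distributions.

    Both samples are binned on a common grid of ``n_bins`` equal-width
    categories spanning the scale (default: the scale's number of response
    categories); the index is ``100 * sum_k min(f_A(k), f_B(k))`` over the
    per-category relative frequencies. Using relative frequencies controls
    for unequal group sizes; the common grid standardizes across
    response-scale lengths. Equals ``100 - 100*TV`` where TV is the total
    variation distance between the binned distributions.
    """
    _check_same_scale(a, b)
    if n_bins is None:
        n_bins = a.scale.n_categories
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    f_a = _relative_frequencies(a.values, a.scale, n_bins)
    f_b = _relative_frequencies(b.values, b.scale, n_bins)
    return float(100.0 * np.minimum(f_a, f_b).sum())


def ae(a: GroupSample, b: GroupSample) -> float:
    """Absolute effect: median difference as a percentage of the scale range.

    ``100 * |median(a) - median(b)| / (maximum - minimum)``; equivalently the
    absolute difference of the two groups' median POMP scores. Unlike d or
    PCR it is independent of the dispersion and the distribution shape, and
    it is 0 iff the medians coincide.
    """
    _check_same_scale(a, b)
    return 100.0 * abs(a.median - b.median) / a.scale.range


def pomp(x: float, scale: ScaleSpec) -> float:
    """Percentage of the maximum possible score: ``100*(x - min)/(max - min)``."""
    if not scale.contains(x):
        raise ValueError(
            f"x={x} outside scale bounds [{scale.minimum}, {scale.maximum}]"
        )
    return 100.0 * (x - scale.minimum) / scale.range


def probability_of_superiority(a: GroupSample, b: GroupSample) -> float:
    """P(random draw from a > random draw from b), ties counted half.

    Computed exactly over all ``n_a * n_b`` pairs (via sorted search, not
    materialized pairs). Satisfies ``ps(a, b) + ps(b, a) == 1``.
    """
    _check_same_scale(a, b)
    b_sorted = np.sort(b.values)
    wins = np.searchsorted(b_sorted, a.values, side="left").sum()
    wins_or_ties = np.searchsorted(b_sorted, a.values, side="right").sum()
    ties = wins_or_ties - wins
    return float((wins + 0.5 * ties) / (a.n * b.n))
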