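"""Bounded response scales and labeled group samples.

These are the two value objects everything else consumes: a
:class:`ScaleSpec` fixes the admissible range and granularity of a survey
response scale (e.g. a 6-point Likert item running 1..6), and a
:class:`GroupSample` holds one group's observed responses on that scale.
Missing data are resolved at ingest; a ``GroupSample`` never contains NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScaleSpec", "GroupSample"]


@dataclass(frozen=True)
class ScaleSpec:
    """Bounds and granularity of a bounded response scale.

    Parameters
    ----------
    minimum, maximum
        Lowest and highest admissible score, in scale units.
    n_categories
        Number of admissible item response options (>= 2). The admissible
        category values are ``n_categories`` equally spaced points from
        ``minimum`` to ``maximum`` inclusive.
    """

    minimum: float
    maximum: float
    n_categories: int

    def __post_init__(self) -> None:
        if not self.maximum > self.minimum:
            raise ValueError(
                f"scale maximum ({self.maximum}) must exceed minimum ({self.minimum})"
            )
        if self.n_categories < 2:
            raise ValueError(f"n_categories must be >= 2, got {self.n_categories}")

    @property
    def range(self) -> float:
        """Maximum possible difference on the scale."""
        return self.maximum - self.minimum

    @property
    def midpoint(self) -> float:
        return (self.minimum + self.maximum) / 2.0

    def category_values(self) -> np.ndarray:
        """The admissible category scores, equally spaced over the range."""
        return np.linspace(self.minimum, self.maximum, self.n_categories)

    def contains(self, x) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all((x >= self.minimum) & (x <= self.maximum)))


@dataclass(frozen=True)
class GroupSample:
    """One group's labeled responses on a bounded scale.

    ``values`` must be finite, non-empty and lie within the scale bounds.
    The array is copied and made read-only on construction.
    """

    label: str
    values: np.ndarray
    scale: ScaleSpec

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel().copy()
        if vals.size < 1:
            raise ValueError(f"group {self.label!r}: values must be non-empty")
        if not np.all(np.isfinite(vals)):
            raise ValueError(
                f"group {self.label!r}: values contain non-finite entries; "
                "resolve missingness before constructing a GroupSample"
            )
        if not self.scale.contains(vals):
            raise ValueError(
                f"group {self.label!r}: values fall outside the scale bounds "
                f"[{self.scale.minimum}, {self.scale.maximum}]"
            )
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        """Sample standard deviation (ddof=1); 0.0 for a single observation."""
        if self.n < 2:
            return 0.0
        return float(self.values.std(ddof=1))

    @property
    def median(self) -> float:
        return float(np.median(self.values))
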