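"""Display modes that emphasize similarity or difference between two groups.

The same two-group dataset can be drawn so that the reader sees mostly
overlap or mostly separation. This module implements both families so they
can be contrasted:

* similarity-emphasizing: two superimposed normal densities (parameterized
  by each group's mean and SD, overlap region shaded), superimposed
  relative-frequency histograms on a common grid, smoothed (KDE) overlays,
  and radar charts spanning the full scale range;
* difference-emphasizing: barplots of group means with error bars, either
  with the y-axis restricted to a narrow window around the means (the
  layout that visually inflates differences) or spanning the full scale.

Figures are rendered headlessly and written to PNG or SVG; every function
returns the matplotlib Figure so callers (and tests) can inspect axes and
artists before anything touches the filesystem.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from . import effect_sizes as es
from .samples import GroupSample, ScaleSpec

__all__ = ["PlotSpec", "plot_pair", "plot_radar", "restricted_ylimits"]

logger = logging.getLogger(__name__)

Mode = Literal[
    "superimposed_normals",
    "superimposed_histograms",
    "kde_overlay",
    "barplot_restricted",
    "barplot_unrestricted",
    "radar",
]

_COLORS = ("#1f77b4", "#d62728")


@dataclass(frozen=True)
class PlotSpec:
    """How to draw a two-group comparison.

    ``error_bars`` applies to the barplot modes: 95% confidence intervals
    (t-based, the conservative default), standard errors, or none.
    ``bins`` defaults to the scale's category count for histogram modes.
    ``annotate`` prints PCR / AE / d in the figure caption area.
    """

    mode: Mode
    error_bars: Literal["ci95", "se", "none"] = "ci95"
    bins: int | None = None
    annotate: bool = False
    y_limits: tuple[float, float] | None = None
    title: str | None = None
    xlabel: str | None = None

    def __post_init__(self) -> None:
        if self.bins is not None and self.bins < 2:
            raise ValueError("bins must be >= 2 for histogram modes")


def restricted_ylimits(a: GroupSample, b: GroupSample) -> tuple[float, float]:
    """Default restricted y-range for a barplot of the two group means.

    ``[min mean - 3*max SE, max mean + 3*max SE]``, snapped outward to the
    scale's category tick spacing — wide enough to contain the error bars,
    narrow enough to reproduce the visual exaggeration a truncated axis
    produces.
    """
    se = max(a.sd / math.sqrt(a.n), b.sd / math.sqrt(b.n))
    lo = min(a.mean, b.mean) - 3 * se
    hi = max(a.mean, b.mean) + 3 * se
    step = a.scale.range / (a.scale.n_categories - 1)
    lo = a.scale.minimum + math.floor((lo - a.scale.minimum) / step) * step
    hi = a.scale.minimum + math.ceil((hi - a.scale.minimum) / step) * step
    lo = max(lo, a.scale.minimum)
    hi = min(hi, a.scale.maximum)
    return (lo, hi)


def _error_bar(sample: GroupSample, kind: str) -> float:
    se = sample.sd / math.sqrt(sample.n)
    if kind == "se":
        return se
    if kind == "ci95":
        return float(stats.t.ppf(0.975, sample.n - 1) * se)
    return 0.0


def _annotation(a: GroupSample, b: GroupSample) -> str:
    try:
        d = es.cohen_d(a, b)
        pcr_txt = f"{es.pcr_from_d(d):.0f}"
        d_txt = f"{d:.2f}"
    except Exception:
        pcr_txt, d_txt = "n/a", "n/a"
    return f"PCR = {pcr_txt}, AE = {es.ae(a, b):.0f}, d = {d_txt}"


def plot_pair(
    a: GroupSample,
    b: GroupSample,
    spec: PlotSpec,
    path: str | Path | None = None,
):
    """Render one of the two-group display modes; optionally write to disk.

    Returns the matplotlib Figure. ``superimposed_normals`` falls back to
    histograms (with a logged warning) when either SD is zero, since a
    normal density is then degenerate.
    """
    scale = a.scale
    mode = spec.mode
    if mode == "superimposed_normals" and (a.sd == 0.0 or b.sd == 0.0):
        logger.warning(
            "degenerate SD in superimposed_normals; falling back to histograms"
        )
        mode = "superimposed_histograms"

    fig, ax = plt.subplots(figsize=(6, 4))
    if mode == "superimposed_normals":
        pad = 0.5 * scale.range / (scale.n_categories - 1)
        x = np.linspace(scale.minimum - pad, scale.maximum + pad, 512)
        da = stats.norm.pdf(x, a.mean, a.sd)
        db = stats.norm.pdf(x, b.mean, b.sd)
        ax.plot(x, da, color=_COLORS[0], label=a.label)
        ax.plot(x, db, color=_COLORS[1], label=b.label)
        ax.fill_between(x, np.minimum(da, db), color="grey", alpha=0.4,
                        label="overlap")
        ax.set_ylabel("density")
    elif mode == "superimposed_histograms":
        bins = spec.bins or scale.n_categories
        for sample, color in ((a, _COLORS[0]), (b, _COLORS[1])):
            ax.hist(
                sample.values,
                bins=bins,
                range=(scale.minimum, scale.maximum),
                weights=np.full(sample.n, 1.0 / sample.n),
                alpha=0.5,
                color=color,
                label=sample.label,
            )
        ax.set_ylabel("relative frequency")
    elif mode == "kde_overlay":
        x = np.linspace(scale.minimum, scale.maximum, 512)
        for sample, color in ((a, _COLORS[0]), (b, _COLORS[1])):
            kde = stats.gaussian_kde(sample.values, bw_method="silverman")
            ax.plot(x, kde(x), color=color, label=sample.label)
        ax.set_ylabel("density")
    elif mode in ("barplot_restricted", "barplot_unrestricted"):
        errs = [_error_bar(s, spec.error_bars) for s in (a, b)]
        yerr = errs if spec.error_bars != "none" else None
        ax.bar(
            [a.label, b.label],
            [a.mean, b.mean],
            yerr=yerr,
            capsize=6,
            color=_COLORS,
        )
        if mode == "barplot_unrestricted":
            ax.set_ylim(scale.minimum, scale.maximum)
        else:
            ax.set_ylim(*(spec.y_limits or restricted_ylimits(a, b)))
        ax.set_ylabel("mean")
    else:
        raise ValueError(f"unknown two-group plot mode {spec.mode!r}")

    if mode not in ("barplot_restricted", "barplot_unrestricted"):
        ax.legend()
        ax.set_xlabel(spec.xlabel or "response")
    if spec.title:
        ax.set_title(spec.title)
    if spec.annotate:
        fig.text(0.5, 0.012, _annotation(a, b), ha="center", fontsize=9)
        fig.subplots_adjust(bottom=0.18)
    if path is not None:
        fig.savefig(path)
    return fig


def plot_radar(
    values_by_group: Mapping[str, tuple[float, float]],
    scale: ScaleSpec,
    spec: PlotSpec | None = None,
    path: str | Path | None = None,
    labels: tuple[str, str] = ("A", "B"),
):
    """Radar chart of per-variable group means, one closed polygon per group.

    The radial axis spans the *full* scale range (its minimum is the scale
    minimum, not zero), so group polygons are shown against the maximum
    possible spread. Requires at least 3 variables.
    """
    variables = list(values_by_group)
    if len(variables) < 3:
        raise ValueError("radar charts need at least 3 variables")
    for var, (ma, mb) in values_by_group.items():
        if not (scale.contains(ma) and scale.contains(mb)):
            raise ValueError(f"variable {var!r}: means outside the scale bounds")
    angles = np.linspace(0, 2 * np.pi, len(variables), endpoint=False)
    angles_closed = np.concatenate([angles, angles[:1]])
    fig, ax = plt.subplots(figsize=(6, 6), subplot_kw={"projection": "polar"})
    for gi, label in enumerate(labels):
        vals = np.array([values_by_group[v][gi] for v in variables])
        vals_closed = np.concatenate([vals, vals[:1]])
        ax.plot(angles_closed, vals_closed, color=_COLORS[gi], label=label)
        ax.fill(angles_closed, vals_closed, color=_COLORS[gi], alpha=0.15)
    ax.set_xticks(angles)
    ax.set_xticklabels(variables)
    ax.set_ylim(scale.minimum, scale.maximum)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.05))
    if spec is not None and spec.title:
        ax.set_title(spec.title)
    if path is not None:
        fig.savefig(path)
    return fig
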