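"""Deterministic generators for Likert-type two-group and survey fixtures.

The two-group generator draws latent scores from normal distributions with
means ``mu +/- d*sigma/2`` (so the standardized mean difference between the
groups targets ``d``) and optionally discretizes them to the scale's
admissible categories by rounding, clipping at the bounds. This mirrors how
bounded ordinal survey responses are commonly modeled: a continuous latent
attitude cut into k ordered options.

The survey generator produces a whole respondent table shaped like a
multi-category social survey — several grouping columns (country, gender,
age band, ...) and many item columns — with controlled group mean shifts
injected per (category, variable), plus the matching declarative
configuration, so the pairwise comparison engine can be exercised end to
end without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .samples import GroupSample, ScaleSpec

__all__ = ["SynthSpec", "generate_pair", "generate_survey", "study1_shape"]


@dataclass(frozen=True)
class SynthSpec:
    """Settings for a two-group Likert draw with a target Cohen's d.

    ``mean`` defaults to the scale midpoint. With
    ``discretization="round_to_categories"`` latent draws are rounded to the
    nearest admissible category value and clipped at the bounds; with
    ``"none"`` they are only clipped at the bounds (for continuous-scale
    simulations).
    """

    scale: ScaleSpec
    n_a: int
    n_b: int
    target_d: float = 0.0
    latent_sd: float = 1.0
    mean: float | None = None
    discretization: Literal["round_to_categories", "none"] = "round_to_categories"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a < 1 or self.n_b < 1:
            raise ConfigError("group sizes must be positive")
        if self.latent_sd <= 0:
            raise ConfigError("latent_sd must be positive")


def _discretize(latent: np.ndarray, scale: ScaleSpec) -> np.ndarray:
    """Round latent draws to the nearest admissible category value."""
    step = scale.range / (scale.n_categories - 1)
    idx = np.round((latent - scale.minimum) / step)
    idx = np.clip(idx, 0, scale.n_categories - 1)
    return scale.minimum + idx * step


def generate_pair(spec: SynthSpec) -> tuple[GroupSample, GroupSample]:
    """Draw two labeled groups ("A", "B") with standardized mean difference d.

    Group A's latent mean is ``mu + d*sigma/2`` and B's is ``mu - d*sigma/2``
    so the signed d (A - B) targets ``spec.target_d``. Deterministic given
    the spec (single seeded generator).
    """
    mu = spec.scale.midpoint if spec.mean is None else spec.mean
    shift = spec.target_d * spec.latent_sd / 2.0
    mu_a, mu_b = mu + shift, mu - shift
    for m, lab in ((mu_a, "A"), (mu_b, "B")):
        if not spec.scale.contains(m):
            raise ConfigError(
                f"group {lab} latent mean {m} falls outside the scale bounds "
                f"[{spec.scale.minimum}, {spec.scale.maximum}]"
            )
    rng = np.random.default_rng(spec.seed)
    lat_a = rng.normal(mu_a, spec.latent_sd, spec.n_a)
    lat_b = rng.normal(mu_b, spec.latent_sd, spec.n_b)
    if spec.discretization == "round_to_categories":
        vals_a = _discretize(lat_a, spec.scale)
        vals_b = _discretize(lat_b, spec.scale)
    else:
        vals_a = np.clip(lat_a, spec.scale.minimum, spec.scale.maximum)
        vals_b = np.clip(lat_b, spec.scale.minimum, spec.scale.maximum)
    return (
        GroupSample("A", vals_a, spec.scale),
        GroupSample("B", vals_b, spec.scale),
    )


DEFAULT_SCALE = ScaleSpec(1, 6, 6)

#: Item-level noise SD as a fraction of the latent SD (keeps multi-item
#: composites internally consistent, alpha well above zero).
ITEM_NOISE_FRACTION = 0.5


def generate_survey(
    categories: Mapping[str, int | Sequence[str]],
    variables: Mapping[str, Mapping] | Sequence[str],
    effects: Mapping[str, Mapping[str, float]] | None = None,
    n_respondents: int | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a long respondent table plus a matching config mapping.

    Parameters
    ----------
    categories
        Mapping category name -> number of levels (labels auto-generated as
        ``<name>_01`` ...) or an explicit label sequence. Respondents are
        assigned to levels in (shuffled) balanced fashion, independently per
        category.
    variables
        Mapping variable name -> settings dict with optional keys
        ``n_items`` (default 1), ``scale`` (:class:`ScaleSpec`, default
        6-point 1..6), ``latent_sd`` (default 1.0). A plain sequence of
        names uses all defaults.
    effects
        ``{category: {variable: d}}``: within that category the group
        latent means are spread linearly across levels so the two extreme
        levels differ by ``d`` latent standard deviations.
    n_respondents
        Default: 40 x the largest number of levels across categories.
    missing_rate
        Probability that any single item response is missing (MCAR),
        to exercise pairwise deletion downstream.

    Returns
    -------
    (table, config_dict)
        ``table`` has one row per respondent with the grouping columns and
        one column per item. ``config_dict`` is the matching declarative
        survey configuration (loadable by
        :func:`groupsim.pairwise.SurveyConfig.from_dict`).
    """
    if isinstance(variables, (list, tuple)):
        variables = {name: {} for name in variables}
    effects = effects or {}
    for cat, per_var in effects.items():
        if cat not in categories:
            raise ConfigError(f"effects refer to unknown category {cat!r}")
        for var in per_var:
            if var not in variables:
                raise ConfigError(f"effects refer to unknown variable {var!r}")

    levels_by_cat: dict[str, list[str]] = {}
    for cat, spec in categories.items():
        if isinstance(spec, int):
            if spec < 1:
                raise ConfigError(f"category {cat!r}: level count must be >= 1")
            width = len(str(spec))
            levels_by_cat[cat] = [f"{cat}_{i + 1:0{width}d}" for i in range(spec)]
        else:
            levels_by_cat[cat] = [str(x) for x in spec]
    if n_respondents is None:
        n_respondents = 40 * max(len(v) for v in levels_by_cat.values())

    rng = np.random.default_rng(seed)
    table = pd.DataFrame(index=range(n_respondents))
    level_idx: dict[str, np.ndarray] = {}
    for cat, levels in levels_by_cat.items():
        idx = np.arange(n_respondents) % len(levels)
        rng.shuffle(idx)
        level_idx[cat] = idx
        table[cat] = np.asarray(levels, dtype=object)[idx]

    config_vars = {}
    for var, vspec in variables.items():
        scale: ScaleSpec = vspec.get("scale", DEFAULT_SCALE)
        n_items = int(vspec.get("n_items", 1))
        latent_sd = float(vspec.get("latent_sd", 1.0))
        latent = np.full(n_respondents, scale.midpoint)
        for cat, per_var in effects.items():
            d = per_var.get(var)
            if d is None:
                continue
            n_levels = len(levels_by_cat[cat])
            if n_levels < 2:
                raise ConfigError(
                    f"effect on category {cat!r} needs >= 2 levels"
                )
            # spread level means so the extremes differ by d latent SDs
            frac = level_idx[cat] / (n_levels - 1) - 0.5
            latent = latent + d * latent_sd * frac
        latent = latent + rng.normal(0.0, latent_sd, n_respondents)
        item_names = (
            [var] if n_items == 1 else [f"{var}_i{j + 1}" for j in range(n_items)]
        )
        item_sd = ITEM_NOISE_FRACTION * latent_sd
        for item in item_names:
            obs = latent if n_items == 1 else latent + rng.normal(
                0.0, item_sd, n_respondents
            )
            col = _discretize(obs, scale)
            if missing_rate > 0.0:
                mask = rng.random(n_respondents) < missing_rate
                col = col.astype(float)
                col[mask] = np.nan
            table[item] = col
        config_vars[var] = {
            "items": item_names,
            "scale": {
                "min": scale.minimum,
                "max": scale.maximum,
                "categories": scale.n_categories,
            },
            "reverse": [],
        }

    config = {
        "grouping": [{"name": cat} for cat in levels_by_cat],
        "variables": config_vars,
        "min_group_size": 30,
        "statistics": ["d", "pcr", "pcs", "ae"],
    }
    return table, config


def study1_shape(
    n_per_country: int = 150,
    n_variables: int = 22,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """A survey fixture shaped like a large multi-category values survey.

    Six grouping categories — 60 countries, 7 religious denominations,
    2 genders, 9 education levels, 10 income bands, 10 age cohorts — and
    ``n_variables`` 6-point variables, with a handful of injected group
    effects (strong country effects on two "moral attitude" variables,
    a moderate cohort effect on one value item) so the output has realistic
    heterogeneity. With all six categories this yields
    C(60,2) + C(7,2) + C(2,2) + C(9,2) + C(10,2) + C(10,2) = 1,918 group
    pairs per variable.
    """
    categories = {
        "country": 60,
        "religion": 7,
        "gender": ["female", "male"],
        "education": 9,
        "income": 10,
        "age_band": 10,
    }
    var_names = [f"var_{i + 1:02d}" for i in range(n_variables)]
    effects: dict[str, dict[str, float]] = {
        "country": {var_names[0]: 2.0},
        "age_band": {},
        "gender": {},
    }
    if n_variables >= 2:
        effects["country"][var_names[1]] = 1.0
    if n_variables >= 3:
        effects["age_band"][var_names[2]] = 1.0
    if n_variables >= 4:
        effects["gender"][var_names[3]] = 0.4
    effects = {cat: m for cat, m in effects.items() if m}
    return generate_survey(
        categories,
        var_names,
        effects=effects,
        n_respondents=60 * n_per_country,
        missing_rate=missing_rate,
        seed=seed,
    )
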