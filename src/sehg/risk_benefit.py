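"""Selenium–mercury molar scoring of foods.

Mercury binds selenium as biologically inert HgSe, so a food's value as a
selenium source depends on how much Se remains after stoichiometric (1:1
molar) sequestration by its Hg content. Two indices capture this on molar
concentrations (µmol/kg):

* the Se:Hg molar ratio, Se/Hg — above 1 means a molar Se surplus;
* the health benefit value of selenium,
  ``HBV_Se = (Se − Hg)/Se × (Se + Hg)``, which weights the surplus by the
  total Se + Hg burden and so does not explode for foods with trace Hg.
  Positive values indicate a net Se surplus, negative a net deficit.

Both are computed from *unrounded* category means; computing them from
rounded printed concentrations introduces last-digit artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import StudyConfig
from .records import FISH_SUBCATEGORIES, FoodSample


def to_molar(conc: float, molar_mass: float) -> float:
    """Convert a mass concentration (mg/kg) to µmol/kg.

    mg/kg ÷ g/mol × 1000 = µmol/kg.
    """
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be strictly positive, got {molar_mass}")
    if conc < 0:
        raise ValueError(f"concentration must be nonnegative, got {conc}")
    return conc * 1000.0 / molar_mass


def se_hg_ratio(se_molar: float, hg_molar: float) -> float:
    """Se:Hg molar ratio (dimensionless); > 1 indicates a molar Se surplus."""
    if hg_molar == 0:
        raise ZeroDivisionError("Se:Hg ratio undefined (no Hg)")
    return se_molar / hg_molar


def hbv_se(se_molar: float, hg_molar: float) -> float:
    """Health benefit value of Se: (Se − Hg)/Se × (Se + Hg), µmol/kg scale.

    Algebraically equals Se − Hg²/Se; collapses to Se when Hg = 0, and is
    strictly decreasing in Hg for fixed Se > 0.
    """
    if se_molar <= 0:
        raise ValueError("HBV_Se undefined (no Se)")
    return (se_molar - hg_molar) / se_molar * (se_molar + hg_molar)


@dataclass(frozen=True)
class CategorySummary:
    """Per-category concentration summary with molar scores.

    Molar moments are exact linear transforms of the mass moments, so the
    molar mean always equals mass mean × 1000 / molar mass. Ratio and HBV
    are computed from the unrounded molar means; a category with zero mean
    Hg reports ratio = +inf and HBV = Se.
    """

    category: str
    n: int
    se_mass_mean: float
    se_mass_sd: float
    se_molar_mean: float
    se_molar_sd: float
    hg_mass_mean: float
    hg_mass_sd: float
    hg_molar_mean: float
    hg_molar_sd: float
    ratio_se_hg: float
    hbv_se: float


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    # Sample SD (n−1), the convention for reported descriptive statistics;
    # a single observation reports SD 0.
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return mean, sd


def summarize_category(
    samples: Sequence[FoodSample],
    config: StudyConfig | None = None,
    label: str | None = None,
) -> CategorySummary:
    """Summarize one food category: mass/molar mean ± SD, Se:Hg ratio, HBV_Se.

    All samples must share one category label (pass ``label`` to summarize
    a fish sub-group under its own name). Nondetect substitutions made at
    read time enter the means like any other value.
    """
    if not samples:
        raise ValueError("cannot summarize an empty sample collection")
    categories = {s.category for s in samples}
    if len(categories) > 1:
        raise ValueError(f"mixed categories in one summary: {sorted(categories)}")
    config = config or StudyConfig()

    se_mass = np.array([s.se_conc for s in samples], dtype=float)
    hg_mass = np.array([s.hg_conc for s in samples], dtype=float)
    se_molar = np.array([to_molar(v, config.molar_mass_se) for v in se_mass])
    hg_molar = np.array([to_molar(v, config.molar_mass_hg) for v in hg_mass])

    se_mass_mean, se_mass_sd = _mean_sd(se_mass)
    hg_mass_mean, hg_mass_sd = _mean_sd(hg_mass)
    se_molar_mean, se_molar_sd = _mean_sd(se_molar)
    hg_molar_mean, hg_molar_sd = _mean_sd(hg_molar)

    if hg_molar_mean == 0:
        ratio = math.inf
        hbv = se_molar_mean  # formula limit as Hg → 0
    else:
        ratio = se_hg_ratio(se_molar_mean, hg_molar_mean)
        hbv = hbv_se(se_molar_mean, hg_molar_mean)

    return CategorySummary(
        category=label or samples[0].category,
        n=len(samples),
        se_mass_mean=se_mass_mean,
        se_mass_sd=se_mass_sd,
        se_molar_mean=se_molar_mean,
        se_molar_sd=se_molar_sd,
        hg_mass_mean=hg_mass_mean,
        hg_mass_sd=hg_mass_sd,
        hg_molar_mean=hg_molar_mean,
        hg_molar_sd=hg_molar_sd,
        ratio_se_hg=ratio,
        hbv_se=hbv,
    )


def summarize_panel(
    samples: Iterable[FoodSample],
    config: StudyConfig | None = None,
    include_fish_subgroups: bool = True,
    include_total: bool = True,
) -> list[CategorySummary]:
    """Summarize a whole food panel, one row per category.

    Fish samples carrying a marine/freshwater subcategory additionally get
    sub-group rows right after the pooled fish row; an all-panel "Total"
    row is appended last.
    """
    config = config or StudyConfig()
    samples = list(samples)
    by_category: dict[str, list[FoodSample]] = {}
    for s in samples:
        by_category.setdefault(s.category, []).append(s)

    summaries: list[CategorySummary] = []
    for category in sorted(by_category):
        group = by_category[category]
        summaries.append(summarize_category(group, config))
        if category == "Fish" and include_fish_subgroups:
            for sub in FISH_SUBCATEGORIES:
                subgroup = [s for s in group if s.subcategory == sub]
                if subgroup:
                    summaries.append(summarize_category(subgroup, config, label=sub))
    if include_total and samples:
        total = summarize_category(
            [s.model_copy(update={"category": samples[0].category, "subcategory": None}) for s in samples],
            config,
            label="Total",
        )
        summaries.append(total)
    return summaries
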