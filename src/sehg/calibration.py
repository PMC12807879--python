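"""Reference calibration values for the Taiwanese preschool-cohort food survey.

These constants are the default "study conditions" for the synthetic
generators and the worked examples: category-level Se/Hg summary statistics
for the 108-sample food panel (11 categories, wet-weight basis), the
cohort marginals (n = 349 children), per-category dietary-intake targets
expressed as percentages of the EFSA adequate Se intake (AI_Se = 20
µg/day), and the per-food growth-association effect sizes used as ground
truth in parameter-recovery simulations.

Two parallel concentration records are kept per category:

* mass-basis mean ± SD in mg/kg (used for intake, consumption-limit and
  servings arithmetic), and
* molar-basis mean ± SD in µmol/kg as published (used for the Se:Hg ratio
  and HBV_Se scores).

The published molar means were computed from unrounded mass means, so the
two bases are not bit-identical after rounding (the eggs row in particular
implies a Se molar mass of ~80.3 g/mol on the printed figures); keeping
both verbatim avoids compounding rounding error in either direction.

The per-category Hg intake implied by the published net-Se column is not
consistent with a single intake rate multiplied by the panel's mean Hg
concentration (the survey aggregated child-level, item-level intakes), so
``reference_exposure_inputs`` back-solves an *exposure-equivalent* Hg
concentration from the published net percentages instead of reusing the
panel Hg mean.
"""

from __future__ import annotations

from typing import NamedTuple

import pandas as pd


class CategoryStats(NamedTuple):
    """Per-category concentration summary (mass mg/kg, molar µmol/kg)."""

    n: int
    se_mass_mean: float
    se_mass_sd: float
    hg_mass_mean: float
    hg_mass_sd: float
    se_molar_mean: float
    se_molar_sd: float
    hg_molar_mean: float
    hg_molar_sd: float


#: Food-panel concentration summaries (wet weight). Keys are the controlled
#: category vocabulary plus the two fish sub-groups.
FOOD_CATEGORY_STATS: dict[str, CategoryStats] = {
    "Eggs": CategoryStats(6, 0.521, 0.045, 0.014, 0.004, 6.486, 0.570, 0.069, 0.021),
    "Fish": CategoryStats(13, 0.408, 0.192, 0.078, 0.072, 5.170, 2.710, 0.389, 0.359),
    "Marine fish": CategoryStats(9, 0.452, 0.199, 0.093, 0.081, 5.726, 2.520, 0.464, 0.404),
    "Freshwater fish": CategoryStats(4, 0.309, 0.149, 0.044, 0.033, 3.920, 1.887, 0.219, 0.165),
    "Fruits": CategoryStats(13, 0.002, 0.002, 0.005, 0.001, 0.020, 0.019, 0.023, 0.006),
    "Grains and related products": CategoryStats(10, 0.158, 0.186, 0.015, 0.010, 2.004, 2.362, 0.076, 0.048),
    "Leafy vegetables": CategoryStats(9, 0.006, 0.005, 0.005, 0.005, 0.075, 0.058, 0.022, 0.023),
    "Legumes and related products": CategoryStats(7, 0.086, 0.063, 0.009, 0.006, 1.094, 0.798, 0.043, 0.030),
    "Meat and meat products": CategoryStats(18, 0.255, 0.099, 0.011, 0.003, 3.232, 1.428, 0.055, 0.019),
    "Milk and dairy products": CategoryStats(10, 0.063, 0.055, 0.007, 0.004, 0.795, 0.706, 0.034, 0.022),
    "Non-leafy vegetables": CategoryStats(13, 0.028, 0.069, 0.004, 0.003, 0.353, 0.878, 0.020, 0.015),
    "Rice": CategoryStats(4, 0.036, 0.039, 0.025, 0.012, 0.460, 0.494, 0.122, 0.060),
    "Shellfish": CategoryStats(5, 0.306, 0.113, 0.022, 0.023, 3.878, 1.429, 0.108, 0.114),
}

#: Published population-level dietary Se adequacy per category, as
#: percentages of AI_Se = 20 µg/day: gross EDI_Se/AI and the net value after
#: subtracting the Hg intake mass ((EDI_Se − EDI_Hg)/AI).
AI_PERCENT_TARGETS: dict[str, tuple[float, float]] = {
    "Eggs": (86.86, 84.04),
    "Fish": (47.06, 37.61),
    "Fruits": (1.19, -2.53),
    "Grains and related products": (78.96, 71.33),
    "Leafy vegetables": (3.55, 0.54),
    "Legumes and related products": (16.29, 14.40),
    "Meat and meat products": (63.17, 60.20),
    "Milk and dairy products": (89.98, 79.94),
    "Non-leafy vegetables": (9.32, 7.98),
    "Rice": (6.86, 6.40),
    "Shellfish": (16.20, 15.03),
}

#: Cohort marginals (n = 349 preschool children).
COHORT_N = 349
HAIR_HG_MEAN = 1.11  # µg/g
HAIR_HG_SD = 1.15  # µg/g
MALE_FRACTION = 0.54
MEAN_AGE_YEARS = 2.9
INCOME_BANDS = ("<2300", "2300-3300", ">3300")  # US$/month
INCOME_PROBS = (0.289, 0.289, 0.421)
PARITY_LEVELS = (1, 2, 3)  # 3 encodes "3 or more"
PARITY_PROBS = (0.605, 0.345, 0.050)

#: Per-food height-association effect sizes (height outcome units per
#: percentage point of net AI_Se) used as default simulation ground truth.
TRUE_HEIGHT_BETAS: dict[str, float] = {
    "Fish": 0.01,
    "Eggs": 0.01,
    "Fruits": -0.41,
}


def reference_exposure_inputs(ai_se: float = 20.0) -> pd.DataFrame:
    """Back-solve population exposure inputs from the published AI percentages.

    Returns one row per category with the panel mean Se concentration
    (mg/kg), the exposure-equivalent Hg concentration (mg/kg), and the
    population mean intake rate (g/day) such that mean-concentration ×
    mean-intake reproduces the published gross and net AI percentages.
    """
    rows = []
    for category, (ai_pct, net_pct) in AI_PERCENT_TARGETS.items():
        stats = FOOD_CATEGORY_STATS[category]
        edi_se = ai_pct * ai_se / 100.0  # µg/day
        edi_hg = (ai_pct - net_pct) * ai_se / 100.0
        intake = edi_se / stats.se_mass_mean  # g/day (mg/kg ≡ µg/g)
        rows.append(
            {
                "category": category,
                "se_conc": stats.se_mass_mean,
                "hg_conc_equiv": edi_hg / intake,
                "intake_g_day": intake,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def reference_intake_means() -> dict[str, float]:
    """Population mean intake rate per category, g/day."""
    frame = reference_exposure_inputs()
    return frame["intake_g_day"].to_dict()
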