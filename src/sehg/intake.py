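"""Dietary intake assessment: EDI, AI percentages, hazard quotients, limits.

Core quantities per child (or per population) and food category:

* ``EDI = C_i × IR_i / BW`` — estimated daily intake of Se or THg in
  µg/kg-BW/day (concentration mg/kg × intake g/day / body weight kg); the
  body-weight-free total is ``C_i × IR_i`` in µg/day.
* AI percentage — gross Se intake as a percentage of the EFSA adequate
  intake (20 µg/day for preschool children).
* net Se surplus — EDI_Se − EDI_Hg in µg/day (mass basis by default; an
  optional molar-equivalent mode subtracts the Hg mass rescaled by the
  Se:Hg molar-mass ratio), and its AI percentage — the exposure variable
  of the growth models.
* ``HQ = EDI / RfD`` against the JECFA mercury reference dose
  (0.23 µg/kg-BW/day); HQ > 1 flags potential non-carcinogenic risk.
* ``CR_lim = RfD × BW / C_i`` (g/day) and ``CR_mm = CR_lim × T / MS``
  (portions/month) against the US EPA reference doses, under both the
  Taiwan exchange-serving and the US EPA 65-g fish-meal conventions.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import StudyConfig
from .records import ChildRecord, IntakeRecord
from .risk_benefit import CategorySummary

HG_TO_SE_MOLAR_EQUIV = 78.971 / 200.59  # µg Se per µg Hg at 1:1 molar binding


def edi(conc: float, intake_rate: float, bw: float) -> tuple[float, float]:
    """Estimated daily intake: (per-BW µg/kg-BW/day, total µg/day).

    mg/kg × g/day ≡ µg/day, divided by body weight (kg) for the per-BW dose.
    """
    if bw <= 0:
        raise ValueError(f"body weight must be strictly positive, got {bw}")
    if conc < 0 or intake_rate < 0:
        raise ValueError("concentration and intake rate must be nonnegative")
    total = conc * intake_rate
    return total / bw, total


def ai_percent(edi_se_total: float, ai: float) -> float:
    """Daily Se intake as a percentage of the adequate intake (µg/day basis)."""
    if ai <= 0:
        raise ValueError(f"adequate intake must be strictly positive, got {ai}")
    return 100.0 * edi_se_total / ai


def net_se(edi_se_total: float, edi_hg_total: float, molar_equivalent: bool = False) -> float:
    """Net Se surplus after Hg, µg/day (may be negative).

    Mass-based subtraction by default; with ``molar_equivalent`` the Hg
    term is rescaled to the Se mass it can sequester at 1:1 molar binding.
    """
    if edi_se_total < 0 or edi_hg_total < 0:
        raise ValueError("EDI inputs must be nonnegative")
    hg_term = edi_hg_total * HG_TO_SE_MOLAR_EQUIV if molar_equivalent else edi_hg_total
    return edi_se_total - hg_term


def hazard_quotient(edi_bw: float, rfd: float) -> float:
    """HQ = EDI / RfD on matching µg/kg-BW/day units; > 1 flags risk."""
    if rfd <= 0:
        raise ValueError(f"reference dose must be strictly positive, got {rfd}")
    return edi_bw / rfd


def hq_flagged(hq: float) -> bool:
    """Risk flag: strictly greater than 1 (HQ = 1 exactly is not flagged)."""
    return hq > 1.0


def cr_lim(rfd: float, bw: float, conc: float) -> float:
    """Maximum safe daily intake of a food, g/day.

    ``rfd`` in mg/kg/day (US EPA convention), ``bw`` kg, ``conc`` mg/kg;
    rfd × bw / conc is kg/day, scaled to g/day.
    """
    if conc <= 0:
        raise ValueError("limit unbounded: concentration must be strictly positive")
    if bw <= 0:
        raise ValueError(f"body weight must be strictly positive, got {bw}")
    if rfd < 0:
        raise ValueError(f"reference dose must be nonnegative, got {rfd}")
    return rfd * bw / conc * 1000.0


def cr_mm(cr_lim_g_day: float, days: float, portion: float) -> float:
    """Monthly safe consumption limit in portions/month: CR_lim × T / MS."""
    if portion <= 0:
        raise ValueError(f"portion size must be strictly positive, got {portion}")
    if cr_lim_g_day < 0 or days <= 0:
        raise ValueError("CR_lim must be nonnegative and days strictly positive")
    return cr_lim_g_day * days / portion


def servings_to_meet_ai(ai: float, conc: float, serving: float, whole_units: bool = False) -> float:
    """Daily servings of a food needed to meet the Se adequate intake.

    ai µg/day ÷ (conc mg/kg ≡ µg/g × serving g). With ``whole_units`` the
    result is rounded up to the next whole practical unit (e.g. "one egg").
    """
    if conc <= 0 or serving <= 0:
        raise ValueError("concentration and serving size must be strictly positive")
    servings = ai / (conc * serving)
    return float(math.ceil(servings)) if whole_units else servings


def nutrient_profile_at_ai(servings: float, nutrient_table: Mapping[str, float]) -> dict[str, float]:
    """Scale per-serving nutrient amounts to the servings meeting the AI."""
    if servings < 0:
        raise ValueError(f"servings must be nonnegative, got {servings}")
    for name, amount in nutrient_table.items():
        if amount < 0:
            raise ValueError(f"nutrient amount for {name!r} must be nonnegative, got {amount}")
    return {name: amount * servings for name, amount in nutrient_table.items()}


# ---------------------------------------------------------------------------
# table-level assessments


def _conc_lookup(
    summaries: Sequence[CategorySummary] | pd.DataFrame,
) -> pd.DataFrame:
    """Normalize category concentrations to a frame with se_conc/hg_conc."""
    if isinstance(summaries, pd.DataFrame):
        frame = summaries
        if not {"se_conc", "hg_conc"} <= set(frame.columns):
            raise ValueError("concentration table needs se_conc and hg_conc columns")
        if "category" in frame.columns:
            frame = frame.set_index("category")
        return frame[["se_conc", "hg_conc"]]
    return pd.DataFrame(
        {
            "se_conc": {s.category: s.se_mass_mean for s in summaries},
            "hg_conc": {s.category: s.hg_mass_mean for s in summaries},
        }
    )


def population_exposure(
    summaries: Sequence[CategorySummary] | pd.DataFrame,
    intake_means: Mapping[str, float],
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Population-level exposure table: one row per category.

    Uses mean concentration × mean intake at the default body weight,
    mirroring the published population assessment. Columns: EDI totals
    (µg/day), per-BW doses, AI percentages (gross and net), net Se surplus
    and the JECFA-based mercury HQ.
    """
    config = config or StudyConfig()
    conc = _conc_lookup(summaries)
    rows = []
    for category, intake in intake_means.items():
        if category not in conc.index:
            raise KeyError(f"no concentration summary for category {category!r}")
        se_bw, se_total = edi(conc.at[category, "se_conc"], intake, config.default_bw)
        hg_bw, hg_total = edi(conc.at[category, "hg_conc"], intake, config.default_bw)
        net = net_se(se_total, hg_total)
        rows.append(
            {
                "category": category,
                "intake_g_day": intake,
                "edi_se_total": se_total,
                "edi_hg_total": hg_total,
                "edi_se_bw": se_bw,
                "edi_hg_bw": hg_bw,
                "ai_pct": ai_percent(se_total, config.ai_se),
                "net_se": net,
                "net_ai_pct": ai_percent(net, config.ai_se),
                "hq_hg": hazard_quotient(hg_bw, config.rfd_hg_jecfa),
            }
        )
    return pd.DataFrame(rows)


def per_child_exposure(
    summaries: Sequence[CategorySummary] | pd.DataFrame,
    intakes: Iterable[IntakeRecord] | pd.DataFrame,
    children: Sequence[ChildRecord] | None = None,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Per-child × category exposure table.

    Category concentrations come from the panel summaries; intakes are the
    tidy FFQ table. Body weight is each child's own weight when ``children``
    is given, otherwise the configured default. Columns as in
    :func:`population_exposure` plus child_id.
    """
    config = config or StudyConfig()
    conc = _conc_lookup(summaries)
    if isinstance(intakes, pd.DataFrame):
        intake_frame = intakes.copy()
    else:
        intake_frame = pd.DataFrame([r.model_dump() for r in intakes])
    missing = set(intake_frame["category"]) - set(conc.index)
    if missing:
        raise KeyError(f"no concentration summary for categories: {sorted(missing)}")

    out = intake_frame.merge(conc, left_on="category", right_index=True, how="left")
    if children is not None:
        bw_map = {c.child_id: c.weight for c in children}
        bw = out["child_id"].map(bw_map).fillna(config.default_bw)
    else:
        bw = pd.Series(config.default_bw, index=out.index)
    out["edi_se_total"] = out["se_conc"] * out["intake_rate"]
    out["edi_hg_total"] = out["hg_conc"] * out["intake_rate"]
    out["edi_se_bw"] = out["edi_se_total"] / bw
    out["edi_hg_bw"] = out["edi_hg_total"] / bw
    out["ai_pct"] = 100.0 * out["edi_se_total"] / config.ai_se
    out["net_se"] = out["edi_se_total"] - out["edi_hg_total"]
    out["net_ai_pct"] = 100.0 * out["net_se"] / config.ai_se
    out["hq_hg"] = out["edi_hg_bw"] / config.rfd_hg_jecfa
    columns = [
        "child_id",
        "category",
        "edi_se_total",
        "edi_hg_total",
        "edi_se_bw",
        "edi_hg_bw",
        "ai_pct",
        "net_se",
        "net_ai_pct",
        "hq_hg",
    ]
    return out[columns]


def net_ai_wide(exposure: pd.DataFrame) -> pd.DataFrame:
    """Pivot a per-child exposure table to child × category net AI percentages."""
    return exposure.pivot(index="child_id", columns="category", values="net_ai_pct")


def consumption_limits(
    summaries: Sequence[CategorySummary] | pd.DataFrame,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Consumption-limit table: CR_lim and CR_mm per category × element.

    CR_mm is reported under the Taiwan exchange-serving convention for all
    categories and additionally under the US EPA 65-g meal convention for
    fish rows. Categories with zero mean concentration of an element are
    unbounded and omitted for that element.
    """
    config = config or StudyConfig()
    conc = _conc_lookup(summaries)
    rows = []
    for category in conc.index:
        if category == "Total":
            continue
        for element, col, rfd in (
            ("Hg", "hg_conc", config.rfd_hg_epa),
            ("Se", "se_conc", config.rfd_se_epa),
        ):
            c = conc.at[category, col]
            if c <= 0:
                continue
            limit = cr_lim(rfd, config.default_bw, c)
            serving = config.serving_sizes.get(category)
            is_fish = "fish" in category.lower()
            rows.append(
                {
                    "category": category,
                    "element": element,
                    "cr_lim": limit,
                    "cr_mm_servings": (
                        cr_mm(limit, config.days_per_month, serving) if serving else math.nan
                    ),
                    "cr_mm_meals": (
                        cr_mm(limit, config.days_per_month, config.epa_meal_size * 1000.0)
                        if is_fish
                        else math.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
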