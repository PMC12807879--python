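"""CSV readers and report writers.

All tables are UTF-8, comma-separated, header-row CSV with decimal points
(comma decimals are rejected rather than guessed). Nondetect concentration
cells may be written as ``<MDL`` (substituting the configured method
detection limit) or ``<0.0005`` (an explicit limit); either form is
substituted at ``nondetect_fraction`` of the limit and flagged so the
substitution remains auditable downstream.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd
from pydantic import ValidationError

from .config import StudyConfig
from .records import CATEGORIES, ChildRecord, FoodSample, IntakeRecord

if TYPE_CHECKING:  # pragma: no cover
    from .risk_benefit import CategorySummary

logger = logging.getLogger(__name__)

LMS_MEASURES = ("weight-for-age", "height-for-age")

_NONDETECT_RE = re.compile(r"^<\s*(MDL|[0-9.eE+-]+)\s*$", re.IGNORECASE)


def _parse_number(cell: str, context: str) -> float:
    cell = cell.strip()
    if "," in cell:
        raise ValueError(
            f"{context}: comma decimals are not accepted ({cell!r}); use a decimal point"
        )
    try:
        return float(cell)
    except ValueError:
        raise ValueError(f"{context}: malformed number {cell!r}") from None


def _parse_concentration(
    cell: str, mdl: float, fraction: float, context: str
) -> tuple[float, bool]:
    """Parse a concentration cell, handling ``<MDL`` / ``<value`` nondetects."""
    match = _NONDETECT_RE.match(cell.strip())
    if match:
        token = match.group(1)
        limit = mdl if token.upper() == "MDL" else _parse_number(token, context)
        return limit * fraction, True
    value = _parse_number(cell, context)
    if value < 0:
        raise ValueError(f"{context}: concentration must be nonnegative, got {value}")
    return value, False


def read_food_samples(path: str | Path, config: StudyConfig | None = None) -> list[FoodSample]:
    """Read and validate a food-sample table.

    Required columns: sample_id, category, se_conc, hg_conc; optional:
    subcategory, feeding_habit. Unknown categories and duplicate sample ids
    are rejected with row-level messages.
    """
    config = config or StudyConfig()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample_id", "category", "se_conc", "hg_conc"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns: {sorted(missing)}")

    samples: list[FoodSample] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        context = f"{path} row {idx + 2}"  # +2: header + 1-based
        sample_id = row["sample_id"].strip()
        if sample_id in seen:
            raise ValueError(f"{context}: duplicate sample_id {sample_id!r}")
        seen.add(sample_id)
        se, se_nd = _parse_concentration(
            row["se_conc"], config.mdl_se, config.nondetect_fraction, context
        )
        hg, hg_nd = _parse_concentration(
            row["hg_conc"], config.mdl_hg, config.nondetect_fraction, context
        )
        try:
            samples.append(
                FoodSample(
                    sample_id=sample_id,
                    category=row["category"],
                    subcategory=row.get("subcategory") or None,
                    feeding_habit=row.get("feeding_habit") or None,
                    se_conc=se,
                    hg_conc=hg,
                    se_nondetect=se_nd,
                    hg_nondetect=hg_nd,
                )
            )
        except ValidationError as exc:
            raise ValueError(f"{context}: {exc.errors()[0]['msg']}") from exc
        if se_nd or hg_nd:
            logger.info("%s: nondetect substituted at %s of the MDL", context, config.nondetect_fraction)
    return samples


def food_samples_to_frame(samples: Iterable[FoodSample]) -> pd.DataFrame:
    return pd.DataFrame([s.model_dump() for s in samples])


def write_food_samples(samples: Iterable[FoodSample], path: str | Path) -> None:
    food_samples_to_frame(samples).to_csv(path, index=False)


def read_children(path: str | Path) -> list[ChildRecord]:
    """Read and validate a child-record table."""
    frame = pd.read_csv(path)
    children = []
    for idx, row in frame.iterrows():
        try:
            children.append(ChildRecord(**{k: row[k] for k in ChildRecord.model_fields if k in row}))
        except ValidationError as exc:
            raise ValueError(f"{path} row {idx + 2}: {exc.errors()[0]['msg']}") from exc
    return children


def children_to_frame(children: Iterable[ChildRecord]) -> pd.DataFrame:
    return pd.DataFrame([c.model_dump() for c in children])


def read_intakes(path: str | Path) -> list[IntakeRecord]:
    """Read the tidy per-child per-category intake table (g/day)."""
    frame = pd.read_csv(path)
    records = []
    seen: set[tuple[str, str]] = set()
    for idx, row in frame.iterrows():
        try:
            record = IntakeRecord(
                child_id=str(row["child_id"]),
                category=row["category"],
                intake_rate=row["intake_rate"],
            )
        except ValidationError as exc:
            raise ValueError(f"{path} row {idx + 2}: {exc.errors()[0]['msg']}") from exc
        key = (record.child_id, record.category)
        if key in seen:
            raise ValueError(f"{path} row {idx + 2}: duplicate (child_id, category) {key}")
        seen.add(key)
        records.append(record)
    return records


def intakes_to_frame(records: Iterable[IntakeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.model_dump() for r in records])


def read_lms_table(path: str | Path) -> pd.DataFrame:
    """Read a growth-reference LMS table (sex, age_months, measure, L, M, S)."""
    frame = pd.read_csv(path)
    required = {"sex", "age_months", "measure", "L", "M", "S"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns: {sorted(missing)}")
    bad_measure = set(frame["measure"]) - set(LMS_MEASURES)
    if bad_measure:
        raise ValueError(f"{path}: unknown measures {sorted(bad_measure)}; allowed: {LMS_MEASURES}")
    if (frame["M"] <= 0).any() or (frame["S"] <= 0).any():
        raise ValueError(f"{path}: M and S must be strictly positive")
    return frame.sort_values(["sex", "measure", "age_months"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# report writers

_PM = " ± "


def _fmt_pm(mean: float, sd: float, decimals: int) -> str:
    return f"{mean:.{decimals}f}{_PM}{sd:.{decimals}f}"


def _fmt_ratio(value: float) -> str:
    if math.isinf(value):
        return "Inf"
    return f"{value:.2f}"


def write_category_report(summaries: Sequence["CategorySummary"], path: str | Path) -> None:
    """Write the per-category concentration/score report.

    Columns mirror the published panel table: n, mass and molar mean ± SD
    for Se and Hg (3 decimals), Se:Hg ratio and HBV_Se (2 decimals; an
    all-nondetect Hg mean yields the ``Inf`` ratio sentinel).
    """
    rows = [
        {
            "category": s.category,
            "n": s.n,
            "se_mg_kg": _fmt_pm(s.se_mass_mean, s.se_mass_sd, 3),
            "se_umol_kg": _fmt_pm(s.se_molar_mean, s.se_molar_sd, 3),
            "hg_mg_kg": _fmt_pm(s.hg_mass_mean, s.hg_mass_sd, 3),
            "hg_umol_kg": _fmt_pm(s.hg_molar_mean, s.hg_molar_sd, 3),
            "ratio_se_hg": _fmt_ratio(s.ratio_se_hg),
            "hbv_se": f"{s.hbv_se:.2f}",
        }
        for s in summaries
    ]
    columns = ["category", "n", "se_mg_kg", "se_umol_kg", "hg_mg_kg", "hg_umol_kg", "ratio_se_hg", "hbv_se"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_category_report(path: str | Path) -> pd.DataFrame:
    """Read a category report back into numeric columns (mean/sd split)."""
    frame = pd.read_csv(path, dtype=str)
    out = pd.DataFrame({"category": frame["category"], "n": frame["n"].astype(int)})
    for col in ("se_mg_kg", "se_umol_kg", "hg_mg_kg", "hg_umol_kg"):
        parts = frame[col].str.split(_PM, regex=False, expand=True)
        out[f"{col}_mean"] = parts[0].astype(float)
        out[f"{col}_sd"] = parts[1].astype(float)
    out["ratio_se_hg"] = frame["ratio_se_hg"].replace("Inf", "inf").astype(float)
    out["hbv_se"] = frame["hbv_se"].astype(float)
    return out


def write_exposure_report(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the per-category dietary Se adequacy report (EDI/AI table)."""
    formatted = frame.copy()
    for col in ("edi_se_total", "edi_hg_total", "net_se", "ai_pct", "net_ai_pct"):
        if col in formatted:
            formatted[col] = formatted[col].map(lambda v: f"{v:.2f}")
    for col in ("hq_hg",):
        if col in formatted:
            formatted[col] = formatted[col].map(lambda v: f"{v:.3f}")
    formatted.to_csv(path, index=False)


def write_limits_report(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the consumption-limit report (CR_lim / CR_mm per category × element)."""
    formatted = frame.copy()
    for col in ("cr_lim", "cr_mm_servings", "cr_mm_meals"):
        if col in formatted:
            formatted[col] = formatted[col].map(
                lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else f"{v:.2f}"
            )
    formatted.to_csv(path, index=False)


def write_model_results(results: Sequence, path: str | Path) -> None:
    """Write growth-model results (one row per outcome × food term)."""
    rows = [
        {
            "outcome": r.outcome,
            "term": r.term,
            "beta": r.beta,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_value": r.p_value,
            "n": r.n,
            "covariates": ";".join(r.covariates_included),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
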