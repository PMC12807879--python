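"""Synthetic study data with known ground truth.

Every pipeline stage is testable without downloads: this module generates

* food-concentration panels — per category, independent lognormal Se and
  Hg draws moment-matched to the survey panel's mean ± SD (an optional
  log-scale correlation is available for sensitivity runs);
* a smooth synthetic growth-reference LMS table spanning 0–72 months for
  both sexes (a real reference table drops in unchanged);
* cohorts of preschool children — ages roughly uniform and calibrated to
  the survey mean of 2.9 years, sex Bernoulli(0.54 male), lognormal hair
  Hg (1.11 ± 1.15 µg/g), income and parity drawn from the survey
  marginals, and weight/height produced by *inverting* the LMS formula at
  each child's age from latent standard-normal growth scores (so z-scores
  recover exactly);
* FFQ intake rates — gamma-distributed (CV 0.5 by default) around
  per-category means back-solved from the published population EDIs;
* growth outcomes from known regression coefficients, for
  parameter-recovery tests of the association models.

All generators are deterministic under a fixed seed.

What this emulates — and what it does not: marginal distributions and a
linear outcome model with independent intakes across categories. Real
FFQ data have correlated intakes, heavier-tailed hair-Hg distributions
(the survey observed 42.4% above 1 µg/g where the matched lognormal gives
38%), Se–Hg correlation within foods, and measurement error, none of
which are simulated by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import calibration
from .config import StudyConfig
from .growth import lms_invert
from .records import CATEGORIES, ChildRecord, FoodSample, IntakeRecord


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and SD.

    mu = ln(mean² / √(sd² + mean²)), sigma = √ln(1 + sd²/mean²); sd = 0
    degenerates to a point mass at ``mean``.
    """
    if mean <= 0:
        raise ValueError(f"mean must be strictly positive, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be nonnegative, got {sd}")
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean**2 / math.sqrt(sd**2 + mean**2))
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class CategoryDistSpec:
    """Concentration distribution of one food category (mg/kg ww)."""

    category: str
    n_samples: int
    se_mean: float
    se_sd: float
    hg_mean: float
    hg_sd: float
    subcategory: str | None = None
    family: str = "lognormal"
    log_correlation: float = 0.0  # Se–Hg correlation on the log scale

    def __post_init__(self) -> None:
        if self.se_mean <= 0 or self.hg_mean <= 0:
            raise ValueError("concentration means must be strictly positive")
        if self.se_sd < 0 or self.hg_sd < 0:
            raise ValueError("concentration SDs must be nonnegative")
        if not -1.0 <= self.log_correlation <= 1.0:
            raise ValueError("log_correlation must lie in [-1, 1]")


def default_food_specs() -> list[CategoryDistSpec]:
    """Panel specs matching the 108-sample survey (11 categories; fish split
    into its 9 marine and 4 freshwater samples with their own distributions).

    Generator means/SDs are taken from the published *molar* summary
    columns converted back to the mass basis: the molar figures carry more
    significant digits for the dilute plant foods (a fruit Se mean printed
    as 0.002 mg/kg is 0.020 µmol/kg, i.e. 0.00158 mg/kg unrounded), and
    the molar basis is what the Se:Hg ratio and HBV_Se scores consume.
    """
    cfg = StudyConfig()

    def spec_for(category: str, label: str, sub: str | None) -> CategoryDistSpec:
        stats = calibration.FOOD_CATEGORY_STATS[label]
        return CategoryDistSpec(
            category,
            stats.n,
            stats.se_molar_mean * cfg.molar_mass_se / 1000.0,
            stats.se_molar_sd * cfg.molar_mass_se / 1000.0,
            stats.hg_molar_mean * cfg.molar_mass_hg / 1000.0,
            stats.hg_molar_sd * cfg.molar_mass_hg / 1000.0,
            subcategory=sub,
        )

    specs: list[CategoryDistSpec] = []
    for category in CATEGORIES:
        if category == "Fish":
            for sub in ("Marine fish", "Freshwater fish"):
                specs.append(spec_for("Fish", sub, sub))
        else:
            specs.append(spec_for(category, category, None))
    return specs


def _draw_lognormal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    mu, sigma = lognormal_params_from_moments(mean, sd)
    if sigma == 0:
        return np.full(n, mean)
    return np.exp(rng.normal(mu, sigma, size=n))


def gen_food_panel(
    specs: Sequence[CategoryDistSpec] | None = None, seed: int = 0
) -> list[FoodSample]:
    """Draw a synthetic food panel; deterministic under a fixed seed."""
    specs = list(specs) if specs is not None else default_food_specs()
    rng = np.random.default_rng(seed)
    samples: list[FoodSample] = []
    counter: dict[str, int] = {}
    for spec in specs:
        n = spec.n_samples
        if spec.family != "lognormal":
            raise ValueError(f"unsupported distribution family {spec.family!r}")
        if spec.log_correlation == 0.0:
            se = _draw_lognormal(rng, spec.se_mean, spec.se_sd, n)
            hg = _draw_lognormal(rng, spec.hg_mean, spec.hg_sd, n)
        else:
            mu_se, s_se = lognormal_params_from_moments(spec.se_mean, spec.se_sd)
            mu_hg, s_hg = lognormal_params_from_moments(spec.hg_mean, spec.hg_sd)
            cov = spec.log_correlation * s_se * s_hg
            draws = rng.multivariate_normal(
                [mu_se, mu_hg], [[s_se**2, cov], [cov, s_hg**2]], size=n
            )
            se, hg = np.exp(draws[:, 0]), np.exp(draws[:, 1])
        label = spec.subcategory or spec.category
        for se_i, hg_i in zip(se, hg):
            counter[label] = counter.get(label, 0) + 1
            prefix = "".join(w[0] for w in label.split()).upper()
            samples.append(
                FoodSample(
                    sample_id=f"{prefix}-{counter[label]:03d}",
                    category=spec.category,
                    subcategory=spec.subcategory,
                    se_conc=float(se_i),
                    hg_conc=float(hg_i),
                )
            )
    return samples


def gen_lms_table(max_age_months: int = 72, step: int = 1) -> pd.DataFrame:
    """Synthetic smooth growth-reference LMS table, both sexes, 0–72 months.

    The curves are plausible for preschool anthropometry (birth weight
    ~3.3 kg rising to ~19 kg at 6 years; length 50 → ~117 cm) but are not
    any official reference — they exist so tests and simulations run
    self-contained. A real reference CSV with the same columns drops in
    unchanged.
    """
    ages = np.arange(0, max_age_months + 1, step, dtype=float)
    rows = []
    for sex, scale in (("male", 1.0), ("female", 0.965)):
        m_weight = scale * (3.3 + 1.05 * ages**0.72)
        l_weight = 0.35 - 0.004 * ages  # mild, age-drifting skewness
        s_weight = 0.11 + 0.0004 * ages
        m_height = scale * (50.0 + 6.5 * ages**0.55)
        s_height = np.full_like(ages, 0.038)
        for age, mw, lw, sw, mh, sh in zip(
            ages, m_weight, l_weight, s_weight, m_height, s_height
        ):
            rows.append(
                {"sex": sex, "age_months": age, "measure": "weight-for-age",
                 "L": round(float(lw), 4), "M": round(float(mw), 4), "S": round(float(sw), 4)}
            )
            rows.append(
                {"sex": sex, "age_months": age, "measure": "height-for-age",
                 "L": 1.0, "M": round(float(mh), 4), "S": float(sh)}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth parameters of a synthetic preschool cohort."""

    n_children: int = calibration.COHORT_N
    hair_hg_mean: float = calibration.HAIR_HG_MEAN  # µg/g
    hair_hg_sd: float = calibration.HAIR_HG_SD  # µg/g
    male_fraction: float = calibration.MALE_FRACTION
    age_min: float = 0.5  # years; uniform ages give the survey mean 2.9 y
    age_max: float = 5.3
    intake_means: Mapping[str, float] = field(
        default_factory=calibration.reference_intake_means
    )
    intake_cv: float = 0.5  # gamma-distributed intakes around the means
    growth_z_sd: float = 1.0  # latent growth score scale
    growth_z_corr: float = 0.5  # weight–height latent correlation
    income_probs: tuple[float, ...] = calibration.INCOME_PROBS
    parity_probs: tuple[float, ...] = calibration.PARITY_PROBS

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be at least 1")
        if not 0 < self.hair_hg_mean:
            raise ValueError("hair_hg_mean must be strictly positive")
        if self.hair_hg_sd < 0 or self.intake_cv < 0 or self.growth_z_sd < 0:
            raise ValueError("dispersion parameters must be nonnegative")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be below age_max")


def gen_cohort(
    spec: CohortSpec | None = None,
    lms_table: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[list[ChildRecord], list[IntakeRecord], dict]:
    """Generate a cohort and its FFQ intakes; returns (children, intakes, truth).

    Weight and height are produced by inverting the LMS formula at each
    child's age from correlated latent standard-normal scores, so
    downstream z-score computation recovers the latent scores exactly.
    The truth dict records the seed and every latent variable.
    """
    spec = spec or CohortSpec()
    lms_table = lms_table if lms_table is not None else gen_lms_table()
    max_age_months = float(lms_table["age_months"].max())
    if spec.age_max * 12.0 > max_age_months:
        raise ValueError(
            f"LMS table spans only {max_age_months} months; "
            f"requested ages up to {spec.age_max * 12.0}"
        )
    rng = np.random.default_rng(seed)
    n = spec.n_children

    ages = rng.uniform(spec.age_min, spec.age_max, size=n)
    sexes = np.where(rng.random(n) < spec.male_fraction, "male", "female")
    mu, sigma = lognormal_params_from_moments(spec.hair_hg_mean, spec.hair_hg_sd)
    hair = np.exp(rng.normal(mu, sigma, size=n)) if sigma else np.full(n, spec.hair_hg_mean)
    cov = spec.growth_z_corr * spec.growth_z_sd**2
    z = rng.multivariate_normal(
        [0.0, 0.0],
        [[spec.growth_z_sd**2, cov], [cov, spec.growth_z_sd**2]],
        size=n,
    )
    income = rng.choice(calibration.INCOME_BANDS, size=n, p=np.asarray(spec.income_probs) / sum(spec.income_probs))
    parity = rng.choice(calibration.PARITY_LEVELS, size=n, p=np.asarray(spec.parity_probs) / sum(spec.parity_probs))

    # vectorized LMS interpolation + inversion per sex stratum
    age_months = ages * 12.0
    weights = np.empty(n)
    heights = np.empty(n)
    for sex in ("male", "female"):
        mask = sexes == sex
        if not mask.any():
            continue
        for measure, target, zcol in (
            ("weight-for-age", weights, z[:, 0]),
            ("height-for-age", heights, z[:, 1]),
        ):
            stratum = lms_table[(lms_table["sex"] == sex) & (lms_table["measure"] == measure)]
            ref_age = stratum["age_months"].to_numpy(dtype=float)
            L = np.interp(age_months[mask], ref_age, stratum["L"].to_numpy(dtype=float))
            M = np.interp(age_months[mask], ref_age, stratum["M"].to_numpy(dtype=float))
            S = np.interp(age_months[mask], ref_age, stratum["S"].to_numpy(dtype=float))
            zs = zcol[mask]
            with np.errstate(invalid="ignore"):
                inv = np.where(
                    L == 0,
                    M * np.exp(S * zs),
                    M * np.power(np.maximum(1.0 + L * S * zs, 1e-12), 1.0 / np.where(L == 0, 1.0, L)),
                )
            target[mask] = inv

    children: list[ChildRecord] = []
    for i in range(n):
        weight = float(weights[i])
        height = float(heights[i])
        children.append(
            ChildRecord(
                child_id=f"C{i + 1:04d}",
                sex=sexes[i],
                age=float(ages[i]),
                weight=weight,
                height=height,
                hair_hg=float(hair[i]),
                income_band=str(income[i]),
                parity=int(parity[i]),
                age_at_measurement=float(ages[i]),
            )
        )

    intakes: list[IntakeRecord] = []
    shape = 1.0 / spec.intake_cv**2 if spec.intake_cv > 0 else None
    for category, mean_intake in spec.intake_means.items():
        if shape is None:
            draws = np.full(n, mean_intake)
        else:
            draws = rng.gamma(shape, mean_intake / shape, size=n)
        for child, rate in zip(children, draws):
            intakes.append(
                IntakeRecord(child_id=child.child_id, category=category, intake_rate=float(rate))
            )

    truth = {
        "seed": seed,
        "n_children": n,
        "latent_waz": z[:, 0].tolist(),
        "latent_haz": z[:, 1].tolist(),
        "hair_hg_lognormal": {"mu": mu, "sigma": sigma},
        "intake_means": dict(spec.intake_means),
        "intake_cv": spec.intake_cv,
    }
    return children, intakes, truth


def gen_outcomes(
    children: Sequence[ChildRecord],
    exposures: pd.DataFrame,
    true_betas: Mapping[str, float],
    noise_sd: float,
    seed: int = 0,
    intercept: float = 0.0,
    covariate_effects: Mapping[str, float] | None = None,
    hair_cutoff: float = 1.0,
) -> tuple[pd.Series, dict]:
    """Outcome column from a known linear model, plus a truth record.

    ``exposures`` is a child × category table of net AI percentages (see
    ``intake.net_ai_wide``). The linear predictor is
    intercept + Σ_c beta_c · netAI_c + covariate effects + N(0, noise_sd),
    where ``covariate_effects`` may name ``male``, ``age`` (per year) and
    ``hg_high`` shifts. Child ids must match between inputs.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    ids = [c.child_id for c in children]
    if set(ids) != set(exposures.index):
        raise ValueError("child ids in exposures do not match the cohort")
    missing = set(true_betas) - set(exposures.columns)
    if missing:
        raise ValueError(f"no exposure columns for categories: {sorted(missing)}")
    exposures = exposures.loc[ids]
    effects = dict(covariate_effects or {})

    rng = np.random.default_rng(seed)
    y = np.full(len(ids), float(intercept))
    for category, beta in true_betas.items():
        y += beta * exposures[category].to_numpy(dtype=float)
    for child, i in zip(children, range(len(ids))):
        if "male" in effects and child.sex == "male":
            y[i] += effects["male"]
        if "age" in effects:
            y[i] += effects["age"] * child.age
        if "hg_high" in effects and child.hair_hg > hair_cutoff:
            y[i] += effects["hg_high"]
    y += rng.normal(0.0, noise_sd, size=len(ids)) if noise_sd else 0.0

    truth = {
        "seed": seed,
        "intercept": intercept,
        "betas": dict(true_betas),
        "covariate_effects": effects,
        "noise_sd": noise_sd,
    }
    return pd.Series(y, index=ids, name="outcome"), truth


def simulate_study(
    n_children: int = calibration.COHORT_N,
    seed: int = 0,
    out_dir: str | Path | None = None,
    config: StudyConfig | None = None,
) -> dict:
    """One-call simulation of a full study: foods, cohort, intakes, outcomes.

    Returns a dict of in-memory artifacts; with ``out_dir`` also writes
    foods.csv, children.csv, intakes.csv, lms.csv and truth.json. Output
    is byte-identical for identical seeds.
    """
    from . import io as sehg_io
    from .intake import net_ai_wide, per_child_exposure
    from .risk_benefit import summarize_panel

    config = config or StudyConfig()
    root = np.random.SeedSequence(seed)
    panel_seed, cohort_seed, outcome_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)
    )
    lms = gen_lms_table()
    foods = gen_food_panel(seed=panel_seed)
    spec = CohortSpec(n_children=n_children)
    children, intakes, cohort_truth = gen_cohort(spec, lms, seed=cohort_seed)

    summaries = summarize_panel(foods, config, include_total=False)
    exposure = per_child_exposure(
        [s for s in summaries if s.category in CATEGORIES and s.category != "Total"],
        intakes,
        children,
        config,
    )
    wide = net_ai_wide(exposure)
    outcome, outcome_truth = gen_outcomes(
        children,
        wide,
        calibration.TRUE_HEIGHT_BETAS,
        noise_sd=0.5,
        seed=outcome_seed,
        covariate_effects={"male": 0.1, "age": 0.05, "hg_high": -0.1},
        hair_cutoff=config.hair_cutoff,
    )
    truth = {"cohort": cohort_truth, "outcome": outcome_truth, "seed": seed}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sehg_io.write_food_samples(foods, out / "foods.csv")
        frame = sehg_io.children_to_frame(children)
        frame["height_outcome"] = outcome.loc[frame["child_id"]].to_numpy()
        frame.to_csv(out / "children.csv", index=False)
        sehg_io.intakes_to_frame(intakes).to_csv(out / "intakes.csv", index=False)
        lms.to_csv(out / "lms.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truth, indent=2), encoding="utf-8")

    return {
        "foods": foods,
        "children": children,
        "intakes": intakes,
        "lms": lms,
        "exposure": exposure,
        "outcome": outcome,
        "truth": truth,
    }
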