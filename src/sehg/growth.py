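"""Growth outcomes: LMS z-scores and the Se-adequacy association models.

Weight- and height-for-age z-scores are computed with the LMS (Box-Cox)
method against a growth-reference table giving, per sex × measure × age in
months, the Box-Cox power (L), median (M) and coefficient of variation (S):

    z = ((x/M)^L − 1) / (L·S)   for L ≠ 0,   ln(x/M)/S   for L = 0.

For weight-based indices the reference convention restricts extreme tails:
beyond |z| > 3 the score is linearly extrapolated from the ±2 and ±3 SD
values, z* = 3 + (x − SD3)/(SD3 − SD2) above, symmetric below.

The association analysis mirrors a standard two-stage epidemiological
workflow: candidate covariates are screened in univariate regressions
(kept at p < 0.2, joint F-test for categorical candidates), then the net
Se adequacy percentage of one food category is fitted against a growth
outcome by OLS adjusted for the screened covariates, reporting the
exposure coefficient with t-based 95% Wald CI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .records import ChildRecord

logger = logging.getLogger(__name__)

__all__ = [
    "lms_zscore",
    "lms_invert",
    "interpolate_lms",
    "zscore_for_child",
    "classify_hg_exposure",
    "screen_covariates",
    "fit_growth_model",
    "GrowthModelResult",
    "plot_forest",
]


def _raw_z(x: float, L: float, M: float, S: float) -> float:
    # expm1 form: identical to ((x/M)^L − 1)/(L·S) but numerically stable
    # as L → 0, where it degenerates smoothly to ln(x/M)/S.
    if L == 0:
        return float(np.log(x / M) / S)
    return float(np.expm1(L * np.log(x / M)) / (L * S))


def lms_invert(z: float, L: float, M: float, S: float) -> float:
    """Measurement at a given (unrestricted) z-score: inverse of the LMS map."""
    if M <= 0 or S <= 0:
        raise ValueError("M and S must be strictly positive")
    if L == 0:
        return float(M * np.exp(S * z))
    arg = 1.0 + L * S * z
    if arg <= 0:
        raise ValueError(f"z = {z} outside the Box-Cox domain for L = {L}, S = {S}")
    return float(M * np.exp(np.log1p(L * S * z) / L))


def lms_zscore(x: float, L: float, M: float, S: float, restricted_tail: bool = False) -> float:
    """LMS z-score of a measurement ``x`` against reference (L, M, S).

    With ``restricted_tail`` (the convention for weight-based indices),
    scores beyond |z| > 3 are replaced by the linear extrapolation from the
    2-SD and 3-SD reference values, limiting the influence of the Box-Cox
    tail on extreme measurements.
    """
    if x <= 0 or M <= 0 or S <= 0:
        raise ValueError("x, M and S must be strictly positive")
    z = _raw_z(x, L, M, S)
    if not restricted_tail or abs(z) <= 3:
        return z
    if z > 3:
        sd3, sd2 = lms_invert(3, L, M, S), lms_invert(2, L, M, S)
        return 3.0 + (x - sd3) / (sd3 - sd2)
    sd3, sd2 = lms_invert(-3, L, M, S), lms_invert(-2, L, M, S)
    return -3.0 + (x - sd3) / (sd2 - sd3)


def interpolate_lms(
    lms_table: pd.DataFrame, sex: str, measure: str, age_months: float
) -> tuple[float, float, float]:
    """Linearly interpolate (L, M, S) to an age within one sex × measure stratum."""
    stratum = lms_table[(lms_table["sex"] == sex) & (lms_table["measure"] == measure)]
    if stratum.empty:
        raise ValueError(f"no LMS rows for sex={sex!r}, measure={measure!r}")
    ages = stratum["age_months"].to_numpy(dtype=float)
    if not ages[0] <= age_months <= ages[-1]:
        raise ValueError(
            f"age {age_months} months outside LMS table range [{ages[0]}, {ages[-1]}]"
        )
    return tuple(
        float(np.interp(age_months, ages, stratum[col].to_numpy(dtype=float)))
        for col in ("L", "M", "S")
    )


def zscore_for_child(
    child: ChildRecord, lms_table: pd.DataFrame, restricted_tail: bool = True
) -> tuple[float, float]:
    """(WAZ, HAZ) for one child against the reference table.

    L, M, S are interpolated to the child's age in months within the
    matching sex stratum; the restricted-tail rule applies to WAZ only.
    """
    age_months = child.age * 12.0
    waz = lms_zscore(
        child.weight,
        *interpolate_lms(lms_table, child.sex, "weight-for-age", age_months),
        restricted_tail=restricted_tail,
    )
    haz = lms_zscore(
        child.height, *interpolate_lms(lms_table, child.sex, "height-for-age", age_months)
    )
    return waz, haz


def classify_hg_exposure(hair_hg: float, cutoff: float = 1.0) -> str:
    """Dichotomize hair Hg at the cutoff: 'high' iff strictly above (1.0 is low)."""
    if hair_hg < 0:
        raise ValueError(f"hair Hg must be nonnegative, got {hair_hg}")
    return "high" if hair_hg > cutoff else "low"


def _term(name: str, data: pd.DataFrame, categorical: Sequence[str]) -> str:
    if name in categorical or not pd.api.types.is_numeric_dtype(data[name]):
        return f"C(Q('{name}'))"
    return f"Q('{name}')"


def screen_covariates(
    data: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str],
    threshold: float = 0.2,
    categorical: Sequence[str] = (),
) -> list[str]:
    """Univariate screen: keep candidates with regression p < threshold.

    Each candidate is fitted alone against the outcome; categorical
    candidates (non-numeric dtype or listed in ``categorical``) expand to
    indicator terms and are judged by the joint F-test. Constant candidates
    are excluded with a warning. Input order is preserved.
    """
    selected: list[str] = []
    for name in candidates:
        if data[name].nunique(dropna=True) <= 1:
            warnings.warn(f"covariate {name!r} is constant; excluded from screening")
            continue
        model = smf.ols(f"Q('{outcome}') ~ {_term(name, data, categorical)}", data=data)
        p = float(model.fit().f_pvalue)
        logger.info("screen %s ~ %s: p = %.4g", outcome, name, p)
        if p < threshold:
            selected.append(name)
    return selected


@dataclass(frozen=True)
class GrowthModelResult:
    """Adjusted association between one food's net Se adequacy and growth."""

    outcome: str
    term: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    covariates_included: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("confidence interval must bracket the point estimate")


def _collinear_terms(exog: pd.DataFrame) -> list[str]:
    # Columns with (near-)zero diagonal in the QR factor are linearly
    # dependent on earlier columns.
    x = exog.to_numpy(dtype=float)
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag.max() or 1.0)
    return [exog.columns[i] for i in np.flatnonzero(diag < tol * 1e6)]


def fit_growth_model(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
    categorical: Sequence[str] = (),
    alpha: float = 0.05,
) -> GrowthModelResult:
    """OLS of a growth outcome on one exposure, adjusted for covariates.

    Missing values are removed listwise (with a logged count). Returns the
    exposure term's coefficient, t-based two-sided (1 − alpha) Wald CI and
    p-value. A rank-deficient design raises, naming the collinear terms.
    """
    used = [outcome, exposure, *covariates]
    complete = data[used].dropna()
    dropped = len(data) - len(complete)
    if dropped:
        logger.info("listwise deletion removed %d of %d rows", dropped, len(data))

    terms = [f"Q('{exposure}')"] + [_term(c, complete, categorical) for c in covariates]
    model = smf.ols(f"Q('{outcome}') ~ {' + '.join(terms)}", data=complete)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        names = _collinear_terms(pd.DataFrame(model.exog, columns=model.exog_names))
        raise ValueError(f"rank-deficient design; collinear terms: {names}")
    if complete.shape[0] <= model.exog.shape[1]:
        raise ValueError(
            f"n = {complete.shape[0]} too small for {model.exog.shape[1]} terms"
        )
    with warnings.catch_warnings():
        # a saturated/noiseless fit emits harmless runtime warnings
        warnings.simplefilter("ignore", category=RuntimeWarning)
        result = model.fit()
        exposure_name = f"Q('{exposure}')"
        ci = result.conf_int(alpha=alpha).loc[exposure_name]
        p = float(result.pvalues[exposure_name])
    beta = float(result.params[exposure_name])
    if np.isnan(p):  # zero residual variance: exact fit
        p = 0.0
    ci_low = beta if np.isnan(ci[0]) else float(ci[0])
    ci_high = beta if np.isnan(ci[1]) else float(ci[1])
    return GrowthModelResult(
        outcome=outcome,
        term=exposure,
        beta=beta,
        ci_low=min(ci_low, beta),
        ci_high=max(ci_high, beta),
        p_value=p,
        n=int(result.nobs),
        covariates_included=tuple(covariates),
    )


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Brute-force normal-equations OLS solve (independent cross-check)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def plot_forest(results: Sequence[GrowthModelResult], path=None, ax=None):
    """Forest plot of per-food growth-association coefficients with 95% CIs."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * len(results) + 1.5))
    ys = np.arange(len(results))[::-1]
    for y, r in zip(ys, results):
        ax.plot([r.ci_low, r.ci_high], [y, y], color="0.3")
        ax.plot([r.beta], [y], "s", color="C0")
    ax.axvline(0, color="0.7", linestyle="--")
    ax.set_yticks(ys)
    ax.set_yticklabels([f"{r.outcome}: {r.term}" for r in results])
    ax.set_xlabel("coefficient per % net AI$_{Se}$ (95% CI)")
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
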