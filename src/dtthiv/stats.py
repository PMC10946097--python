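"""Statistical comparisons: rank tests, chi-squared, odds ratios, logistic models.

Conventions follow common epidemiological reporting practice: two-sided tests
at alpha = 0.05, Wald 95% confidence intervals on the log-odds scale, no
multiple-testing adjustment, and complete-case handling of missing model
covariates. The crude logistic model for a binary exposure is algebraically
identical to the 2x2 odds ratio; both routes are exposed (and the identity is
exercised in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

Z975 = 1.959963984540054  # standard normal 97.5th percentile


class ModelFitError(RuntimeError):
    """Logistic model failed to converge (e.g. perfect separation)."""


@dataclass
class OrEstimate:
    """An odds ratio with its Wald 95% confidence interval."""

    outcome: str
    adjusted: bool
    n_analyzed: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: Optional[float] = None
    counts: Optional[tuple] = None  # (a, b, c, d) for crude 2x2 estimates

    def __post_init__(self):
        if not (self.ci_low <= self.odds_ratio * (1 + 1e-12) and
                self.odds_ratio <= self.ci_high * (1 + 1e-12)):
            raise ValueError("confidence interval does not bracket the estimate")
        if min(self.odds_ratio, self.ci_low, self.ci_high) <= 0:
            raise ValueError("odds ratio and CI must be positive")


def _clean(values: Sequence) -> np.ndarray:
    arr = np.asarray(pd.Series(list(values), dtype="float64").dropna(), dtype=float)
    return arr


def mann_whitney(group_a: Sequence, group_b: Sequence) -> tuple:
    """Two-sided Mann-Whitney U test (normal approximation, tie-corrected).

    Returns ``(U, p)`` where U is the statistic for ``group_a`` versus
    ``group_b``. Missing values are dropped; an empty group is an error.
    """
    a, b = _clean(group_a), _clean(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires at least one value per group")
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def chi_squared(table) -> tuple:
    """Pearson chi-squared test without continuity correction.

    ``table`` is a 2xk (or general r x k) contingency table of counts with
    strictly positive row and column margins.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be two-dimensional")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) <= 0).any() or (t.sum(axis=1) <= 0).any():
        raise ValueError("zero margin in contingency table")
    res = sps.chi2_contingency(t, correction=False)
    return float(res[0]), float(res[1])


def odds_ratio_2x2(
    a: float, b: float, c: float, d: float, outcome: str = "outcome"
) -> OrEstimate:
    """Odds ratio ``(a*d)/(b*c)`` with a Wald 95% CI.

    Cell layout: ``a``/``b`` = exposed with/without the outcome, ``c``/``d``
    = unexposed with/without. All cells must be positive for the Wald CI.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if min(a, b, c, d) == 0:
        raise ValueError(
            "zero cell in 2x2 table; Wald odds ratio undefined "
            "(an exact or penalized method would be needed, out of scope)"
        )
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - Z975 * se), math.exp(math.log(or_) + Z975 * se)
    z = math.log(or_) / se
    p = 2 * sps.norm.sf(abs(z))
    return OrEstimate(
        outcome=outcome,
        adjusted=False,
        n_analyzed=int(a + b + c + d),
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        p_value=float(p),
        counts=(a, b, c, d),
    )


def _fit_logit(y: np.ndarray, X: pd.DataFrame, term: str):
    """Newton-fit logistic regression; returns (OR, lo, hi, p) for ``term``."""
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(np.asarray(y, dtype=float), Xc.astype(float))
    fit = None
    try:
        with np.errstate(all="ignore"):
            fit = model.fit(disp=0, method="newton", maxiter=200, tol=1e-10)
    except (np.linalg.LinAlgError, PerfectSeparationError) as e:
        raise ModelFitError(f"logistic fit failed: {e}") from e
    if not fit.mle_retvals.get("converged", True):
        # Newton can oscillate under quasi-separation in a covariate cell;
        # a gradient method usually still settles on the MLE plateau.
        with np.errstate(all="ignore"):
            fit = model.fit(disp=0, method="bfgs", maxiter=1000)
        if not fit.mle_retvals.get("converged", True):
            raise ModelFitError("logistic fit did not converge")
    coef = fit.params[term]
    lo, hi = fit.conf_int().loc[term]
    return (
        float(np.exp(coef)),
        float(np.exp(lo)),
        float(np.exp(hi)),
        float(fit.pvalues[term]),
    )


#: outcome name -> (column in the outcomes table, eligibility column or None)
OUTCOME_COLUMNS = {
    "viral_suppression": ("suppressed", "eligible_suppression"),
    "physical_health_satisfaction": ("physical_satisfied", None),
    "psychological_health_satisfaction": ("psychological_satisfied", None),
}

RISK_LEVELS = ("heterosexual", "MSM", "IDU", "other")


def covariate_frame(covariates: pd.DataFrame, index_age_center: float = 50.0) -> pd.DataFrame:
    """Design columns for the adjusted models (complete-case rows only).

    Expects ``sex_at_birth``, ``age_years`` and ``risk_group`` columns; rows
    with missing sex, age, or risk group are dropped. Reference categories:
    man, heterosexual. Age enters linearly, centered at 50 years (centering
    does not change the exposure OR; it only conditions the optimization).
    """
    cov = covariates.copy()
    cov = cov[cov["sex_at_birth"].isin(["man", "woman"])]
    cov = cov[cov["risk_group"].isin(RISK_LEVELS)]
    cov = cov[cov["age_years"].notna()]
    out = pd.DataFrame(index=cov.index)
    out["person_id"] = cov["person_id"]
    out["woman"] = (cov["sex_at_birth"] == "woman").astype(float)
    out["age_c"] = cov["age_years"].astype(float) - index_age_center
    for level in RISK_LEVELS[1:]:
        out[f"risk_{level}"] = (cov["risk_group"] == level).astype(float)
    return out


def fit_outcome_models(
    flags: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
) -> list:
    """Crude and adjusted logistic ORs for the three treatment outcomes.

    The exposure is the ``difficult`` flag. For each outcome the crude model
    (outcome ~ difficult) is fitted on all rows with an observed outcome
    (restricted to eligible persons for viral suppression); the adjusted model
    additionally includes sex, linear age, and risk group on complete-case
    rows. Returns a list of :class:`OrEstimate` (crude first for each
    outcome, then adjusted when covariates were supplied).
    """
    df = flags.merge(outcomes, on="person_id", validate="one_to_one")
    cov_design = covariate_frame(covariates) if covariates is not None else None
    results = []
    for name, (col, elig) in OUTCOME_COLUMNS.items():
        sub = df
        if elig is not None:
            sub = sub[sub[elig].astype(bool)]
        sub = sub[sub[col].notna()]
        if len(sub) == 0:
            continue  # outcome not observed for anyone (e.g. no questionnaires)
        y = sub[col].astype(bool).to_numpy()
        x = sub["difficult"].astype(bool).to_numpy()
        a = int((x & y).sum())
        b = int((x & ~y).sum())
        c = int((~x & y).sum())
        d = int((~x & ~y).sum())
        X = pd.DataFrame({"difficult": x.astype(float)}, index=sub.index)
        or_, lo, hi, p = _fit_logit(y.astype(int), X, "difficult")
        results.append(
            OrEstimate(name, False, len(sub), or_, lo, hi, p, counts=(a, b, c, d))
        )
        if cov_design is not None:
            adj = sub[["person_id", col, "difficult"]].merge(
                cov_design, on="person_id", how="inner"
            )
            Xa = adj[["difficult", "woman", "age_c",
                      "risk_MSM", "risk_IDU", "risk_other"]].astype(float)
            ya = adj[col].astype(bool).astype(int).to_numpy()
            or_, lo, hi, p = _fit_logit(ya, Xa, "difficult")
            results.append(OrEstimate(name, True, len(adj), or_, lo, hi, p))
    return results


@dataclass
class SensitivityResult:
    """Suppression comparison after removing the recent-failure category."""

    n_difficult: int
    n_non_difficult: int
    rate_difficult: Optional[float]
    rate_non_difficult: Optional[float]
    p_value: Optional[float]
    or_estimate: Optional[OrEstimate]
    degenerate: bool


def sensitivity_excluding_recent_vf(
    flags: pd.DataFrame, outcomes: pd.DataFrame
) -> SensitivityResult:
    """Recompute the suppression comparison without recent-failure members.

    Persons flagged for recent virologic failure are removed from the analysis
    altogether (they, by construction, tend to have unsuppressed last viral
    loads). A difficult group left empty is reported as degenerate.
    """
    keep = flags[~flags["recent_virologic_failure"].astype(bool)]
    df = keep.merge(outcomes, on="person_id")
    df = df[df["eligible_suppression"].astype(bool) & df["suppressed"].notna()]
    x = df["difficult"].astype(bool).to_numpy()
    y = df["suppressed"].astype(bool).to_numpy()
    n_d, n_nd = int(x.sum()), int((~x).sum())
    rate_d = float(y[x].mean()) if n_d else None
    rate_nd = float(y[~x].mean()) if n_nd else None
    if n_d == 0 or n_nd == 0:
        return SensitivityResult(n_d, n_nd, rate_d, rate_nd, None, None, True)
    a, b = int((x & y).sum()), int((x & ~y).sum())
    c, d = int((~x & y).sum()), int((~x & ~y).sum())
    table = [[a, b], [c, d]]
    p = None
    if all(m > 0 for m in np.asarray(table).sum(axis=0)):
        p = chi_squared(table)[1]
    est = None
    if min(a, b, c, d) > 0:
        est = odds_ratio_2x2(a, b, c, d, outcome="viral_suppression_excluding_recent_vf")
    return SensitivityResult(n_d, n_nd, rate_d, rate_nd, p, est, False)
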