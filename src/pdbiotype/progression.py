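"""Longitudinal disease-progression contrasts between biotypes.

For each clinical outcome a linear mixed model is fitted by restricted
maximum likelihood:

    y_it = b0 + b_bio * bio1_i + b_t * t_it + b_int * (bio1_i * t_it)
           + covariates + u0_i + u1_i * t_it + e_it

with correlated Gaussian subject random intercepts u0 and slopes u1 and
Gaussian residuals.  ``bio1`` is an indicator for biotype 1, so ``b_int``
is the biotype slope contrast per month (positive = biotype 1 worsens
faster on scales where higher is worse).  Fixed-effect inference uses
Wald z tests; across the outcome family the interaction p-values are
Benjamini-Hochberg adjusted.

If the correlated random-effect covariance is singular the model is
automatically refitted with independent random intercepts and slopes,
and the result notes the fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = ["MixedModelResult", "fit_progression_lmm", "progression_summary"]

DEFAULT_COVARIATES = ("age", "sex", "race", "site")


@dataclass
class MixedModelResult:
    """REML fit of one outcome's progression model."""

    outcome: str
    params: pd.Series  # fixed effects
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    beta_interaction: float  # biotype-1 slope minus biotype-2 slope, per month
    se_interaction: float
    p_interaction: float
    slope_biotype1: float
    slope_biotype2: float
    intercept_sd: float
    slope_sd: float
    re_correlation: float
    residual_sd: float
    converged: bool
    uncorrelated_refit: bool
    n_subjects: int
    n_observations: int
    warnings: list[str] = field(default_factory=list)

    def wald_ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return (self.beta_interaction - z * self.se_interaction, self.beta_interaction + z * self.se_interaction)


def _prepare(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    df = table[table["outcome"] == outcome].copy()
    if df.empty:
        raise ValueError(f"no rows for outcome {outcome!r}")
    biotypes = np.unique(df["biotype"])
    if biotypes.size < 2:
        raise ValueError("both biotypes must be present in the longitudinal table")
    df["bio1"] = (df["biotype"] == 1).astype(float)
    df["months"] = df["visit_month"].astype(float)
    # the model is fitted on time in years: with five years of monthly-
    # scale follow-up the slope variance is ~1e4 smaller than the
    # intercept variance on the month scale, which stalls the REML
    # optimizer; coefficients are converted back to per-month units
    df["years"] = df["months"] / 12.0
    n_visits = df.groupby("subject_id")["months"].nunique()
    if (n_visits >= 2).mean() < 0.8:
        raise ValueError("fewer than 80% of subjects have >= 2 visits")
    return df


def _exact_result(outcome: str, ols, df: pd.DataFrame) -> MixedModelResult:
    params = ols.params.copy()
    bse = ols.bse.copy()
    rename = {"years": "months", "years:bio1": "months:bio1"}
    for name in ("years", "years:bio1"):
        params[name] /= 12.0
        bse[name] /= 12.0
    params = params.rename(rename)
    bse = bse.rename(rename)
    key = "months:bio1"
    beta_int = float(params[key])
    slope2 = float(params["months"])
    return MixedModelResult(
        outcome=outcome,
        params=params,
        bse=bse,
        zvalues=ols.tvalues.rename(rename),
        pvalues=ols.pvalues.rename(rename),
        beta_interaction=beta_int,
        se_interaction=float(bse[key]),
        p_interaction=float(ols.pvalues.rename(rename)[key]),
        slope_biotype1=slope2 + beta_int,
        slope_biotype2=slope2,
        intercept_sd=0.0,
        slope_sd=0.0,
        re_correlation=0.0,
        residual_sd=float(np.sqrt(max(ols.mse_resid, 0.0))),
        converged=True,
        uncorrelated_refit=False,
        n_subjects=int(df["subject_id"].nunique()),
        n_observations=len(df),
        warnings=["noise-free data: fixed-effects OLS is exact; variance components unidentified"],
    )


def fit_progression_lmm(
    table: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> MixedModelResult:
    """Fit the random-intercept/random-slope model for one outcome.

    Covariates are entered as fixed effects (site and race as categorical
    dummies).  Returns Wald z inference for every fixed effect plus the
    variance components; non-convergence is flagged on the result, never
    silent.
    """
    df = _prepare(table, outcome)
    terms = ["years * bio1"]
    for c in covariates:
        if c not in df.columns:
            raise ValueError(f"covariate {c!r} missing from the table")
        terms.append(f"C({c})" if df[c].dtype == object or c in ("site", "race", "sex") else c)
    formula = "value ~ " + " + ".join(terms)

    # degenerate input: if fixed effects alone fit the data exactly the
    # variance components are unidentified and OLS *is* the solution
    ols = smf.ols(formula, df).fit()
    y_scale = float(np.var(df["value"])) or 1.0
    if ols.mse_resid / y_scale < 1e-16:
        return _exact_result(outcome, ols, df)

    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups=df["subject_id"], re_formula="~years")
        fit = model.fit(reml=True)
        caught += [str(w.message) for w in wrec]

    uncorrelated = False
    cov_re = np.asarray(fit.cov_re)
    if not fit.converged or np.linalg.matrix_rank(cov_re) < 2 or np.linalg.cond(cov_re) > 1e10:
        # singular random-effect covariance: refit with independent
        # intercept and slope variance components
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            model2 = smf.mixedlm(
                formula,
                df,
                groups=df["subject_id"],
                re_formula="1",
                vc_formula={"slope": "0 + years"},
            )
            fit2 = model2.fit(reml=True)
            caught += [str(w.message) for w in wrec]
        if fit2.converged or not fit.converged:
            fit = fit2
            uncorrelated = True

    fe = fit.fe_params.index
    params = fit.params[fe].copy()
    bse = fit.bse[fe].copy()
    # convert the time-family coefficients back to per-month units
    rename = {"years": "months", "years:bio1": "months:bio1"}
    for name in ("years", "years:bio1"):
        params[name] /= 12.0
        bse[name] /= 12.0
    params = params.rename(rename)
    bse = bse.rename(rename)
    z = params / bse
    from scipy.stats import norm

    pvals = pd.Series(2.0 * norm.sf(np.abs(z)), index=params.index)

    key = "months:bio1"
    beta_int = float(params[key])
    slope2 = float(params["months"])

    if uncorrelated:
        intercept_sd = float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0)))
        slope_var = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
        slope_sd = float(np.sqrt(max(slope_var, 0.0))) / 12.0
        corr = 0.0
    else:
        cov_re = np.asarray(fit.cov_re)
        intercept_sd = float(np.sqrt(max(cov_re[0, 0], 0.0)))
        slope_sd = float(np.sqrt(max(cov_re[1, 1], 0.0))) / 12.0
        corr = float(cov_re[0, 1] / np.sqrt(cov_re[0, 0] * cov_re[1, 1])) if cov_re[0, 0] > 0 and cov_re[1, 1] > 0 else 0.0

    return MixedModelResult(
        outcome=outcome,
        params=params,
        bse=bse,
        zvalues=z,
        pvalues=pvals,
        beta_interaction=beta_int,
        se_interaction=float(bse[key]),
        p_interaction=float(pvals[key]),
        slope_biotype1=slope2 + beta_int,
        slope_biotype2=slope2,
        intercept_sd=intercept_sd,
        slope_sd=slope_sd,
        re_correlation=float(np.clip(corr, -1.0, 1.0)),
        residual_sd=float(np.sqrt(fit.scale)),
        converged=bool(fit.converged),
        uncorrelated_refit=uncorrelated,
        n_subjects=int(df["subject_id"].nunique()),
        n_observations=len(df),
        warnings=caught,
    )


def progression_summary(
    table: pd.DataFrame,
    outcomes: tuple[str, ...],
    q: float = 0.05,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """One row per outcome: slope contrast, Wald inference, BH adjustment.

    ``faster_biotype`` is the biotype with the larger fitted slope
    magnitude, i.e. the faster-declining group on worsening scales.
    """
    rows, failures = [], []
    for k in outcomes:
        try:
            res = fit_progression_lmm(table, k, covariates=covariates)
        except Exception as exc:  # pragma: no cover - aggregate error path
            failures.append((k, exc))
            continue
        rows.append(
            {
                "outcome": k,
                "beta_interaction": res.beta_interaction,
                "se": res.se_interaction,
                "slope_biotype1": res.slope_biotype1,
                "slope_biotype2": res.slope_biotype2,
                "p": res.p_interaction,
                "converged": res.converged,
                "faster_biotype": 1 if abs(res.slope_biotype1) > abs(res.slope_biotype2) else 2,
            }
        )
    if not rows:
        raise RuntimeError(f"all progression models failed: {failures}")
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p"].to_numpy(), alpha=q, method="fdr_bh")[1]
    out["significant"] = multipletests(out["p"].to_numpy(), alpha=q, method="fdr_bh")[0]
    return out
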