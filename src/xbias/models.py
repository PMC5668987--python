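"""Linear models relating selection pressure, escape status, and sex bias.

Two multi-covariate models and a univariate family, all ordinary least
squares with treatment (dummy) coding:

* dN/dS model: ``dnds ~ region + xy_pair + avg_expr + escape_status +
  disease_flag`` over X-linked genes, asking whether escape genes are under
  different protein-level selection once strata, Y homology, expression
  level, and disease status are accounted for. Reference levels: XAR,
  non-escape, non-XY-pair, non-disease.
* breadth model: ``breadth ~ bias + dnds + avg_expr`` over autosomal genes,
  relating expression breadth (tissue count, a pleiotropy proxy) to sex
  bias with unbiased as the reference level.
* univariate fits ``y ~ x`` for any response/predictor pair, including
  two-level gene-set flags, where the slope equals the difference of group
  means exactly.

P values come from the t distribution with residual degrees of freedom;
rows with missing fields are dropped per model (complete case) and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .io import require_columns


class RankDeficientError(ValueError):
    """The design matrix is rank-deficient (collinear terms are named)."""


@dataclass
class RegressionFit:
    """Coefficient table plus fit summary for one OLS model."""

    terms: list[str]
    coefficients: pd.Series
    standard_errors: pd.Series
    t_statistics: pd.Series
    p_values: pd.Series
    n: int
    r_squared: float
    n_dropped: int = 0
    f_pvalue: float = float("nan")
    spearman: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (term, beta, se, t, p) table."""
        return pd.DataFrame({
            "term": self.terms,
            "beta": self.coefficients.to_numpy(),
            "se": self.standard_errors.to_numpy(),
            "t": self.t_statistics.to_numpy(),
            "p": self.p_values.to_numpy(),
        })


def _collinear_columns(exog: pd.DataFrame) -> list[str]:
    """Names of columns that do not increase the design rank."""
    bad = []
    rank = 0
    kept: list[np.ndarray] = []
    for col in exog.columns:
        candidate = np.column_stack(kept + [exog[col].to_numpy(dtype=float)])
        new_rank = np.linalg.matrix_rank(candidate)
        if new_rank > rank:
            rank = new_rank
            kept.append(exog[col].to_numpy(dtype=float))
        else:
            bad.append(col)
    return bad


def _fit_ols(formula: str, data: pd.DataFrame, n_dropped: int,
             anova_term: str | None = None) -> RegressionFit:
    model = smf.ols(formula, data=data)
    exog = pd.DataFrame(model.exog, columns=model.exog_names)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise RankDeficientError(
            "rank-deficient design; collinear terms: "
            + ", ".join(_collinear_columns(exog)))
    if model.exog.shape[0] <= model.exog.shape[1]:
        raise ValueError("not enough observations for the number of design columns")
    fit = model.fit()
    f_p = float("nan")
    if anova_term is not None:
        cols = [name for name in model.exog_names if anova_term in name]
        if cols:
            hypothesis = ", ".join(f"{c} = 0" for c in cols)
            f_p = float(fit.f_test(hypothesis).pvalue)
    return RegressionFit(
        terms=list(fit.params.index),
        coefficients=fit.params,
        standard_errors=fit.bse,
        t_statistics=fit.tvalues,
        p_values=fit.pvalues,
        n=int(fit.nobs),
        r_squared=float(fit.rsquared),
        n_dropped=n_dropped,
        f_pvalue=f_p,
    )


def _complete_cases(records: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, int]:
    sub = records[columns].dropna()
    return sub.reset_index(drop=True), len(records) - len(sub)


def _quote(level) -> str:
    return f"Treatment('{level}')"


def fit_dnds_model(records: pd.DataFrame) -> RegressionFit:
    """dN/dS on {region, XY pair, mean expression, escape status, disease}.

    Categorical reference levels follow the reporting convention of the
    coefficient tables this model feeds (XCR vs XAR, escape vs non-escape,
    etc.). Boolean flags enter as 0/1.
    """
    require_columns(records, ["dnds", "region", "xy_pair", "avg_expr",
                              "escape_status", "disease_flag"], "record table")
    data, n_dropped = _complete_cases(
        records, ["dnds", "region", "xy_pair", "avg_expr",
                  "escape_status", "disease_flag"])
    data = data.assign(xy_pair=data["xy_pair"].astype(int),
                       disease_flag=data["disease_flag"].astype(int))
    terms = []
    if data["region"].nunique() > 1:
        terms.append(f"C(region, {_quote('XAR')})")
    terms.append("xy_pair")
    terms.append("avg_expr")
    if data["escape_status"].nunique() > 1:
        terms.append(f"C(escape_status, {_quote('non-escape')})")
    terms.append("disease_flag")
    return _fit_ols("dnds ~ " + " + ".join(terms), data, n_dropped,
                    anova_term="escape_status")


def fit_breadth_model(records: pd.DataFrame) -> RegressionFit:
    """Expression breadth on {sex bias, dN/dS, mean expression}.

    Unbiased genes are the reference level; with a single bias level in the
    input the categorical term is dropped and an intercept-plus-covariates
    model is fitted.
    """
    require_columns(records, ["breadth", "bias", "dnds", "avg_expr"], "record table")
    data, n_dropped = _complete_cases(records, ["breadth", "bias", "dnds", "avg_expr"])
    terms = []
    if data["bias"].nunique() > 1:
        ref = "unbiased" if "unbiased" in set(data["bias"]) else sorted(set(data["bias"]))[0]
        terms.append(f"C(bias, {_quote(ref)})")
    terms += ["dnds", "avg_expr"]
    return _fit_ols("breadth ~ " + " + ".join(terms), data, n_dropped,
                    anova_term="bias")


def fit_univariate(records: pd.DataFrame,
                   response: str,
                   predictor: str) -> RegressionFit:
    """Simple OLS ``response ~ predictor``.

    Categorical/boolean predictors are dummy-coded (reference: 'unbiased'
    when present, else the first level); for a two-level flag the slope is
    exactly the difference of group means. Numeric response/predictor pairs
    additionally get a Spearman correlation in ``fit.spearman``.
    """
    require_columns(records, [response, predictor], "record table")
    data, n_dropped = _complete_cases(records, [response, predictor])
    col = data[predictor]
    if col.dtype == bool:
        data = data.assign(**{predictor: col.astype(int)})
        col = data[predictor]
    if pd.api.types.is_numeric_dtype(col):
        if np.ptp(col.to_numpy(dtype=float)) == 0:
            raise RankDeficientError(f"constant predictor {predictor!r}")
        formula = f"{response} ~ {predictor}"
    else:
        if col.nunique() < 2:
            raise RankDeficientError(f"constant predictor {predictor!r}")
        ref = "unbiased" if "unbiased" in set(col) else sorted(set(col))[0]
        formula = f"{response} ~ C({predictor}, {_quote(ref)})"
    fit = _fit_ols(formula, data, n_dropped, anova_term=predictor)
    if pd.api.types.is_numeric_dtype(col):
        from scipy import stats
        rho, p = stats.spearmanr(data[response], col)
        fit.spearman = {"rho": float(rho), "p": float(p)}
    return fit
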