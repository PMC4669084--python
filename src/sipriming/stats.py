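"""Categorical linear models, sequential ANOVA, Tukey HSD and diagnostics.

A two-way categorical linear model (time, treatment, optionally their
interaction) fitted by OLS, decomposed by sequential (type-1) ANOVA in
entry order, with all-pairs Tukey honest-significant-difference
post-hocs based on the studentized range distribution, and
model-validation tables (residuals vs fitted, normal QQ pairs,
residuals vs each factor).

Model fitting and the sequential decomposition are delegated to
statsmodels; the Tukey–Kramer assembly (marginal means, pooled residual
mean square, studentized-range probabilities via scipy) is local.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["AnovaFit", "fit_two_way_lm", "tukey_hsd", "diagnostics"]


@dataclass
class AnovaFit:
    """A fitted categorical linear model plus its sequential ANOVA table.

    ``table`` rows follow the term entry order and end with Residual;
    columns: df, sum_sq (sequential), mean_sq, F, p.
    """

    model: object  # statsmodels RegressionResultsWrapper
    table: pd.DataFrame
    response: str
    factors: tuple[str, ...]
    data: pd.DataFrame


def fit_two_way_lm(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str] = ("day", "treatment"),
    with_interaction: bool = True,
) -> AnovaFit:
    """Fit response ~ factor₁ + factor₂ (+ interaction), all categorical.

    The sum-of-squares decomposition is sequential (type 1) in the
    order the factors are given, so term sums of squares depend on that
    order (their total does not).  Raises on a saturated model with no
    residual degrees of freedom.
    """
    for col in (response, *factors):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not in data")
    terms = [f"C(Q('{f}'))" for f in factors]
    if with_interaction:
        if len(factors) < 2:
            raise ValueError("interaction requires two factors")
        terms.append(":".join(terms[:2]))
    formula = f"Q('{response}') ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=data).fit()
    if fit.df_resid <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")

    table = sm.stats.anova_lm(fit, typ=1)
    # tidy names: C(Q('day')) -> day, interaction -> day:treatment
    rename = {}
    for raw in table.index:
        name = raw
        for f in factors:
            name = name.replace(f"C(Q('{f}'))", f)
        rename[raw] = name
    table = table.rename(index=rename)
    table = table.rename(columns={"PR(>F)": "p"})
    table["mean_sq"] = table["sum_sq"] / table["df"]
    table = table[["df", "sum_sq", "mean_sq", "F", "p"]]
    return AnovaFit(
        model=fit,
        table=table,
        response=response,
        factors=tuple(factors),
        data=data.reset_index(drop=True),
    )


def tukey_hsd(fit: AnovaFit, factor: str, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD (Tukey–Kramer when unbalanced) for one factor.

    Uses the fitted model's residual mean square and residual degrees
    of freedom (so post-hocs inherit the full model's error estimate)
    and the factor's marginal group means.  For each level pair:
    mean difference, studentized-range adjusted p, and a familywise
    ``1 − alpha`` confidence interval with half-width
    q_crit × √(MSE/2 × (1/nᵢ + 1/nⱼ)).
    """
    if factor not in fit.data.columns:
        raise ValueError(f"{factor!r} is not a column of the model data")
    groups = fit.data.groupby(factor)[fit.response]
    means = groups.mean()
    counts = groups.count()
    k = len(means)
    if k < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    mse = float(fit.model.mse_resid)
    df_resid = float(fit.model.df_resid)
    qcrit = sps.studentized_range.ppf(1 - alpha, k, df_resid)

    rows = []
    levels = list(means.index)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = float(means[b] - means[a])
            se = np.sqrt(mse / 2.0 * (1.0 / counts[a] + 1.0 / counts[b]))
            q = abs(diff) / se
            p = float(np.clip(sps.studentized_range.sf(q, k, df_resid), 0.0, 1.0))
            half = qcrit * se
            rows.append(
                {
                    "level_a": a,
                    "level_b": b,
                    "diff": diff,
                    "se": float(se),
                    "q": float(q),
                    "p_adj": p,
                    "ci_low": diff - half,
                    "ci_high": diff + half,
                }
            )
    return pd.DataFrame(rows)


def diagnostics(fit: AnovaFit) -> dict[str, pd.DataFrame]:
    """Model-validation tables (no rendering; plot-ready).

    * ``residuals_fitted``: fitted values vs raw residuals
      (homogeneity of variance check);
    * ``qq``: theoretical normal quantiles vs sorted standardised
      residuals (normality check);
    * ``residuals_by_<factor>``: residuals against each explanatory
      factor (independence check).
    """
    resid = np.asarray(fit.model.resid, dtype=float)
    fitted = np.asarray(fit.model.fittedvalues, dtype=float)
    out: dict[str, pd.DataFrame] = {
        "residuals_fitted": pd.DataFrame({"fitted": fitted, "residual": resid})
    }
    sd = resid.std(ddof=1)
    std_resid = (resid - resid.mean()) / sd if sd > 0 else np.zeros_like(resid)
    n = len(resid)
    theo = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    out["qq"] = pd.DataFrame(
        {"theoretical": theo, "standardised_residual": np.sort(std_resid)}
    )
    for f in fit.factors:
        out[f"residuals_by_{f}"] = pd.DataFrame(
            {f: fit.data[f].to_numpy(), "residual": resid}
        )
    return out
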