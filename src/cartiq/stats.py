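"""Site-level association analysis: GAG vs. stiffness vs. sodium.

Joins the biomechanical, imaging and biochemical read-outs per indentation
site and quantifies their pairwise association three ways: Pearson
correlation over all sites, Pearson correlation within thickness strata
(severely degraded cartilage <= 1.5 mm vs. moderately degraded > 1.5 mm),
and plateau-adjusted linear models (plateau as categorical fixed effect,
with an optional random-intercept variant).  Raw p-values are reported
without multiplicity correction; sites with missing values are excluded
listwise and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "AdjustedModelFit",
    "ANALYSIS_VARIABLES",
    "stratify_by_thickness",
    "pearson_correlation",
    "adjusted_linear_model",
    "correlation_table",
]

#: Variables entering the pairwise correlation structure.
ANALYSIS_VARIABLES = (
    "gag_mg_per_ml",
    "sodium_mM",
    "peak_modulus_MPa",
    "eq_modulus_MPa",
    "permeability_k1",
)

SEVERE_THICKNESS_MM = 1.5


@dataclass
class CorrelationResult:
    var_x: str
    var_y: str
    pearson_r: float
    p_value: float
    n: int


@dataclass
class AdjustedModelFit:
    outcome: str
    predictor: str
    coefficient: float
    std_error: float
    p_value: float
    plateau_terms: dict[str, float]
    method: str
    n: int


def stratify_by_thickness(thickness_mm: float) -> str:
    """'severe' for cartilage height <= 1.5 mm, 'moderate' above."""
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    return "severe" if thickness_mm <= SEVERE_THICKNESS_MM else "moderate"


def pearson_correlation(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Product-moment correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(var_x, var_y, float(r), float(p), int(x.size))


def adjusted_linear_model(
    records: pd.DataFrame,
    outcome: str,
    predictor: str,
    method: str = "fixed",
) -> AdjustedModelFit:
    """Linear model of ``outcome ~ predictor`` adjusted for plateau.

    ``method='fixed'`` fits an OLS model with plateau as a categorical
    fixed effect; ``method='mixed'`` fits a random-intercept-per-plateau
    mixed model instead.  With a single plateau the adjustment is absorbed
    by the intercept and the model degenerates to simple regression.
    """
    df = records[[outcome, predictor, "plateau_id"]].dropna()
    n = len(df)
    if n <= 2:
        raise ValueError("too few complete records")
    plateaus = df["plateau_id"].nunique()
    if method == "fixed":
        formula = f"{outcome} ~ {predictor}"
        if plateaus > 1:
            formula += " + C(plateau_id)"
        fit = smf.ols(formula, data=df).fit()
        plateau_terms = {
            k: float(v) for k, v in fit.params.items() if k.startswith("C(plateau_id)")
        }
    elif method == "mixed":
        if plateaus < 2:
            raise ValueError("mixed model needs at least 2 plateaus")
        fit = smf.mixedlm(
            f"{outcome} ~ {predictor}", data=df, groups=df["plateau_id"]
        ).fit(method="lbfgs")
        plateau_terms = {"random_intercept_var": float(fit.cov_re.iloc[0, 0])}
    else:
        raise ValueError("method must be 'fixed' or 'mixed'")
    if not np.isfinite(fit.params[predictor]):
        raise ValueError("rank-deficient design: non-finite estimate")
    return AdjustedModelFit(
        outcome=outcome,
        predictor=predictor,
        coefficient=float(fit.params[predictor]),
        std_error=float(fit.bse[predictor]),
        p_value=float(fit.pvalues[predictor]),
        plateau_terms=plateau_terms,
        method=method,
        n=n,
    )


def correlation_table(records: pd.DataFrame) -> pd.DataFrame:
    """All pairwise correlations, overall and within each thickness stratum.

    Returns a tidy frame with columns var_x, var_y, scope (all | moderate |
    severe), r, p, n and flag.  Strata with fewer than 3 complete pairs are
    emitted with NaN statistics and flag ``insufficient_n``; listwise
    exclusions are reflected in ``n``.
    """
    df = records.copy()
    if "stratum" not in df.columns:
        df["stratum"] = df["thickness_mm"].map(stratify_by_thickness)
    rows = []
    scopes = {"all": df} | {
        s: df[df["stratum"] == s] for s in ("moderate", "severe")
    }
    for vx, vy in combinations(ANALYSIS_VARIABLES, 2):
        for scope, sub in scopes.items():
            pair = sub[[vx, vy]].dropna()
            if len(pair) < 3:
                rows.append(
                    dict(var_x=vx, var_y=vy, scope=scope, r=np.nan, p=np.nan,
                         n=len(pair), flag="insufficient_n")
                )
                continue
            try:
                res = pearson_correlation(pair[vx], pair[vy], vx, vy)
            except ValueError:
                rows.append(
                    dict(var_x=vx, var_y=vy, scope=scope, r=np.nan, p=np.nan,
                         n=len(pair), flag="degenerate")
                )
                continue
            rows.append(
                dict(var_x=vx, var_y=vy, scope=scope, r=res.pearson_r,
                     p=res.p_value, n=res.n, flag="ok")
            )
    return pd.DataFrame(rows)
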