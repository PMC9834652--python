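"""Prediction equations and statistics for ingredient net energy.

Three pieces:

* The classical NE prediction equations of Noblet and co-workers for pig
  feeds, re-expressed in MJ/kg DM (the bracketed chemistry terms are in
  kcal and converted with 4.184 kJ/kcal):

      NE1 = 0.700*DE + (16.1*EE + 4.8*starch - 9.1*CP - 8.7*ADF)/1000*4.184
      NE2 = 0.726*ME + (13.3*EE + 3.9*starch - 6.2*CP - 8.3*ADF)/1000*4.184

  with EE, starch, CP, ADF in % DM, and the relative error of a determined
  NE against the mean of the two predictions.

* A Pearson correlation matrix with two-sided p-values (t transform).

* OLS and forward-with-backward-check stepwise regression with R2, RMSE,
  AIC, BIC and the overall F-test p-value. AIC/BIC use the Gaussian
  log-likelihood form AIC = n*ln(SSE/n) + 2k, BIC = n*ln(SSE/n) + k*ln(n),
  with k counting the intercept.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError

KCAL_TO_KJ = 4.184

NE1_COEFFS = {"DE": 0.700, "EE": 16.1, "starch": 4.8, "CP": -9.1, "ADF": -8.7}
NE2_COEFFS = {"ME": 0.726, "EE": 13.3, "starch": 3.9, "CP": -6.2, "ADF": -8.3}


def noblet_ne1(de: float, ee: float, starch: float, cp: float, adf: float) -> float:
    """DE-based NE prediction, MJ/kg DM (chemistry in % DM)."""
    return 0.700 * de + (16.1 * ee + 4.8 * starch - 9.1 * cp - 8.7 * adf) / 1000.0 * KCAL_TO_KJ


def noblet_ne2(me: float, ee: float, starch: float, cp: float, adf: float) -> float:
    """ME-based NE prediction, MJ/kg DM (chemistry in % DM)."""
    return 0.726 * me + (13.3 * ee + 3.9 * starch - 6.2 * cp - 8.3 * adf) / 1000.0 * KCAL_TO_KJ


def relative_error(determined: float, ne1: float, ne2: float) -> float:
    """Percent deviation of a determined NE from the mean of the two predictions."""
    mean_pred = (ne1 + ne2) / 2.0
    if mean_pred <= 0:
        raise DomainError(f"mean predicted NE must be positive, got {mean_pred}")
    return 100.0 * (determined - mean_pred) / mean_pred


@dataclass(frozen=True)
class NobletPrediction:
    ingredient_id: str
    predicted_NE1: float  # MJ/kg DM
    predicted_NE2: float  # MJ/kg DM
    relative_error_pct: float


def predict_noblet(
    ingredient_id: str, de: float, me: float, ee: float, starch: float, cp: float,
    adf: float, determined_ne: float,
) -> NobletPrediction:
    ne1 = noblet_ne1(de, ee, starch, cp, adf)
    ne2 = noblet_ne2(me, ee, starch, cp, adf)
    return NobletPrediction(ingredient_id, ne1, ne2, relative_error(determined_ne, ne1, ne2))


# ---------------------------------------------------------------------------
# Correlation


@dataclass
class CorrelationMatrix:
    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int


def pearson_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson r and two-sided p-values over the table's columns.

    Rows are samples (ingredients), columns variables. Zero-variance columns
    give undefined correlations, reported as NaN with a warning.
    """
    if table.isna().any().any():
        raise DomainError("correlation table must have no missing cells")
    n = len(table)
    if n < 3:
        raise DomainError(f"need >= 3 rows for p-values, got {n}")
    cols = tuple(table.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    degenerate = [c for c in cols if np.ptp(table[c].to_numpy()) == 0]
    if degenerate:
        warnings.warn(f"zero-variance columns, correlations undefined: {degenerate}")
    for a, b in itertools.combinations(cols, 2):
        if a in degenerate or b in degenerate:
            rv, pv = np.nan, np.nan
        else:
            rv, pv = stats.pearsonr(table[a], table[b])
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
    for c in degenerate:
        r.loc[c, c] = np.nan
        p.loc[c, c] = np.nan
    return CorrelationMatrix(cols, r, p, n)


# ---------------------------------------------------------------------------
# Regression


@dataclass
class RegressionModel:
    response: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    r2: float
    rmse: float
    aic: float
    bic: float
    p_value: float
    n: int
    sse: float = field(repr=False, default=np.nan)

    @property
    def equation(self) -> str:
        """Human-readable equation with 2-decimal coefficients (report convention)."""
        parts = [f"{self.response} = {self.intercept:.2f}"]
        for name, c in self.coefficients.items():
            parts.append(f"{'+' if c >= 0 else '-'} {abs(c):.2f}*{name}")
        return " ".join(parts)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.intercept, dtype=float)
        for name, c in self.coefficients.items():
            out += c * X[name].to_numpy(dtype=float)
        return out


def ols_fit(data: pd.DataFrame, response: str, predictors: list[str] | tuple[str, ...]) -> RegressionModel:
    """Ordinary least squares of ``response`` on ``predictors`` with intercept.

    RMSE uses the residual degrees of freedom, sqrt(SSE/(n - p - 1)).
    Raises on rank deficiency, naming the collinear predictor set.
    """
    predictors = list(predictors)
    y = data[response].to_numpy(dtype=float)
    X = sm.add_constant(data[predictors].to_numpy(dtype=float))
    n, k = X.shape
    if n <= k:
        raise DomainError(f"n={n} too small for {k} parameters")
    if np.linalg.matrix_rank(X) < k:
        raise DomainError(f"design matrix rank-deficient; collinear set: {predictors}")
    fit = sm.OLS(y, X).fit()
    sse = float(fit.ssr)
    return RegressionModel(
        response=response,
        predictors=tuple(predictors),
        intercept=float(fit.params[0]),
        coefficients={p: float(c) for p, c in zip(predictors, fit.params[1:])},
        r2=float(fit.rsquared),
        rmse=float(np.sqrt(sse / (n - k))),
        aic=float(n * np.log(sse / n) + 2 * k),
        bic=float(n * np.log(sse / n) + k * np.log(n)),
        p_value=float(fit.f_pvalue),
        n=n,
        sse=sse,
    )


def _partial_f_pvalue(data: pd.DataFrame, response: str, base: list[str], add: str) -> float:
    """p-value of the partial F test for adding ``add`` to ``base``."""
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    sse0 = ols_fit(data, response, base).sse if base else float(
        ((y - y.mean()) ** 2).sum()
    )
    m1 = ols_fit(data, response, base + [add])
    df2 = n - len(base) - 2
    if df2 <= 0 or m1.sse <= 0:
        return 0.0 if m1.sse < sse0 else 1.0
    f = (sse0 - m1.sse) / (m1.sse / df2)
    return float(stats.f.sf(f, 1, df2))


def variance_inflation(data: pd.DataFrame, predictors: list[str]) -> dict[str, float]:
    """VIF of each predictor against the others (1.0 for a single predictor)."""
    out = {}
    for p in predictors:
        others = [q for q in predictors if q != p]
        if not others:
            out[p] = 1.0
            continue
        r2 = ols_fit(data, p, others).r2
        out[p] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def stepwise_select(
    data: pd.DataFrame,
    response: str,
    candidates: list[str] | tuple[str, ...],
    entry_alpha: float = 0.15,
    stay_alpha: float = 0.15,
    vif_limit: float = 10.0,
) -> list[RegressionModel]:
    """Forward stepwise selection with backward checks and a collinearity guard.

    At each step the candidate with the smallest partial-F p-value below
    ``entry_alpha`` enters, provided no variance-inflation factor would exceed
    ``vif_limit``; after entry, any term whose p-value rises above
    ``stay_alpha`` is dropped. Every admissible model visited along the path
    is returned, ranked by (R2 desc, RMSE asc), ties broken by fewer
    parameters then alphabetical predictors. Deterministic given the data.
    """
    if not candidates:
        raise DomainError("candidate predictor list is empty")
    candidates = list(candidates)
    selected: list[str] = []
    seen: dict[tuple[str, ...], RegressionModel] = {}
    while True:
        remaining = [c for c in candidates if c not in selected]
        best, best_p = None, entry_alpha
        for c in remaining:
            if len(selected) + 2 >= len(data):
                break  # no residual degrees of freedom left
            try:
                pv = _partial_f_pvalue(data, response, selected, c)
            except DomainError:
                continue  # collinear with current terms
            vifs = variance_inflation(data, selected + [c])
            if max(vifs.values()) > vif_limit:
                continue
            if pv < best_p:
                best, best_p = c, pv
        if best is None:
            break
        selected.append(best)
        # backward check: drop terms no longer significant
        while len(selected) > 1:
            worst, worst_p = None, stay_alpha
            for c in selected:
                pv = _partial_f_pvalue(
                    data, response, [q for q in selected if q != c], c
                )
                if pv > worst_p:
                    worst, worst_p = c, pv
            if worst is None:
                break
            selected.remove(worst)
        model = ols_fit(data, response, selected)
        seen[tuple(sorted(selected))] = model
    if not seen:
        warnings.warn(
            f"no candidate passed entry_alpha={entry_alpha} for response {response!r}"
        )
        return []
    return sorted(
        seen.values(),
        key=lambda m: (-m.r2, m.rmse, len(m.predictors), tuple(sorted(m.predictors))),
    )
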