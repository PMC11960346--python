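"""Linear ILR regression of mental well-being on the 24-h composition.

Implements the three-model covariate ladder used in cross-sectional
time-use epidemiology:

* model 1 — unadjusted (intercept + 3 ILR coordinates),
* model 2 — adjusted for age, sex, education, marital status and
  professional activity,
* model 3 — additionally adjusted for smoking and chronic conditions.

Per-behaviour coefficients are obtained by pivot rotation: the model is
refit once per behaviour with that behaviour in the first (pivot) ILR
coordinate, whose coefficient is then the association of time in that
behaviour relative to all remaining behaviours.  Fitted values, R² and the
overall F-test are identical across rotations (same column space).

Reported coefficients are per unit ILR.  This is the only scale on which
the coefficient of a single coordinate is well defined in this model; a
"per hour" reading would require fixing the whole reallocation path and is
handled by the substitution module instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .coda import PART_ORDER, ilr, sbp_pivot

#: Covariates entering each model; order fixes the design-matrix layout.
MODEL_COVARIATES: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("age", "sex", "education", "marital", "professional"),
    3: ("age", "sex", "education", "marital", "professional", "smoking", "chronic"),
}

#: Category levels (first entry = dummy reference level).
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "education": ("low", "medium", "high"),
    "marital": ("married/cohabitant", "single"),
    "professional": ("active", "inactive"),
    "smoking": ("no", "yes"),
    "chronic": ("no", "yes"),
}

ILR_COLUMNS = ("ilr1", "ilr2", "ilr3")


class ScoringError(ValueError):
    """Raised for invalid WEMWBS item responses."""


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise unusable design matrices."""


def score_wemwbs(items) -> int:
    """Total WEMWBS score: the sum of 14 item responses, each in 1..5.

    The scale runs 14 (all items 1) to 70 (all items 5); higher scores
    indicate better mental well-being.  Missing or out-of-range items raise
    — no imputation is performed.
    """
    arr = np.asarray(items, dtype=float)
    if arr.shape != (14,):
        raise ScoringError(f"expected 14 item responses, got shape {arr.shape}")
    if np.any(~np.isfinite(arr)):
        raise ScoringError("missing item response")
    if np.any((arr < 1) | (arr > 5)) or np.any(arr != np.round(arr)):
        raise ScoringError("item responses must be integers in 1..5")
    return int(arr.sum())


@dataclass
class RegressionFit:
    """OLS fit summary with the pieces substitution modelling needs."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    r2: float
    f_p: float
    n_used: int
    df_resid: float
    pivot_index: int
    model_id: int
    pvalues: pd.Series = field(repr=False, default=None)
    fittedvalues: np.ndarray = field(repr=False, default=None)

    @property
    def ilr_params(self) -> np.ndarray:
        return self.params[list(ILR_COLUMNS)].to_numpy()

    @property
    def ilr_cov(self) -> np.ndarray:
        return self.cov.loc[list(ILR_COLUMNS), list(ILR_COLUMNS)].to_numpy()


def build_design(
    participants: pd.DataFrame,
    pivot_index: int = 1,
    model_id: int = 1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix and response for one model/pivot combination.

    Columns: intercept, the three ILR coordinates under
    ``sbp_pivot(4, pivot_index)``, then dummy-coded covariates with
    first-listed reference levels.  Rows with a missing chronic-condition
    status are dropped (listwise) only when the model includes chronic.
    """
    if model_id not in MODEL_COVARIATES:
        raise ValueError(f"model_id must be one of {sorted(MODEL_COVARIATES)}")
    covs = MODEL_COVARIATES[model_id]
    df = participants
    if "chronic" in covs:
        df = df[df["chronic"].isin(CATEGORY_LEVELS["chronic"])]

    comp = df[list(PART_ORDER)].to_numpy(dtype=float)
    z = ilr(comp, sbp_pivot(4, pivot_index))
    X = pd.DataFrame(
        {"const": 1.0, **dict(zip(ILR_COLUMNS, z.T))}, index=df.index
    )
    for cov in covs:
        if cov == "age":
            X["age"] = df["age"].to_numpy(dtype=float)
            continue
        levels = CATEGORY_LEVELS[cov]
        vals = df[cov]
        unknown = set(vals) - set(levels)
        if unknown:
            raise DesignError(f"unknown {cov} level(s): {sorted(unknown)}")
        for level in levels[1:]:  # first level is the reference
            X[f"{cov}[{level}]"] = (vals == level).astype(float).to_numpy()

    y = df["wemwbs"].astype(float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError(f"rank-deficient design; columns: {list(X.columns)}")
    return X, y


def fit_ols(X: pd.DataFrame, y: pd.Series, *, pivot_index=1, model_id=1) -> RegressionFit:
    """Ordinary least squares with classical (homoskedastic) errors.

    Returns coefficient estimates, standard errors, the full coefficient
    covariance matrix, R² and the overall F-test p-value.
    """
    if X.shape[0] <= X.shape[1]:
        raise DesignError("need more rows than columns")
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return RegressionFit(
        params=res.params,
        bse=res.bse,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        r2=float(res.rsquared),
        f_p=float(res.f_pvalue),
        n_used=int(res.nobs),
        df_resid=float(res.df_resid),
        pivot_index=pivot_index,
        model_id=model_id,
        pvalues=res.pvalues,
        fittedvalues=np.asarray(res.fittedvalues),
    )


def fit_model(
    participants: pd.DataFrame,
    model_id: int = 1,
    pivot_index: int = 1,
) -> RegressionFit:
    """Convenience: build the design and fit in one call."""
    X, y = build_design(participants, pivot_index, model_id)
    return fit_ols(X, y, pivot_index=pivot_index, model_id=model_id)


def behaviour_betas(
    participants: pd.DataFrame,
    model_id: int = 1,
) -> pd.DataFrame:
    """Per-behaviour first-pivot coefficients for one model.

    Refits the model with each behaviour rotated into the pivot position
    and reports its coefficient (association of time in that behaviour
    relative to all others), SE and p-value, together with the shared R²
    and overall model-fit p-value (identical across rotations).
    """
    rows = []
    for k, behaviour in enumerate(PART_ORDER, start=1):
        fit = fit_model(participants, model_id=model_id, pivot_index=k)
        rows.append(
            {
                "behaviour": behaviour,
                "model": model_id,
                "beta": float(fit.params["ilr1"]),
                "se": float(fit.bse["ilr1"]),
                "p": float(fit.pvalues["ilr1"]),
                "r2": fit.r2,
                "model_p": fit.f_p,
                "n_used": fit.n_used,
            }
        )
    return pd.DataFrame(rows)
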