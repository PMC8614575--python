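"""Residual-CH4 emitter ranking.

Observed daily CH4 is regressed on dry matter intake, body weight and
experimental period (OLS with an intercept; period as categorical
indicators). The residual — observed minus predicted — is the phenotype:
cows with the most negative residuals are "low" emitters, the most positive
"high", and pairs are formed by matching the i-th lowest with the i-th
highest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateDesignError, InvalidParameterError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("cow_id", "dmi", "bw", "period", "ch4_obs")


@dataclass
class ModelFit:
    """OLS fit of ch4_obs ~ dmi + bw + C(period)."""

    params: pd.Series
    fitted: pd.Series
    residuals: pd.Series
    data: pd.DataFrame
    result: object = field(repr=False, default=None)

    @property
    def beta_dmi(self) -> float:
        return float(self.params["dmi"])

    @property
    def beta_bw(self) -> float:
        return float(self.params["bw"])


@dataclass
class EmitterRanking:
    """Per-cow ranking table plus low/high pair assignments."""

    table: pd.DataFrame  # cow_id, predicted, residual, rank, group
    pairs: pd.DataFrame  # pair_id, low_cow, high_cow
    n_pairs: int


def _validate_cows(cows: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in cows.columns]
    if missing:
        raise InvalidParameterError(f"cow table is missing columns: {missing}")
    if (cows["dmi"] <= 0).any() or (cows["bw"] <= 0).any():
        raise InvalidParameterError("dmi and bw must be positive")
    if (cows["ch4_obs"] < 0).any():
        raise InvalidParameterError("ch4_obs must be nonnegative")
    return cows


def _design_matrix(cows: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, "dmi": cows["dmi"].astype(float),
                      "bw": cows["bw"].astype(float)}, index=cows.index)
    periods = pd.Categorical(cows["period"])
    for level in periods.categories[1:]:  # first level absorbed by the intercept
        X[f"period[{level}]"] = (periods == level).astype(float)
    return X


def _collinear_columns(X: pd.DataFrame) -> list:
    """Columns whose removal does not reduce the design rank."""
    full_rank = np.linalg.matrix_rank(X.values)
    out = []
    for col in X.columns:
        reduced = X.drop(columns=[col]).values
        if np.linalg.matrix_rank(reduced) == full_rank:
            out.append(col)
    return out


def fit_ch4_model(cows: pd.DataFrame) -> ModelFit:
    """OLS of observed CH4 on intake, body weight and period."""
    cows = _validate_cows(cows)
    X = _design_matrix(cows)
    constant = [c for c in X.columns
                if c != "const" and np.ptp(X[c].to_numpy()) == 0]
    if constant:
        # zero-variance regressors are absorbed by the intercept
        logger.info("dropping constant column(s) from the design: %s", constant)
        X = X.drop(columns=constant)
    p = X.shape[1]
    if len(cows) < p + 2:
        raise InvalidParameterError(
            f"need at least {p + 2} records to fit {p} columns, got {len(cows)}"
        )
    if np.linalg.matrix_rank(X.values) < p:
        cols = _collinear_columns(X)
        raise DegenerateDesignError(
            f"rank-deficient design; collinear columns: {cols}", columns=cols
        )
    result = sm.OLS(cows["ch4_obs"].astype(float), X).fit()
    fitted = pd.Series(result.fittedvalues, index=cows.index, name="predicted")
    residuals = pd.Series(result.resid, index=cows.index, name="residual")
    return ModelFit(params=result.params, fitted=fitted, residuals=residuals,
                    data=cows, result=result)


def rank_emitters(fit: ModelFit, n_pairs: int) -> EmitterRanking:
    """Select the n_pairs most negative / most positive residual cows.

    Residuals of cows with multiple records (periods) are averaged per cow.
    Ties are broken by a stable sort on cow_id for reproducibility; ties that
    cross the selection boundary are logged.
    """
    if n_pairs < 0:
        raise InvalidParameterError("n_pairs must be nonnegative")
    per_cow = (
        pd.DataFrame({
            "cow_id": fit.data["cow_id"],
            "predicted": fit.fitted,
            "residual": fit.residuals,
        })
        .groupby("cow_id", sort=False)
        .mean(numeric_only=True)
        .reset_index()
    )
    n_cows = len(per_cow)
    if n_pairs > n_cows // 2:
        raise InvalidParameterError(
            f"n_pairs={n_pairs} exceeds floor(n_cows/2)={n_cows // 2}"
        )
    ranked = per_cow.sort_values(["residual", "cow_id"], kind="stable").reset_index(drop=True)
    ranked["rank"] = np.arange(1, n_cows + 1)
    group = np.array(["unselected"] * n_cows, dtype=object)
    group[:n_pairs] = "low"
    if n_pairs:
        group[-n_pairs:] = "high"
    ranked["group"] = group

    if n_pairs and 0 < n_pairs < n_cows:
        res = ranked["residual"].to_numpy()
        if res[n_pairs - 1] == res[n_pairs] or res[-n_pairs] == res[-n_pairs - 1]:
            logger.warning("residual tie crosses the selection boundary; "
                           "tie broken by cow_id order")

    pairs = pd.DataFrame({
        "pair_id": np.arange(1, n_pairs + 1),
        "low_cow": ranked["cow_id"].iloc[:n_pairs].to_numpy(),
        "high_cow": ranked["cow_id"].iloc[::-1].iloc[:n_pairs].to_numpy(),
    })
    return EmitterRanking(table=ranked, pairs=pairs, n_pairs=n_pairs)


def ch4_yield(cows: pd.DataFrame) -> pd.Series:
    """Reported CH4 yield, g CH4 per kg DMI (descriptive only)."""
    cows = _validate_cows(cows)
    return cows["ch4_obs"] / cows["dmi"]
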