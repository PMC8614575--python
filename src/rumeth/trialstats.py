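"""Factorial trial statistics: 2x2x2 (emitter x diet x CNSL) with run block.

The incubation run enters as a fixed block; with runs crossed and balanced
the treatment F-tests against residual error coincide with the random-run
mixed model the trial layout implies (the block variance component is simply
not estimated separately). Mean separation uses the least significant
difference at alpha = 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import InvalidParameterError, UnbalancedDesignError

FACTORS = ("emitter", "diet", "cnsl")
TREATMENT_TERMS = (
    "C(emitter)", "C(diet)", "C(cnsl)",
    "C(emitter):C(diet)", "C(emitter):C(cnsl)", "C(diet):C(cnsl)",
    "C(emitter):C(diet):C(cnsl)",
)


@dataclass
class AnovaTable:
    """Decomposition of a balanced blocked factorial response."""

    terms: pd.DataFrame  # index: term; columns: df, sum_sq, mean_sq, F, p
    residual_df: float
    residual_ms: float
    lsmeans: dict  # factor -> Series of level means
    cell_means: pd.DataFrame
    n_per_mean: dict  # factor -> observations behind each marginal mean
    grand_mean: float
    result: object = field(repr=False, default=None)


def _check_balance(design: pd.DataFrame) -> int:
    required = ["run", "value"] + list(FACTORS)
    missing = [c for c in required if c not in design.columns]
    if missing:
        raise InvalidParameterError(f"design is missing columns: {missing}")
    cells = design.groupby(["run", *FACTORS], observed=True).size()
    runs = design["run"].unique()
    levels = [design[f].unique() for f in FACTORS]
    expected = len(runs) * int(np.prod([len(l) for l in levels]))
    if len(cells) != expected or cells.nunique() != 1:
        raise UnbalancedDesignError(
            "every emitter x diet x cnsl cell must appear in every run with "
            "equal replication"
        )
    return int(cells.iloc[0])


def factorial_block_anova(design: pd.DataFrame) -> AnovaTable:
    """Fixed-effects ANOVA of value ~ emitter*diet*cnsl + run (block)."""
    n_rep = _check_balance(design)
    data = design.copy()
    formula = "value ~ C(emitter) * C(diet) * C(cnsl) + C(run)"
    result = smf.ols(formula, data=data).fit()
    if np.allclose(result.resid, 0.0, atol=1e-10) and np.isclose(result.ess, 0.0, atol=1e-10):
        # all responses equal: report a zero table rather than 0/0 F ratios
        terms = []
        for term in list(TREATMENT_TERMS) + ["C(run)"]:
            terms.append({"term": term, "df": np.nan, "sum_sq": 0.0,
                          "mean_sq": 0.0, "F": 0.0, "p": 1.0})
        anova = pd.DataFrame(terms).set_index("term")
    else:
        anova = sm.stats.anova_lm(result, typ=2)
        anova = anova.rename(columns={"PR(>F)": "p"})
        anova["mean_sq"] = anova["sum_sq"] / anova["df"]
    resid_df = float(result.df_resid)
    resid_ms = float(result.mse_resid) if resid_df > 0 else 0.0

    lsmeans, n_per_mean = {}, {}
    for f in FACTORS:
        lsmeans[f] = data.groupby(f, observed=True)["value"].mean()
        n_per_mean[f] = int(len(data) / data[f].nunique())
    cell_means = data.groupby(list(FACTORS), observed=True)["value"].mean().reset_index()

    keep = [t for t in list(TREATMENT_TERMS) + ["C(run)"] if t in anova.index]
    return AnovaTable(terms=anova.loc[keep], residual_df=resid_df,
                      residual_ms=resid_ms, lsmeans=lsmeans,
                      cell_means=cell_means, n_per_mean=n_per_mean,
                      grand_mean=float(data["value"].mean()), result=result)


def lsd_value(ms_residual: float, residual_df: float, n_per_mean: int,
              alpha: float = 0.05) -> float:
    """Least significant difference: t(1 - alpha/2, df) * sqrt(2*MSE/n)."""
    if residual_df < 1:
        raise InvalidParameterError("residual df must be >= 1")
    if n_per_mean < 1:
        raise InvalidParameterError("n_per_mean must be >= 1")
    t_crit = stats.t.ppf(1 - alpha / 2, residual_df)
    return float(t_crit * np.sqrt(2.0 * ms_residual / n_per_mean))


def lsd_separation(table: AnovaTable, means, n_per_mean: int,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Flag every pair of means differing by more than the LSD.

    With a zero residual mean square any nonzero difference is flagged.
    """
    means = pd.Series(means)
    lsd = lsd_value(table.residual_ms, table.residual_df, n_per_mean, alpha)
    rows = []
    for (name_a, mean_a), (name_b, mean_b) in itertools.combinations(means.items(), 2):
        diff = abs(mean_a - mean_b)
        rows.append({
            "level_a": name_a, "level_b": name_b, "difference": diff,
            "lsd": lsd, "different": bool(diff > lsd),
        })
    return pd.DataFrame(rows)
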