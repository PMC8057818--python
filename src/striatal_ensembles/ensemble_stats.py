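"""Recruitment fractions, per-cell correlations, and group comparisons.

Summaries are computed per section (the unit of replication), then
aggregated per condition as mean +/- SD across sections; correlations of
IEG puncta with receptor puncta (or IEG pairs) are computed over
individual cells; group comparisons use fixed-effects one- or two-way
ANOVA with Tukey HSD post hoc tests on the studentized range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """OLS fit of IEG puncta on a covariate over single cells, with both
    Pearson and Spearman association on the same pairs."""

    slope: float
    intercept: float
    r_squared: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n_cells: int


@dataclass
class ComparisonResult:
    """ANOVA F table plus Tukey HSD pairwise comparisons."""

    anova: pd.DataFrame  # index: effect; columns: sum_sq, df, F, p
    tukey: pd.DataFrame  # columns: factor, level_a, level_b, diff, q, p_adj
    residual_df: int
    mse: float


def recruitment_summary(
    cells: pd.DataFrame,
    gene: str,
    mean_over: str = "all",
) -> pd.DataFrame:
    """Per-section recruitment summary for one IEG.

    Returns one row per (condition, region, section_id) with the
    suprathreshold fraction, the mean puncta/cell (over all cells of the
    stratum by default; ``mean_over='supra'`` restricts to suprathreshold
    cells) and the number of cells. Empty strata are omitted with a
    warning.
    """
    flag = f"supra_{gene}"
    if flag not in cells.columns:
        raise KeyError(f"cells lack {flag!r}; run classify_cells first")
    if mean_over not in ("all", "supra"):
        raise ValueError("mean_over must be 'all' or 'supra'")
    rows = []
    for (condition, region, section), sub in cells.groupby(
        ["condition", "region", "section_id"], sort=True, observed=True
    ):
        if sub.empty:  # pragma: no cover - groupby drops empty strata
            logger.warning("empty stratum %s/%s/%s omitted", condition, region, section)
            continue
        supra = sub[flag].to_numpy()
        puncta = sub[gene].to_numpy()
        pool = puncta[supra] if mean_over == "supra" else puncta
        rows.append(
            {
                "gene": gene,
                "condition": condition,
                "region": region,
                "section_id": section,
                "fraction_supra": float(supra.mean()),
                "mean_puncta": float(pool.mean()) if pool.size else 0.0,
                "n_cells": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)


def condition_means(summary: pd.DataFrame) -> pd.DataFrame:
    """Condition x region aggregation: mean +/- SD over sections."""
    return (
        summary.groupby(["gene", "condition", "region"], sort=True)
        .agg(
            fraction_mean=("fraction_supra", "mean"),
            fraction_sd=("fraction_supra", "std"),
            puncta_mean=("mean_puncta", "mean"),
            puncta_sd=("mean_puncta", "std"),
            n_sections=("section_id", "nunique"),
        )
        .reset_index()
    )


def _cell_correlation(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    if len(x) < 3:
        raise ValueError("need at least 3 cells")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor puncta; slope undefined")
    ols = stats.linregress(x, y)
    rho, sp = stats.spearmanr(x, y)
    return CorrelationResult(
        slope=float(ols.slope),
        intercept=float(ols.intercept),
        r_squared=float(ols.rvalue**2),
        pearson_p=float(ols.pvalue),
        spearman_rho=float(rho),
        spearman_p=float(sp),
        n_cells=len(x),
    )


def ieg_receptor_correlation(
    cells: pd.DataFrame,
    ieg: str,
    receptor: str,
    region: str | None = None,
    condition: str | None = None,
    exclude_dual: bool = True,
    include_zero: bool = True,
) -> CorrelationResult:
    """Single-cell correlation of IEG expression with receptor expression.

    OLS of IEG puncta on receptor puncta over individual cells of the
    stratum; dual receptor-positive cells are excluded by default
    (receptor populations treated as disjoint). ``include_zero=False``
    drops cells with zero IEG puncta.
    """
    sub = cells
    if region is not None:
        sub = sub[sub["region"] == region]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    if exclude_dual and "receptor_class" in sub.columns:
        sub = sub[sub["receptor_class"] != "dual"]
    if not include_zero:
        sub = sub[sub[ieg] > 0]
    return _cell_correlation(sub[receptor].to_numpy(float), sub[ieg].to_numpy(float))


def coexpression(
    cells: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    region: str | None = None,
    condition: str | None = None,
) -> CorrelationResult:
    """Pairwise IEG co-expression over individual cells of a stratum."""
    sub = cells
    if region is not None:
        sub = sub[sub["region"] == region]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    return _cell_correlation(sub[gene_a].to_numpy(float), sub[gene_b].to_numpy(float))


def _tukey_for_factor(
    data: pd.DataFrame, value: str, factor: str, mse: float, df_resid: int
) -> list[dict]:
    """Tukey HSD over the levels of one factor using the model MSE.

    Uses the harmonic mean of group sizes when groups are unbalanced
    (Tukey-Kramer via per-pair sizes).
    """
    groups = data.groupby(factor, sort=True)[value]
    means = groups.mean()
    sizes = groups.size()
    k = len(means)
    rows = []
    for a, b in combinations(means.index, 2):
        diff = means[b] - means[a]
        nh = 2.0 / (1.0 / sizes[a] + 1.0 / sizes[b])
        se = np.sqrt(mse / nh)
        q = np.abs(diff) / se if se > 0 else 0.0
        p = float(stats.studentized_range.sf(q, k, df_resid)) if se > 0 else 1.0
        rows.append(
            {"factor": factor, "level_a": a, "level_b": b,
             "diff": float(diff), "q": float(q), "p_adj": min(p, 1.0)}
        )
    return rows


def anova_tukey(
    data: pd.DataFrame,
    value: str,
    factors: list[str] | str,
) -> ComparisonResult:
    """One- or two-way fixed-effects ANOVA with Tukey HSD post hoc tests.

    Two factors include their interaction. Each group (factor-level
    combination) must hold at least two observations. Tukey-adjusted
    pairwise p-values use the studentized range with the residual MSE.
    """
    if isinstance(factors, str):
        factors = [factors]
    if not 1 <= len(factors) <= 2:
        raise ValueError("one or two factors supported")
    counts = data.groupby(factors, sort=True).size()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"groups with < 2 observations: {list(small.index)}")

    df = data[[value] + factors].copy()
    df.columns = ["y"] + [f"f{i}" for i in range(len(factors))]
    terms = " * ".join(f"C(f{i})" for i in range(len(factors)))
    fit = smf.ols(f"y ~ {terms}", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)

    rename = {f"C(f{i})": factors[i] for i in range(len(factors))}
    if len(factors) == 2:
        rename["C(f0):C(f1)"] = f"{factors[0]}:{factors[1]}"
    table = table.rename(index=rename).rename(
        columns={"sum_sq": "sum_sq", "PR(>F)": "p"}
    )
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    df_resid = int(table.loc["Residual", "df"])
    tukey_rows: list[dict] = []
    for f in factors:
        tukey_rows.extend(_tukey_for_factor(data, value, f, mse, df_resid))
    return ComparisonResult(
        anova=table, tukey=pd.DataFrame(tukey_rows), residual_df=df_resid, mse=mse
    )
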