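"""Contingency statistics on printed group frequencies, plus the adjusted
linear association of vascular-risk burden with total WMH load.

Group denominators are reconstructed from printed "count (percent)" cells,
Pearson chi-square tests (no continuity correction) compare symptom
frequency across the five diagnostic groups, and pairwise contrasts use
two-sided Fisher exact tests (probability-mass convention).  Published
p-values that disagree with the computed ones are flagged, not matched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import published

__all__ = [
    "ComparisonError",
    "ChiSquareResult",
    "FisherResult",
    "LinearAssociationResult",
    "reconstruct_denominator",
    "pearson_chi2",
    "fisher_exact",
    "adjusted_linear_association",
    "frequency_chi2_report",
    "pairwise_fisher_report",
]


class ComparisonError(ValueError):
    pass


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class FisherResult:
    p: float
    table: tuple


@dataclass(frozen=True)
class LinearAssociationResult:
    beta: float
    ci_low: float
    ci_high: float
    p: float
    covariates: tuple


def reconstruct_denominator(count: int, percent: float) -> int:
    """Group denominator implied by a printed ``count (percent)`` cell.

    Returns ``round(100 * count / percent)``; warns if the implied
    percentage disagrees with the printed one by more than 0.05 points.
    """
    if percent <= 0 or percent > 100:
        raise ComparisonError(f"percent must be in (0, 100], got {percent}")
    if count < 0:
        raise ComparisonError(f"count must be >= 0, got {count}")
    denom = int(round(100.0 * count / percent))
    if denom > 0 and abs(100.0 * count / denom - percent) > 0.05:
        warnings.warn(
            f"reconstructed denominator {denom} gives "
            f"{100.0 * count / denom:.2f}%, printed {percent}%",
            stacklevel=2)
    return denom


def pearson_chi2(table) -> ChiSquareResult:
    """Pearson chi-square test of homogeneity, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ComparisonError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise ComparisonError("counts must be >= 0")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ComparisonError("zero row or column margin")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(float(stat), int(dof), float(p))


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Two-sidedness follows the probability-mass convention: the p-value sums
    hypergeometric probabilities of all tables with the same margins whose
    probability does not exceed the observed table's.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ComparisonError("Fisher test requires a 2x2 table")
    if (table < 0).any():
        raise ComparisonError("counts must be >= 0")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return FisherResult(float(p), tuple(map(tuple, table.tolist())))


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    _, r = np.linalg.qr(X.to_numpy(dtype=float))
    diag = np.abs(np.diag(r))
    thresh = diag.max() * len(X.columns) * np.finfo(float).eps * 1e3
    return [c for c, d in zip(X.columns, diag) if d <= thresh]


def adjusted_linear_association(df: pd.DataFrame, outcome: str, exposure: str,
                                covariates=()) -> LinearAssociationResult:
    """OLS association of a z-scored exposure with a z-scored outcome,
    adjusted for covariates; 95% CI from the t distribution.

    The reported beta is the standardized coefficient of the exposure.
    """
    import statsmodels.api as sm

    cols = [outcome, exposure, *covariates]
    data = df[cols].dropna()
    n, k = len(data), 2 + len(covariates)
    if n < k + 10:
        raise ComparisonError(
            f"need at least {k + 10} complete rows, got {n}")

    def z(x):
        s = x.std(ddof=0)
        return (x - x.mean()) / s if s > 0 else x - x.mean()

    y = z(data[outcome].astype(float))
    X = pd.DataFrame({exposure: z(data[exposure].astype(float))})
    for cov in covariates:
        col = data[cov]
        X[cov] = (col.astype("category").cat.codes if col.dtype == object
                  else col.astype(float))
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ComparisonError(
            f"rank-deficient design; collinear columns: {_collinear_columns(X)}")
    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    i = list(X.columns).index(exposure)
    ci = fit.conf_int(alpha=0.05)
    return LinearAssociationResult(
        beta=float(fit.params[i]), ci_low=float(ci[i][0]),
        ci_high=float(ci[i][1]), p=float(fit.pvalues[i]),
        covariates=tuple(covariates))


def _group_tables(symptom: str, frequencies) -> dict:
    """Per-group (present, denominator) reconstructed from printed cells."""
    out = {}
    for dx, (count, percent) in frequencies[symptom].items():
        out[dx] = (count, reconstruct_denominator(count, percent))
    return out


def frequency_chi2_report(frequencies=None, printed=None) -> pd.DataFrame:
    """Chi-square of symptom frequency across groups for every printed
    symptom row, with the published statistic and a discrepancy flag
    (|computed - published| > 0.05)."""
    frequencies = frequencies or published.NPS_FREQUENCIES
    printed = printed or published.PUBLISHED_CHI2
    rows = []
    for symptom in frequencies:
        groups = _group_tables(symptom, frequencies)
        table = [[count, denom - count] for count, denom in groups.values()]
        res = pearson_chi2(table)
        pub = printed.get(symptom)
        rows.append({
            "symptom": symptom, "chi2": res.statistic, "df": res.df,
            "p": res.p, "published_chi2": pub,
            "discrepant": (pub is not None
                           and abs(res.statistic - pub) > 0.05),
        })
    return pd.DataFrame(rows)


def pairwise_fisher_report(comparisons=None, frequencies=None) -> pd.DataFrame:
    """Two-sided Fisher exact test for every published pairwise contrast.

    ``matched`` is True when the computed p, rounded to 3 decimals, equals
    the published value (or falls below a published "<p" bound); rows where
    the published value cannot be reproduced from the printed counts are
    flagged, not forced to agree.
    """
    comparisons = comparisons or published.PAIRWISE_COMPARISONS
    frequencies = frequencies or published.NPS_FREQUENCIES
    rows = []
    for symptom, hi, lo, pub_p, is_bound in comparisons:
        groups = _group_tables(symptom, frequencies)
        (a, na), (b, nb) = groups[hi], groups[lo]
        res = fisher_exact([[a, na - a], [b, nb - b]])
        matched = (res.p < pub_p if is_bound
                   else round(res.p, 3) == round(pub_p, 3))
        rows.append({
            "symptom": symptom, "higher": hi, "lower": lo,
            "p": res.p, "published_p": pub_p, "published_is_bound": is_bound,
            "matched": matched,
        })
    return pd.DataFrame(rows)
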