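"""Repeated stratified train/test elastic net with lambda-consensus selection.

The procedure models one neuropsychiatric subsyndrome score from 82
predictors (two sex indicators, age, MoCA, 68 cortical-thickness regions,
10 normalized WMH volumes).  Each of ``repeats`` iterations draws a
stratified 75/25 train/test split (sex-by-dx cells preserved by
largest-remainder rounding), selects a penalty strength lambda by
10-fold stratified cross-validation on the training portion, evaluates
candidate lambdas on the held-out quarter, and records the
test-MSE-minimizing lambda.  Lambdas selected in at least 5% of repeats
are retained and refit on the full sample, yielding one coefficient
vector per retained lambda; the union of their non-zero predictors is
the consensus variable set.

The lambda grid is 100 log-spaced values from lambda_max (the smallest
penalty that zeroes every coefficient) down to 1e-4 * lambda_max, plus an
explicit sentinel value of 1000 whose fit is always the intercept-only
model.  The grid is computed once from the full sample and shared across
repeats so that consensus counting is exact.  Coordinate descent is
scikit-learn's; the lambda parameterization follows the glmnet
convention (objective RSS/(2n) + lambda * (alpha*L1 + (1-alpha)/2 * L2))
with predictors standardized internally and coefficients reported on the
original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import enet_path
from sklearn.model_selection import StratifiedKFold

from .cohort import thickness_columns
from .npiq import SUBSYNDROME_ITEMS
from .wmh import wmhlog_columns

__all__ = [
    "EnetError",
    "EnetConfig",
    "DesignMatrix",
    "build_design",
    "stratified_split",
    "lambda_grid",
    "cv_lambda_select",
    "penalized_fit",
    "ConsensusElasticNet",
    "ConsensusElasticNetResults",
]

SENTINEL_LAMBDA = 1000.0


class EnetError(ValueError):
    pass


@dataclass
class EnetConfig:
    """Settings of the consensus procedure.

    ``alpha`` is the L1/L2 mixing weight (1 = pure lasso, the default);
    ``selection`` chooses whether the per-repeat recorded lambda is the
    test-MSE minimizer over the whole grid ("test", default) or the
    internal cross-validation winner ("cv").
    """

    alpha: float = 1.0
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    sentinel: float = SENTINEL_LAMBDA
    k_folds: int = 10
    train_fraction: float = 0.75
    repeats: int = 500
    retention_fraction: float = 0.05
    selection: str = "test"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise EnetError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 < self.train_fraction < 1.0:
            raise EnetError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.repeats < 1:
            raise EnetError("repeats must be >= 1")
        if self.k_folds < 2:
            raise EnetError("k_folds must be >= 2")
        if self.selection not in ("test", "cv"):
            raise EnetError("selection must be 'test' or 'cv'")
        if self.n_lambda < 2:
            raise EnetError("n_lambda must be >= 2")


@dataclass
class DesignMatrix:
    """Outcome, 82 predictor columns, and sex-by-dx stratum label per row."""

    X: pd.DataFrame
    y: pd.Series
    strata: pd.Series
    outcome_name: str
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.y)


def predictor_columns() -> list[str]:
    return (["sex_female", "sex_male", "age", "moca"]
            + thickness_columns() + wmhlog_columns())


def build_design(cohort: pd.DataFrame, subsyndrome: str) -> DesignMatrix:
    """Assemble the modelling design for one subsyndrome from a scored,
    normalized cohort; incomplete rows are dropped and counted."""
    if subsyndrome not in SUBSYNDROME_ITEMS:
        raise EnetError(
            f"unknown subsyndrome {subsyndrome!r}; "
            f"expected one of {sorted(SUBSYNDROME_ITEMS)}")
    outcome = f"sub_{subsyndrome}"
    needed = [outcome, "dx", "sex", "age", "moca"] + thickness_columns() \
        + wmhlog_columns()
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise EnetError(
            f"cohort lacks columns required for the design: {missing[:8]}"
            + ("..." if len(missing) > 8 else ""))
    data = cohort[needed].copy()
    complete = data.dropna()
    n_dropped = len(data) - len(complete)

    X = pd.DataFrame(index=complete.index)
    X["sex_female"] = (cohort.loc[complete.index, "sex"] == "F").astype(float)
    X["sex_male"] = (cohort.loc[complete.index, "sex"] == "M").astype(float)
    X["age"] = complete["age"].astype(float)
    X["moca"] = complete["moca"].astype(float)
    for col in thickness_columns() + wmhlog_columns():
        X[col] = complete[col].astype(float)
    y = complete[outcome].astype(float)
    strata = (cohort.loc[complete.index, "sex"].astype(str) + ":"
              + cohort.loc[complete.index, "dx"].astype(str))
    return DesignMatrix(X=X.reset_index(drop=True),
                        y=y.reset_index(drop=True).rename(outcome),
                        strata=strata.reset_index(drop=True).rename("stratum"),
                        outcome_name=outcome, n_dropped=n_dropped)


def stratified_split(strata, train_fraction: float, seed):
    """Disjoint, exhaustive train/test indices preserving stratum margins.

    Each stratum contributes floor(train_fraction * size) training rows,
    with the remaining training slots distributed by largest fractional
    remainder so that the overall training size equals
    round(train_fraction * n).
    """
    strata = pd.Series(strata).reset_index(drop=True)
    if not 0.0 < train_fraction < 1.0:
        raise EnetError(
            f"train_fraction must be in (0, 1), got {train_fraction}")
    sizes = strata.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise EnetError(
            f"strata with fewer than 2 members: {sorted(small.index)}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    n = len(strata)
    target_total = int(round(train_fraction * n))
    labels = list(sizes.index)
    exact = {s: train_fraction * sizes[s] for s in labels}
    take = {s: int(np.floor(exact[s])) for s in labels}
    shortfall = target_total - sum(take.values())
    # ties in the fractional remainder break by stratum-size order, then name
    by_remainder = sorted(labels, key=lambda s: (-(exact[s] - take[s]), s))
    for s in by_remainder[:shortfall]:
        take[s] += 1

    train_idx, test_idx = [], []
    for s in labels:
        members = np.flatnonzero(strata.to_numpy() == s)
        members = rng.permutation(members)
        train_idx.extend(members[:take[s]])
        test_idx.extend(members[take[s]:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def lambda_grid(X: np.ndarray, y: np.ndarray, cfg: EnetConfig) -> np.ndarray:
    """Decreasing penalty grid: sentinel, then n_lambda log-spaced values
    from lambda_max down to lambda_min_ratio * lambda_max."""
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    yc = np.asarray(y, dtype=float) - np.mean(y)
    denom = max(cfg.alpha, 1e-3)
    lmax = np.max(np.abs(Xs.T @ yc)) / (len(yc) * denom)
    if lmax <= 0:
        raise EnetError("degenerate design: lambda_max is 0")
    grid = np.logspace(np.log10(lmax),
                       np.log10(lmax * cfg.lambda_min_ratio), cfg.n_lambda)
    return np.concatenate([[cfg.sentinel], grid])


def _fit_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
              alpha: float):
    """Original-scale intercepts and coefficients along a decreasing
    lambda path (glmnet parameterization)."""
    Xs, mean, sd = _standardize(X)
    ybar = float(np.mean(y))
    yc = y - ybar
    l1_ratio = alpha if alpha > 0 else 1e-3
    _, coefs_std, _ = enet_path(Xs, yc, l1_ratio=l1_ratio, alphas=lambdas)
    coefs = coefs_std / sd[:, None]
    intercepts = ybar - mean @ coefs
    return intercepts, coefs


def penalized_fit(X, y, lam: float, alpha: float = 1.0):
    """Single penalized fit; returns (intercept, coefficient vector) on the
    original predictor scale.  At the sentinel lambda the coefficients are
    exactly zero and the intercept is the outcome mean."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    icepts, coefs = _fit_path(X, y, np.array([max(lam, 1e-12)]), alpha)
    return float(icepts[0]), coefs[:, 0]


def cv_lambda_select(X, y, strata, grid: np.ndarray, cfg: EnetConfig, seed):
    """Mean held-out squared error per grid lambda over k stratified folds;
    returns (lambda*, cv-MSE curve).  Ties break toward the larger lambda."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    if len(y) < cfg.k_folds:
        raise EnetError(
            f"k_folds={cfg.k_folds} exceeds the {len(y)} training rows")
    if np.std(y) == 0:
        raise EnetError("degenerate outcome: zero variance in training rows")
    skf = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True,
                          random_state=int(seed) % (2 ** 31))
    fold_mse = np.zeros((cfg.k_folds, len(grid)))
    for f, (tr, te) in enumerate(skf.split(X, strata)):
        icepts, coefs = _fit_path(X[tr], y[tr], grid, cfg.alpha)
        pred = X[te] @ coefs + icepts
        fold_mse[f] = np.mean((pred - y[te][:, None]) ** 2, axis=0)
    curve = fold_mse.mean(axis=0)
    # grid is decreasing, so the first argmin is the largest tied lambda
    return float(grid[int(np.argmin(curve))]), curve


@dataclass
class _RepeatRecord:
    lambda_test: float
    test_mse: float
    lambda_cv: float


class ConsensusElasticNet:
    """Consensus elastic-net model for one subsyndrome outcome.

    Construct from a :class:`DesignMatrix` (or via :meth:`from_cohort`)
    and call :meth:`fit` to run the repeated train/test procedure.
    """

    def __init__(self, design: DesignMatrix, config: EnetConfig | None = None):
        config = config or EnetConfig()
        config.validate()
        if design.y.std() == 0:
            raise EnetError("degenerate outcome: zero variance")
        self.design = design
        self.config = config

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, subsyndrome: str,
                    config: EnetConfig | None = None) -> "ConsensusElasticNet":
        return cls(build_design(cohort, subsyndrome), config)

    def fit(self, seed: int | None = None) -> "ConsensusElasticNetResults":
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        X = self.design.X.to_numpy(dtype=float)
        y = self.design.y.to_numpy(dtype=float)
        strata = self.design.strata.to_numpy()
        grid = lambda_grid(X, y, cfg)

        ss = np.random.SeedSequence(cfg.seed)
        repeat_seeds = ss.generate_state(2 * cfg.repeats) % (2 ** 31)
        records: list[_RepeatRecord] = []
        for r in range(cfg.repeats):
            split_rng = np.random.default_rng(int(repeat_seeds[2 * r]))
            tr, te = stratified_split(strata, cfg.train_fraction, split_rng)
            lam_cv, _ = cv_lambda_select(X[tr], y[tr], strata[tr], grid, cfg,
                                         int(repeat_seeds[2 * r + 1]))
            icepts, coefs = _fit_path(X[tr], y[tr], grid, cfg.alpha)
            test_mse = np.mean(
                (X[te] @ coefs + icepts - y[te][:, None]) ** 2, axis=0)
            if cfg.selection == "test":
                j = int(np.argmin(test_mse))
                lam = float(grid[j])
            else:
                j = int(np.argmin(np.abs(grid - lam_cv)))
                lam = lam_cv
            records.append(_RepeatRecord(lam, float(test_mse[j]), lam_cv))

        return ConsensusElasticNetResults(self, grid, records)


class ConsensusElasticNetResults:
    """Lambda consensus and full-sample refits of the retained lambdas."""

    def __init__(self, model: ConsensusElasticNet, grid: np.ndarray,
                 records: list[_RepeatRecord]):
        self.model = model
        self.grid = grid
        self.records = records
        cfg = model.config
        self.lambda_per_repeat = np.array([r.lambda_test for r in records])
        self.test_mse_per_repeat = np.array([r.test_mse for r in records])

        counts = pd.Series(self.lambda_per_repeat).value_counts()
        self.frequency_table = pd.DataFrame({
            "lambda": counts.index.to_numpy(),
            "count": counts.to_numpy(),
        }).sort_values("lambda", ascending=False, ignore_index=True)
        threshold = int(np.ceil(cfg.retention_fraction * cfg.repeats))
        self.retention_threshold = threshold
        retained = self.frequency_table[
            self.frequency_table["count"] >= threshold]
        self.retained_lambdas = retained["lambda"].to_numpy()
        self.retention_warning = None
        if len(self.retained_lambdas) == 0:
            top5 = self.frequency_table.nlargest(5, "count")
            self.retention_warning = (
                f"no lambda reached the retention threshold of {threshold}; "
                f"top-5 by frequency: {top5['lambda'].tolist()}")
            import warnings
            warnings.warn(self.retention_warning, stacklevel=2)
            self._report_lambdas = top5["lambda"].to_numpy()
        else:
            self._report_lambdas = self.retained_lambdas

        self._full_sample_refit()

    def _full_sample_refit(self) -> None:
        X = self.model.design.X.to_numpy(dtype=float)
        y = self.model.design.y.to_numpy(dtype=float)
        lambdas = np.sort(self._report_lambdas)[::-1]
        icepts, coefs = _fit_path(X, y, lambdas, self.model.config.alpha)
        names = list(self.model.design.X.columns)
        counts = dict(zip(self.frequency_table["lambda"],
                          self.frequency_table["count"]))
        cols = {}
        repeats = self.model.config.repeats
        for j, lam in enumerate(lambdas):
            header = f"{lam:.4g} ({counts[lam]}/{repeats})"
            cols[header] = np.concatenate([[icepts[j]], coefs[:, j]])
        full = pd.DataFrame(cols, index=["(Intercept)"] + names)
        full[full == 0] = 0.0  # normalize -0.0 from coordinate descent
        self.coef_table_full = full
        nonzero = (full.iloc[1:] != 0).any(axis=1)
        self.selected_variables = list(full.index[1:][nonzero])
        self.coef_table = full.loc[["(Intercept)"] + self.selected_variables]
        self._coefs_by_lambda = {lam: (float(icepts[j]), coefs[:, j])
                                 for j, lam in enumerate(lambdas)}

    def coefficients(self, lam: float):
        """(intercept, coefficient Series) of the full-sample refit at a
        retained lambda."""
        key = min(self._coefs_by_lambda, key=lambda v: abs(v - lam))
        if not np.isclose(key, lam, rtol=1e-9, atol=0):
            raise EnetError(f"lambda {lam} was not refit; retained: "
                            f"{sorted(self._coefs_by_lambda)}")
        icept, coef = self._coefs_by_lambda[key]
        return icept, pd.Series(coef, index=self.model.design.X.columns)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            f"Consensus elastic net: {self.model.design.outcome_name}",
            f"  n = {self.model.design.n}, predictors = "
            f"{self.model.design.X.shape[1]}, alpha = {cfg.alpha}",
            f"  repeats = {cfg.repeats}, selection = {cfg.selection}, "
            f"retention >= {self.retention_threshold}/{cfg.repeats}",
            f"  retained lambdas: "
            + ", ".join(f"{l:.4g} ({int(dict(zip(self.frequency_table['lambda'], self.frequency_table['count']))[l])}/{cfg.repeats})"
                        for l in np.sort(self._report_lambdas)[::-1]),
        ]
        if self.retention_warning:
            lines.append(f"  WARNING: {self.retention_warning}")
        lines.append("")
        lines.append(self.coef_table.round(4).to_string())
        return "\n".join(lines)
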