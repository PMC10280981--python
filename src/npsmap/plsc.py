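"""Two-block partial least squares correlation (behavioural PLS).

Both blocks are column-wise z-scored; the cross-block matrix
R = X'Y/(n-1) is decomposed by SVD into paired saliences (orthonormal
weight vectors over each block) and singular values.  The proportion of
shared variance per component is s_i^2 / sum_j s_j^2 (the squared-value
base is standard; a raw-value base is available).  Inference is by
stratified resampling that preserves the sex-by-dx cell counts exactly:

* permutation - rows of Y are permuted within strata and the decomposition
  refit; component p-values use the add-one estimator
  p = (1 + #{perm s >= observed s}) / (1 + n_perm), comparing each null
  singular value at the same component index (an optional rotation mode
  projects each null cross-block matrix onto the observed saliences);
* bootstrap - rows are resampled with replacement within strata, replicate
  saliences are sign/order-aligned to the original by maximal absolute
  inner product, and the bootstrap ratio (BSR) is the original salience
  divided by the SD of the aligned replicate saliences.  |BSR| >= 2 marks
  a stable contributor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .enet import predictor_columns
from .npiq import SUBSYNDROME_COLUMNS

__all__ = [
    "PlscError",
    "PLSCorrelation",
    "PLSCResults",
    "PermutationResult",
    "BootstrapResult",
    "stable_contributors",
]


class PlscError(ValueError):
    pass


@dataclass
class PermutationResult:
    p_values: np.ndarray
    n_perm: int
    null_samples: np.ndarray  # (n_perm, k)
    rotated: bool = False


@dataclass
class BootstrapResult:
    bsr_x: pd.DataFrame  # (p, k)
    bsr_y: pd.DataFrame  # (q, k)
    n_boot: int
    n_dropped: int
    threshold: float = 2.0

    def stable_x(self, component: int) -> pd.Series:
        col = self.bsr_x.iloc[:, component]
        return col[col.abs() >= self.threshold]


def _zscore_block(M: np.ndarray, names) -> np.ndarray:
    sd = M.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise PlscError(
            f"zero-variance column(s): {[names[i] for i in zero]}")
    return (M - M.mean(axis=0)) / sd


def _fix_signs(u: np.ndarray, v: np.ndarray):
    """Per component, make the largest-magnitude entry of v non-negative."""
    for j in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, j])))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
            u[:, j] = -u[:, j]
    return u, v


def _cross_svd(Xz: np.ndarray, Yz: np.ndarray):
    R = Xz.T @ Yz / (len(Xz) - 1)
    u, s, vt = np.linalg.svd(R, full_matrices=False)
    return _fix_signs(u, vt.T) + (s,)


class PLSCorrelation:
    """PLS correlation model between a predictor block X and an outcome
    block Y (here the four subsyndrome scores), with optional sex-by-dx
    strata for resampling."""

    def __init__(self, X: pd.DataFrame, Y: pd.DataFrame, strata=None):
        X = pd.DataFrame(X)
        Y = pd.DataFrame(Y)
        if len(X) != len(Y):
            raise PlscError("X and Y must have the same number of rows")
        if len(X) < 3:
            raise PlscError("need at least 3 rows")
        if X.isna().any().any() or Y.isna().any().any():
            raise PlscError("blocks must be complete (no missing values)")
        self.X, self.Y = X, Y
        self.strata = (pd.Series(["all"] * len(X)) if strata is None
                       else pd.Series(strata).reset_index(drop=True))

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame) -> "PLSCorrelation":
        """82-predictor X block and 4-subsyndrome Y block from a scored,
        normalized cohort (complete cases)."""
        cols = predictor_columns()
        needed = SUBSYNDROME_COLUMNS + ["dx", "sex", "age", "moca"]
        missing = [c for c in needed if c not in cohort.columns]
        if missing:
            raise PlscError(f"cohort lacks columns: {missing}")
        df = cohort.copy()
        df["sex_female"] = (df["sex"] == "F").astype(float)
        df["sex_male"] = (df["sex"] == "M").astype(float)
        keep = [c for c in cols + SUBSYNDROME_COLUMNS + ["dx", "sex"]]
        df = df[keep].dropna().reset_index(drop=True)
        strata = df["sex"].astype(str) + ":" + df["dx"].astype(str)
        return cls(df[cols], df[SUBSYNDROME_COLUMNS], strata)

    def fit(self, variance_base: str = "squared") -> "PLSCResults":
        if variance_base not in ("squared", "raw"):
            raise PlscError("variance_base must be 'squared' or 'raw'")
        Xz = _zscore_block(self.X.to_numpy(dtype=float), list(self.X.columns))
        Yz = _zscore_block(self.Y.to_numpy(dtype=float), list(self.Y.columns))
        u, v, s = _cross_svd(Xz, Yz)
        return PLSCResults(self, Xz, Yz, u, v, s, variance_base)


class PLSCResults:
    """Saliences, singular values, variance explained, latent scores, and
    resampling inference for a fitted PLS correlation."""

    def __init__(self, model, Xz, Yz, u, v, s, variance_base):
        self.model = model
        self._Xz, self._Yz = Xz, Yz
        self.x_names = list(model.X.columns)
        self.y_names = list(model.Y.columns)
        self.u, self.v = u, v
        self.singular_values = s
        self.n_components = len(s)
        base = s ** 2 if variance_base == "squared" else s
        self.variance_explained = 100.0 * base / base.sum()
        self.variance_base = variance_base
        self.x_scores = Xz @ u
        self.y_scores = Yz @ v
        self.permutation: PermutationResult | None = None
        self.bootstrap: BootstrapResult | None = None

    @property
    def x_saliences(self) -> pd.DataFrame:
        return pd.DataFrame(self.u, index=self.x_names,
                            columns=[f"comp{j+1}" for j in range(self.n_components)])

    @property
    def y_saliences(self) -> pd.DataFrame:
        return pd.DataFrame(self.v, index=self.y_names,
                            columns=[f"comp{j+1}" for j in range(self.n_components)])

    def _strata_indices(self, min_size: int = 2) -> list[np.ndarray]:
        strata = self.model.strata.to_numpy()
        groups = [np.flatnonzero(strata == s) for s in pd.unique(strata)]
        small = [len(g) for g in groups if len(g) < min_size]
        if small:
            raise PlscError(
                f"{len(small)} stratum/strata with fewer than {min_size} rows")
        return groups

    def permutation_test(self, n_perm: int = 5000, seed: int = 0,
                         rotate: bool = False) -> PermutationResult:
        """Stratified permutation test of the singular values."""
        if n_perm < 19:
            raise PlscError("n_perm must be >= 19")
        groups = self._strata_indices()
        rng = np.random.default_rng(seed)
        n = len(self._Yz)
        k = self.n_components
        null = np.empty((n_perm, k))
        denom = n - 1
        for b in range(n_perm):
            perm = np.arange(n)
            for g in groups:
                perm[g] = g[rng.permutation(len(g))]
            R = self._Xz.T @ self._Yz[perm] / denom
            if rotate:
                # project the null cross-block matrix onto the observed
                # salience frame; null singular value i = ||R v_i||
                null[b] = np.linalg.norm(R @ self.v, axis=0)
            else:
                null[b] = np.linalg.svd(R, compute_uv=False)[:k]
        p = (1 + (null >= self.singular_values).sum(axis=0)) / (1 + n_perm)
        self.permutation = PermutationResult(p, n_perm, null, rotate)
        return self.permutation

    def _align(self, u_rep, v_rep):
        """Match replicate components to the original by maximal |inner
        product| of stacked saliences, then align signs."""
        ref = np.vstack([self.u, self.v])
        rep = np.vstack([u_rep, v_rep])
        corr = ref.T @ rep
        _, order = linear_sum_assignment(-np.abs(corr))
        signs = np.sign(corr[np.arange(len(order)), order])
        signs[signs == 0] = 1.0
        return u_rep[:, order] * signs, v_rep[:, order] * signs

    def bootstrap_ratios(self, n_boot: int = 1000, seed: int = 0,
                         threshold: float = 2.0) -> BootstrapResult:
        """Stratified bootstrap ratios for every variable and component."""
        if n_boot < 100:
            raise PlscError("n_boot must be >= 100")
        groups = self._strata_indices()
        rng = np.random.default_rng(seed)
        X = self.model.X.to_numpy(dtype=float)
        Y = self.model.Y.to_numpy(dtype=float)
        us, vs = [], []
        dropped = 0
        for b in range(n_boot):
            idx = np.concatenate(
                [g[rng.integers(0, len(g), len(g))] for g in groups])
            try:
                Xz = _zscore_block(X[idx], self.x_names)
                Yz = _zscore_block(Y[idx], self.y_names)
            except PlscError:
                dropped += 1
                continue
            u_rep, v_rep, _ = _cross_svd(Xz, Yz)
            u_rep, v_rep = self._align(u_rep, v_rep)
            us.append(u_rep)
            vs.append(v_rep)
        if dropped > 0.1 * n_boot:
            raise PlscError(
                f"{dropped}/{n_boot} bootstrap replicates dropped "
                "(zero-variance columns)")
        u_sd = np.std(np.stack(us), axis=0, ddof=1)
        v_sd = np.std(np.stack(vs), axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            bsr_u = np.where(u_sd > 0, self.u / u_sd, np.inf * np.sign(self.u))
            bsr_v = np.where(v_sd > 0, self.v / v_sd, np.inf * np.sign(self.v))
        comp_cols = [f"comp{j+1}" for j in range(self.n_components)]
        self.bootstrap = BootstrapResult(
            bsr_x=pd.DataFrame(bsr_u, index=self.x_names, columns=comp_cols),
            bsr_y=pd.DataFrame(bsr_v, index=self.y_names, columns=comp_cols),
            n_boot=n_boot, n_dropped=dropped, threshold=threshold)
        return self.bootstrap

    def component_table(self) -> pd.DataFrame:
        tab = pd.DataFrame({
            "component": np.arange(1, self.n_components + 1),
            "singular_value": self.singular_values,
            "pct_variance": self.variance_explained,
        })
        if self.permutation is not None:
            tab["perm_p"] = self.permutation.p_values
        return tab

    def score_table(self, labels=None) -> pd.DataFrame:
        """Per-participant latent scores (for plotting), optionally joined
        with a label column such as dx."""
        cols = {}
        for j in range(self.n_components):
            cols[f"lx{j+1}"] = self.x_scores[:, j]
            cols[f"ly{j+1}"] = self.y_scores[:, j]
        tab = pd.DataFrame(cols)
        if labels is not None:
            tab.insert(0, "label", np.asarray(labels))
        return tab

    def summary(self) -> str:
        lines = [
            f"PLS correlation: {len(self.x_names)} predictors x "
            f"{len(self.y_names)} outcomes, n = {len(self._Xz)}",
            self.component_table().round(4).to_string(index=False),
        ]
        if self.bootstrap is not None:
            stable = stable_contributors(self.bootstrap, 0,
                                         self.bootstrap.threshold)
            lines.append(
                f"stable contributors (|BSR| >= {self.bootstrap.threshold}, "
                f"component 1): {len(stable)}")
        return "\n".join(lines)


def stable_contributors(boot: BootstrapResult, component: int,
                        threshold: float = 2.0, block: str = "x") -> list[str]:
    """Variables with |BSR| at or above ``threshold`` on one component,
    sorted by |BSR| descending."""
    table = boot.bsr_x if block == "x" else boot.bsr_y
    if not 0 <= component < table.shape[1]:
        raise PlscError(
            f"component {component} outside fitted range 0..{table.shape[1]-1}")
    col = table.iloc[:, component]
    hits = col[col.abs() >= threshold]
    return list(hits.abs().sort_values(ascending=False).index)
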