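import numpy as np
import pandas as pd
import pytest

from npsmap.cohort import CohortSpec, generate_cohort
from npsmap.enet import (ConsensusElasticNet, EnetConfig, EnetError,
                         build_design, cv_lambda_select, lambda_grid,
                         penalized_fit, stratified_split)
from npsmap.npiq import score_cohort
from npsmap.wmh import normalize_cohort


@pytest.fixture(scope="module")
def design(scored_cohort):
    return build_design(scored_cohort, "apathy")


def test_design_dimensions(design):
    assert design.n == 490
    assert design.X.shape[1] == 82  # 2 sex + age + MoCA + 68 + 10
    assert design.n_dropped == 0
    assert design.strata.nunique() == 10


def test_design_rejects_unknown_subsyndrome(scored_cohort):
    with pytest.raises(EnetError, match="unknown subsyndrome"):
        build_design(scored_cohort, "mood")


def test_design_drops_incomplete_rows(scored_cohort):
    df = scored_cohort.copy()
    df.loc[df.index[0], "moca"] = np.nan
    d = build_design(df, "apathy")
    assert d.n == 489
    assert d.n_dropped == 1


def test_stratified_split_largest_remainder(design):
    tr, te = stratified_split(design.strata, 0.75, seed=0)
    assert len(tr) == 368  # round(0.75 * 490)
    assert len(te) == 122
    assert len(np.intersect1d(tr, te)) == 0
    assert len(tr) + len(te) == design.n


def test_stratified_split_preserves_stratum_counts(design):
    tr1, _ = stratified_split(design.strata, 0.75, seed=1)
    tr2, _ = stratified_split(design.strata, 0.75, seed=2)
    counts1 = design.strata.iloc[tr1].value_counts()
    counts2 = design.strata.iloc[tr2].value_counts()
    pd.testing.assert_series_equal(counts1, counts2)
    assert not np.array_equal(tr1, tr2)


def test_stratified_split_guards():
    strata = pd.Series(["a"] * 5 + ["b"])
    with pytest.raises(EnetError, match="fewer than 2"):
        stratified_split(strata, 0.75, seed=0)
    with pytest.raises(EnetError, match="train_fraction"):
        stratified_split(pd.Series(["a"] * 10), 1.0, seed=0)


def test_sentinel_lambda_gives_intercept_only(design):
    X = design.X.to_numpy()
    y = design.y.to_numpy()
    icept, coef = penalized_fit(X, y, 1000.0)
    assert icept == pytest.approx(y.mean(), rel=1e-12)
    assert np.all(coef == 0.0)


def test_zero_penalty_matches_least_squares():
    """With alpha = 1 and lambda = 0 on a full-rank overdetermined design
    the penalized fit equals OLS."""
    rng = np.random.default_rng(12)
    X = rng.normal(size=(200, 10))
    y = X @ rng.normal(size=10) + rng.normal(size=200)
    icept, coef = penalized_fit(X, y, 0.0)
    ols = np.linalg.lstsq(np.column_stack([np.ones(200), X]), y, rcond=None)[0]
    assert icept == pytest.approx(ols[0], abs=1e-6)
    np.testing.assert_allclose(coef, ols[1:], atol=1e-6)


def test_aggregate_shrinkage_is_monotone_in_lambda(design):
    X = design.X.to_numpy()
    y = design.y.to_numpy()
    grid = lambda_grid(X, y, EnetConfig())
    norms = [np.abs(penalized_fit(X, y, lam)[1]).sum() for lam in grid[::10]]
    # grid is decreasing, so the L1 norm of the fit must be non-decreasing
    assert all(b >= a - 1e-10 for a, b in zip(norms, norms[1:]))


def test_cv_prefers_sentinel_on_pure_noise():
    """When the outcome is noise and every candidate penalty is strong
    (at or above the full-sample lambda_max), the parsimony tie-break
    sends the cross-validated choice to the sentinel in most seeds."""
    cfg = EnetConfig()
    rng = np.random.default_rng(0)
    wins = 0
    n_seeds = 50
    for s in range(n_seeds):
        X = rng.normal(size=(200, 30))
        y = rng.normal(size=200)
        strata = np.repeat(np.arange(10), 20)
        Xs = (X - X.mean(0)) / X.std(0)
        lmax = np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y)
        grid = np.array([cfg.sentinel, 3 * lmax, 2 * lmax, 1.4 * lmax, lmax])
        lam, _ = cv_lambda_select(X, y, strata, grid, cfg, seed=s)
        wins += lam == cfg.sentinel
    assert wins >= 0.8 * n_seeds


def test_cv_detects_planted_signal():
    cfg = EnetConfig()
    rng = np.random.default_rng(1)
    detected = 0
    n_seeds = 20
    for s in range(n_seeds):
        X = rng.normal(size=(200, 30))
        y = 0.5 * X[:, 3] + rng.normal(size=200)
        strata = np.repeat(np.arange(10), 20)
        grid = lambda_grid(X, y, cfg)
        lam, _ = cv_lambda_select(X, y, strata, grid, cfg, seed=s)
        detected += lam < cfg.sentinel
    assert detected >= 0.95 * n_seeds


def test_cv_guards(design):
    cfg = EnetConfig(k_folds=600)
    X = design.X.to_numpy()[:50]
    strata = design.strata.to_numpy()[:50]
    grid = np.array([1000.0, 0.1])
    with pytest.raises(EnetError, match="k_folds"):
        cv_lambda_select(X, design.y.to_numpy()[:50], strata, grid, cfg, 0)
    with pytest.raises(EnetError, match="zero variance"):
        cv_lambda_select(X, np.ones(50), strata, grid, EnetConfig(), 0)


@pytest.fixture(scope="module")
def small_consensus(design):
    model = ConsensusElasticNet(design, EnetConfig(repeats=25, seed=3))
    return model.fit()


def test_consensus_frequencies_sum_to_repeats(small_consensus):
    assert small_consensus.frequency_table["count"].sum() == 25
    assert len(small_consensus.lambda_per_repeat) == 25


def test_consensus_null_outcome_favours_sentinel(small_consensus):
    """On a cohort without planted effects the sentinel (intercept-only)
    lambda dominates the consensus."""
    top = small_consensus.frequency_table.nlargest(1, "count")
    assert top["lambda"].iloc[0] == 1000.0


def test_consensus_coefficient_table_layout(small_consensus):
    tab = small_consensus.coef_table
    assert tab.index[0] == "(Intercept)"
    # column headers carry the occurrence counts
    assert all("/25)" in c for c in tab.columns)
    # the sentinel column is intercept-only
    sentinel_cols = [c for c in tab.columns if c.startswith("1000")]
    assert sentinel_cols
    assert (tab[sentinel_cols[0]].iloc[1:] == 0).all()


def test_consensus_retention_warning(design):
    cfg = EnetConfig(repeats=4, retention_fraction=2.0, seed=0)
    with pytest.warns(UserWarning, match="retention threshold"):
        res = ConsensusElasticNet(design, cfg).fit()
    assert len(res.retained_lambdas) == 0
    assert len(res._report_lambdas) <= 5


def test_consensus_selection_mode_cv(design):
    res = ConsensusElasticNet(design,
                              EnetConfig(repeats=5, selection="cv",
                                         seed=4)).fit()
    assert res.frequency_table["count"].sum() == 5


def test_planted_effect_signs_are_consistent():
    """A planted positive effect never produces a negative full-sample
    coefficient at a retained lambda."""
    for s in range(5):
        spec = CohortSpec(seed=900 + s, effect_spec=[
            ("thick_lh_rostralmiddlefrontal", "apathy", 0.5)])
        cohort = normalize_cohort(score_cohort(generate_cohort(spec)))
        res = ConsensusElasticNet.from_cohort(
            cohort, "apathy", EnetConfig(repeats=15, seed=s)).fit()
        for lam in res.retained_lambdas:
            _, coef = res.coefficients(lam)
            assert coef["thick_lh_rostralmiddlefrontal"] >= 0


def test_summary_mentions_outcome_and_lambdas(small_consensus):
    text = small_consensus.summary()
    assert "sub_apathy" in text
    assert "(Intercept)" in text


def test_invalid_config_rejected(design):
    with pytest.raises(EnetError):
        EnetConfig(alpha=1.5).validate()
    with pytest.raises(EnetError):
        EnetConfig(train_fraction=1.0).validate()
    with pytest.raises(EnetError):
        EnetConfig(selection="both").validate()
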