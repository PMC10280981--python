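import numpy as np
import pandas as pd
import pytest

from conftest import no_dx_offset_spec
from npsmap.cohort import CohortSpec, generate_cohort
from npsmap.npiq import score_cohort
from npsmap.plsc import (PlscError, PLSCorrelation, stable_contributors)
from npsmap.wmh import normalize_cohort


@pytest.fixture(scope="module")
def fit(scored_cohort):
    return PLSCorrelation.from_cohort(scored_cohort).fit()


@pytest.fixture(scope="module")
def planted_fit(planted_cohort):
    return PLSCorrelation.from_cohort(planted_cohort).fit()


def test_four_components_with_orthonormal_saliences(fit):
    assert fit.n_components == 4
    assert fit.u.shape == (82, 4)
    assert fit.v.shape == (4, 4)
    np.testing.assert_allclose(fit.u.T @ fit.u, np.eye(4), atol=1e-8)
    np.testing.assert_allclose(fit.v.T @ fit.v, np.eye(4), atol=1e-8)
    assert fit.variance_explained.sum() == pytest.approx(100.0, abs=1e-6)
    assert np.all(np.diff(fit.variance_explained) <= 1e-12)


def test_sign_convention_fixes_largest_v_entry(fit):
    for j in range(fit.n_components):
        i = np.argmax(np.abs(fit.v[:, j]))
        assert fit.v[i, j] >= 0


def test_symmetric_case_matches_eigendecomposition():
    """With Y = X the singular values equal the eigenvalues of the
    correlation matrix and the two salience blocks coincide."""
    rng = np.random.default_rng(2)
    Y = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
    res = PLSCorrelation(Y, Y).fit()
    corr = np.corrcoef(Y.to_numpy(), rowvar=False) * 300 / 299
    eigvals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    np.testing.assert_allclose(res.singular_values, eigvals, atol=1e-10)
    np.testing.assert_allclose(np.abs(res.u), np.abs(res.v), atol=1e-8)


def test_rank_one_coupling_concentrates_variance():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(100, 6)))
    w = rng.normal(size=6)
    c = rng.normal(size=3)
    Y = pd.DataFrame(np.outer(X.to_numpy() @ w, c))
    res = PLSCorrelation(X, Y).fit()
    assert res.variance_explained[0] == pytest.approx(100.0, abs=1e-6)


def test_squared_singular_values_match_independent_eigensolver():
    """Oracle equivalence on random instances with p <= 20."""
    rng = np.random.default_rng(4)
    for _ in range(100):
        n = int(rng.integers(20, 60))
        p = int(rng.integers(4, 21))
        q = int(rng.integers(2, 5))
        X = pd.DataFrame(rng.normal(size=(n, p)))
        Y = pd.DataFrame(rng.normal(size=(n, q)))
        res = PLSCorrelation(X, Y).fit()
        Xz = (X - X.mean()) / X.std(ddof=0)
        Yz = (Y - Y.mean()) / Y.std(ddof=0)
        R = Xz.to_numpy().T @ Yz.to_numpy() / (n - 1)
        eig = np.sort(np.linalg.eigvalsh(R.T @ R))[::-1]
        np.testing.assert_allclose(res.singular_values ** 2, eig, atol=1e-8)


def test_latent_score_covariance_equals_singular_value(fit):
    for i in range(fit.n_components):
        cov = np.cov(fit.x_scores[:, i], fit.y_scores[:, i], ddof=1)[0, 1]
        assert cov == pytest.approx(fit.singular_values[i], abs=1e-8)


def test_zero_variance_column_is_named():
    X = pd.DataFrame({"good": [1.0, 2.0, 3.0, 4.0], "flat": [1.0] * 4})
    Y = pd.DataFrame({"y1": [0.1, 0.5, 0.2, 0.9], "y2": [1.0, 0.0, 2.0, 1.5]})
    with pytest.raises(PlscError, match="flat"):
        PLSCorrelation(X, Y).fit()


def test_permutation_pvalues_respect_add_one_bounds(fit):
    perm = fit.permutation_test(n_perm=99, seed=0)
    assert np.all(perm.p_values > 0)
    assert np.all(perm.p_values <= 1)
    assert perm.null_samples.shape == (99, 4)


def test_permutation_guards(fit):
    with pytest.raises(PlscError, match="n_perm"):
        fit.permutation_test(n_perm=10, seed=0)


def test_strong_coupling_attains_minimum_pvalue():
    spec = CohortSpec(seed=31, effect_spec=[
        ("thick_rh_parstriangularis", "apathy", 0.8)])
    cohort = normalize_cohort(score_cohort(generate_cohort(spec)))
    res = PLSCorrelation.from_cohort(cohort).fit()
    perm = res.permutation_test(n_perm=200, seed=1)
    assert perm.p_values[0] == pytest.approx(1 / 201)


def test_rotated_permutation_mode_runs(planted_fit):
    perm = planted_fit.permutation_test(n_perm=50, seed=2, rotate=True)
    assert perm.rotated
    assert perm.p_values[0] <= 0.1


def test_bootstrap_sign_equivariance(planted_cohort):
    """Flipping one predictor column flips the sign of its bootstrap
    ratios and changes nothing else."""
    base = PLSCorrelation.from_cohort(planted_cohort)
    flipped_X = base.X.copy()
    col = "thick_lh_precuneus"
    flipped_X[col] = -flipped_X[col]
    flipped = PLSCorrelation(flipped_X, base.Y, base.strata)
    b1 = base.fit().bootstrap_ratios(n_boot=150, seed=7)
    b2 = flipped.fit().bootstrap_ratios(n_boot=150, seed=7)
    np.testing.assert_allclose(b2.bsr_x.loc[col], -b1.bsr_x.loc[col],
                               atol=1e-6)
    others = [c for c in b1.bsr_x.index if c != col]
    np.testing.assert_allclose(b2.bsr_x.loc[others], b1.bsr_x.loc[others],
                               atol=1e-6)


def test_bootstrap_guards(fit):
    with pytest.raises(PlscError, match="n_boot"):
        fit.bootstrap_ratios(n_boot=10, seed=0)


def test_planted_contributor_is_stable():
    spec = CohortSpec(seed=41, effect_spec=[
        ("thick_rh_parstriangularis", "apathy", 0.8)])
    cohort = normalize_cohort(score_cohort(generate_cohort(spec)))
    res = PLSCorrelation.from_cohort(cohort).fit()
    boot = res.bootstrap_ratios(n_boot=300, seed=3)
    stable = stable_contributors(boot, 0, threshold=2.0)
    assert "thick_rh_parstriangularis" in stable
    assert stable_contributors(boot, 0, threshold=np.inf) == []
    assert len(stable_contributors(boot, 0, threshold=0.0)) == 82


def test_independent_predictor_is_rarely_stable():
    """A predictor with no path to the outcomes keeps |BSR| < 2 in at
    least 90% of seeds."""
    ok = 0
    n_seeds = 30
    for s in range(n_seeds):
        spec = no_dx_offset_spec(6000 + s, [
            ("thick_rh_parstriangularis", "apathy", 0.8)])
        cohort = normalize_cohort(score_cohort(generate_cohort(spec)))
        res = PLSCorrelation.from_cohort(cohort).fit()
        boot = res.bootstrap_ratios(n_boot=300, seed=s)
        ok += abs(boot.bsr_x.loc["wmhlog_occipital_l", "comp1"]) < 2
    assert ok >= 0.9 * n_seeds


def test_stable_contributors_component_range(fit):
    boot = fit.bootstrap_ratios(n_boot=120, seed=5)
    with pytest.raises(PlscError, match="component"):
        stable_contributors(boot, 4)


def test_component_and_score_tables(fit):
    tab = fit.component_table()
    assert list(tab["component"]) == [1, 2, 3, 4]
    scores = fit.score_table(labels=["x"] * len(fit.x_scores))
    assert {"label", "lx1", "ly1", "lx4", "ly4"} <= set(scores.columns)
    assert "PLS correlation" in fit.summary()


def test_variance_base_raw_option(scored_cohort):
    res = PLSCorrelation.from_cohort(scored_cohort).fit(variance_base="raw")
    expected = 100 * res.singular_values / res.singular_values.sum()
    np.testing.assert_allclose(res.variance_explained, expected)
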