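import numpy as np
import pandas as pd
import pytest
from scipy import stats

from olfevo.comparative import (
    branch_correlation,
    pagel_lambda_signal,
    pgls_fit,
    phylo_covariance,
    repertoire_report,
)
from olfevo.simulate import simulate_species_tree
from olfevo.trees import TimeTree


@pytest.fixture(scope="module")
def tree50():
    return simulate_species_tree(50, 100.0, seed=3)


@pytest.fixture(scope="module")
def chol50(tree50):
    C = phylo_covariance(tree50, tree50.leaf_names())
    return C, np.linalg.cholesky(C)


def test_perfect_fit(tree50):
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    res = pgls_fit(x, 2.0 * x + 1.0, tree50)
    assert res.slope == pytest.approx(2.0, abs=1e-8)
    assert res.intercept == pytest.approx(1.0, abs=1e-8)
    assert res.r2 == pytest.approx(1.0, abs=1e-10)


def test_fixed_lambda_matches_matrix_oracle(tree50, chol50):
    C, L = chol50
    rng = np.random.default_rng(1)
    x = L @ rng.normal(size=50)
    y = 2 * x + L @ rng.normal(size=50)
    res = pgls_fit(x, y, tree50, lambda_mode=1.0)
    Vi = np.linalg.inv(C)
    X = np.column_stack([np.ones(50), x])
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    assert res.intercept == pytest.approx(beta[0], abs=1e-8)
    assert res.slope == pytest.approx(beta[1], abs=1e-8)


def test_lambda_zero_equals_ols(tree50):
    rng = np.random.default_rng(2)
    x = rng.normal(size=50)
    y = 1.5 * x + rng.normal(size=50)
    res = pgls_fit(x, y, tree50, lambda_mode=0.0)
    slope, intercept = np.polyfit(x, y, 1)
    assert res.slope == pytest.approx(slope, abs=1e-10)
    assert res.intercept == pytest.approx(intercept, abs=1e-10)


def test_star_tree_equals_ols():
    leaves = ",".join(f"t{i}:10" for i in range(12))
    tree = TimeTree.from_newick(f"({leaves});")
    rng = np.random.default_rng(3)
    x = rng.normal(size=12)
    y = 0.5 * x + rng.normal(size=12)
    res = pgls_fit(x, y, tree)  # C proportional to identity at any lambda
    slope, intercept = np.polyfit(x, y, 1)
    assert res.slope == pytest.approx(slope, abs=1e-8)


def test_constant_predictor_rejected(tree50):
    with pytest.raises(ValueError, match="constant"):
        pgls_fit(np.ones(50), np.arange(50.0), tree50)


def test_species_permutation_invariance(tree50, chol50):
    _, L = chol50
    rng = np.random.default_rng(4)
    x = L @ rng.normal(size=50)
    y = L @ rng.normal(size=50)
    sp = tree50.leaf_names()
    res = pgls_fit(x, y, tree50, species=sp)
    perm = rng.permutation(50)
    res_p = pgls_fit(x[perm], y[perm], tree50, species=[sp[i] for i in perm])
    assert res_p.slope == pytest.approx(res.slope, abs=1e-9)
    assert res_p.lam == pytest.approx(res.lam, abs=1e-5)
    assert res_p.r2 == pytest.approx(res.r2, abs=1e-9)


def test_loglik_maximum_beats_endpoints(tree50, chol50):
    from olfevo.comparative import _scale_lambda, gls_fit

    C, L = chol50
    rng = np.random.default_rng(5)
    y = L @ rng.normal(size=50)
    x = L @ rng.normal(size=50)
    res = pgls_fit(x, y, tree50)
    X = np.column_stack([np.ones(50), x])
    ll_hat = gls_fit(y, X, _scale_lambda(C, res.lam))["loglik"]
    for lam in (0.0, 1.0):
        assert ll_hat >= gls_fit(y, X, _scale_lambda(C, lam))["loglik"] - 1e-9


# ------------------------------------------------------------- lambda signal

def test_lambda_signal_constant_trait_rejected(tree50):
    with pytest.raises(ValueError, match="zero-variance"):
        pagel_lambda_signal(np.ones(50), tree50)


def test_lambda_signal_detects_brownian(tree50, chol50):
    _, L = chol50
    rng = np.random.default_rng(6)
    trait = L @ rng.normal(size=50)
    sig = pagel_lambda_signal(trait, tree50)
    assert sig.lam > 0.5
    assert sig.loglik >= sig.loglik0


# ---------------------------------------------------------- correlations

def test_correlation_identical_vectors():
    r, p = branch_correlation([1, 2, 3, 4], [1, 2, 3, 4])
    assert r == pytest.approx(1.0)


def test_correlation_reversed():
    r, _ = branch_correlation([1, 2, 3], [3, 2, 1])
    assert r == pytest.approx(-1.0)


def test_correlation_matches_formula_oracle():
    rng = np.random.default_rng(7)
    for _ in range(10):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        r, p = branch_correlation(a, b)
        # textbook product-moment formula
        ra = (np.sum((a - a.mean()) * (b - b.mean()))
              / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)))
        assert r == pytest.approx(ra, abs=1e-12)
        t = ra * np.sqrt(28 / (1 - ra ** 2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 28), rel=1e-9)


def test_correlation_zero_variance_rejected():
    with pytest.raises(ValueError):
        branch_correlation([1, 1, 1], [1, 2, 3])


# ------------------------------------------------------------------ report

def test_repertoire_report_columns(tree50, chol50):
    _, L = chol50
    rng = np.random.default_rng(8)
    sp = tree50.leaf_names()
    base = L @ rng.normal(size=50)
    table = pd.DataFrame(
        {
            "species": sp,
            "OR": np.round(np.abs(base * 10 + 100)),
            "TAAR": np.round(np.abs(base * 6 + 60 + rng.normal(size=50))),
            "OlfC": np.round(np.abs(base * 4 + 40 + rng.normal(size=50))),
            "lamellae": np.round(np.abs(base * 2 + 10)),
        }
    )
    table["total"] = table[["OR", "TAAR", "OlfC"]].sum(axis=1)
    report = repertoire_report(table, tree50)
    assert set(report.columns) >= {"response", "predictor", "slope", "lambda", "r2", "p"}
    assert len(report) == 7


def test_repertoire_report_skips_degenerate(tree50):
    table = pd.DataFrame({"species": ["zz1", "zz2"], "OR": [1, 2], "TAAR": [2, 3]})
    report = repertoire_report(table, tree50, pairs=[("TAAR", "OR")])
    assert report.empty
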