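"""REML engine: closed-form oracles, BLUP/PEV identities, invariances."""

import numpy as np
import pytest

from cloneval import mixedmodel as mm
from cloneval import simulate as sim
from cloneval.relmat import vanraden_Ga, vitezica_Gd
from conftest import tiny_config


# ----------------------------------------------------------------------
# AR1 correlation
# ----------------------------------------------------------------------
def test_ar1_identity_at_zero():
    np.testing.assert_allclose(mm.ar1_correlation(4, 0.0), np.eye(4))


def test_ar1_hand_example():
    np.testing.assert_allclose(
        mm.ar1_correlation(3, 0.5),
        [[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]],
    )


@pytest.mark.parametrize("n, rho", [(4, 0.3), (6, -0.7), (10, 0.95)])
def test_ar1_log_determinant_closed_form(n, rho):
    sign, logdet = np.linalg.slogdet(mm.ar1_correlation(n, rho))
    assert sign == 1.0
    assert logdet == pytest.approx((n - 1) * np.log(1 - rho**2), rel=1e-10)


def test_ar1_rejects_bad_inputs():
    with pytest.raises(ValueError):
        mm.ar1_correlation(3, 1.0)
    with pytest.raises(ValueError):
        mm.ar1_correlation(0, 0.5)


# ----------------------------------------------------------------------
# REML oracles
# ----------------------------------------------------------------------
def _balanced_oneway(seed, groups=5, reps=4, sb=2.0, se=1.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(groups), reps)
    y = 3.0 + rng.normal(0, sb, groups)[g] + rng.normal(0, se, groups * reps)
    return y, g, groups, reps


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_reml_equals_anova_on_balanced_oneway(seed):
    y, g, groups, reps = _balanced_oneway(seed)
    spec = mm.ModelSpec(
        y=y, X=np.ones((y.size, 1)), random_terms=[mm.term_from_labels("group", g)]
    )
    fit = mm.fit_reml(spec)
    ybar = y.reshape(groups, reps).mean(axis=1)
    msb = reps * np.sum((ybar - y.mean()) ** 2) / (groups - 1)
    msw = np.sum((y.reshape(groups, reps) - ybar[:, None]) ** 2) / (groups * (reps - 1))
    assert fit.converged
    assert fit.variance_components["group"] == pytest.approx((msb - msw) / reps, abs=1e-6)
    assert fit.variance_components["residual"] == pytest.approx(msw, abs=1e-6)


def test_noiseless_response_hits_boundary():
    rng = np.random.default_rng(4)
    X = np.column_stack([np.ones(15), rng.normal(size=15)])
    beta = np.array([2.0, -1.5])
    y = X @ beta  # exactly in the column space of X
    fit = mm.fit_reml(mm.ModelSpec(y=y, X=X, random_terms=[]))
    assert fit.variance_components["residual"] <= 1e-6 * np.var(y)
    np.testing.assert_allclose(fit.fixed_effects, beta, atol=1e-6)


def test_blup_pev_match_dense_gls_oracle():
    # n = 12, one kernel term at fixed variances vs explicit dense formulas
    rng = np.random.default_rng(5)
    n, q = 12, 4
    levels = rng.integers(0, q, n)
    Kh = rng.normal(size=(q, q))
    K = Kh @ Kh.T / q + np.eye(q)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.normal(size=n)
    su, se = 2.5, 1.3
    term = mm.RandomTerm("u", levels, q, K=K, level_ids=list(range(q)))
    fit = mm.solve_mixed(mm.ModelSpec(y=y, X=X, random_terms=[term]),
                         {"u": su, "residual": se})

    Z = np.zeros((n, q))
    Z[np.arange(n), levels] = 1.0
    V = su * Z @ K @ Z.T + se * np.eye(n)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
    u = su * K @ Z.T @ P @ y
    pev = np.diag(su * K - su**2 * K @ Z.T @ P @ Z @ K)
    ll = -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(X.T @ Vi @ X)[1]
        + y @ P @ y
        + (n - 2) * np.log(2 * np.pi)
    )
    np.testing.assert_allclose(fit.fixed_effects, beta, atol=1e-8)
    np.testing.assert_allclose(fit.random_effects["u"], u, atol=1e-8)
    np.testing.assert_allclose(fit.pev["u"], pev, atol=1e-8)
    assert fit.loglik == pytest.approx(ll, abs=1e-8)


def test_ar1_residual_matches_kronecker_oracle():
    # loglik through the spatial residual path equals an explicit Kronecker V
    rng = np.random.default_rng(6)
    nr, nc = 5, 6
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    n = nr * nc
    y = rng.normal(size=n)
    X = np.ones((n, 1))
    rc, rr = 0.4, -0.3
    spec = mm.ModelSpec(
        y=y, X=X, random_terms=[],
        residual=mm.Residual(kind="ar1_by_ar1", rows=rows, cols=cols,
                             rho_col=rc, rho_row=rr, estimate_rho=False),
    )
    sxi = 1.7
    ll = mm.restricted_loglik(spec, {"residual_spatial": sxi})
    V = sxi * np.kron(mm.ar1_correlation(nr, rr), mm.ar1_correlation(nc, rc))
    Vi = np.linalg.inv(V)
    P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
    ll_oracle = -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(X.T @ Vi @ X)[1]
        + y @ P @ y
        + (n - 1) * np.log(2 * np.pi)
    )
    assert ll == pytest.approx(ll_oracle, abs=1e-8)


# ----------------------------------------------------------------------
# algorithmic properties
# ----------------------------------------------------------------------
def test_em_loglik_monotone():
    y, g, *_ = _balanced_oneway(7)
    spec = mm.ModelSpec(
        y=y, X=np.ones((y.size, 1)), random_terms=[mm.term_from_labels("group", g)]
    )
    fit = mm.fit_reml(spec, mm.REMLOptions(algorithm="em", max_iter=150, tol_loglik=1e-10))
    diffs = np.diff(fit.trace)
    assert (diffs >= -1e-6).all()


def test_permutation_invariance():
    rng = np.random.default_rng(8)
    y, g, *_ = _balanced_oneway(9)
    perm = rng.permutation(y.size)
    spec1 = mm.ModelSpec(y=y, X=np.ones((y.size, 1)),
                         random_terms=[mm.term_from_labels("group", g)])
    spec2 = mm.ModelSpec(y=y[perm], X=np.ones((y.size, 1)),
                         random_terms=[mm.term_from_labels("group", g[perm])])
    f1, f2 = mm.fit_reml(spec1), mm.fit_reml(spec2)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
    for k in f1.variance_components:
        assert f1.variance_components[k] == pytest.approx(
            f2.variance_components[k], rel=1e-4, abs=1e-8
        )
    np.testing.assert_allclose(f1.random_effects["group"], f2.random_effects["group"],
                               atol=1e-6)


def test_rank_deficient_fixed_design_rejected():
    X = np.column_stack([np.ones(10), np.ones(10)])
    y = np.arange(10.0)
    with pytest.raises(ValueError, match="rank deficient"):
        mm.fit_reml(mm.ModelSpec(y=y, X=X, random_terms=[], fixed_names=["a", "b"]))


def test_heterogeneous_residual_groups():
    rng = np.random.default_rng(10)
    groups = np.repeat(["A", "B"], 200)
    y = np.concatenate([rng.normal(0, 1.0, 200), rng.normal(0, 3.0, 200)])
    spec = mm.ModelSpec(
        y=y, X=np.ones((400, 1)), random_terms=[],
        residual=mm.Residual(kind="heterogeneous_by_group", groups=groups),
    )
    fit = mm.fit_reml(spec)
    assert fit.variance_components["residual_A"] == pytest.approx(1.0, rel=0.3)
    assert fit.variance_components["residual_B"] == pytest.approx(9.0, rel=0.3)


# ----------------------------------------------------------------------
# accuracy / reliability helpers
# ----------------------------------------------------------------------
def test_pev_to_accuracy_examples():
    assert mm.pev_to_accuracy(0.0, 2.0) == 1.0
    assert mm.pev_to_accuracy(2.0, 2.0) == 0.0
    assert mm.pev_to_accuracy(0.25 * 2.0, 2.0) == pytest.approx(0.866025, abs=1e-6)
    with pytest.raises(ValueError):
        mm.pev_to_accuracy(0.1, 0.0)


def test_reliability_per_level():
    rel = mm.pev_to_reliability(np.array([0.0, 0.5, 1.0]), 1.0)
    np.testing.assert_allclose(rel, [1.0, 0.5, 0.0])


# ----------------------------------------------------------------------
# parameter recovery with genomic kernels
# ----------------------------------------------------------------------
def test_two_kernel_parameter_recovery():
    """Additive + dominance + residual on 500 genotypes, 30 seeds:
    mean REML estimates fall within 3 Monte-Carlo s.e. of the truth."""
    cfg = tiny_config(n_founders=24, n_snps=800, n_hs_families=20, n_fs_families=5,
                      progeny_per_family=20, seed=1)
    rng = np.random.default_rng(1)
    founders = sim.simulate_founders(cfg, rng)
    fam = sim.make_families(founders, cfg, rng)
    g = fam.progeny
    Ga = vanraden_Ga(g)
    Gd = vitezica_Gd(g, freqs=Ga.allele_freqs)
    m = g.n_samples
    La = np.linalg.cholesky(Ga.values + 1e-6 * np.eye(m))
    Ld = np.linalg.cholesky(Gd.values + 1e-6 * np.eye(m))
    truth = {"a": 2.0, "d": 1.5, "e": 1.0}
    terms = lambda: [
        mm.RandomTerm("a", np.arange(m), m, K=Ga.values, level_ids=list(g.samples)),
        mm.RandomTerm("d", np.arange(m), m, K=Gd.values, level_ids=list(g.samples)),
    ]
    ests = []
    opts = mm.REMLOptions(compute_pev=False)
    for seed in range(30):
        r = np.random.default_rng(100 + seed)
        y = (
            np.sqrt(truth["a"]) * (La @ r.standard_normal(m))
            + np.sqrt(truth["d"]) * (Ld @ r.standard_normal(m))
            + np.sqrt(truth["e"]) * r.standard_normal(m)
        )
        fit = mm.fit_reml(mm.ModelSpec(y=y, X=np.ones((m, 1)), random_terms=terms()), opts)
        ests.append([fit.variance_components[k] for k in ("a", "d", "residual")])
    ests = np.asarray(ests)
    for col, key in enumerate(("a", "d", "e")):
        mean = ests[:, col].mean()
        se = ests[:, col].std(ddof=1) / np.sqrt(len(ests))
        assert abs(mean - truth[key]) <= 3 * se, (key, mean, se)
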