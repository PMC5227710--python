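"""Henderson III, F-tests, permutation null, tail extrapolation, Gibbs."""

import numpy as np
import pytest
from scipy import stats

from fullgwas.coding import DesignMatrices, ModelSpec, RandomBlock, build_design
from fullgwas.engine import (
    GroupFTester,
    experimentwise_p,
    gibbs_estimate,
    henderson3_components,
    permutation_threshold,
    term_F,
)

from conftest import make_genotypes, make_phenotypes


def _manual_design(y, X, fixed_labels, blocks):
    """DesignMatrices straight from matrices (each row = one individual)."""
    n = len(y)
    cols = np.hstack([X] + [b.matrix for b in blocks]) if blocks else X
    cmap = {lab: {"group": lab, "kind": "mu", "unit": None, "level": None}
            for lab in fixed_labels}
    for b in blocks:
        for lab, grp in zip(b.labels, b.groups):
            cmap[lab] = {"group": grp, "kind": b.cls, "unit": None, "level": None}
    return DesignMatrices(
        fixed=X, fixed_labels=fixed_labels, random_blocks=blocks,
        column_map=cmap,
        record_iids=np.array([f"i{k}" for k in range(n)]),
        record_exams=np.array(["e1"] * n),
        ind_index=np.arange(n),
        individuals=np.array([f"i{k}" for k in range(n)]),
        geno_ind=cols, pheno_part=np.ones_like(cols),
        n_dropped_records=0, y=np.asarray(y, float), spec=None,
    )


# ---------------------------------------------------------------------------
# Henderson method III


def test_henderson_equals_oneway_anova_closed_form():
    """Balanced one-way random model: sigma2_group = (MSB - MSW)/n_per,
    sigma2_eps = MSW."""
    y = np.array([1.0, 1.2, 2.0, 2.2])
    G = np.zeros((4, 2))
    G[:2, 0] = 1
    G[2:, 1] = 1
    d = _manual_design(y, np.ones((4, 1)), ["mu"],
                       [RandomBlock("g", G, ["g1", "g2"], ["g", "g"])])
    vc = henderson3_components(d)
    assert vc.components["g"] == pytest.approx(0.49)
    assert vc.residual == pytest.approx(0.02)


def test_henderson_equals_twoway_anova_closed_form():
    """Balanced two-way crossed random model (a x b, r reps): the
    method-of-moments solutions from the classical EMS table."""
    rng = np.random.default_rng(4)
    a_lv, b_lv, r = 6, 5, 3
    sa, sb, se = 2.0, 1.0, 0.5
    ai = rng.normal(0, np.sqrt(sa), a_lv)
    bj = rng.normal(0, np.sqrt(sb), b_lv)
    rows = []
    y = []
    for i in range(a_lv):
        for j in range(b_lv):
            for _ in range(r):
                rows.append((i, j))
                y.append(5 + ai[i] + bj[j] + rng.normal(0, np.sqrt(se)))
    y = np.array(y)
    A = np.zeros((len(y), a_lv))
    B = np.zeros((len(y), b_lv))
    for k, (i, j) in enumerate(rows):
        A[k, i] = 1
        B[k, j] = 1
    d = _manual_design(
        y, np.ones((len(y), 1)), ["mu"],
        [RandomBlock("A", A, [f"a{i}" for i in range(a_lv)], ["A"] * a_lv),
         RandomBlock("B", B, [f"b{j}" for j in range(b_lv)], ["B"] * b_lv)],
    )
    vc = henderson3_components(d)
    # closed-form ANOVA (no interaction term in the model): from mean squares
    ybar = y.mean()
    ya = y.reshape(a_lv, b_lv, r).mean(axis=(1, 2))
    yb = y.reshape(a_lv, b_lv, r).mean(axis=(0, 2))
    ssa = b_lv * r * ((ya - ybar) ** 2).sum()
    ssb = a_lv * r * ((yb - ybar) ** 2).sum()
    sse = ((y.reshape(a_lv, b_lv, r)
            - ya[:, None, None] - yb[None, :, None] + ybar) ** 2).sum()
    dfe = len(y) - a_lv - b_lv + 1
    mse = sse / dfe
    sa_hat = (ssa / (a_lv - 1) - mse) / (b_lv * r)
    sb_hat = (ssb / (b_lv - 1) - mse) / (a_lv * r)
    assert vc.residual == pytest.approx(mse, rel=1e-8)
    assert vc.components["A"] == pytest.approx(sa_hat, rel=1e-8)
    assert vc.components["B"] == pytest.approx(sb_hat, rel=1e-8)


def test_henderson_without_random_classes_returns_ols_mse():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(40), rng.normal(size=40)])
    y = X @ [1.0, 2.0] + rng.normal(size=40)
    d = _manual_design(y, X, ["mu", "x"], [])
    vc = henderson3_components(d)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    mse = ((y - X @ beta) ** 2).sum() / (40 - 2)
    assert vc.residual == pytest.approx(mse)
    assert vc.components == {}


def test_zero_variance_class_truncates_to_zero_on_average():
    """Data simulated with sigma2_group = 0: estimates average to ~0 and
    negative draws are truncated (flagged)."""
    rng = np.random.default_rng(7)
    G = np.kron(np.eye(8), np.ones((4, 1)))
    ests, any_truncated = [], False
    for _ in range(120):
        y = rng.normal(size=32)
        d = _manual_design(y, np.ones((32, 1)), ["mu"],
                           [RandomBlock("g", G, [f"g{i}" for i in range(8)], ["g"] * 8)])
        vc = henderson3_components(d)
        ests.append(vc.components["g"])
        any_truncated |= bool(vc.truncated)
    assert np.mean(ests) < 0.08  # ~half the raw draws are negative -> near 0
    assert any_truncated


# ---------------------------------------------------------------------------
# term F-tests


def test_term_f_equals_ols_partial_f():
    """Without random classes the Henderson-III term F is exactly the
    classical partial F of least squares (statsmodels oracle)."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(3)
    gm = make_genotypes(rng.integers(0, 3, size=(80, 3)))
    ph = make_phenotypes(rng.normal(size=80), sex=rng.integers(0, 2, 80))
    spec = ModelSpec(loci={"snp0": {"a", "d"}, "snp1": {"a"}}, random_classes=frozenset())
    d = build_design(gm, ph, spec)
    full = sm.OLS(d.y, d.fixed).fit()
    for j, lab in enumerate(d.fixed_labels):
        if lab in ("mu",):
            continue
        red = sm.OLS(d.y, np.delete(d.fixed, j, axis=1)).fit()
        f_oracle = (red.ssr - full.ssr) / full.mse_resid
        assert term_F(d, term=lab).F == pytest.approx(f_oracle, rel=1e-9)


def test_null_term_f_mean_matches_f_distribution():
    """With no true effect the term F follows F(df, df_res); its empirical
    mean approaches df_res/(df_res - 2)."""
    rng = np.random.default_rng(5)
    n = 40
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    d = _manual_design(np.zeros(n), X, ["mu", "x1", "x2", "x3"], [])
    means = []
    for _ in range(800):
        d.y = rng.normal(size=n)
        means.append(term_F(d, term="x1").F)
    df_res = n - 4
    assert np.mean(means) == pytest.approx(df_res / (df_res - 2), rel=0.1)


def test_duplicated_test_column_raises_aliasing_error():
    rng = np.random.default_rng(1)
    x = rng.normal(size=30)
    X = np.column_stack([np.ones(30), x, x])
    d = _manual_design(rng.normal(size=30), X, ["mu", "x", "x_copy"], [])
    with pytest.raises(ValueError, match="aliased"):
        term_F(d, term="x_copy")


# ---------------------------------------------------------------------------
# permutation null


def _noise_design(n=120, seed=0):
    rng = np.random.default_rng(seed)
    gm = make_genotypes(rng.integers(0, 3, size=(n, 1)))
    ph = make_phenotypes(rng.normal(size=n))
    spec = ModelSpec(loci={"snp0": {"a"}}, random_classes=frozenset(),
                     include_sex_block=False)
    return build_design(gm, ph, spec)


def test_permutation_critical_f_approximates_analytic_quantile():
    """Pure-noise response, a single tested term: the permutation critical
    F converges to the analytic F(1, df_res) 95% quantile."""
    d = _noise_design(n=150, seed=2)
    null = permutation_threshold(d, ["a:snp0"], n_perm=800, alpha_ew=0.05, seed=9)
    analytic = stats.f.ppf(0.95, 1, 150 - 2)
    assert null.critical_F == pytest.approx(analytic, rel=0.2)


def test_permutation_determinism_and_trivial_alpha():
    d = _noise_design(n=60, seed=3)
    a = permutation_threshold(d, ["a:snp0"], n_perm=120, seed=5)
    b = permutation_threshold(d, ["a:snp0"], n_perm=120, seed=5)
    np.testing.assert_array_equal(a.max_F_samples, b.max_F_samples)
    c = permutation_threshold(d, ["a:snp0"], n_perm=120, alpha_ew=1.0, seed=5)
    assert c.critical_F == a.max_F_samples.min()
    with pytest.raises(ValueError, match="n_perm"):
        permutation_threshold(d, ["a:snp0"], n_perm=50, seed=5)


def test_experimentwise_p_boundaries_and_monotonicity():
    d = _noise_design(n=100, seed=4)
    null = permutation_threshold(d, ["a:snp0"], n_perm=400, seed=11)
    p_low, ex = experimentwise_p(0.0, null)
    assert p_low == pytest.approx(1.0) and not ex
    q95 = float(np.quantile(null.max_F_samples, 0.95))
    p95, _ = experimentwise_p(q95, null)
    assert p95 == pytest.approx(0.05, abs=0.02)
    grid = np.linspace(0, 3 * null.max_F_samples.max(), 200)
    ps = [experimentwise_p(f, null)[0] for f in grid]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_tail_extrapolation_tracks_analytic_f_tail():
    """Far beyond the permutation range, the generalised-Pareto tail gives
    P within about an order of magnitude of the analytic F survival
    function on a Gaussian single-term null."""
    d = _noise_design(n=200, seed=6)
    null = permutation_threshold(d, ["a:snp0"], n_perm=2000, seed=13)
    f_far = stats.f.isf(1e-5, 1, 200 - 2)  # analytic p = 1e-5
    p_fit, extrapolated = experimentwise_p(f_far, null)
    assert extrapolated
    assert abs(np.log10(p_fit) - (-5.0)) < 1.3


# ---------------------------------------------------------------------------
# Gibbs sampler


def test_gibbs_matches_ols_on_fixed_effects_design():
    rng = np.random.default_rng(8)
    n = 120
    gm = make_genotypes(rng.integers(0, 3, size=(n, 2)))
    ph = make_phenotypes(rng.normal(size=n), sex=rng.integers(0, 2, n))
    spec = ModelSpec(loci={"snp0": {"a", "d"}, "snp1": {"a"}}, random_classes=frozenset())
    d = build_design(gm, ph, spec)
    est, vc = gibbs_estimate(d, iterations=4000, burn_in=1000, seed=2)
    beta = np.linalg.lstsq(d.fixed, d.y, rcond=None)[0]
    for j, lab in enumerate(d.fixed_labels):
        mean, sd = est.fixed[lab]
        mc_se = sd / np.sqrt(3000)
        assert abs(mean - beta[j]) < 2 * mc_se + 0.05 * sd + 1e-6


def test_gibbs_determinism_and_degenerate_input():
    rng = np.random.default_rng(9)
    gm = make_genotypes(rng.integers(0, 3, size=(40, 1)))
    ph = make_phenotypes(rng.normal(size=40), sex=rng.integers(0, 2, 40))
    d = build_design(gm, ph, ModelSpec(loci={"snp0": {"a"}}, random_classes={"e"}))
    a, _ = gibbs_estimate(d, iterations=500, burn_in=100, seed=3)
    b, _ = gibbs_estimate(d, iterations=500, burn_in=100, seed=3)
    assert a.fixed == b.fixed and a.random == b.random
    d.y = np.ones(40)
    with pytest.raises(ValueError, match="zero variance"):
        gibbs_estimate(d, iterations=500, burn_in=100, seed=3)
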