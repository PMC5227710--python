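"""Synthetic genotype and phenotype generation."""

import numpy as np
import pytest
from scipy import stats

from fullgwas.coding import code_additive
from fullgwas.simulate import (
    SCENARIO_I_TRUTH,
    PopulationModel,
    SimulationScenario,
    TruthEffect,
    assign_groups,
    calibrate_residual,
    gen_genotypes,
    scenario_i,
    scenario_ii,
    scenario_panel,
    simulate_phenotypes,
    truth_loci,
    truth_model_spec,
)


def test_population_model_validation():
    with pytest.raises(ValueError, match="MAF"):
        PopulationModel(maf=0.6)
    with pytest.raises(ValueError, match="FST"):
        PopulationModel(fst=1.0)
    with pytest.raises(ValueError, match="LD"):
        PopulationModel(ld_rho=1.0)


def test_group_assignment_shares():
    model = PopulationModel()
    g = assign_groups(model, 5277)
    counts = np.bincount(g)[1:]
    assert counts.sum() == 5277
    # recruitment shares: 38% E-A, 12% C-A, 28% A-A, 22% H-A
    np.testing.assert_allclose(counts / 5277, [0.38, 0.12, 0.28, 0.22], atol=0.001)


def test_fst_zero_gives_identical_group_frequencies():
    model = PopulationModel(fst=0.0, maf=0.25, seed=5)
    gm = gen_genotypes(model, 4000, 3)
    groups = assign_groups(model, 4000)
    for j in range(3):
        freqs = [np.mean(2 - gm.calls[groups == h, j]) / 2 for h in range(1, 5)]
        # all groups draw from the same ancestral frequency
        assert np.std(freqs) < 0.03
        assert abs(np.mean(freqs) - 0.25) < 0.03


def test_same_seed_reproduces_matrix():
    model = PopulationModel(seed=9)
    a = gen_genotypes(model, 100, 10)
    b = gen_genotypes(model, 100, 10)
    np.testing.assert_array_equal(a.calls, b.calls)


def test_ld_block_creates_high_genotype_r2():
    model = PopulationModel(ld_rho=0.95, seed=2)
    gm = gen_genotypes(model, 5000, 2, blocks=[2])
    d0, d1 = (2.0 - gm.calls[:, 0]), (2.0 - gm.calls[:, 1])
    r2 = np.corrcoef(d0, d1)[0, 1] ** 2
    assert r2 > 0.75


def test_within_group_hardy_weinberg():
    """Genotype counts inside one ethnic group match Hardy-Weinberg
    proportions at the group's realised allele frequency."""
    model = PopulationModel(seed=13, fst=0.05)
    gm = gen_genotypes(model, 8000, 1)
    groups = assign_groups(model, 8000)
    calls = gm.calls[groups == 1, 0]
    p = np.mean(calls) / 2  # major allele frequency
    n = len(calls)
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    observed = np.bincount(calls, minlength=3)
    chi2 = ((observed - expected) ** 2 / expected).sum()
    assert stats.chi2.sf(chi2, df=1) > 0.001


# ---------------------------------------------------------------------------
# phenotypes


def _flat_scenario(truth, sigma=1.0, **kw):
    return SimulationScenario(tag="I", truth=truth, sigma_eps=sigma, mu=200.0,
                              sex_effect=0.0, group_effects=(0, 0, 0, 0), **kw)


def test_null_trait_mean_and_variance():
    model = PopulationModel(seed=3)
    gm = gen_genotypes(model, 4000, 1)
    groups = assign_groups(model, 4000)
    scen = _flat_scenario((TruthEffect("snp0", "a", 0.0),), sigma=3.0)
    ph, _ = simulate_phenotypes(scen, gm, groups, np.zeros(4000, int), seed=4)
    y = ph.values()
    assert y.mean() == pytest.approx(200.0, abs=0.2)
    assert y.var() == pytest.approx(9.0, rel=0.1)


def test_homozygote_contrast_is_twice_additive_effect():
    model = PopulationModel(seed=5)
    gm = gen_genotypes(model, 500, 1)
    groups = assign_groups(model, 500)
    scen = _flat_scenario((TruthEffect("snp0", "a", 2.0),), sigma=1e-9)
    ph, _ = simulate_phenotypes(scen, gm, groups, np.zeros(500, int), seed=6)
    one = ph.records[ph.records["exam"] == "exam1"]
    calls = gm.calls[:, 0]
    y = one["value"].to_numpy()
    assert y[calls == 2].mean() - y[calls == 0].mean() == pytest.approx(4.0, abs=1e-6)


def test_generator_is_linear_in_effects():
    """Doubling every true effect doubles the genetic contribution exactly
    (noise held fixed through the seed)."""
    model = PopulationModel(seed=6)
    truth = SCENARIO_I_TRUTH
    gm = scenario_panel(truth, model, 300, seed=6)
    groups = assign_groups(model, 300)
    sex = np.zeros(300, int)
    t1 = _flat_scenario(truth, sigma=1.0)
    t2 = _flat_scenario(tuple(
        TruthEffect(t.unit, t.kind, 2 * t.value, t.level) for t in truth), sigma=1.0)
    y1, _ = simulate_phenotypes(t1, gm, groups, sex, seed=7)
    y2, _ = simulate_phenotypes(t2, gm, groups, sex, seed=7)
    g1 = y1.values() - 200.0  # noise cancels in the difference below
    g2 = y2.values() - 200.0
    eps = g2 - 2 * g1  # = -noise; must equal the (shared) negated noise
    y0, _ = simulate_phenotypes(_flat_scenario(tuple(
        TruthEffect(t.unit, t.kind, 0.0, t.level) for t in truth), sigma=1.0),
        gm, groups, sex, seed=7)
    np.testing.assert_allclose(eps, -(y0.values() - 200.0), atol=1e-9)


def test_replicates_share_genetic_value():
    model = PopulationModel(seed=8)
    gm = scenario_panel(SCENARIO_I_TRUTH, model, 200, seed=8)
    groups = assign_groups(model, 200)
    scen = _flat_scenario(SCENARIO_I_TRUTH, sigma=1e-9)
    ph, _ = simulate_phenotypes(scen, gm, groups, np.zeros(200, int), seed=9)
    wide = ph.records.pivot(index="iid", columns="exam", values="value")
    np.testing.assert_allclose(wide["exam1"], wide["exam3"], atol=1e-6)


def test_missing_truth_genotype_drops_records():
    model = PopulationModel(seed=10, missing_rate=0.1)
    gm = gen_genotypes(model, 300, 1)
    groups = assign_groups(model, 300)
    scen = _flat_scenario((TruthEffect("snp0", "a", 1.0),))
    ph, dropped = simulate_phenotypes(scen, gm, groups, np.zeros(300, int), seed=11)
    n_miss = int((gm.calls[:, 0] == -1).sum())
    assert dropped == 2 * n_miss
    assert ph.n_records == 2 * (300 - n_miss)


# ---------------------------------------------------------------------------
# residual calibration


def test_calibrate_simple_half_share():
    """Genetic variance v, target share 50% -> sigma_eps = sqrt(v)."""
    calls = np.array([[2], [0]] * 100)  # x_a alternates +1/-1: variance 1
    from conftest import make_genotypes

    gm = make_genotypes(calls)
    truth = (TruthEffect("snp0", "a", 1.0),)
    scen = _flat_scenario(truth, sigma=None)
    groups = np.ones(200, int)
    sex = np.zeros(200, int)
    out = calibrate_residual(scen, gm, groups, sex, target_total_h2=0.5)
    assert out.sigma_eps == pytest.approx(1.0)
    with pytest.raises(ValueError, match="positive"):
        calibrate_residual(scen, gm, groups, sex, target_total_h2=0.0)


def test_calibrate_total_heritability_realised():
    """Calibrating to the full model's total heritability (33.64%) makes
    the realised genetic share match within one percentage point."""
    model = PopulationModel(seed=12)
    gm = scenario_panel(SCENARIO_I_TRUTH, model, 6000, seed=12)
    groups = assign_groups(model, 6000)
    sex = np.random.default_rng(12).integers(0, 2, 6000)
    scen = scenario_i(n=6000)
    scen = calibrate_residual(scen, gm, groups, sex, target_total_h2=0.3364)
    ph, _ = simulate_phenotypes(scen, gm, groups, sex, seed=13)
    from fullgwas.simulate import _genetic_values

    g, ok = _genetic_values(scen.truth, gm, groups)
    share = np.var(g[ok]) / np.var(ph.values())
    assert share == pytest.approx(0.3364, abs=0.01)


def test_anchor_calibration_share():
    model = PopulationModel(seed=14)
    gm = scenario_panel(SCENARIO_I_TRUTH, model, 5000, seed=14)
    groups = assign_groups(model, 5000)
    sex = np.random.default_rng(14).integers(0, 2, 5000)
    scen = calibrate_residual(scenario_i(n=5000), gm, groups, sex)  # default anchor
    ph, _ = simulate_phenotypes(scen, gm, groups, sex, seed=15)
    xa = code_additive(gm.column("rs629301"))
    share = np.var(4.94 * xa) / np.var(ph.values())
    assert share == pytest.approx(0.0146, abs=0.002)


# ---------------------------------------------------------------------------
# truth bookkeeping


def test_scenario_truth_sets_and_spec():
    truth = scenario_i().truth
    assert len(truth_loci(truth)) == 20  # 17 main-effect loci + 3 pair-only
    spec = truth_model_spec(truth)
    assert spec.loci["rs7694118"] == {"d"}
    assert spec.epistasis_pairs[("rs2264802", "rs9548318")] == {"aa", "ad"}
    assert "de" in spec.random_classes
    # scenario II restricts kinds
    with pytest.raises(ValueError, match="scenario II"):
        scenario_ii(ae_truth=(TruthEffect("rs629301", "d", 1.0),))
    add = truth_model_spec(scenario_ii().truth)
    assert all(t == {"a"} for t in add.loci.values())
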