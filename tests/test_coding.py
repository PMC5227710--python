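"""Effect codings and design-matrix construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fullgwas.coding import (
    ModelSpec,
    build_design,
    code_additive,
    code_dominance,
    code_epistasis,
)
from fullgwas.genotypes import CodingError

from conftest import make_genotypes, make_phenotypes

# genotype call = count of major alleles: 2=QQ, 1=Qq, 0=qq


@pytest.mark.parametrize(
    "call, x_a, x_d",
    [(2, 1.0, 0.0), (1, 0.0, 1.0), (0, -1.0, 0.0)],
)
def test_main_effect_codings(call, x_a, x_d):
    assert code_additive(np.array([call]))[0] == x_a
    assert code_dominance(np.array([call]))[0] == x_d


def test_missing_propagates_and_bad_value_raises():
    out = code_additive(np.array([2, -1, 0]))
    assert np.isnan(out[1]) and out[0] == 1 and out[2] == -1
    assert np.isnan(code_dominance(np.array([-1]))[0])
    with pytest.raises(CodingError, match="rs9"):
        code_additive(np.array([3]), snp_id="rs9")


# The epistasis coefficients written out genotype-by-genotype: rows/cols in
# (QQ, Qq, qq) order for locus i x locus j.
_AA = {(2, 2): 1, (2, 0): -1, (0, 2): -1, (0, 0): 1}
_AD = {(2, 1): 1, (0, 1): -1}
_DA = {(1, 2): 1, (1, 0): -1}
_DD = {(1, 1): 1}


def test_epistasis_matches_enumerated_tables_exhaustively():
    """All nine genotype combinations reproduce the enumerated aa/ad/da/dd
    coefficient tables (1 for QQxQQ and qqxqq, -1 for QQxqq and qqxQQ, 0
    otherwise, etc.)."""
    for gi in (0, 1, 2):
        for gj in (0, 1, 2):
            xa_i, xd_i = code_additive(np.array([gi])), code_dominance(np.array([gi]))
            xa_j, xd_j = code_additive(np.array([gj])), code_dominance(np.array([gj]))
            aa, ad, da, dd = code_epistasis(xa_i, xd_i, xa_j, xd_j)
            assert aa[0] == _AA.get((gi, gj), 0)
            assert ad[0] == _AD.get((gi, gj), 0)
            assert da[0] == _DA.get((gi, gj), 0)
            assert dd[0] == _DD.get((gi, gj), 0)


def test_epistasis_missing_blanks_all_four():
    xa_i = code_additive(np.array([-1]))
    xd_i = code_dominance(np.array([-1]))
    xa_j = code_additive(np.array([2]))
    xd_j = code_dominance(np.array([2]))
    for arr in code_epistasis(xa_i, xd_i, xa_j, xd_j):
        assert np.isnan(arr[0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=30))
def test_allele_swap_antisymmetry(calls):
    """Swapping major/minor orientation (calls -> 2 - calls) flips the sign
    of the additive coding and leaves the dominance coding unchanged."""
    calls = np.array(calls)
    np.testing.assert_array_equal(code_additive(2 - calls), -code_additive(calls))
    np.testing.assert_array_equal(code_dominance(2 - calls), code_dominance(calls))


# ---------------------------------------------------------------------------
# model specification


def test_modelspec_validation():
    with pytest.raises(ValueError, match="differ"):
        ModelSpec(epistasis_pairs={("s1", "s1"): {"aa"}})
    with pytest.raises(ValueError, match="additive"):
        ModelSpec(loci={"s1": {"a", "d"}}, reduced_additive=True)
    with pytest.raises(ValueError, match="random"):
        ModelSpec(loci={"s1": {"a"}}, random_classes={"e", "de"}, reduced_additive=True)


def test_reduce_to_additive_strips_nonadditive_terms():
    spec = ModelSpec(
        loci={"s1": {"a", "d"}, "s2": {"d"}},
        epistasis_pairs={("s1", "s2"): {"aa", "dd"}},
        random_classes={"e", "ae", "de"},
    )
    red = spec.reduce_to_additive()
    assert red.loci == {"s1": frozenset({"a"})}
    assert not red.epistasis_pairs
    assert red.random_classes == {"e", "ae"}
    assert red.reduced_additive


def test_modelspec_dict_roundtrip():
    spec = ModelSpec(
        loci={"s1": {"a", "d"}},
        epistasis_pairs={("s1", "s2"): {"aa"}},
        random_classes={"e", "ae"},
        interaction_terms={"ae": ("s1",)},
    )
    again = ModelSpec.from_dict(spec.to_dict())
    assert again == spec


# ---------------------------------------------------------------------------
# design construction


def test_single_locus_additive_design_columns():
    gm = make_genotypes([[2], [1], [0]])
    ph = make_phenotypes([1.0, 2.0, 3.0], sex=[0, 1, 0])
    spec = ModelSpec(loci={"snp0": {"a"}}, random_classes=frozenset())
    d = build_design(gm, ph, spec)
    assert d.fixed_labels == ["mu", "sex", "a:snp0"]
    np.testing.assert_array_equal(d.fixed[:, 2], [1.0, 0.0, -1.0])
    np.testing.assert_array_equal(d.fixed[:, 0], 1.0)


def test_interaction_block_width_and_placement():
    gm = make_genotypes([[2, 1], [0, 2], [1, 1], [2, 0]])
    ph = make_phenotypes([1, 2, 3, 4], ethnicity=[1, 3, 2, 4])
    spec = ModelSpec(loci={"snp0": {"a"}, "snp1": {"a"}}, random_classes={"e", "ae"})
    d = build_design(gm, ph, spec)
    ae = [b for b in d.random_blocks if b.cls == "ae"][0]
    assert ae.matrix.shape == (4, 8)  # 2 loci x 4 groups
    # individual 1 is group 3 with snp0 call qq -> x_a = -1 lands in the
    # (snp0, group 3) column, zero elsewhere in snp0's sub-block
    j = ae.labels.index("ae_3:snp0")
    assert ae.matrix[1, j] == -1.0
    row = ae.matrix[1, [ae.labels.index(f"ae_{h}:snp0") for h in (1, 2, 4)]]
    np.testing.assert_array_equal(row, 0.0)


def test_interaction_rows_sum_to_main_coefficient():
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 3, size=(30, 2))
    gm = make_genotypes(calls)
    ph = make_phenotypes(rng.normal(size=30), ethnicity=rng.integers(1, 5, 30),
                         replicates=2)
    spec = ModelSpec(loci={"snp0": {"a", "d"}, "snp1": {"a"}},
                     random_classes={"e", "ae", "de"})
    d = build_design(gm, ph, spec)
    for b in d.random_blocks:
        if b.cls == "e":
            continue
        for grp in sorted(set(b.groups)):
            cols = [i for i, g in enumerate(b.groups) if g == grp]
            summed = b.matrix[:, cols].sum(axis=1)
            kind, unit = grp.split(":")
            main = {"ae": "a", "de": "d"}[kind] + ":" + unit
            np.testing.assert_allclose(summed, d.fixed[:, d.fixed_labels.index(main)])


def test_missing_genotype_drops_individual_records_listwise():
    calls = np.array([[2], [1], [-1], [0]])
    gm = make_genotypes(calls)
    ph = make_phenotypes([1, 2, 3, 4], replicates=2)
    spec = ModelSpec(loci={"snp0": {"a"}}, random_classes=frozenset())
    d = build_design(gm, ph, spec)
    assert d.n_records == 6  # 3 individuals x 2 exams
    assert d.n_dropped_records == 2
    assert "ind2" not in set(d.record_iids)


def test_unknown_snp_and_empty_result_raise():
    gm = make_genotypes([[2], [1]])
    ph = make_phenotypes([1, 2])
    with pytest.raises(KeyError, match="nope"):
        build_design(gm, ph, ModelSpec(loci={"nope": {"a"}}))
    all_missing = make_genotypes([[-1], [-1]])
    with pytest.raises(ValueError, match="no phenotype records"):
        build_design(all_missing, ph, ModelSpec(loci={"snp0": {"a"}}))
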