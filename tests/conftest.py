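import numpy as np
import pandas as pd
import pytest

from fullgwas.genotypes import GenotypeMatrix, PhenotypeTable, SNP_META_COLUMNS
from fullgwas.simulate import PopulationModel, assign_groups


def make_genotypes(calls, ids=None, chrom="1"):
    """GenotypeMatrix from a raw call array (individuals x SNPs)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    ids = ids or [f"snp{j}" for j in range(m)]
    meta = pd.DataFrame(
        {"chrom": chrom, "id": ids, "pos": np.arange(1, m + 1) * 1000,
         "major": "A", "minor": "G"}
    )[SNP_META_COLUMNS]
    samples = np.array([f"ind{i}" for i in range(n)], dtype=object)
    return GenotypeMatrix(samples, meta, calls)


def make_phenotypes(values, sex=None, ethnicity=None, replicates=1, iids=None):
    """PhenotypeTable with ``replicates`` stacked exam records per
    individual; ``values`` may be a vector (repeated) or records x 1."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    iids = iids if iids is not None else [f"ind{i}" for i in range(n)]
    sex = np.zeros(n, int) if sex is None else np.asarray(sex, int)
    eth = np.ones(n, int) if ethnicity is None else np.asarray(ethnicity, int)
    frames = []
    for r in range(replicates):
        frames.append(pd.DataFrame({
            "iid": iids, "sex": sex, "ethnicity": eth,
            "exam": f"exam{2 * r + 1}", "value": values,
        }))
    return PhenotypeTable(pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def four_group_cohort():
    """A small structured cohort: 400 individuals, four ethnic groups at
    the study's recruitment shares, random sex."""
    model = PopulationModel(seed=11)
    n = 400
    groups = assign_groups(model, n)
    sex = np.random.default_rng(11).integers(0, 2, n)
    return model, n, groups, sex
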