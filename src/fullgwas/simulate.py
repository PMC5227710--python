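"""Synthetic genotype and phenotype generation.

Genotypes follow the Balding-Nichols construction: each SNP has an
ancestral minor-allele frequency, and each of the four ethnic groups draws
its own frequency from Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst); genotypes are
then Hardy-Weinberg within group.  Optional LD blocks are produced on the
haplotypes by copying a hub SNP's allele with probability rho, so the
allelic (and genotype-dosage) correlation with the hub is rho.

Phenotypes are generated from a truth set of genetic effects - additive,
dominance, digenic epistasis, and ethnicity-interaction effects activated
by group membership - plus a sex block, group main effects, and i.i.d.
normal residuals drawn independently for each of the two replicate records
per individual.  Two study scenarios are bundled: scenario I carries the
complete full-model architecture (mains, epistasis and ethnic-interaction
effects), scenario II an additive-plus-additive-by-ethnicity architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .coding import ModelSpec, code_additive, code_dominance, code_epistasis
from .genotypes import MISSING, N_GROUPS, GenotypeMatrix, PhenotypeTable, SNP_META_COLUMNS

#: group shares of the cohort in group-code order (E-A, C-A, A-A, H-A)
DEFAULT_GROUP_PROPS = (0.38, 0.12, 0.28, 0.22)


@dataclass
class PopulationModel:
    """Parameters of the genotype generator."""

    group_props: tuple = DEFAULT_GROUP_PROPS
    maf: float = 0.30
    fst: float = 0.05
    ld_rho: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError("ancestral MAF must lie in (0, 0.5]")
        if not 0 <= self.fst < 1:
            raise ValueError("FST must lie in [0, 1)")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("LD correlation must lie in [0, 1)")
        if abs(sum(self.group_props) - 1.0) > 1e-9 or len(self.group_props) != N_GROUPS:
            raise ValueError("group proportions must be 4 values summing to 1")


@dataclass(frozen=True)
class TruthEffect:
    """One true effect: ``unit`` is a SNP id or an ordered pair of ids,
    ``kind`` one of a/d/aa/ad/da/dd/ae/de/aae/ade/dae/dde, ``level`` the
    ethnic group (1..4) for interaction kinds."""

    unit: object
    kind: str
    value: float
    level: int | None = None


@dataclass
class SimulationScenario:
    tag: str
    truth: tuple
    sigma_eps: float | None = None
    mu: float = 193.0
    sex_effect: float = -7.0
    group_effects: tuple = (3.0, -4.0, 1.5, -0.5)
    n: int = 5277
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tag == "II":
            bad = {t.kind for t in self.truth} - {"a", "ae"}
            if bad:
                raise ValueError(f"scenario II truth admits only a/ae effects, got {bad}")


def assign_groups(model: PopulationModel, n: int) -> np.ndarray:
    """Deterministic group codes 1..4 with largest-remainder rounding."""
    raw = np.array(model.group_props) * n
    sizes = np.floor(raw).astype(int)
    order = np.argsort(-(raw - sizes))
    for k in range(n - sizes.sum()):
        sizes[order[k]] += 1
    return np.repeat(np.arange(1, N_GROUPS + 1), sizes)


def gen_genotypes(
    model: PopulationModel,
    n: int,
    m_snps: int,
    snp_meta: pd.DataFrame | None = None,
    blocks: list[int] | None = None,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Generate a genotype matrix under the population model.

    ``blocks`` partitions the SNPs into consecutive LD blocks (sizes summing
    to ``m_snps``); SNPs within a block share the copula correlation
    ``model.ld_rho``.  Default: all SNPs independent.
    """
    if n < 1 or m_snps < 1:
        raise ValueError("n and m_snps must be positive")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    groups = assign_groups(model, n)
    if blocks is None:
        blocks = [1] * m_snps
    if sum(blocks) != m_snps:
        raise ValueError("block sizes must sum to m_snps")

    maf = np.broadcast_to(np.asarray(model.maf, float), (m_snps,))
    # group-specific minor-allele frequencies (Balding-Nichols)
    if model.fst > 0:
        a = maf * (1 - model.fst) / model.fst
        b = (1 - maf) * (1 - model.fst) / model.fst
        pg = rng.beta(a[None, :], b[None, :], size=(N_GROUPS, m_snps))
        pg = np.clip(pg, 0.01, 0.99)
    else:
        pg = np.tile(maf, (N_GROUPS, 1))

    minor = np.empty((n, m_snps), dtype=np.int8)
    offsets = np.concatenate([[0], np.cumsum(blocks)])
    for h in range(N_GROUPS):
        rows = np.flatnonzero(groups == h + 1)
        for b0, b1 in zip(offsets[:-1], offsets[1:]):
            L = b1 - b0
            dose = np.zeros((len(rows), L), dtype=np.int8)
            # haplotype construction: the block's first SNP is the hub; each
            # other allele copies the hub with probability ld_rho (allelic
            # correlation rho to the hub, rho^2 between members), otherwise
            # it is an independent draw at the hub's group frequency
            p_hub = pg[h, b0]
            for _hap in range(2):
                hub = rng.random(len(rows)) < p_hub
                hap = np.empty((len(rows), L), dtype=bool)
                hap[:, 0] = hub
                for j in range(1, L):
                    copy = rng.random(len(rows)) < model.ld_rho
                    fresh = rng.random(len(rows)) < p_hub
                    hap[:, j] = np.where(copy, hub, fresh)
                dose += hap.astype(np.int8)
            minor[rows, b0:b1] = dose
    calls = (2 - minor).astype(np.int8)
    if model.missing_rate > 0:
        mask = rng.random((n, m_snps)) < model.missing_rate
        calls[mask] = MISSING

    if snp_meta is None:
        snp_meta = pd.DataFrame(
            {
                "chrom": "1",
                "id": [f"snp{j}" for j in range(m_snps)],
                "pos": np.arange(1, m_snps + 1) * 10_000,
                "major": "A",
                "minor": "G",
            }
        )
    samples = np.array([f"ind{i}" for i in range(n)], dtype=object)
    return GenotypeMatrix(samples=samples, snps=snp_meta[SNP_META_COLUMNS], calls=calls)


# ---------------------------------------------------------------------------
# truth sets from the two study scenarios

_CHROM = {
    "rs629301": "1", "rs2499595": "1", "rs478442": "2", "rs7624679": "3",
    "rs7694118": "4", "rs17409624": "5", "rs6465748": "7", "rs2264802": "7",
    "rs10503377": "8", "rs12246594": "10", "rs10768634": "11", "rs7124873": "11",
    "rs9548318": "13", "rs10483461": "14", "rs12595211": "15", "rs1532625": "16",
    "rs4888652": "16", "rs2649485": "17", "rs9946067": "18", "rs1654452": "19",
}

_T = TruthEffect
SCENARIO_I_TRUTH: tuple = (
    _T("rs629301", "a", 4.94), _T("rs629301", "ae", 1.75, 4),
    _T("rs2499595", "a", 1.86), _T("rs2499595", "ae", 1.36, 1),
    _T("rs2499595", "ae", -3.73, 2), _T("rs2499595", "ae", 1.94, 4),
    _T("rs478442", "a", 5.73), _T("rs478442", "ae", -2.37, 1),
    _T("rs478442", "de", -3.85, 1), _T("rs478442", "de", -2.91, 3),
    _T("rs478442", "de", 5.40, 4),
    _T("rs7624679", "a", 1.47), _T("rs7624679", "de", -1.81, 4),
    _T("rs7694118", "d", 3.11), _T("rs7694118", "de", 8.31, 1),
    _T("rs7694118", "de", -6.08, 3),
    _T("rs17409624", "a", 2.14), _T("rs17409624", "ae", 3.14, 3),
    _T("rs17409624", "ae", -3.00, 4),
    _T("rs6465748", "a", -3.11), _T("rs6465748", "d", 2.14),
    _T("rs6465748", "ae", 1.55, 1), _T("rs6465748", "ae", -4.67, 3),
    _T("rs6465748", "ae", 4.33, 4),
    _T("rs10503377", "a", 3.16), _T("rs10503377", "ae", -2.12, 1),
    _T("rs10503377", "ae", 4.74, 2), _T("rs10503377", "ae", -2.30, 4),
    _T("rs10768634", "a", -1.15), _T("rs10768634", "d", -3.45),
    _T("rs7124873", "a", 2.57),
    _T("rs10483461", "a", 2.35), _T("rs10483461", "d", -2.73),
    _T("rs10483461", "ae", 4.02, 3), _T("rs10483461", "ae", -1.47, 4),
    _T("rs12595211", "a", -2.52), _T("rs12595211", "de", 1.94, 4),
    _T("rs1532625", "a", -2.85),
    _T("rs4888652", "a", 1.91),
    _T("rs2649485", "a", -2.58),
    _T("rs9946067", "a", -2.23), _T("rs9946067", "d", 2.89),
    _T("rs1654452", "a", -2.02), _T("rs1654452", "d", 1.62),
    _T(("rs478442", "rs7694118"), "aa", 2.38),
    _T(("rs478442", "rs7694118"), "ad", -2.60),
    _T(("rs478442", "rs7694118"), "da", 3.59),
    _T(("rs4888652", "rs9946067"), "da", 2.64),
    _T(("rs4888652", "rs9946067"), "dd", -1.95),
    _T(("rs2264802", "rs9548318"), "aa", -4.71),
    _T(("rs2264802", "rs9548318"), "ad", -6.14),
    _T(("rs12246594", "rs12595211"), "aa", 7.46),
)

SCENARIO_II_TRUTH: tuple = (
    _T("rs629301", "a", 4.94), _T("rs2499595", "a", 1.86),
    _T("rs478442", "a", 5.73), _T("rs7624679", "a", 1.47),
    _T("rs17409624", "a", 2.14), _T("rs10503377", "a", 3.16),
    _T("rs10768634", "a", -1.15), _T("rs12595211", "a", -2.52),
    _T("rs1532625", "a", -2.85), _T("rs4888652", "a", 1.91),
    _T("rs2649485", "a", -2.58), _T("rs9946067", "a", -2.23),
    _T("rs1654452", "a", -2.02),
)

#: calibration anchor for scenario I: the CELSR2-region locus's additive
#: term explains 1.46% of phenotypic variance
ANCHOR_LOCUS = ("rs629301", "a", 0.0146)


def scenario_i(**kw) -> SimulationScenario:
    return SimulationScenario(tag="I", truth=SCENARIO_I_TRUTH, **kw)


def scenario_ii(ae_truth: tuple = (), **kw) -> SimulationScenario:
    """Scenario II: additive architecture; additive-by-ethnicity effects
    default to zero unless supplied."""
    return SimulationScenario(tag="II", truth=SCENARIO_II_TRUTH + tuple(ae_truth), **kw)


def truth_loci(truth) -> list[str]:
    """All SNP ids appearing in a truth set, in first-appearance order."""
    seen: dict[str, None] = {}
    for t in truth:
        units = t.unit if isinstance(t.unit, tuple) else (t.unit,)
        for s in units:
            seen.setdefault(s, None)
    return list(seen)


def truth_model_spec(truth) -> ModelSpec:
    """The model specification matching a truth set exactly: fixed main and
    epistasis terms where the truth has them, and interaction blocks only
    for loci/pairs with an ethnic-interaction truth effect."""
    loci: dict[str, set] = {}
    pairs: dict[tuple, set] = {}
    inter: dict[str, list] = {}
    for t in truth:
        if t.kind in ("a", "d"):
            loci.setdefault(t.unit, set()).add(t.kind)
        elif t.kind in ("aa", "ad", "da", "dd"):
            pairs.setdefault(tuple(t.unit), set()).add(t.kind)
        else:
            key = tuple(t.unit) if isinstance(t.unit, tuple) else t.unit
            lst = inter.setdefault(t.kind, [])
            if key not in lst:
                lst.append(key)
            if not isinstance(key, tuple):
                loci.setdefault(key, set())
    classes = {"e"} | set(inter)
    return ModelSpec(
        loci={s: frozenset(k) for s, k in loci.items()},
        epistasis_pairs={p: frozenset(k) for p, k in pairs.items()},
        random_classes=frozenset(classes),
        interaction_terms={c: tuple(u) for c, u in inter.items()},
    )


def scenario_panel(
    truth,
    model: PopulationModel,
    n: int,
    neighbors: int = 0,
    n_null: int = 0,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Genotype panel containing every truth locus, optionally flanked by
    ``neighbors`` LD partners each (allelic correlation ``model.ld_rho``)
    plus ``n_null`` unlinked null SNPs."""
    loci = truth_loci(truth)
    rows = []
    blocks = []
    for s in loci:
        chrom = _CHROM.get(s, "1")
        base = 1_000_000 * (len(rows) + 1)
        rows.append((chrom, s, base, "A", "G"))
        for j in range(neighbors):
            rows.append((chrom, f"{s}_ld{j + 1}", base + (j + 1) * 1000, "A", "G"))
        blocks.append(1 + neighbors)
    for j in range(n_null):
        rows.append(("20", f"null{j + 1}", 1_000_000 + j * 50_000, "A", "G"))
        blocks.append(1)
    meta = pd.DataFrame(rows, columns=SNP_META_COLUMNS)
    return gen_genotypes(model, n, len(meta), snp_meta=meta, blocks=blocks, seed=seed)


# ---------------------------------------------------------------------------
# phenotype generation


def _genetic_values(
    truth, genotypes: GenotypeMatrix, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual genetic value and a complete-genotype mask."""
    n = genotypes.n_samples
    loci = truth_loci(truth)
    xa = {s: code_additive(genotypes.column(s), s) for s in loci}
    xd = {s: code_dominance(genotypes.column(s), s) for s in loci}
    ok = np.ones(n, dtype=bool)
    for s in loci:
        ok &= ~np.isnan(xa[s])

    def coef(t: TruthEffect) -> np.ndarray:
        base = t.kind[:-1] if t.kind.endswith("e") and t.kind != "d" else t.kind
        if isinstance(t.unit, tuple):
            i, j = t.unit
            aa, ad, da, dd = code_epistasis(xa[i], xd[i], xa[j], xd[j])
            c = {"aa": aa, "ad": ad, "da": da, "dd": dd}[base]
        else:
            c = xa[t.unit] if base == "a" else xd[t.unit]
        if t.level is not None:
            c = c * (groups == t.level)
        return c

    g = np.zeros(n)
    for t in truth:
        g[ok] += t.value * coef(t)[ok]
    return g, ok


def simulate_phenotypes(
    scenario: SimulationScenario,
    genotypes: GenotypeMatrix,
    groups: np.ndarray,
    sex: np.ndarray,
    seed: int | None = None,
) -> tuple[PhenotypeTable, int]:
    """Trait records for every individual and replicate.

    y = mu + sex block + group effect + genetic value + eps, with eps drawn
    independently per replicate record.  Individuals missing a genotype at
    any truth locus are dropped (the count of dropped records is returned).
    """
    if scenario.sigma_eps is None:
        raise ValueError("sigma_eps is unset; call calibrate_residual first")
    if scenario.sigma_eps <= 0:
        raise ValueError("sigma_eps must be positive")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    g, ok = _genetic_values(scenario.truth, genotypes, groups)
    base = (
        scenario.mu
        + scenario.sex_effect * np.asarray(sex, float)
        + np.asarray(scenario.group_effects)[np.asarray(groups) - 1]
        + g
    )
    frames = []
    exams = [f"exam{2 * r + 1}" for r in range(scenario.replicates)]
    for exam in exams:
        eps = rng.normal(0.0, scenario.sigma_eps, size=genotypes.n_samples)
        frames.append(
            pd.DataFrame(
                {
                    "iid": genotypes.samples,
                    "sex": np.asarray(sex, int),
                    "ethnicity": np.asarray(groups, int),
                    "exam": exam,
                    "value": base + eps,
                }
            ).loc[ok]
        )
    table = PhenotypeTable(pd.concat(frames, ignore_index=True))
    n_dropped = int((~ok).sum()) * scenario.replicates
    return table, n_dropped


def calibrate_residual(
    scenario: SimulationScenario,
    genotypes: GenotypeMatrix,
    groups: np.ndarray,
    sex: np.ndarray,
    target_total_h2: float | None = None,
    anchor: tuple | None = None,
) -> SimulationScenario:
    """Choose the residual SD so a variance-share target is met.

    Either ``target_total_h2`` (realised genetic share of phenotypic
    variance) or ``anchor = (locus, kind, share)`` fixing one term's share;
    the default anchor makes the largest-additive-effect locus explain its
    observed per-locus heritability.  Returns a scenario copy with
    ``sigma_eps`` set.
    """
    if target_total_h2 is None and anchor is None:
        anchor = ANCHOR_LOCUS
    g, ok = _genetic_values(scenario.truth, genotypes, groups)
    det = (
        scenario.sex_effect * np.asarray(sex, float)
        + np.asarray(scenario.group_effects)[np.asarray(groups) - 1]
        + g
    )[ok]
    v_det = float(np.var(det))
    if target_total_h2 is not None:
        if target_total_h2 <= 0:
            raise ValueError("target heritability must be positive")
        v_gen = float(np.var(g[ok]))
        vp = v_gen / target_total_h2
    else:
        locus, kind, share = anchor
        if share <= 0:
            raise ValueError("anchor share must be positive")
        term = [t for t in scenario.truth if t.unit == locus and t.kind == kind and t.level is None]
        if not term:
            raise ValueError(f"anchor term {kind}:{locus} not in truth set")
        coef = {"a": code_additive, "d": code_dominance}[kind](genotypes.column(locus), locus)
        v_anchor = float(np.var(term[0].value * coef[ok]))
        vp = v_anchor / share
    var_eps = vp - v_det
    if var_eps <= 0:
        raise ValueError("variance target unattainable: deterministic variance exceeds it")
    return replace(scenario, sigma_eps=float(np.sqrt(var_eps)))
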