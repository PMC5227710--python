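"""Effect coding and design-matrix construction for the full genetic model.

The trait model for individual *k* of ethnic group *h* is

    y_hk = mu + s_k
         + sum_i  x_a(i) a_i + x_d(i) d_i
         + sum_ij x_aa aa_ij + x_ad ad_ij + x_da da_ij + x_dd dd_ij
         + e_h + sum_i x_a(i) I_h ae_ih + x_d(i) I_h de_ih
         + (epistasis-by-ethnicity terms)
         + eps_hk

with the locus coefficients

    x_a = +1 (QQ), 0 (Qq), -1 (qq)      Q = major allele
    x_d = +1 (Qq), 0 (QQ and qq)

and the four digenic epistasis coefficients formed as products of the two
loci's a/d codings.  Ethnicity (e) and every locus-by-ethnicity class
(ae, de, aae, ade, dae, dde) enter as random effects; their incidence
columns are the genetic coefficient times the group indicator, so the four
group columns of an interaction block sum back to the main-term column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import (
    MISSING,
    N_GROUPS,
    CodingError,
    GenotypeMatrix,
    PhenotypeTable,
)

MAIN_KINDS = ("a", "d")
EPISTASIS_KINDS = ("aa", "ad", "da", "dd")
INTERACTION_OF = {"a": "ae", "d": "de", "aa": "aae", "ad": "ade", "da": "dae", "dd": "dde"}
RANDOM_CLASSES = ("e", "ae", "de", "aae", "ade", "dae", "dde")


def code_additive(calls: np.ndarray, snp_id: str = "?") -> np.ndarray:
    """Additive coefficient x_a: QQ(2) -> +1, Qq(1) -> 0, qq(0) -> -1.

    Missing calls propagate as NaN.
    """
    calls = np.asarray(calls)
    if not np.isin(calls, (0, 1, 2, MISSING)).all():
        raise CodingError(f"invalid genotype call for SNP {snp_id!r}")
    out = calls.astype(float) - 1.0
    out[calls == MISSING] = np.nan
    return out


def code_dominance(calls: np.ndarray, snp_id: str = "?") -> np.ndarray:
    """Dominance coefficient x_d: Qq(1) -> 1, QQ and qq -> 0; missing -> NaN."""
    calls = np.asarray(calls)
    if not np.isin(calls, (0, 1, 2, MISSING)).all():
        raise CodingError(f"invalid genotype call for SNP {snp_id!r}")
    out = (calls == 1).astype(float)
    out[calls == MISSING] = np.nan
    return out


def code_epistasis(
    x_a_i: np.ndarray, x_d_i: np.ndarray, x_a_j: np.ndarray, x_d_j: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Digenic epistasis coefficients (aa, ad, da, dd) as coding products.

    aa = x_a_i * x_a_j, ad = x_a_i * x_d_j, da = x_d_i * x_a_j,
    dd = x_d_i * x_d_j.  A missing genotype at either locus (NaN in any
    input coding) makes all four coefficients NaN.
    """
    x_a_i, x_d_i = np.asarray(x_a_i, float), np.asarray(x_d_i, float)
    x_a_j, x_d_j = np.asarray(x_a_j, float), np.asarray(x_d_j, float)
    bad = np.isnan(x_a_i) | np.isnan(x_d_i) | np.isnan(x_a_j) | np.isnan(x_d_j)
    aa = x_a_i * x_a_j
    ad = x_a_i * x_d_j
    da = x_d_i * x_a_j
    dd = x_d_i * x_d_j
    for arr in (aa, ad, da, dd):
        arr[bad] = np.nan
    return aa, ad, da, dd


# ---------------------------------------------------------------------------
# model specification


@dataclass
class ModelSpec:
    """Terms included in a fit.

    ``loci`` maps SNP id -> subset of {"a", "d"}; ``epistasis_pairs`` maps an
    ordered (snp_i, snp_j) pair -> subset of {"aa", "ad", "da", "dd"}.
    ``random_classes`` selects the random-effect classes; interaction blocks
    are built per locus (or pair).  By default a class covers every locus
    whose coding it needs (ae needs x_a, de needs x_d, regardless of whether
    the fixed main term is included); ``interaction_terms`` can restrict a
    class to an explicit list of loci/pairs, which is how an optimum model
    keeps e.g. a de block for a locus without a fixed d term.
    """

    loci: dict[str, frozenset] = field(default_factory=dict)
    epistasis_pairs: dict[tuple, frozenset] = field(default_factory=dict)
    random_classes: frozenset = frozenset({"e"})
    interaction_terms: dict[str, tuple] | None = None
    include_sex_block: bool = True
    reduced_additive: bool = False

    def __post_init__(self) -> None:
        self.loci = {s: frozenset(t) for s, t in self.loci.items()}
        self.epistasis_pairs = {tuple(p): frozenset(t) for p, t in self.epistasis_pairs.items()}
        self.random_classes = frozenset(self.random_classes)
        for s, terms in self.loci.items():
            if not terms <= set(MAIN_KINDS):
                raise ValueError(f"invalid main terms {set(terms)} for locus {s}")
        for pair, terms in self.epistasis_pairs.items():
            if pair[0] == pair[1]:
                raise ValueError(f"epistasis pair members must differ: {pair}")
            if not terms <= set(EPISTASIS_KINDS):
                raise ValueError(f"invalid epistasis terms {set(terms)} for {pair}")
        if not self.random_classes <= set(RANDOM_CLASSES):
            raise ValueError(f"unknown random classes {set(self.random_classes) - set(RANDOM_CLASSES)}")
        if self.reduced_additive:
            if any("d" in t for t in self.loci.values()) or self.epistasis_pairs:
                raise ValueError("reduced additive model admits only 'a' main terms")
            if not self.random_classes <= {"e", "ae"}:
                raise ValueError("reduced additive model admits only {e, ae} random classes")

    def interaction_units(self, cls: str) -> tuple:
        """Loci (or pairs) carrying an interaction block of class ``cls``."""
        if self.interaction_terms is not None and cls in self.interaction_terms:
            return tuple(self.interaction_terms[cls])
        if cls == "e":
            return ()
        base = cls[:-1]  # strip trailing 'e'
        if base in MAIN_KINDS:
            return tuple(s for s, t in self.loci.items() if base in t)
        return tuple(p for p, t in self.epistasis_pairs.items() if base in t)

    def to_dict(self) -> dict:
        """Plain-dict form for structured-text (YAML) round-tripping."""
        out = {
            "loci": {s: sorted(t) for s, t in self.loci.items()},
            "epistasis_pairs": [[p[0], p[1], sorted(t)] for p, t in self.epistasis_pairs.items()],
            "random_classes": sorted(self.random_classes),
            "include_sex_block": self.include_sex_block,
            "reduced_additive": self.reduced_additive,
        }
        if self.interaction_terms is not None:
            out["interaction_terms"] = {
                c: [list(u) if isinstance(u, tuple) else u for u in units]
                for c, units in self.interaction_terms.items()
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        inter = None
        if d.get("interaction_terms") is not None:
            inter = {
                c: tuple(tuple(u) if isinstance(u, list) else u for u in units)
                for c, units in d["interaction_terms"].items()
            }
        return cls(
            loci={s: frozenset(t) for s, t in d.get("loci", {}).items()},
            epistasis_pairs={(a, b): frozenset(t) for a, b, t in d.get("epistasis_pairs", [])},
            random_classes=frozenset(d.get("random_classes", ["e"])),
            interaction_terms=inter,
            include_sex_block=d.get("include_sex_block", True),
            reduced_additive=d.get("reduced_additive", False),
        )

    def reduce_to_additive(self) -> "ModelSpec":
        """The additive restriction: keep only 'a' mains and {e, ae}."""
        loci = {s: frozenset({"a"}) for s, t in self.loci.items() if "a" in t}
        inter = None
        if self.interaction_terms is not None:
            inter = {"ae": tuple(s for s in self.interaction_terms.get("ae", ()) if s in loci)}
        return ModelSpec(
            loci=loci,
            epistasis_pairs={},
            random_classes=self.random_classes & {"e", "ae"},
            interaction_terms=inter,
            include_sex_block=self.include_sex_block,
            reduced_additive=True,
        )


def _pair_label(pair: tuple) -> str:
    return f"{pair[0]}x{pair[1]}"


@dataclass
class RandomBlock:
    """One random-effect class: records x levels incidence matrix."""

    cls: str
    matrix: np.ndarray
    labels: list[str]
    #: term-group label per column (e.g. "ae:rs1"); the class F-test and the
    #: Gibbs variance component pool columns by ``cls``.
    groups: list[str]


@dataclass
class DesignMatrices:
    """Fixed coefficient matrix and random incidence blocks, one row per
    phenotype record, plus the genotype/phenotype factorisation used by the
    individual-level permutation test.

    Every column c of the stacked matrix ``W = [fixed | random blocks]``
    factorises as ``geno_ind[ind_index[r], c] * pheno_part[r, c]``: the
    genotype-derived coefficient is constant within individual, while the
    phenotype-side factor (sex, group indicator) travels with the record.
    Permuting individuals' genotypes against their phenotype records is then
    a row gather of ``geno_ind``.
    """

    fixed: np.ndarray
    fixed_labels: list[str]
    random_blocks: list[RandomBlock]
    column_map: dict
    record_iids: np.ndarray
    record_exams: np.ndarray
    ind_index: np.ndarray
    individuals: np.ndarray
    geno_ind: np.ndarray
    pheno_part: np.ndarray
    n_dropped_records: int
    y: np.ndarray
    spec: ModelSpec

    @property
    def n_records(self) -> int:
        return self.fixed.shape[0]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def stacked(self) -> tuple[np.ndarray, list[str], dict]:
        """Full matrix ``W``, column labels, and term-group -> column indices."""
        mats = [self.fixed] + [b.matrix for b in self.random_blocks]
        labels = list(self.fixed_labels)
        groups: dict[str, list[int]] = {}
        for j, lab in enumerate(self.fixed_labels):
            groups.setdefault(self.column_map[lab]["group"], []).append(j)
        off = len(labels)
        for b in self.random_blocks:
            for j, (lab, grp) in enumerate(zip(b.labels, b.groups)):
                labels.append(lab)
                groups.setdefault(grp, []).append(off + j)
            off += len(b.labels)
        W = np.hstack(mats) if mats else np.empty((self.n_records, 0))
        return W, labels, {g: np.array(ix) for g, ix in groups.items()}

    def permuted_stacked(self, perm: np.ndarray) -> np.ndarray:
        """W with individuals' genotypes relabelled by permutation ``perm``."""
        return self.geno_ind[perm[self.ind_index], :] * self.pheno_part

    def marginality_excludes(self, group: str) -> list[str]:
        """Term groups to leave out of the conditioning model when testing
        ``group``.

        With indicator-coded interactions, the four group columns of an
        ethnicity-interaction block sum to the main-term column, so a fixed
        main term is aliased with its own interaction block.  The main-term
        F-test therefore conditions on everything except that block.  A
        single ethnic level of an interaction block, when its main term is
        in the model, is a *deviation* from that main effect: it is tested
        keeping the main column but dropping the block's sibling level
        columns (otherwise the five columns are mutually saturated and the
        level is untestable); without a main term the level is the whole
        group-specific effect and is tested against the full model.  Whole
        interaction-class tests condition on the full model (the main
        column being spanned inside the block reduces the block's test df
        by one).
        """
        if ":" not in group:
            return []
        kind, unit = group.split(":", 1)
        present = {b_grp for b in self.random_blocks for b_grp in b.groups}
        present.update(self.column_map[lab]["group"] for lab in self.fixed_labels)
        if kind in INTERACTION_OF:
            inter = INTERACTION_OF[kind] + ":" + unit
            if inter in present:
                return [inter]
        if "_" in kind:  # per-level interaction term, e.g. "ae_3"
            cls = kind.split("_", 1)[0]
            main_of = {v: k for k, v in INTERACTION_OF.items()}
            main = main_of.get(cls, "") + ":" + unit
            if main in present:
                siblings = []
                for b in self.random_blocks:
                    for lab, grp in zip(b.labels, b.groups):
                        if grp == f"{cls}:{unit}" and lab != group:
                            siblings.append(lab)
                return siblings
        return []


def build_design(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    spec: ModelSpec,
) -> DesignMatrices:
    """Assemble fixed and random design matrices for a model specification.

    One row per phenotype record (replicates stacked).  Records of
    individuals with a missing genotype at any required locus are dropped
    listwise and counted in ``n_dropped_records``.
    """
    needed = set(spec.loci)
    for pair in spec.epistasis_pairs:
        needed.update(pair)
    for cls in spec.random_classes:
        for unit in spec.interaction_units(cls):
            if isinstance(unit, tuple):
                needed.update(unit)
            else:
                needed.add(unit)
    for s in needed:
        genotypes.snp_position(s)  # raises on unknown id

    rec = phenotypes.records
    inds = phenotypes.individuals
    ind_pos = {iid: k for k, iid in enumerate(inds)}
    try:
        geno_rows = np.array([genotypes.sample_position(i) for i in inds])
    except KeyError as exc:
        raise ValueError(f"phenotype individual not genotyped: {exc}") from exc

    # per-individual codings for every needed locus
    xa: dict[str, np.ndarray] = {}
    xd: dict[str, np.ndarray] = {}
    for s in sorted(needed):
        calls = genotypes.column(s)[geno_rows]
        xa[s] = code_additive(calls, s)
        xd[s] = code_dominance(calls, s)

    ok_ind = np.ones(len(inds), dtype=bool)
    for s in needed:
        ok_ind &= ~np.isnan(xa[s])
    rec_ind = rec["iid"].map(ind_pos).to_numpy()
    keep_rec = ok_ind[rec_ind]
    n_dropped = int((~keep_rec).sum())
    rec = rec.loc[keep_rec].reset_index(drop=True)
    if len(rec) == 0:
        raise ValueError("no phenotype records left after missing-genotype drops")

    kept_inds = inds[ok_ind]
    kept_pos = {iid: k for k, iid in enumerate(kept_inds)}
    old_new = np.flatnonzero(ok_ind)
    xa = {s: v[old_new] for s, v in xa.items()}
    xd = {s: v[old_new] for s, v in xd.items()}

    ind_index = rec["iid"].map(kept_pos).to_numpy()
    sex = rec["sex"].to_numpy(dtype=float)
    eth = rec["ethnicity"].to_numpy(dtype=int)
    n_rec, n_ind = len(rec), len(kept_inds)
    eth_ind = np.zeros((n_rec, N_GROUPS))
    eth_ind[np.arange(n_rec), eth - 1] = 1.0

    def pair_coef(pair: tuple, kind: str) -> np.ndarray:
        i, j = pair
        aa, ad, da, dd = code_epistasis(xa[i], xd[i], xa[j], xd[j])
        return {"aa": aa, "ad": ad, "da": da, "dd": dd}[kind]

    def unit_coef(unit, base: str) -> np.ndarray:
        if isinstance(unit, tuple):
            return pair_coef(unit, base)
        return {"a": xa, "d": xd}[base][unit]

    # --- fixed columns: geno side per individual, pheno side per record
    fixed_geno: list[np.ndarray] = [np.ones(n_ind)]
    fixed_pheno: list[np.ndarray] = [np.ones(n_rec)]
    fixed_labels = ["mu"]
    column_map = {"mu": {"group": "mu", "kind": "mu", "unit": None, "level": None}}
    if spec.include_sex_block:
        fixed_geno.append(np.ones(n_ind))
        fixed_pheno.append(sex)
        fixed_labels.append("sex")
        column_map["sex"] = {"group": "sex", "kind": "sex", "unit": None, "level": None}
    for s in spec.loci:
        for kind in MAIN_KINDS:
            if kind in spec.loci[s]:
                lab = f"{kind}:{s}"
                fixed_geno.append({"a": xa, "d": xd}[kind][s])
                fixed_pheno.append(np.ones(n_rec))
                fixed_labels.append(lab)
                column_map[lab] = {"group": lab, "kind": kind, "unit": s, "level": None}
    for pair in spec.epistasis_pairs:
        for kind in EPISTASIS_KINDS:
            if kind in spec.epistasis_pairs[pair]:
                lab = f"{kind}:{_pair_label(pair)}"
                fixed_geno.append(pair_coef(pair, kind))
                fixed_pheno.append(np.ones(n_rec))
                fixed_labels.append(lab)
                column_map[lab] = {"group": lab, "kind": kind, "unit": pair, "level": None}

    # --- random blocks
    blocks: list[RandomBlock] = []
    blk_geno: list[np.ndarray] = []
    blk_pheno: list[np.ndarray] = []
    if "e" in spec.random_classes:
        labels, grp, cols_g, cols_p = [], [], [], []
        for h in range(1, N_GROUPS + 1):
            lab = f"e_{h}"
            labels.append(lab)
            grp.append("e")
            cols_g.append(np.ones(n_ind))
            cols_p.append(eth_ind[:, h - 1])
            column_map[lab] = {"group": "e", "kind": "e", "unit": None, "level": h}
        mat = np.column_stack([g[ind_index] * p for g, p in zip(cols_g, cols_p)])
        blocks.append(RandomBlock("e", mat, labels, grp))
        blk_geno += cols_g
        blk_pheno += cols_p
    for cls in RANDOM_CLASSES[1:]:
        if cls not in spec.random_classes:
            continue
        base = cls[:-1]
        units = spec.interaction_units(cls)
        if not units:
            continue
        labels, grp, cols_g, cols_p = [], [], [], []
        for unit in units:
            coef = unit_coef(unit, base)
            uname = _pair_label(unit) if isinstance(unit, tuple) else unit
            for h in range(1, N_GROUPS + 1):
                lab = f"{cls}_{h}:{uname}"
                labels.append(lab)
                grp.append(f"{cls}:{uname}")
                cols_g.append(coef)
                cols_p.append(eth_ind[:, h - 1])
                column_map[lab] = {"group": f"{cls}:{uname}", "kind": cls, "unit": unit, "level": h}
        mat = np.column_stack([g[ind_index] * p for g, p in zip(cols_g, cols_p)])
        blocks.append(RandomBlock(cls, mat, labels, grp))
        blk_geno += cols_g
        blk_pheno += cols_p

    geno_ind = np.column_stack(fixed_geno + blk_geno)
    pheno_part = np.column_stack(fixed_pheno + blk_pheno)
    fixed = geno_ind[ind_index, : len(fixed_labels)] * pheno_part[:, : len(fixed_labels)]

    return DesignMatrices(
        fixed=fixed,
        fixed_labels=fixed_labels,
        random_blocks=blocks,
        column_map=column_map,
        record_iids=rec["iid"].to_numpy(),
        record_exams=rec["exam"].to_numpy(),
        ind_index=ind_index,
        individuals=kept_inds,
        geno_ind=geno_ind,
        pheno_part=pheno_part,
        n_dropped_records=n_dropped,
        y=rec["value"].to_numpy(dtype=float),
        spec=spec,
    )
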