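"""Two-stage association analysis.

Stage one is an exhaustive F-test screen (per-SNP joint additive+dominance
test, then pairwise epistasis among the strongest SNPs) that replaces the
cited dimensionality-reduction pre-filter; stage two builds an optimum
model by forward selection with backward elimination under the
permutation experiment-wise threshold, then fits the full (or reduced
additive) mixed model: Henderson-III F statistics with experiment-wise P
values, Gibbs effect estimation, and the heritability partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coding import (
    EPISTASIS_KINDS,
    DesignMatrices,
    ModelSpec,
    build_design,
    code_additive,
    code_dominance,
    code_epistasis,
)
from .engine import (
    EffectEstimates,
    GroupFTester,
    PermutationNull,
    TermTest,
    VarianceComponents,
    experimentwise_p,
    genetic_test_labels,
    gibbs_estimate,
    henderson3_components,
    null_from_samples,
)
from .genotypes import N_GROUPS, GenotypeMatrix, PhenotypeTable


# ---------------------------------------------------------------------------
# candidate screening


@dataclass
class ScreenResult:
    snp_neglog10p: dict
    pair_neglog10p: dict
    snps: list
    pairs: list
    p1d: float
    p2d: float


def _stacked_covariates(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable):
    rec = phenotypes.records
    rows = np.array([genotypes.sample_position(i) for i in rec["iid"]])
    y = rec["value"].to_numpy(dtype=float)
    n = len(y)
    eth = rec["ethnicity"].to_numpy(dtype=int)
    G = np.zeros((n, N_GROUPS - 1))
    for h in range(2, N_GROUPS + 1):
        G[:, h - 2] = eth == h
    C = np.column_stack([np.ones(n), rec["sex"].to_numpy(dtype=float), G])
    q, _ = np.linalg.qr(C)
    return rows, y, C, q


def _codings(genotypes: GenotypeMatrix, rows: np.ndarray):
    """Record-level a/d codings for every SNP, missing filled with the
    column mean (screening only)."""
    calls = genotypes.calls[rows].astype(float)
    xa = calls - 1.0
    xd = (calls == 1).astype(float)
    miss = calls < 0
    for X in (xa, xd):
        X[miss] = np.nan
        mean = np.nanmean(X, axis=0)
        idx = np.where(miss)
        X[idx] = np.where(np.isnan(mean[idx[1]]), 0.0, mean[idx[1]])
    return xa, xd


def screen_candidates(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    p1d: float = 1e-3,
    p2d: float = 1e-5,
    max_candidates: int = 50,
    top_m: int = 20,
) -> ScreenResult:
    """Candidate loci and pairs by exhaustive F-test scans.

    1D: per SNP, the joint F-test of its additive and dominance codings
    given sex and ethnic-group means.  2D: among the ``top_m`` strongest 1D
    SNPs, the joint F-test of the four epistasis columns given both loci's
    main codings.  Candidates passing the P thresholds are returned, capped
    at ``max_candidates`` by score.
    """
    if max_candidates < 1:
        raise ValueError("max_candidates must be at least 1")
    rows, y, C, q = _stacked_covariates(genotypes, phenotypes)
    n, c = len(y), C.shape[1]
    ry = y - q @ (q.T @ y)
    syy = float(ry @ ry)
    xa, xd = _codings(genotypes, rows)
    ra = xa - q @ (q.T @ xa)
    rd = xd - q @ (q.T @ xd)

    snp_p: dict[str, float] = {}
    Fs = np.zeros(genotypes.n_snps)
    dfs = np.zeros(genotypes.n_snps, dtype=int)
    for j in range(genotypes.n_snps):
        Z = np.column_stack([ra[:, j], rd[:, j]])
        ZtZ = Z.T @ Z
        keep = np.diag(ZtZ) > 1e-10 * n
        Z = Z[:, keep]
        df = int(keep.sum())
        if df == 0:
            snp_p[genotypes.snps["id"][j]] = 1.0
            continue
        coef = np.linalg.lstsq(Z, ry, rcond=None)[0]
        ss = float(ry @ (Z @ coef))
        dof = n - c - df
        F = (ss / df) / max(syy - ss, 1e-300) * dof
        p = float(stats.f.sf(F, df, dof))
        snp_p[genotypes.snps["id"][j]] = p
        Fs[j], dfs[j] = F, df

    ids = genotypes.snps["id"].to_numpy()
    order = np.argsort([snp_p[s] for s in ids])
    top = [ids[j] for j in order[: min(top_m, len(ids))]]
    pair_p: dict[tuple, float] = {}
    for ii in range(len(top)):
        for jj in range(ii + 1, len(top)):
            si, sj = top[ii], top[jj]
            a_i, d_i = xa[:, genotypes.snp_position(si)], xd[:, genotypes.snp_position(si)]
            a_j, d_j = xa[:, genotypes.snp_position(sj)], xd[:, genotypes.snp_position(sj)]
            epi = np.column_stack(code_epistasis(a_i, d_i, a_j, d_j))
            mains = np.column_stack([a_i, d_i, a_j, d_j])
            rm = mains - q @ (q.T @ mains)
            qm, _ = np.linalg.qr(np.column_stack([q, rm]))
            re = epi - qm @ (qm.T @ epi)
            ry2 = y - qm @ (qm.T @ y)
            keep = (re**2).sum(axis=0) > 1e-10 * n
            Z = re[:, keep]
            df = int(keep.sum())
            if df == 0:
                continue
            coef = np.linalg.lstsq(Z, ry2, rcond=None)[0]
            ss = float(ry2 @ (Z @ coef))
            syy2 = float(ry2 @ ry2)
            dof = n - c - 4 - df
            F = (ss / df) / max(syy2 - ss, 1e-300) * dof
            pair_p[(si, sj)] = float(stats.f.sf(F, df, dof))

    hits = [(s, p) for s, p in snp_p.items() if p <= p1d]
    pair_hits = [(pr, p) for pr, p in pair_p.items() if p <= p2d]
    pooled = sorted(hits + pair_hits, key=lambda t: t[1])[:max_candidates]
    sel_snps = [u for u, _ in pooled if not isinstance(u, tuple)]
    sel_pairs = [u for u, _ in pooled if isinstance(u, tuple)]
    nl10 = lambda p: -math.log10(max(p, 1e-300))
    return ScreenResult(
        snp_neglog10p={s: nl10(p) for s, p in snp_p.items()},
        pair_neglog10p={pr: nl10(p) for pr, p in pair_p.items()},
        snps=sel_snps,
        pairs=sel_pairs,
        p1d=p1d,
        p2d=p2d,
    )


# ---------------------------------------------------------------------------
# stepwise model construction


def _unit_terms(unit, full_terms: bool) -> list[str]:
    if isinstance(unit, tuple):
        return [f"{k}:{unit[0]}x{unit[1]}" for k in EPISTASIS_KINDS]
    return [f"a:{unit}", f"d:{unit}"] if full_terms else [f"a:{unit}"]


def stepwise_build(
    candidates: ScreenResult,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    alpha_ew: float = 0.05,
    n_perm: int = 2000,
    seed: int = 0,
    full_terms: bool = True,
    max_rounds: int | None = None,
) -> ModelSpec:
    """Forward selection with backward elimination under the permutation
    experiment-wise threshold.

    Each round tests every not-yet-included candidate unit (locus = joint
    a+d columns, pair = joint epistasis columns) conditional on the current
    model; the unit with the largest F enters if it exceeds the
    experiment-wise critical F of the round's permutation null (max F over
    all remaining candidates).  Included units whose conditional F falls
    below the critical value are removed.  Ties on F are broken by genome
    order.  Deterministic given the seed.
    """
    units: list = list(candidates.snps) + [tuple(p) for p in candidates.pairs]
    if not units:
        return ModelSpec(random_classes=frozenset({"e"}))
    if alpha_ew <= 0:
        return ModelSpec(random_classes=frozenset({"e"}))

    def genome_key(unit):
        s = unit[0] if isinstance(unit, tuple) else unit
        j = genotypes.snp_position(s)
        ch = genotypes.snps["chrom"][j]
        ch_num = int(ch) if str(ch).isdigit() else 10_000
        return (ch_num, genotypes.snps["pos"][j])

    current: list = []
    banned: set = set()
    max_rounds = max_rounds or 2 * len(units)
    for rnd in range(max_rounds):
        remaining = [u for u in units if u not in current and u not in banned]
        if not remaining:
            break
        spec_all = _units_spec(current + remaining, full_terms)
        design = build_design(genotypes, phenotypes, spec_all)
        base_cond = ["mu", "e"] + (["sex"] if spec_all.include_sex_block else [])
        cond_groups = base_cond + [t for u in current for t in _unit_terms(u, full_terms)]
        tests = [(str(u), _unit_terms(u, full_terms)) for u in remaining]
        tester = GroupFTester(
            design, tests=tests, conditioning={str(u): cond_groups for u in remaining},
            on_aliased="skip",
        )
        obs = tester.observed()
        if not obs:  # every remaining candidate is aliased with the model
            break
        null = tester.null_max_F(n_perm, seed + rnd)
        critical = float(np.quantile(null, 1.0 - alpha_ew))
        scored = sorted(
            ((obs[str(u)].F, u) for u in remaining if str(u) in obs),
            key=lambda t: (-t[0],) + genome_key(t[1]),
        )
        best_F, best = scored[0]
        if best_F <= critical:
            break
        current.append(best)
        # backward pass: drop included units no longer significant
        changed = True
        while changed and len(current) > 1:
            changed = False
            spec_cur = _units_spec(current, full_terms)
            design_cur = build_design(genotypes, phenotypes, spec_cur)
            tests_cur = [(str(u), _unit_terms(u, full_terms)) for u in current]
            cond = {
                str(u): base_cond
                + [t for v in current if v != u for t in _unit_terms(v, full_terms)]
                for u in current
            }
            obs_cur = GroupFTester(design_cur, tests=tests_cur, conditioning=cond,
                                   on_aliased="skip").observed()
            f_of = lambda u: obs_cur[str(u)].F if str(u) in obs_cur else -np.inf
            weakest = min(current, key=f_of)
            if f_of(weakest) < critical:
                current.remove(weakest)
                banned.add(weakest)
                changed = True
    return _units_spec(current, full_terms)


def _units_spec(units: list, full_terms: bool) -> ModelSpec:
    loci: dict[str, frozenset] = {}
    pairs: dict[tuple, frozenset] = {}
    for u in units:
        if isinstance(u, tuple):
            pairs[u] = frozenset(EPISTASIS_KINDS)
        else:
            loci[u] = frozenset({"a", "d"} if full_terms else {"a"})
    classes = {"e"}
    if loci:
        classes.add("ae")
        if full_terms:
            classes.add("de")
    return ModelSpec(
        loci=loci,
        epistasis_pairs=pairs,
        random_classes=frozenset(classes),
        reduced_additive=not full_terms and not pairs,
    )


# ---------------------------------------------------------------------------
# outlier handling


def remove_outliers(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    spec: ModelSpec,
    z_threshold: float = 3.0,
) -> tuple[PhenotypeTable, int]:
    """Drop records whose standardised residual from the all-terms
    least-squares fit exceeds ``z_threshold`` in magnitude; the model is
    refit once on the cleaned records by the caller."""
    design = build_design(genotypes, phenotypes, spec)
    tester = GroupFTester(design, tests=[])
    B = tester.W[:, tester.basis]
    coef = np.linalg.lstsq(B, design.y, rcond=None)[0]
    resid = design.y - B @ coef
    dof = max(len(design.y) - tester.rank, 1)
    sigma = math.sqrt(float(resid @ resid) / dof)
    z = resid / sigma if sigma > 0 else np.zeros_like(resid)
    flagged = {
        (design.record_iids[i], design.record_exams[i])
        for i in np.flatnonzero(np.abs(z) > z_threshold)
    }
    rec = phenotypes.records
    mask = np.array([(i, e) in flagged for i, e in zip(rec["iid"], rec["exam"])])
    return phenotypes.drop_records(mask), int(mask.sum())


# ---------------------------------------------------------------------------
# heritability partition


@dataclass
class HeritabilityPartition:
    """Per-class shares of phenotypic variance, in percent.

    The total is the sum of the class components; for the reduced additive
    model only ``h2_a`` and ``h2_ae`` are populated.
    """

    h2_a: float = 0.0
    h2_d: float = 0.0
    h2_epistasis: float = 0.0
    h2_ae: float = 0.0
    h2_de: float = 0.0
    h2_epistasis_e: float = 0.0

    @property
    def h2_total(self) -> float:
        return (
            self.h2_a
            + self.h2_d
            + self.h2_epistasis
            + self.h2_ae
            + self.h2_de
            + self.h2_epistasis_e
        )

    @classmethod
    def from_components(cls, **kw) -> "HeritabilityPartition":
        return cls(**kw)


_CLASS_OF_KIND = {
    "a": "h2_a",
    "d": "h2_d",
    "aa": "h2_epistasis",
    "ad": "h2_epistasis",
    "da": "h2_epistasis",
    "dd": "h2_epistasis",
    "ae": "h2_ae",
    "de": "h2_de",
    "aae": "h2_epistasis_e",
    "ade": "h2_epistasis_e",
    "dae": "h2_epistasis_e",
    "dde": "h2_epistasis_e",
}


def heritability_partition(
    estimates: EffectEstimates,
    design: DesignMatrices,
    y: np.ndarray | None = None,
) -> tuple[HeritabilityPartition, dict]:
    """Realised-variance heritability partition.

    Each fixed genetic term contributes the sample variance across records
    of (coefficient column x estimate); an ethnicity-interaction unit
    contributes the variance of its four level columns' combined fitted
    effect.  Class heritabilities are the class sums divided by the
    phenotypic variance, in percent.  Also returns the per-term shares
    keyed by term-group label.
    """
    y = design.y if y is None else np.asarray(y, float)
    vp = float(np.var(y))
    if vp == 0:
        raise ValueError("phenotypic variance is zero")
    W, labels, groups = design.stacked()
    col_of = {lab: j for j, lab in enumerate(labels)}

    per_term: dict[str, float] = {}
    part = HeritabilityPartition()
    for lab in design.fixed_labels:
        info = design.column_map[lab]
        if info["kind"] in ("mu", "sex"):
            continue
        est = estimates.fixed.get(lab, (0.0,))[0]
        if not np.isfinite(est):
            est = 0.0
        contrib = float(np.var(W[:, col_of[lab]] * est))
        share = 100.0 * contrib / vp
        per_term[info["group"]] = share
        attr = _CLASS_OF_KIND[info["kind"]]
        setattr(part, attr, getattr(part, attr) + share)
    for b in design.random_blocks:
        if b.cls == "e":
            continue
        by_group: dict[str, np.ndarray] = {}
        for lab, grp in zip(b.labels, b.groups):
            est = estimates.random.get(lab, (0.0,))[0]
            v = by_group.setdefault(grp, np.zeros(design.n_records))
            v += W[:, col_of[lab]] * est
        for grp, fitted in by_group.items():
            share = 100.0 * float(np.var(fitted)) / vp
            per_term[grp] = share
            attr = _CLASS_OF_KIND[b.cls]
            setattr(part, attr, getattr(part, attr) + share)
    return part, per_term


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class EngineSettings:
    n_perm: int = 2000
    alpha_ew: float = 0.05
    gibbs_iterations: int = 20000
    gibbs_burn_in: int = 2000
    gibbs_thinning: int = 1
    seed: int = 0


@dataclass
class QTSRecord:
    unit: object
    kind: str
    level: int | None
    estimate: float
    se: float
    F: float
    delta_df: int
    p_ew: float
    p_ew_extrapolated: bool
    h2_pct: float | None

    @property
    def neglog10_p_ew(self) -> float:
        return -math.log10(self.p_ew)


@dataclass
class FitResult:
    records: list
    partition: HeritabilityPartition
    varcomp_h3: VarianceComponents
    varcomp_gibbs: VarianceComponents
    null: PermutationNull
    estimates: EffectEstimates
    tests: dict
    design: DesignMatrices

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            unit = f"{r.unit[0]}x{r.unit[1]}" if isinstance(r.unit, tuple) else r.unit
            kind = r.kind if r.level is None else f"{r.kind}_{r.level}"
            rows.append(
                {
                    "locus": unit,
                    "effect": kind,
                    "estimate": r.estimate,
                    "se": r.se,
                    "F": r.F,
                    "neglog10_p_ew": r.neglog10_p_ew,
                    "p_ew_extrapolated": r.p_ew_extrapolated,
                    "h2_pct": r.h2_pct,
                }
            )
        return pd.DataFrame(rows)

    def significant_records(self, alpha_ew: float = 0.05) -> list:
        return [r for r in self.records if r.p_ew <= alpha_ew]


def fit_full_model(
    spec: ModelSpec,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    settings: EngineSettings | None = None,
) -> FitResult:
    """Fit the mixed model for a chosen specification: Henderson-III
    variance components, per-term F with permutation experiment-wise P, and
    Gibbs effect estimates with the heritability partition."""
    settings = settings or EngineSettings()
    design = build_design(genotypes, phenotypes, spec)
    tester = GroupFTester(design, on_aliased="skip")
    obs = tester.observed()
    samples = tester.null_max_F(settings.n_perm, settings.seed)
    null = null_from_samples(samples, settings.alpha_ew, settings.seed)
    for t in obs.values():
        t.p_ew, t.p_ew_extrapolated = experimentwise_p(t.F, null)
    vc_h3 = henderson3_components(design)
    est, vc_gibbs = gibbs_estimate(
        design,
        iterations=settings.gibbs_iterations,
        burn_in=settings.gibbs_burn_in,
        thinning=settings.gibbs_thinning,
        seed=settings.seed,
    )
    part, per_term = heritability_partition(est, design)

    records: list[QTSRecord] = []
    for lab in design.fixed_labels:
        info = design.column_map[lab]
        if info["kind"] in ("mu", "sex"):
            continue
        t = obs.get(info["group"])
        if t is None:  # aliased under this design; no testable df
            continue
        e, s = est.fixed[lab]
        records.append(
            QTSRecord(
                unit=info["unit"],
                kind=info["kind"],
                level=None,
                estimate=e,
                se=s,
                F=t.F,
                delta_df=t.delta_df,
                p_ew=t.p_ew,
                p_ew_extrapolated=t.p_ew_extrapolated,
                h2_pct=per_term.get(info["group"]),
            )
        )
    for b in design.random_blocks:
        if b.cls == "e":
            continue
        for lab in b.labels:
            info = design.column_map[lab]
            t = obs.get(lab)
            if t is None:
                continue
            e, s = est.random[lab]
            records.append(
                QTSRecord(
                    unit=info["unit"],
                    kind=b.cls,
                    level=info["level"],
                    estimate=e,
                    se=s,
                    F=t.F,
                    delta_df=t.delta_df,
                    p_ew=t.p_ew,
                    p_ew_extrapolated=t.p_ew_extrapolated,
                    h2_pct=per_term.get(info["group"]),
                )
            )
    return FitResult(
        records=records,
        partition=part,
        varcomp_h3=vc_h3,
        varcomp_gibbs=vc_gibbs,
        null=null,
        estimates=est,
        tests=obs,
        design=design,
    )


def fit_additive_model(
    spec: ModelSpec,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    settings: EngineSettings | None = None,
) -> FitResult:
    """The reduced multi-locus additive model: same machinery restricted to
    additive mains with ethnicity and additive-by-ethnicity random
    classes."""
    if not spec.reduced_additive:
        spec = spec.reduce_to_additive()
    return fit_full_model(spec, genotypes, phenotypes, settings)
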