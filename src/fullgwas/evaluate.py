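"""Simulation benchmarking: repeated analyses scored for per-locus and
per-effect detection power, false discovery rate (raw and with
LD-representative matching), and estimation bias from empirical
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coding import build_design
from .engine import GroupFTester, gibbs_estimate
from .genotypes import GenotypeMatrix
from .pipeline import screen_candidates, stepwise_build
from .simulate import (
    ANCHOR_LOCUS,
    PopulationModel,
    SimulationScenario,
    assign_groups,
    calibrate_residual,
    scenario_i,
    scenario_panel,
    simulate_phenotypes,
    truth_loci,
    truth_model_spec,
)
from .single_locus import bonferroni_threshold, pca_covariates, single_locus_scan


@dataclass
class ReplicateSettings:
    n_perm: int = 500
    alpha_ew: float = 0.05
    estimator: str = "ols"  # "ols" or "gibbs"
    gibbs_iterations: int = 2000
    gibbs_burn_in: int = 500
    mode: str = "fit_truth"  # or "pipeline"
    screen_p1d: float = 1e-3
    screen_p2d: float = 1e-5
    max_candidates: int = 30
    single_alpha: float = 0.05
    n_pcs: int = 4


@dataclass
class RawResults:
    """Per-simulation detections and estimates for each method."""

    methods: tuple
    sims: list  # list of dict: method -> {"loci": set, "terms": {label: (F, sig, est)}}
    n_sims: int
    base_seed: int
    scenario: SimulationScenario
    genotypes: GenotypeMatrix


def _truth_term_label(t) -> str:
    unit = f"{t.unit[0]}x{t.unit[1]}" if isinstance(t.unit, tuple) else t.unit
    if t.level is None:
        return f"{t.kind}:{unit}"
    return f"{t.kind}_{t.level}:{unit}"


def _loci_of_label(label: str) -> list:
    unit = label.split(":", 1)[1]
    return unit.split("x") if "x" in unit else [unit]


def _fit_truth_method(design, n_perm, alpha_ew, seed, estimator, gibbs_kw):
    tester = GroupFTester(design, on_aliased="skip")
    obs = tester.observed()
    null = tester.null_max_F(n_perm, seed)
    critical = float(np.quantile(null, 1.0 - alpha_ew))
    if estimator == "gibbs":
        est, _ = gibbs_estimate(design, seed=seed, **gibbs_kw)
        coefs = {**{k: v[0] for k, v in est.fixed.items()}, **{k: v[0] for k, v in est.random.items()}}
    else:
        coefs = tester.ols_estimates()
    terms = {}
    loci = set()
    for lab, t in obs.items():
        sig = bool(t.F > critical)
        terms[lab] = (t.F, sig, coefs.get(lab, float("nan")))
        if sig:
            loci.update(_loci_of_label(lab))
    return {"loci": loci, "terms": terms, "critical_F": critical}


def run_replicates(
    scenario: SimulationScenario,
    model: PopulationModel,
    methods: tuple = ("full", "additive"),
    n_sims: int = 100,
    base_seed: int = 0,
    settings: ReplicateSettings | None = None,
    genotypes: GenotypeMatrix | None = None,
    neighbors: int = 0,
    n_null: int = 0,
) -> RawResults:
    """Run ``n_sims`` seeded simulations and analyse each with the
    requested methods.

    Genotypes are generated once (seed ``base_seed``) and reused across
    simulations, mirroring a study that re-analyses one cohort's genotypes
    with fresh simulated traits; simulation i draws its phenotype noise
    with seed ``base_seed + 10000 + i``.  ``full`` and ``additive`` fit the
    truth-matched model specification when ``settings.mode`` is
    ``fit_truth``, or run the screen+stepwise pipeline when it is
    ``pipeline``; ``single`` runs the per-exam single-locus scan against
    the panel-wide Bonferroni threshold.
    """
    settings = settings or ReplicateSettings()
    rng = np.random.default_rng(base_seed)
    if genotypes is None:
        genotypes = scenario_panel(
            scenario.truth, model, scenario.n, neighbors=neighbors, n_null=n_null, seed=base_seed
        )
    groups = assign_groups(model, genotypes.n_samples)
    sex = rng.integers(0, 2, size=genotypes.n_samples)
    if scenario.sigma_eps is None:
        scenario = calibrate_residual(scenario, genotypes, groups, sex)

    full_spec = truth_model_spec(scenario.truth)
    add_spec = full_spec.reduce_to_additive()
    gibbs_kw = {
        "iterations": settings.gibbs_iterations,
        "burn_in": settings.gibbs_burn_in,
    }
    sims = []
    for i in range(n_sims):
        sim_seed = base_seed + 10_000 + i
        phen, _ = simulate_phenotypes(scenario, genotypes, groups, sex, seed=sim_seed)
        per_method = {}
        for method in methods:
            if method in ("full", "additive"):
                full_terms = method == "full"
                if settings.mode == "pipeline":
                    screen = screen_candidates(
                        genotypes,
                        phen,
                        p1d=settings.screen_p1d,
                        p2d=settings.screen_p2d,
                        max_candidates=settings.max_candidates,
                    )
                    spec = stepwise_build(
                        screen,
                        genotypes,
                        phen,
                        alpha_ew=settings.alpha_ew,
                        n_perm=settings.n_perm,
                        seed=sim_seed,
                        full_terms=full_terms,
                    )
                    if not spec.loci and not spec.epistasis_pairs:
                        per_method[method] = {"loci": set(), "terms": {}, "critical_F": np.nan}
                        continue
                else:
                    spec = full_spec if full_terms else add_spec
                design = build_design(genotypes, phen, spec)
                per_method[method] = _fit_truth_method(
                    design,
                    settings.n_perm,
                    settings.alpha_ew,
                    sim_seed,
                    settings.estimator,
                    gibbs_kw,
                )
            elif method == "single":
                first_exam = phen.records["exam"].iloc[0]
                one = phen.records[phen.records["exam"] == first_exam]
                k = min(settings.n_pcs, genotypes.n_snps - 1)
                pcs = pca_covariates(genotypes, k) if k >= 1 else None
                rows = [genotypes.sample_position(i_) for i_ in one["iid"]]
                scan = single_locus_scan(
                    genotypes, one, covariates=pcs[rows] if pcs is not None else None
                )
                thr = bonferroni_threshold(genotypes.n_snps, settings.single_alpha)
                tab = scan.table
                det = set(tab.loc[-np.log10(np.clip(tab["p"], 1e-300, 1)) > thr, "snp"])
                terms = {
                    f"a:{s}": (np.nan, s in det, -b)  # flip sign: minor-dosage slope
                    for s, b in zip(tab["snp"], tab["beta"])
                }
                per_method[method] = {"loci": det, "terms": terms, "critical_F": np.nan}
            else:
                raise ValueError(f"unknown method {method!r}")
        sims.append(per_method)
    return RawResults(
        methods=tuple(methods),
        sims=sims,
        n_sims=n_sims,
        base_seed=base_seed,
        scenario=scenario,
        genotypes=genotypes,
    )


# ---------------------------------------------------------------------------
# scoring


@dataclass
class EvaluationReport:
    per_effect: pd.DataFrame
    per_locus: pd.DataFrame
    summary: pd.DataFrame
    n_sims: int
    base_seed: int
    r2_match: float


def _pairwise_r2(genotypes: GenotypeMatrix, a: str, b: str) -> float:
    from .single_locus import _dosage

    D = _dosage(genotypes)
    x = D[:, genotypes.snp_position(a)]
    y = D[:, genotypes.snp_position(b)]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def score(
    raw: RawResults,
    truth=None,
    genotypes: GenotypeMatrix | None = None,
    r2_match: float = 0.85,
) -> EvaluationReport:
    """Score raw detections against the truth set.

    A detected locus counts as true when it is a truth locus or has
    genotype r-squared above ``r2_match`` with one (LD-representative
    matching); FDR is reported both raw and LD-adjusted.  Per-effect power
    is the percentage of simulations in which the effect's own term is
    experiment-wise significant, and bias flags come from the empirical
    95% interval of the estimates across simulations ("over" when the
    truth lies below the interval, "under" when above).
    """
    truth = raw.scenario.truth if truth is None else truth
    genotypes = raw.genotypes if genotypes is None else genotypes
    t_loci = set(truth_loci(truth))

    ld_cache: dict[str, bool] = {}

    def ld_true(snp: str) -> bool:
        if snp in t_loci:
            return True
        if snp not in ld_cache:
            ld_cache[snp] = any(
                _pairwise_r2(genotypes, snp, t) > r2_match
                for t in t_loci
                if genotypes.snps["chrom"][genotypes.snp_position(t)]
                == genotypes.snps["chrom"][genotypes.snp_position(snp)]
            )
        return ld_cache[snp]

    effect_rows, locus_rows, summary_rows = [], [], []
    for method in raw.methods:
        fdr_vals, fdr_adj_vals = [], []
        locus_hits: dict[str, int] = {s: 0 for s in t_loci}
        for sim in raw.sims:
            res = sim[method]
            det = res["loci"]
            if det:
                false = {s for s in det if s not in t_loci}
                fdr_vals.append(100.0 * len(false) / len(det))
                false_adj = {s for s in false if not ld_true(s)}
                fdr_adj_vals.append(100.0 * len(false_adj) / len(det))
            for s in t_loci:
                if s in det:
                    locus_hits[s] += 1
        for s in sorted(t_loci):
            locus_rows.append(
                {
                    "method": method,
                    "locus": s,
                    "power_pct": 100.0 * locus_hits[s] / raw.n_sims,
                }
            )
        for t in truth:
            lab = _truth_term_label(t)
            sig = 0
            ests = []
            for sim in raw.sims:
                terms = sim[method]["terms"]
                if lab in terms:
                    F, is_sig, est = terms[lab]
                    sig += bool(is_sig)
                    if np.isfinite(est):
                        ests.append(est)
            if not ests and lab not in raw.sims[0][method]["terms"]:
                continue  # effect not modelled by this method
            lo, hi = (np.percentile(ests, [2.5, 97.5]) if ests else (np.nan, np.nan))
            bias = "unbiased"
            if np.isfinite(lo):
                if t.value < lo:
                    bias = "over"
                elif t.value > hi:
                    bias = "under"
            effect_rows.append(
                {
                    "method": method,
                    "term": lab,
                    "truth": t.value,
                    "power_pct": 100.0 * sig / raw.n_sims,
                    "mean_estimate": float(np.mean(ests)) if ests else np.nan,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "bias": bias,
                }
            )
        locus_power = [r["power_pct"] for r in locus_rows if r["method"] == method]
        summary_rows.append(
            {
                "method": method,
                "mean_locus_power_pct": float(np.mean(locus_power)),
                "fdr_pct": float(np.mean(fdr_vals)) if fdr_vals else np.nan,
                "fdr_ld_adjusted_pct": float(np.mean(fdr_adj_vals)) if fdr_adj_vals else np.nan,
                "n_sims_with_detections": len(fdr_vals),
            }
        )
    return EvaluationReport(
        per_effect=pd.DataFrame(effect_rows),
        per_locus=pd.DataFrame(locus_rows),
        summary=pd.DataFrame(summary_rows),
        n_sims=raw.n_sims,
        base_seed=raw.base_seed,
        r2_match=r2_match,
    )


# ---------------------------------------------------------------------------
# headline benchmark


def anchor_power_scenario_i(
    n_sims: int = 50,
    n_perm: int = 500,
    seed: int = 1,
    n: int = 5277,
    alpha_ew: float = 0.05,
) -> dict:
    """Scenario-I detection power of the additive effect at the
    largest-effect (CELSR2-region analog) locus.

    Synthetic genotypes (ancestral MAF 0.30, FST 0.05, four groups at the
    cohort's recruitment shares), n individuals x two replicate records,
    residual SD calibrated so the anchor locus's additive term explains
    1.46% of phenotypic variance; each simulation fits the full model at
    the truth specification and checks the anchor additive term against
    the experiment-wise permutation threshold.
    """
    scen = scenario_i(n=n)
    model = PopulationModel(seed=seed)
    settings = ReplicateSettings(n_perm=n_perm, alpha_ew=alpha_ew, estimator="ols")
    raw = run_replicates(
        scen, model, methods=("full",), n_sims=n_sims, base_seed=seed, settings=settings
    )
    anchor_lab = f"a:{ANCHOR_LOCUS[0]}"
    hits = sum(bool(sim["full"]["terms"][anchor_lab][1]) for sim in raw.sims)
    return {
        "power_pct": 100.0 * hits / n_sims,
        "n_sims": n_sims,
        "n_perm": n_perm,
        "n": n,
        "raw": raw,
    }
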