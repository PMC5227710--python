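# fullgwas

Genome-wide association analysis of quantitative traits under the **full
genetic model**: additive (*a*), dominance (*d*) and digenic epistasis
(*aa, ad, da, dd*) effects of multiple loci as fixed terms, with ethnicity
(*e*) and every gene-by-ethnicity interaction class (*ae, de, aae, ade,
dae, dde*) as random terms.  The package is aimed at multi-ethnic cohort
studies with repeated trait measurements (e.g. serum cholesterol measured
at two examinations), where single-locus additive scans leave most of the
genetic architecture — non-additive effects and ethnic-specific effects —
on the table.

For individual *k* of ethnic group *h* the trait model is

```
y_hk = mu + s_k + sum_i [ x_a(i) a_i + x_d(i) d_i ]
     + sum_(i<j) [ x_aa aa_ij + x_ad ad_ij + x_da da_ij + x_dd dd_ij ]
     + e_h + sum_i [ x_a(i) ae_ih + x_d(i) de_ih ] + (epistasis x e terms)
     + eps_hk
```

with locus codings `x_a = +1 (QQ), 0 (Qq), -1 (qq)` (Q the major allele),
`x_d = 1 (Qq), 0 (hom)`, and epistasis codings formed as products of the
two loci's a/d codings.  Terms are tested by Henderson method III
F-statistics (reductions in sums of squares), calibrated experiment-wise by
the permutation distribution of the maximum F over all tested terms
(default 2,000 permutations, with a generalised-Pareto tail fit for P
values beyond the permutation resolution).  Effects and their SEs are
estimated by a Gibbs-sampled Bayesian linear mixed model (default 20,000
iterations), and each term's realised variance share yields the
heritability partition `h2_total = h2_a + h2_d + h2_epistasis + h2_ae +
h2_de + h2_epistasis_x_e`.

Alongside the full model the package provides the reduced multi-locus
additive model (only *a* mains with *e*/*ae* random classes), a
PLINK-style single-locus baseline (per-SNP additive regression with sex +
principal-component covariates, genomic control lambda, greedy
`--indep-pairwise`-style LD pruning, LD-based Bonferroni threshold), a
synthetic-cohort generator (Balding–Nichols population structure over four
ethnic groups, Hardy–Weinberg within group, optional tight-LD partners,
two replicate records per individual), and an evaluation harness that
scores repeated simulations for per-locus/per-effect power, raw and
LD-representative-adjusted FDR, and estimation bias.

## Worked example

Simulate a 1,500-individual cohort under the bundled full-model scenario
(truth effects of 20 loci and 4 epistasis pairs; residual SD calibrated so
the largest-effect locus's additive term explains 1.46 % of variance), fit
the full model at the truth specification, and print two loci:

```python
import numpy as np
from fullgwas import PopulationModel, EngineSettings, fit_full_model
from fullgwas.simulate import (scenario_i, scenario_panel, assign_groups,
                               calibrate_residual, simulate_phenotypes,
                               truth_model_spec)

model = PopulationModel(maf=0.30, fst=0.05, seed=42)
scenario = scenario_i(n=1500)
genotypes = scenario_panel(scenario.truth, model, n=1500, seed=42)
groups = assign_groups(model, 1500)
sex = np.random.default_rng(42).integers(0, 2, 1500)
scenario = calibrate_residual(scenario, genotypes, groups, sex)
phenotypes, _ = simulate_phenotypes(scenario, genotypes, groups, sex, seed=43)

fit = fit_full_model(truth_model_spec(scenario.truth), genotypes, phenotypes,
                     EngineSettings(n_perm=500, gibbs_iterations=4000,
                                    gibbs_burn_in=1000, seed=0))
print(fit.to_frame()[lambda t: t["locus"].isin(["rs629301", "rs7694118"])]
      .round(2).to_string(index=False))
```

```
    locus effect  estimate   se     F  neglog10_p_ew  p_ew_extrapolated  h2_pct
 rs629301      a      6.59 1.61 84.62           5.68               True    2.60
rs7694118      d      4.69 1.77 35.87           3.80               True    0.96
 rs629301   ae_1      0.37 1.69  0.34          -0.00              False    0.16
 rs629301   ae_2     -0.63 1.88  0.12          -0.00              False    0.16
 rs629301   ae_3     -1.77 1.84  1.69          -0.00              False    0.16
 rs629301   ae_4      1.12 1.79  0.96          -0.00              False    0.16
rs7694118   de_1      5.24 1.90 33.63           3.65               True    1.26
rs7694118   de_2      0.13 2.20  0.01          -0.00              False    1.26
rs7694118   de_3     -3.59 1.98 14.42           1.34              False    1.26
rs7694118   de_4     -2.46 2.05  7.26           0.17              False    1.26
```

Reading the output: `rs629301` carries a strong additive effect (true
value 4.94; the estimate 6.59 also absorbs the shrunken mean of its
interaction levels) with experiment-wise −log10 P = 5.68, past the
permutation critical F of 13.93 — flagged `p_ew_extrapolated` because the
P value lies beyond the resolution of 500 permutations and comes from the
fitted tail.  `rs7694118` is a dominance locus whose group-1-specific
dominance deviation (`de_1`, true value 8.31) is itself experiment-wise
significant, while null interaction levels stay far below threshold.
`h2_pct` is each term's share of phenotypic variance (interaction rows
show the pooled 4-level share).  The same fit object carries the class
partition (here a=11.4 %, epistasis=6.5 %, total 25.0 % at this reduced n)
and both Henderson-III and posterior variance components.

The same pipeline is scriptable from the shell:

```sh
fullgwas simulate --scenario I --n 2000 --seed 1 --outdir out
fullgwas qc --genotypes out/genotypes --outdir out
fullgwas screen --genotypes out/genotypes --phenotypes out/phenotypes.tsv --outdir out
fullgwas fit-full --genotypes out/genotypes --phenotypes out/phenotypes.tsv --outdir out
fullgwas scan-single --genotypes out/genotypes --phenotypes out/phenotypes.tsv --outdir out
```

Every stage reads and writes plain files (PLINK .ped/.map or
.bed/.bim/.fam, TSV tables, YAML model specs) and logs its seeds and
thresholds to `run.log`, so re-running a stage with the same inputs
reproduces its outputs byte for byte.

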