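"""Single-locus additive scan with stratification covariates.

The comparison arm: per-SNP least-squares regression of the trait on
minor-allele dosage (0/1/2) plus sex and top principal components, genomic
control, greedy LD pruning, and the LD-based Bonferroni threshold.  Note
the dosage coding here (count of the *minor* allele) differs from the full
model's {+1, 0, -1} major-oriented coding; the sign of a slope is therefore
opposite to the corresponding additive effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix

CHI2_1_MEDIAN = 0.4549364231  # median of the chi-square(1) distribution


def _dosage(genotypes: GenotypeMatrix, impute: bool = True) -> np.ndarray:
    """Minor-allele dosage matrix with missing calls mean-imputed."""
    d = (2 - genotypes.calls).astype(float)
    d[genotypes.calls == MISSING] = np.nan
    if impute:
        mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        mean = np.where(np.isnan(mean), 0.0, mean)
        idx = np.where(np.isnan(d))
        d[idx] = mean[idx[1]]
    return d


def pca_covariates(genotypes: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k principal component scores of the centred, standardised
    genotype matrix; sign fixed so each component's largest-magnitude
    loading is positive."""
    if k < 1:
        raise ValueError("k must be at least 1")
    X = _dosage(genotypes)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((S > S[0] * 1e-9).sum()) if len(S) else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds genotype matrix rank {rank}")
    scores = U[:, :k] * S[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] *= -1.0
    return scores


@dataclass
class ScanResult:
    table: pd.DataFrame  # snp, chrom, pos, beta, se, p, flag
    covariates: str
    lambda_gc_value: float

    def sorted_p(self) -> pd.DataFrame:
        return self.table.sort_values("p").reset_index(drop=True)


def single_locus_scan(
    genotypes: GenotypeMatrix,
    phenotype: pd.DataFrame,
    covariates: np.ndarray | None = None,
    dominance: bool = False,
) -> ScanResult:
    """Per-SNP additive regression on one examination's records.

    ``phenotype`` must hold one record per individual (columns ``iid`` and
    ``value``; optional ``sex`` is appended to the covariates).  Monomorphic
    or covariate-aliased SNPs are flagged and given P = 1.  ``dominance``
    adds a heterozygote-indicator term and reports its Wald P alongside.
    """
    if phenotype["iid"].duplicated().any():
        raise ValueError("single-locus scan needs one record per individual")
    rows = np.array([genotypes.sample_position(i) for i in phenotype["iid"]])
    y = phenotype["value"].to_numpy(dtype=float)
    n = len(y)

    covs = [np.ones(n)]
    desc = ["intercept"]
    if "sex" in phenotype.columns:
        covs.append(phenotype["sex"].to_numpy(dtype=float))
        desc.append("sex")
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        covs.extend(C.T)
        desc.append(f"{C.shape[1]} PCs")
    C = np.column_stack(covs)
    q, _ = np.linalg.qr(C)
    ry = y - q @ (q.T @ y)

    D = _dosage(genotypes)[rows]
    H = ((genotypes.calls[rows] == 1).astype(float)) if dominance else None
    out = []
    dof = n - C.shape[1] - (2 if dominance else 1)
    for j in range(genotypes.n_snps):
        x = D[:, j]
        rx = x - q @ (q.T @ x)
        sxx = float(rx @ rx)
        if x.std() == 0 or sxx / max(float(x @ x), 1.0) < 1e-12:
            out.append((np.nan, np.nan, 1.0, np.nan, "monomorphic_or_aliased"))
            continue
        if dominance:
            h = H[:, j]
            rh = h - q @ (q.T @ h)
            Z = np.column_stack([rx, rh])
            ZtZ = Z.T @ Z
            try:
                coef = np.linalg.solve(ZtZ, Z.T @ ry)
            except np.linalg.LinAlgError:
                out.append((np.nan, np.nan, 1.0, np.nan, "aliased_dominance"))
                continue
            resid = ry - Z @ coef
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.inv(ZtZ)
            t_a = coef[0] / math.sqrt(cov[0, 0])
            t_d = coef[1] / math.sqrt(cov[1, 1]) if cov[1, 1] > 0 else 0.0
            p_a = 2 * stats.t.sf(abs(t_a), dof)
            p_d = 2 * stats.t.sf(abs(t_d), dof)
            out.append((coef[0], math.sqrt(cov[0, 0]), p_a, p_d, ""))
        else:
            beta = float(rx @ ry) / sxx
            resid = ry - beta * rx
            s2 = float(resid @ resid) / dof
            se = math.sqrt(s2 / sxx)
            t = beta / se if se > 0 else 0.0
            p = 2 * stats.t.sf(abs(t), dof)
            out.append((beta, se, p, np.nan, ""))
    table = pd.DataFrame(
        out, columns=["beta", "se", "p", "p_dominance", "flag"]
    )
    table.insert(0, "pos", genotypes.snps["pos"].to_numpy())
    table.insert(0, "chrom", genotypes.snps["chrom"].to_numpy())
    table.insert(0, "snp", genotypes.snps["id"].to_numpy())
    clean = table.loc[table["flag"] == "", "p"]
    lam = lambda_gc(clean.to_numpy()) if len(clean) else float("nan")
    return ScanResult(table=table, covariates=" + ".join(desc), lambda_gc_value=lam)


def lambda_gc(pvalues: np.ndarray) -> float:
    """Genomic inflation factor: median association chi-square (from the
    quantile transform of the P values) over the null chi-square(1)
    median."""
    p = np.asarray(pvalues, float)
    if len(p) == 0:
        raise ValueError("no P values")
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def ld_prune(
    genotypes: GenotypeMatrix,
    window_snps: int = 50,
    step: int = 5,
    r2_max: float = 0.75,
) -> list[str]:
    """Greedy sliding-window LD pruning (the ``--indep-pairwise`` scheme).

    Within each window of ``window_snps`` currently-retained SNPs, while any
    pair has squared dosage correlation above ``r2_max``, the pair member
    with the lower MAF is dropped (ties: the later position); the window
    then advances by ``step`` SNPs.  The result is order-stable and
    idempotent.
    """
    if window_snps < step:
        raise ValueError("window must be at least as large as the step")
    D = _dosage(genotypes)
    maf = genotypes.maf()
    pos = genotypes.snps["pos"].to_numpy()
    ids = genotypes.snps["id"].to_numpy()
    m = genotypes.n_snps
    alive = np.ones(m, dtype=bool)

    start = 0
    while start < m:
        win = np.flatnonzero(alive)
        win = win[(win >= start) & (win < start + window_snps)]
        while len(win) > 1:
            X = D[:, win]
            X = X - X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            R = (X.T @ X) / (len(X) * np.outer(sd, sd))
            np.fill_diagonal(R, 0.0)
            i, j = np.unravel_index(np.argmax(R**2), R.shape)
            if R[i, j] ** 2 <= r2_max:
                break
            a, b = win[i], win[j]
            if maf[a] < maf[b] or (maf[a] == maf[b] and pos[a] > pos[b]):
                drop = a
            else:
                drop = b
            alive[drop] = False
            win = win[win != drop]
        start += step
    return [ids[j] for j in np.flatnonzero(alive)]


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """-log10 genome-wide significance threshold, to 2 decimals."""
    if n_tests < 1 or not 0 < alpha < 1:
        raise ValueError("need n_tests >= 1 and alpha in (0, 1)")
    return round(-math.log10(alpha / n_tests), 2)
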