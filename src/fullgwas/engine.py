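"""Mixed-model machinery: Henderson method III variance components,
term-wise F-statistics, permutation experiment-wise thresholds, and
Gibbs-sampling effect estimation.

All F-statistics are built from reductions in sums of squares computed with
every effect treated as fixed (Henderson's method III construction).  The
denominator is the residual mean square of the all-terms least-squares fit;
the permutation null calibrates the resulting test experiment-wise, so the
exact denominator choice does not affect validity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .coding import DesignMatrices

__all__ = [
    "VarianceComponents",
    "TermTest",
    "PermutationNull",
    "EffectEstimates",
    "GroupFTester",
    "henderson3_components",
    "term_F",
    "permutation_threshold",
    "experimentwise_p",
    "gibbs_estimate",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class VarianceComponents:
    """Per-class variances and the residual variance."""

    components: dict
    residual: float
    method: str
    truncated: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.residual <= 0:
            raise ValueError("residual variance must be strictly positive")
        for k, v in self.components.items():
            if v < 0:
                raise ValueError(f"negative variance for class {k}")


@dataclass
class TermTest:
    term: str
    delta_ss: float
    delta_df: int
    F: float
    p_ew: float | None = None
    p_ew_extrapolated: bool = False

    @property
    def neglog10_p_ew(self) -> float | None:
        if self.p_ew is None:
            return None
        return -math.log10(self.p_ew)


@dataclass
class PermutationNull:
    """Null distribution of the maximum F over tested terms."""

    n_perm: int
    max_F_samples: np.ndarray
    alpha_ew: float
    critical_F: float
    seed: int
    tail_threshold: float
    tail_frac: float
    tail_shape: float
    tail_scale: float


@dataclass
class EffectEstimates:
    """Posterior means (estimates) and SDs (SEs) from the Gibbs chain."""

    fixed: dict
    random: dict
    iterations: int
    burn_in: int
    thinning: int
    seed: int
    dropped_fixed: list = field(default_factory=list)

    def estimate(self, label: str) -> float:
        if label in self.fixed:
            return self.fixed[label][0]
        return self.random[label][0]

    def se(self, label: str) -> float:
        if label in self.fixed:
            return self.fixed[label][1]
        return self.random[label][1]


# ---------------------------------------------------------------------------
# linear-algebra helpers


def _greedy_basis(A: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
    """Order-respecting full-rank column subset from the Gram matrix ``A``.

    Columns are scanned left to right; a column whose residual squared norm
    after projection on the already-kept columns falls below ``rtol`` times
    its own squared norm is aliased and skipped.  Earlier columns win, so
    main-effect columns (placed before interaction blocks) stay in the
    basis.
    """
    p = A.shape[0]
    kept: list[int] = []
    L = np.zeros((p, p))  # growing Cholesky factor of A[kept, kept]
    scale = np.maximum(np.diag(A), 1e-300)
    for j in range(p):
        k = len(kept)
        if k == 0:
            r2 = A[j, j]
            w = np.empty(0)
        else:
            w = linalg.solve_triangular(L[:k, :k], A[kept, j], lower=True)
            r2 = A[j, j] - w @ w
        if r2 > rtol * scale[j]:
            L[k, :k] = w
            L[k, k] = math.sqrt(r2)
            kept.append(j)
    return np.array(kept, dtype=int)


_LSTSQ_COND = 1e-10  # relative singular-value cutoff for rank decisions


def _reduction(W: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """R(model) = y' P_W y and rank(W), rank-aware."""
    if W.shape[1] == 0:
        return 0.0, 0
    coef, _, rank, _ = linalg.lstsq(W, y, cond=_LSTSQ_COND, lapack_driver="gelsd")
    return float(y @ (W @ coef)), int(rank)


def _subset_R(A: np.ndarray, c: np.ndarray, idx: np.ndarray) -> float:
    """R for the column subset ``idx`` of a full-rank basis with Gram ``A``."""
    if len(idx) == 0:
        return 0.0
    Asub = A[np.ix_(idx, idx)]
    csub = c[idx]
    try:
        cf = linalg.cho_factor(Asub, check_finite=False)
        b = linalg.cho_solve(cf, csub, check_finite=False)
    except linalg.LinAlgError:
        b = np.linalg.lstsq(Asub, csub, rcond=None)[0]
    return float(csub @ b)


# ---------------------------------------------------------------------------
# Henderson method III variance components


def henderson3_components(design: DesignMatrices, y: np.ndarray | None = None) -> VarianceComponents:
    """Method-of-moments variance components from least-squares reductions.

    For each random class v, the reduction R(all) - R(all minus v) is
    equated to its expectation, a linear form in the class variances (trace
    terms) plus the residual variance times the rank difference; the
    resulting linear system is solved and negative solutions are truncated
    to zero.
    """
    y = design.y if y is None else np.asarray(y, float)
    n = len(y)
    blocks = design.random_blocks
    X = design.fixed
    if not blocks:
        R_all, rank = _reduction(X, y)
        dof = n - rank
        if dof <= 0:
            raise ValueError("no residual degrees of freedom")
        return VarianceComponents({}, (y @ y - R_all) / dof, "henderson3")

    classes = [b.cls for b in blocks]
    W_all = np.hstack([X] + [b.matrix for b in blocks])
    R_all, rank_all = _reduction(W_all, y)

    def traces(W: np.ndarray) -> np.ndarray:
        out = np.empty(len(blocks))
        if W.shape[1] == 0:
            for w, b in enumerate(blocks):
                out[w] = 0.0
            return out
        coef, _, _, _ = linalg.lstsq(
            W, np.hstack([b.matrix for b in blocks]), cond=_LSTSQ_COND, lapack_driver="gelsd"
        )
        proj = W @ coef
        off = 0
        for w, b in enumerate(blocks):
            q = b.matrix.shape[1]
            out[w] = float((b.matrix * proj[:, off : off + q]).sum())
            off += q
        return out

    T_all = traces(W_all)
    n_cls = len(classes)
    Amat = np.zeros((n_cls + 1, n_cls + 1))
    rhs = np.zeros(n_cls + 1)
    for v in range(n_cls):
        W_red = np.hstack([X] + [b.matrix for w, b in enumerate(blocks) if w != v])
        R_red, rank_red = _reduction(W_red, y)
        T_red = traces(W_red)
        Amat[v, :n_cls] = T_all - T_red
        Amat[v, n_cls] = rank_all - rank_red
        rhs[v] = R_all - R_red
    for w, b in enumerate(blocks):
        Amat[n_cls, w] = float((b.matrix**2).sum()) - T_all[w]
    Amat[n_cls, n_cls] = n - rank_all
    rhs[n_cls] = y @ y - R_all

    sol, _, sys_rank, _ = np.linalg.lstsq(Amat, rhs, rcond=None)
    if sys_rank < n_cls + 1:
        raise ValueError(
            "singular Henderson III system; consider removing an aliased random class"
        )
    truncated = [classes[v] for v in range(n_cls) if sol[v] < 0]
    comps = {classes[v]: max(float(sol[v]), 0.0) for v in range(n_cls)}
    resid = float(sol[n_cls])
    if resid <= 0:
        # the moment system can solve negative on small unbalanced designs;
        # fall back to the all-terms mean squared error
        resid = (float(y @ y) - R_all) / (n - rank_all)
        truncated.append("residual")
    if resid <= 0:
        raise ValueError("non-positive residual variance estimate")
    return VarianceComponents(comps, resid, "henderson3", truncated)


# ---------------------------------------------------------------------------
# group F tests


def genetic_test_labels(design: DesignMatrices) -> list[str]:
    """Default tested terms: every fixed genetic term group plus every
    single ethnic level of every interaction block (matching how results
    tables report per-level interaction effects)."""
    out = []
    for lab in design.fixed_labels:
        if design.column_map[lab]["kind"] not in ("mu", "sex"):
            out.append(design.column_map[lab]["group"])
    for b in design.random_blocks:
        if b.cls == "e":
            continue
        out.extend(b.labels)
    return out


class GroupFTester:
    """Type-III style F-statistics for term groups, with a fast path for
    individual-level permutations.

    Parameters
    ----------
    design
        Factorised design matrices.
    tests
        What to test.  Each entry is a term-group label (e.g. ``"a:rs1"``,
        ``"ae:rs1"``), a single column label (e.g. ``"ae_3:rs1"``), or a
        tuple ``(label, [labels...])`` testing several groups jointly.
        ``None`` selects :func:`genetic_test_labels`.
    conditioning
        ``"marginality"`` (default): each term is tested against all other
        columns except any group that structurally spans or is spanned by
        it (see ``DesignMatrices.marginality_excludes``); the F denominator
        is the all-columns residual mean square.  Or a mapping
        label -> explicit list of conditioning labels (used by the stepwise
        search), in which case the denominator comes from the
        conditioning-plus-term fit.
    """

    def __init__(
        self,
        design: DesignMatrices,
        tests: list | None = None,
        conditioning: str | dict = "marginality",
        on_aliased: str = "error",
    ) -> None:
        self.design = design
        W, labels, groups = design.stacked()
        self.W = W
        self.labels = labels
        self.groups = groups
        self.col_of = {lab: j for j, lab in enumerate(labels)}
        self.y = design.y
        self.n = W.shape[0]
        self.n_cols = W.shape[1]

        A = W.T @ W
        self.basis = _greedy_basis(A)
        self.rank = len(self.basis)

        if tests is None:
            tests = genetic_test_labels(design)

        def resolve(lab: str) -> list[int]:
            if lab in groups:
                return [int(j) for j in groups[lab]]
            if lab in self.col_of:
                return [self.col_of[lab]]
            raise KeyError(f"unknown term or column label {lab!r}")

        all_cols = set(range(self.n_cols))
        self.skipped_aliased: list[str] = []
        self.tests: list[tuple[str, np.ndarray, np.ndarray, int, bool]] = []
        for entry in tests:
            if isinstance(entry, tuple):
                name, members = entry
            else:
                name, members = entry, [entry]
            g_cols: list[int] = []
            for m in members:
                g_cols.extend(resolve(m))
            if conditioning == "marginality":
                excl: set[int] = set()
                for m in members:
                    for ex in design.marginality_excludes(m):
                        excl.update(resolve(ex))
                cond = sorted(all_cols - set(g_cols) - excl)
                full_denom = True
            else:
                cond_cols: set[int] = set()
                for cg in conditioning[name]:
                    cond_cols.update(resolve(cg))
                cond = sorted(cond_cols - set(g_cols))
                full_denom = False
            # rank structure of (conditioning | term) determined once on the
            # observed design; permutations reuse the same column subsets
            sub = np.array(cond + g_cols, dtype=int)
            kept = _greedy_basis(A[np.ix_(sub, sub)])
            with_sorted = np.sort(sub[kept])
            g_kept = sub[kept[kept >= len(cond)]]
            g_pos = np.searchsorted(with_sorted, np.sort(g_kept))
            df = len(g_pos)
            if df == 0:
                if on_aliased == "skip":
                    self.skipped_aliased.append(name)
                    continue
                raise ValueError(f"term {name!r} is completely aliased (delta df = 0)")
            self.tests.append((name, with_sorted, g_pos, df, full_denom))

        # group tests sharing one conditioning-plus-term model so each model
        # is factorised once per evaluation
        models: dict[tuple, list] = {}
        for name, with_sorted, g_pos, df, full_denom in self.tests:
            models.setdefault(tuple(with_sorted), []).append((name, g_pos, df, full_denom))
        models.setdefault(tuple(np.sort(self.basis)), [])
        self._models = [(np.array(k, dtype=int), v) for k, v in models.items()]

    # -- core evaluation -------------------------------------------------

    def _evaluate(self, A: np.ndarray, c: np.ndarray, yy: float) -> dict[str, TermTest]:
        dof_full = self.n - self.rank
        ms_full = None
        out: dict[str, TermTest] = {}
        results = []
        for with_idx, tests in self._models:
            A_ww = A[np.ix_(with_idx, with_idx)]
            try:
                cf = linalg.cho_factor(A_ww, check_finite=False)
                C = linalg.cho_solve(cf, np.eye(len(with_idx)), check_finite=False)
            except linalg.LinAlgError:
                # a permutation can create an exact within-group collinearity
                # (e.g. two high-LD loci sharing a dominant coding inside one
                # ethnic group); the pseudo-inverse zeroes that direction
                C = np.linalg.pinv(A_ww, hermitian=True)
            beta = C @ c[with_idx]
            R1 = float(c[with_idx] @ beta)
            if len(with_idx) == self.rank and ms_full is None:
                ms_full = max(yy - R1, 0.0) / dof_full
            results.append((with_idx, tests, C, beta, R1))
        for with_idx, tests, C, beta, R1 in results:
            for name, g_pos, df, full_denom in tests:
                # SS for dropping the term from its model (general linear
                # hypothesis on the term's coefficients)
                bE = beta[g_pos]
                CE = C[np.ix_(g_pos, g_pos)]
                if df == 1:
                    dss = float(bE[0] * bE[0] / CE[0, 0]) if CE[0, 0] > 0 else 0.0
                else:
                    try:
                        dss = float(bE @ linalg.solve(CE, bE, assume_a="pos"))
                    except linalg.LinAlgError:
                        dss = float(bE @ np.linalg.lstsq(CE, bE, rcond=None)[0])
                dss = max(dss, 0.0)
                if full_denom:
                    ms = ms_full
                else:
                    ms = max(yy - R1, 0.0) / (self.n - len(with_idx))
                out[name] = TermTest(name, dss, df, (dss / df) / ms if ms > 0 else np.inf)
        return out

    def observed(self) -> dict[str, TermTest]:
        A = self.W.T @ self.W
        return self._evaluate(A, self.W.T @ self.y, float(self.y @ self.y))

    def null_max_F(self, n_perm: int, seed: int) -> np.ndarray:
        """Per-permutation maximum F over the tested terms.

        Individuals' genotypes are relabelled against the phenotype records
        (both replicate records of an individual travel together; sex and
        ethnicity stay with the phenotype record).
        """
        rng = np.random.default_rng(seed)
        n_ind = self.design.n_individuals
        if math.lgamma(n_ind + 1) < math.log(max(n_perm, 1)):
            raise ValueError("fewer distinct permutations than n_perm possible")
        if not self.tests:
            return np.zeros(n_perm)
        yy = float(self.y @ self.y)
        out = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(n_ind)
            Wp = self.design.permuted_stacked(perm)
            res = self._evaluate(Wp.T @ Wp, Wp.T @ self.y, yy)
            out[b] = max(t.F for t in res.values())
        return out

    def residual_ms(self) -> tuple[float, int]:
        """Residual mean square and df of the all-terms fit."""
        A = self.W.T @ self.W
        c = self.W.T @ self.y
        R_full = _subset_R(A, c, self.basis)
        dof = self.n - self.rank
        return (float(self.y @ self.y) - R_full) / dof, dof

    def ols_estimates(self) -> dict[str, float]:
        """Least-squares coefficients on the full-rank basis, keyed by
        column label; aliased columns get NaN."""
        B = self.W[:, self.basis]
        coef = np.linalg.lstsq(B, self.y, rcond=None)[0]
        out = {lab: float("nan") for lab in self.labels}
        for k, j in enumerate(self.basis):
            out[self.labels[j]] = float(coef[k])
        return out


def term_F(design: DesignMatrices, y: np.ndarray | None = None, term: str = "") -> TermTest:
    """Partial F for one term group (marginality conditioning, all-terms
    residual denominator).  Equals the classical OLS partial F when no
    interaction block spans the term."""
    if y is not None:
        design = _with_y(design, y)
    tester = GroupFTester(design, tests=[term])
    return tester.observed()[term]


def _with_y(design: DesignMatrices, y: np.ndarray) -> DesignMatrices:
    import copy

    d = copy.copy(design)
    d.y = np.asarray(y, float)
    return d


# ---------------------------------------------------------------------------
# permutation null and experiment-wise P


def permutation_threshold(
    design: DesignMatrices,
    tested_terms: list[str] | None = None,
    n_perm: int = 2000,
    alpha_ew: float = 0.05,
    seed: int = 0,
    tail_frac: float = 0.10,
) -> PermutationNull:
    """Experiment-wise critical F from the permutation distribution of the
    maximum F over the tested terms.

    A generalised Pareto distribution is fitted to the upper ``tail_frac``
    of the max-F samples so that P values beyond the permutation resolution
    (about 1/(n_perm+1)) can be extrapolated.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    tester = GroupFTester(design, tests=tested_terms)
    samples = tester.null_max_F(n_perm, seed)
    return null_from_samples(samples, alpha_ew, seed, tail_frac)


def null_from_samples(
    samples: np.ndarray, alpha_ew: float, seed: int, tail_frac: float = 0.10
) -> PermutationNull:
    """Assemble a :class:`PermutationNull` from max-F samples."""
    n_perm = len(samples)
    critical = float(np.quantile(samples, 1.0 - alpha_ew))
    u = float(np.quantile(samples, 1.0 - tail_frac))
    exc = samples[samples > u] - u
    if len(exc) >= 10:
        shape, _, scale = stats.genpareto.fit(exc, floc=0.0)
        frac = len(exc) / n_perm
        if shape < 0:
            # a bounded-support fit would put zero mass beyond its endpoint;
            # force an exponential (unbounded) tail instead
            shape, scale = 0.0, float(np.mean(exc))
    else:  # degenerate tail; fall back to exponential-like decay
        shape, scale = 0.0, float(max(np.mean(exc), 1e-12)) if len(exc) else 1.0
        frac = max(len(exc), 1) / n_perm
    return PermutationNull(
        n_perm=n_perm,
        max_F_samples=np.sort(samples),
        alpha_ew=alpha_ew,
        critical_F=critical,
        seed=seed,
        tail_threshold=u,
        tail_frac=frac,
        tail_shape=float(shape),
        tail_scale=float(scale),
    )


def experimentwise_p(F_obs: float, null: PermutationNull) -> tuple[float, bool]:
    """Experiment-wise P for an observed F against the permutation null.

    Within the empirical range, ``p = (1 + #{max-F >= F_obs})/(n_perm+1)``;
    beyond it, the survival function of the fitted generalised Pareto tail
    is used and the result is flagged as an extrapolation.
    """
    if F_obs < 0:
        raise ValueError("F must be non-negative")
    samples = null.max_F_samples
    k = int((samples >= F_obs).sum())
    p_emp = (1.0 + k) / (null.n_perm + 1.0)
    if k > 0:
        return p_emp, False
    p_tail = null.tail_frac * float(
        stats.genpareto.sf(F_obs - null.tail_threshold, null.tail_shape, scale=null.tail_scale)
    )
    p = min(p_tail, 1.0 / (null.n_perm + 1.0))
    return max(p, 1e-300), True


# ---------------------------------------------------------------------------
# Gibbs sampler


def gibbs_estimate(
    design: DesignMatrices,
    y: np.ndarray | None = None,
    iterations: int = 20000,
    burn_in: int = 2000,
    thinning: int = 1,
    seed: int = 0,
    prior_shape: float = 0.001,
    prior_scale: float = 0.001,
) -> tuple[EffectEstimates, VarianceComponents]:
    """Bayesian linear mixed model by Gibbs sampling.

    Flat priors on fixed effects; each random class gets an i.i.d. normal
    prior with class variance, and all variances get inverse-gamma
    (``prior_shape``, ``prior_scale``) priors.  Returns posterior means and
    SDs after burn-in and thinning, plus posterior-mean variance
    components.
    """
    y = design.y if y is None else np.asarray(y, float)
    n = len(y)
    if np.var(y) == 0:
        raise ValueError("trait has zero variance")
    rng = np.random.default_rng(seed)

    X_all = design.fixed
    keep = _greedy_basis(X_all.T @ X_all)
    dropped = [design.fixed_labels[j] for j in range(X_all.shape[1]) if j not in set(keep.tolist())]
    X = X_all[:, keep]
    fixed_labels = [design.fixed_labels[j] for j in keep]
    p = X.shape[1]
    blocks = design.random_blocks
    Us = [b.matrix for b in blocks]
    qs = [U.shape[1] for U in Us]

    XtX = X.T @ X
    cfX = linalg.cho_factor(XtX, check_finite=False)
    Rx = linalg.cholesky(XtX, lower=False)
    UtUs = [U.T @ U for U in Us]

    beta = linalg.cho_solve(cfX, X.T @ y)
    us = [np.zeros(q) for q in qs]
    sig_e = float(np.var(y)) / 2.0 or 1.0
    sig_v = [float(np.var(y)) / (2.0 * max(len(qs), 1)) + 1e-6 for _ in qs]

    n_keep = (iterations - burn_in) // thinning
    if n_keep < 2:
        raise ValueError("too few retained iterations")
    beta_draws = np.empty((n_keep, p))
    u_draws = [np.empty((n_keep, q)) for q in qs]
    sv_draws = np.empty((n_keep, len(qs)))
    se_draws = np.empty(n_keep)

    fitted_random = sum((U @ u for U, u in zip(Us, us)), np.zeros(n))
    kdx = 0
    for it in range(iterations):
        # fixed effects
        resid_f = y - fitted_random
        mean = linalg.cho_solve(cfX, X.T @ resid_f, check_finite=False)
        beta = mean + math.sqrt(sig_e) * linalg.solve_triangular(
            Rx, rng.standard_normal(p), lower=False
        )
        fitted_fixed = X @ beta
        # random classes
        for v, (U, UtU, q) in enumerate(zip(Us, UtUs, qs)):
            fitted_random -= U @ us[v]
            r = y - fitted_fixed - fitted_random
            M = UtU / sig_e + np.eye(q) / sig_v[v]
            Lm = linalg.cholesky(M, lower=True)
            mean_v = linalg.cho_solve((Lm, True), U.T @ r / sig_e, check_finite=False)
            us[v] = mean_v + linalg.solve_triangular(Lm.T, rng.standard_normal(q), lower=False)
            fitted_random += U @ us[v]
            sh = prior_shape + q / 2.0
            sc = prior_scale + float(us[v] @ us[v]) / 2.0
            sig_v[v] = sc / rng.gamma(sh)
        # residual variance
        e = y - fitted_fixed - fitted_random
        sh = prior_shape + n / 2.0
        sc = prior_scale + float(e @ e) / 2.0
        sig_e = sc / rng.gamma(sh)
        if not (np.isfinite(sig_e) and all(np.isfinite(s) for s in sig_v)):
            raise FloatingPointError(f"divergent Gibbs chain at iteration {it}")
        if it >= burn_in and (it - burn_in) % thinning == 0 and kdx < n_keep:
            beta_draws[kdx] = beta
            for v in range(len(qs)):
                u_draws[v][kdx] = us[v]
            sv_draws[kdx] = sig_v
            se_draws[kdx] = sig_e
            kdx += 1

    fixed = {
        lab: (float(m), float(s))
        for lab, m, s in zip(fixed_labels, beta_draws.mean(axis=0), beta_draws.std(axis=0, ddof=1))
    }
    for lab in dropped:
        fixed[lab] = (float("nan"), float("nan"))
    random: dict[str, tuple[float, float]] = {}
    for v, b in enumerate(blocks):
        means = u_draws[v].mean(axis=0)
        sds = u_draws[v].std(axis=0, ddof=1)
        for j, lab in enumerate(b.labels):
            random[lab] = (float(means[j]), float(sds[j]))
    est = EffectEstimates(
        fixed=fixed,
        random=random,
        iterations=iterations,
        burn_in=burn_in,
        thinning=thinning,
        seed=seed,
        dropped_fixed=dropped,
    )
    vc = VarianceComponents(
        components={b.cls: float(sv_draws[:, v].mean()) for v, b in enumerate(blocks)},
        residual=float(se_draws.mean()),
        method="gibbs",
    )
    return est, vc
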