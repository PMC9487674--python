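"""Differential-state test families for multi-subject scRNA-seq.

Four families are implemented, mirroring the structure (normalization,
model, test, gene filter) of the methods commonly compared for this task:

* **naive single-cell tests** treating cells as independent — Wilcoxon
  rank-sum, logistic regression, Poisson and negative-binomial GLMs, and a
  two-part (hurdle) model on log-normalized expression;
* **latent-variable variants** of the regression tests, which condition on
  extra covariates (here, subject identity dummies) and assess the group
  term by a likelihood-ratio test given those covariates;
* a **mixed model** — Gaussian random intercept per subject, fitted by a
  profiled likelihood over the variance ratio, with a likelihood-ratio test
  of the condition term;
* **pseudobulk tests** on genes x samples aggregates — a moderated-t with
  empirical-Bayes variance shrinkage, a negative-binomial GLM with trended
  dispersion shrinkage and Wald test, and a reproducibility-optimized test
  statistic (ROTS-style) whose tuning constants are selected by maximizing
  the bootstrap reproducibility of top gene lists.

Each family is a structural analogue of its reference implementation, not a
numeric clone: the skeleton (normalization, model class, test) matches, the
dispersion / shrinkage estimators are simplified.

All tests return a :class:`TestResult` over the full gene universe of the
input, with missing p-values (NaN) for genes the method's filter removed or
the fit failed on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import polygamma
import statsmodels.api as sm

from .simgen import CellCountMatrix, ValidationError
from . import normagg
from .normagg import PseudobulkMatrix

logger = logging.getLogger("dsbench")

__all__ = [
    "TestResult",
    "wilcoxon_test",
    "lr_test",
    "poisson_glm_test",
    "negbinom_glm_test",
    "hurdle_test",
    "lmm_random_intercept_test",
    "fit_random_intercept",
    "pb_moderated_t",
    "pb_nbglm",
    "pb_rots",
    "subject_dummies",
    "run_method",
    "METHOD_NAMES",
]

# exact Wilcoxon null distribution below this total sample size (no ties)
_WILCOXON_EXACT_N = 25

# ROTS defaults: bootstrap pairs, candidate top-list sizes, (a1, a2) grid
ROTS_N_BOOTSTRAP = 100
ROTS_TOPLIST_SIZES = (5, 10, 25, 50)
ROTS_A1_GRID = (0.0, 0.01, 0.1, 0.25, 0.5, 1.0)
ROTS_A2_GRID = (0.0, 1.0)

# prior weight (in samples) pulling gene-wise NB dispersions to the trend
_NB_PRIOR_WEIGHT = 10.0


@dataclass
class TestResult:
    """Per-gene p-values and effects of one method on one dataset."""

    __test__ = False  # not a pytest class, despite the name

    method: str
    gene_ids: list[str]
    p_value: np.ndarray
    effect: np.ndarray
    tested: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p_value = np.asarray(self.p_value, dtype=float)
        self.tested = np.asarray(self.tested, dtype=bool)
        present = ~np.isnan(self.p_value)
        if np.any(present & ~self.tested):
            raise ValidationError("p-values present for untested genes")
        if present.any():
            pv = self.p_value[present]
            if pv.min() < 0 or pv.max() > 1:
                raise ValidationError("p-values outside [0, 1]")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "p_value": self.p_value,
                "effect": self.effect,
                "tested": self.tested,
                "method": self.method,
            }
        )


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _two_groups(groups) -> tuple[np.ndarray, np.ndarray, list]:
    groups = np.asarray(groups, dtype=object)
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValidationError(f"expected exactly two groups, got {levels}")
    a = groups == levels[0]
    b = groups == levels[1]
    if a.sum() == 0 or b.sum() == 0:
        raise ValidationError("each group needs at least one observation")
    return a, b, levels


def _log2fc_expm1(normalized: np.ndarray, mask_a, mask_b) -> np.ndarray:
    """log2 fold change (second vs first group) of expm1 means, pseudocount 1."""
    ma = np.expm1(normalized[:, mask_a]).mean(axis=1)
    mb = np.expm1(normalized[:, mask_b]).mean(axis=1)
    return np.log2(mb + 1.0) - np.log2(ma + 1.0)


def subject_dummies(subjects) -> np.ndarray:
    """Treatment-coded indicator columns for subjects (first level dropped)."""
    subjects = np.asarray(subjects, dtype=object)
    levels = sorted(set(subjects))
    return np.column_stack(
        [(subjects == s).astype(float) for s in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(subjects), 0))


def _group_in_span(group_col: np.ndarray, null_design: np.ndarray) -> bool:
    """True when the group indicator lies in the column span of the null design."""
    resid = group_col - null_design @ np.linalg.lstsq(null_design, group_col, rcond=None)[0]
    return bool(np.max(np.abs(resid)) < 1e-8)


def _chi2_sf(stat: float, df: int) -> float:
    return float(stats.chi2.sf(max(stat, 0.0), df)) if df > 0 else 1.0


# ---------------------------------------------------------------------------
# naive single-cell tests
# ---------------------------------------------------------------------------

def wilcoxon_test(normalized: np.ndarray, groups, gene_ids=None) -> TestResult:
    """Two-sided Wilcoxon rank-sum test per gene.

    Small samples (total <= 25, no ties) use the exact null distribution;
    otherwise the normal approximation with tie and continuity correction.
    """
    normalized = np.asarray(normalized, dtype=float)
    mask_a, mask_b, _ = _two_groups(groups)
    G = normalized.shape[0]
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(G)]
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    n = na + nb
    vals = np.concatenate([normalized[:, mask_a], normalized[:, mask_b]], axis=1)

    p = np.empty(G)
    if n <= _WILCOXON_EXACT_N:
        for g in range(G):
            res = stats.mannwhitneyu(
                vals[g, :na], vals[g, na:], alternative="two-sided", method="auto"
            )
            p[g] = res.pvalue
    else:
        ranks = stats.rankdata(vals, axis=1)
        ra = ranks[:, :na].sum(axis=1)
        u = ra - na * (na + 1) / 2.0
        mu = na * nb / 2.0
        tie_term = np.empty(G)
        for g in range(G):
            _, cnt = np.unique(vals[g], return_counts=True)
            tie_term[g] = np.sum(cnt**3 - cnt)
        sigma2 = (na * nb / 12.0) * ((n + 1) - tie_term / (n * (n - 1.0)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(sigma2)
        p = np.where(sigma2 > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
        p = np.minimum(p, 1.0)

    effect = _log2fc_expm1(normalized, mask_a, mask_b)
    return TestResult(
        method="wilcoxon",
        gene_ids=gene_ids,
        p_value=p,
        effect=effect,
        tested=np.ones(G, dtype=bool),
        metadata={"family": "naive"},
    )


def _glm_lrt_gene_on_group(endog, group, latent, family, offset=None):
    """LRT (df 1) of the group term in a GLM of ``endog`` on group (+ latent)."""
    n = len(endog)
    ones = np.ones((n, 1))
    null_X = ones if latent is None else np.column_stack([ones, latent])
    full_X = np.column_stack([null_X, group])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m0 = sm.GLM(endog, null_X, family=family, offset=offset).fit()
        m1 = sm.GLM(endog, full_X, family=family, offset=offset).fit()
    stat = 2.0 * (m1.llf - m0.llf)
    return stat, m1.params[-1]


def lr_test(normalized: np.ndarray, groups, latent=None, gene_ids=None) -> TestResult:
    """Logistic regression of group membership on per-gene expression.

    The p-value is a likelihood-ratio test (df 1) of the expression term in
    ``group ~ expression (+ latent covariates)``.  If the latent covariates
    already determine group membership exactly, the expression term cannot
    improve the fit and every p-value is 1.
    """
    normalized = np.asarray(normalized, dtype=float)
    mask_a, mask_b, _ = _two_groups(groups)
    G, n = normalized.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(G)]
    y = mask_b.astype(float)
    effect = _log2fc_expm1(normalized, mask_a, mask_b)
    p = np.full(G, np.nan)

    if latent is not None:
        latent = np.asarray(latent, dtype=float)
        # latent profiles that fully separate the groups: the null model is
        # saturated and the gene term is uninformative
        keys = [tuple(row) for row in latent]
        by_key: dict = {}
        separated = True
        for k, yi in zip(keys, y):
            if by_key.setdefault(k, yi) != yi:
                separated = False
                break
        if separated:
            return TestResult(
                method="lr", gene_ids=gene_ids, p_value=np.ones(G),
                effect=effect, tested=np.ones(G, dtype=bool),
                metadata={"family": "latent", "note": "latent encodes groups"},
            )

    ones = np.ones((n, 1))
    null_X = ones if latent is None else np.column_stack([ones, latent])
    fam = sm.families.Binomial()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m0 = sm.GLM(y, null_X, family=fam).fit()
    ll0 = m0.llf
    for g in range(G):
        full_X = np.column_stack([null_X, normalized[g]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m1 = sm.GLM(y, full_X, family=fam).fit(maxiter=100)
            p[g] = _chi2_sf(2.0 * (m1.llf - ll0), 1)
        except Exception:  # non-convergence / separation
            logger.debug("lr_test: gene %s did not converge", gene_ids[g])
    return TestResult(
        method="lr", gene_ids=gene_ids, p_value=p, effect=effect,
        tested=np.ones(G, dtype=bool),
        metadata={"family": "latent" if latent is not None else "naive"},
    )


def _count_glm_test(counts, groups, latent, family_name, gene_ids, method):
    counts = np.asarray(counts, dtype=float)
    mask_a, mask_b, _ = _two_groups(groups)
    G, n = counts.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(G)]
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        raise ValidationError("cells with zero library size")
    offset = np.log(lib)
    group_col = mask_b.astype(float)
    p = np.full(G, np.nan)
    effect = np.full(G, np.nan)
    dispersions = np.full(G, np.nan)

    ones = np.ones((n, 1))
    null_X = ones if latent is None else np.column_stack([ones, np.asarray(latent, float)])
    if latent is not None and _group_in_span(group_col, null_X):
        # group adds nothing on top of the latent terms: LRT is identically 0
        mean_a = counts[:, mask_a].mean(axis=1)
        mean_b = counts[:, mask_b].mean(axis=1)
        return TestResult(
            method=method, gene_ids=gene_ids, p_value=np.ones(G),
            effect=np.log2(mean_b + 1) - np.log2(mean_a + 1),
            tested=np.ones(G, dtype=bool),
            metadata={"family": "latent", "note": "group in latent span"},
        )

    for g in range(G):
        y = counts[g]
        try:
            if family_name == "poisson":
                stat, coef = _glm_lrt_gene_on_group(
                    y, group_col, None if latent is None else np.asarray(latent, float),
                    sm.families.Poisson(), offset=offset,
                )
            else:  # negative binomial with ML dispersion
                stat, coef, alpha = _nb_lrt(y, group_col, latent, offset)
                dispersions[g] = alpha
            p[g] = _chi2_sf(stat, 1)
            effect[g] = coef / np.log(2.0)  # natural-log coef -> log2 FC
        except Exception:
            logger.debug("%s: gene %s did not converge", method, gene_ids[g])
    return TestResult(
        method=method, gene_ids=gene_ids, p_value=p, effect=effect,
        tested=np.ones(G, dtype=bool),
        metadata={
            "family": "latent" if latent is not None else "naive",
            "dispersions": dispersions,
        },
    )


def poisson_glm_test(counts, groups, latent=None, gene_ids=None) -> TestResult:
    """Per-gene Poisson GLM ``count ~ group (+ latent)`` with log library-size
    offset; likelihood-ratio test (df 1) on the group term."""
    return _count_glm_test(counts, groups, latent, "poisson", gene_ids, "poisson")


def negbinom_glm_test(counts, groups, latent=None, gene_ids=None) -> TestResult:
    """Per-gene NB GLM with maximum-likelihood dispersion; LRT on the group
    term.  Falls back to Poisson when the dispersion estimate collapses to 0."""
    return _count_glm_test(counts, groups, latent, "negbinomial", gene_ids, "negbinom")


def _nb_lrt(y, group_col, latent, offset):
    """NB2 LRT of the group term with dispersion estimated by ML (MoM start)."""
    n = len(y)
    ones = np.ones((n, 1))
    null_X = ones if latent is None else np.column_stack([ones, np.asarray(latent, float)])
    full_X = np.column_stack([null_X, group_col])
    # method-of-moments start for alpha on offset-adjusted counts
    z = y / np.exp(offset - offset.mean())
    mu, v = z.mean(), z.var()
    alpha0 = max((v - mu) / mu**2, 1e-4) if mu > 0 else 1e-4
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            m1 = sm.NegativeBinomial(y, full_X, offset=offset).fit(
                disp=False, start_params=np.r_[np.zeros(full_X.shape[1]), alpha0],
                maxiter=200,
            )
            m0 = sm.NegativeBinomial(y, null_X, offset=offset).fit(
                disp=False, maxiter=200,
            )
            alpha = float(m1.params[-1])
        except Exception:
            alpha = 0.0
        if alpha <= 1e-6:
            # dispersion degenerate: Poisson fallback
            logger.debug("negbinom: dispersion -> 0, Poisson fallback")
            fam = sm.families.Poisson()
            m0 = sm.GLM(y, null_X, family=fam, offset=offset).fit()
            m1 = sm.GLM(y, full_X, family=fam, offset=offset).fit()
            return 2.0 * (m1.llf - m0.llf), m1.params[-1], 0.0
    return 2.0 * (m1.llf - m0.llf), float(m1.params[-2]), alpha


def _binom_ll(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Maximized Bernoulli log-likelihood for k successes of n (vectorized)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = k / n
        ll = k * np.log(p) + (n - k) * np.log1p(-p)
    return np.where((k == 0) | (k == n), 0.0, np.nan_to_num(ll))


def hurdle_test(normalized, groups, latent=None, gene_ids=None) -> TestResult:
    """Two-part hurdle test on log-normalized expression.

    The discrete part is a logistic model of detection (value > 0) on group
    (+ latent); the continuous part a Gaussian linear model on the positive
    values.  The per-part likelihood-ratio chi-squares on the group term are
    summed (df summed) into one combined p-value.
    """
    normalized = np.asarray(normalized, dtype=float)
    mask_a, mask_b, _ = _two_groups(groups)
    G, n = normalized.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(G)]
    group_col = mask_b.astype(float)
    detected = normalized > 0
    effect = _log2fc_expm1(normalized, mask_a, mask_b)
    p = np.full(G, np.nan)
    chi2_parts = np.zeros((G, 2))
    df_parts = np.zeros((G, 2), dtype=int)

    ones = np.ones((n, 1))
    null_X = ones if latent is None else np.column_stack([ones, np.asarray(latent, float)])
    latent_saturates = latent is not None and _group_in_span(group_col, null_X)

    if latent is None:
        # closed form: group-wise detection rates are the logistic MLE
        ka = detected[:, mask_a].sum(axis=1).astype(float)
        kb = detected[:, mask_b].sum(axis=1).astype(float)
        na, nb = float(mask_a.sum()), float(mask_b.sum())
        ll_full = _binom_ll(ka, na) + _binom_ll(kb, nb)
        ll_null = _binom_ll(ka + kb, na + nb)
        chi2_parts[:, 0] = 2.0 * (ll_full - ll_null)
        df_parts[:, 0] = 1

    for g in range(G):
        det = detected[g]
        if not det.any():
            continue  # all-zero gene: missing p
        if latent is not None and not latent_saturates:
            try:
                stat, _ = _glm_lrt_gene_on_group(
                    det.astype(float), group_col, np.asarray(latent, float),
                    sm.families.Binomial(),
                )
                chi2_parts[g, 0] = max(stat, 0.0)
                df_parts[g, 0] = 1
            except Exception:
                logger.debug("hurdle: discrete part failed for %s", gene_ids[g])
        elif latent_saturates:
            df_parts[g, 0] = 1  # statistic identically 0

        # continuous part on detected cells
        da, db = det & mask_a, det & mask_b
        if da.sum() >= 2 and db.sum() >= 2:
            y = normalized[g, det]
            gc = group_col[det]
            X0 = null_X[det]
            X1 = np.column_stack([X0, gc])
            b0 = np.linalg.lstsq(X0, y, rcond=None)[0]
            b1 = np.linalg.lstsq(X1, y, rcond=None)[0]
            rss0 = float(np.sum((y - X0 @ b0) ** 2))
            rss1 = float(np.sum((y - X1 @ b1) ** 2))
            if rss1 > 0:
                chi2_parts[g, 1] = len(y) * np.log(rss0 / rss1)
                df_parts[g, 1] = 1
        tot_df = int(df_parts[g].sum())
        p[g] = _chi2_sf(float(chi2_parts[g].sum()), tot_df)

    return TestResult(
        method="hurdle", gene_ids=gene_ids, p_value=p, effect=effect,
        tested=np.ones(G, dtype=bool),
        metadata={
            "family": "latent" if latent is not None else "naive",
            "chi2_parts": chi2_parts,
            "df_parts": df_parts,
        },
    )


# ---------------------------------------------------------------------------
# mixed model: Gaussian random intercept per subject
# ---------------------------------------------------------------------------

def _subject_stats(y, subjects):
    labels, inv = np.unique(subjects, return_inverse=True)
    n_i = np.bincount(inv).astype(float)
    sums = np.bincount(inv, weights=y)
    ybar = sums / n_i
    ssw = float(np.sum((y - ybar[inv]) ** 2))
    return labels, inv, n_i, ybar, ssw


def _profiled_m2ll(lam, n_i, ybar, ssw, X, reml):
    """-2 log-likelihood profiled over fixed effects and residual variance.

    The random-intercept model with subject-constant covariates reduces to a
    weighted regression of subject means with weights n_i / (1 + n_i * lam),
    lam = sigma_b^2 / sigma_e^2.
    """
    w = n_i / (1.0 + n_i * lam)
    XtW = X.T * w
    A = XtW @ X
    beta = np.linalg.solve(A, XtW @ ybar)
    r = ybar - X @ beta
    rss = ssw + float(np.sum(w * r * r))
    N = n_i.sum()
    pcol = X.shape[1]
    log_pen = float(np.sum(np.log1p(n_i * lam)))
    if reml:
        s2 = rss / (N - pcol)
        val = ((N - pcol) * (np.log(2 * np.pi * s2) + 1.0) + log_pen
               + float(np.linalg.slogdet(A)[1]))
    else:
        s2 = rss / N
        val = N * (np.log(2 * np.pi * s2) + 1.0) + log_pen
    return val, beta, s2


def _optimize_lambda(n_i, ybar, ssw, X, reml):
    def obj(t):
        return _profiled_m2ll(np.exp(t), n_i, ybar, ssw, X, reml)[0]

    res = minimize_scalar(obj, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    cand = [(res.fun, float(np.exp(res.x)))]
    v0, _, _ = _profiled_m2ll(0.0, n_i, ybar, ssw, X, reml)
    cand.append((v0, 0.0))
    best = min(cand, key=lambda c: c[0])
    return best[1], best[0]


def fit_random_intercept(y, condition, subjects, reml=True) -> dict:
    """Fit ``y ~ condition + (1 | subject)`` by profiled (restricted) likelihood.

    Returns the fixed-effect estimates and the variance components
    ``sigma2_subject`` / ``sigma2_resid``.  ``condition`` must be constant
    within subject.
    """
    y = np.asarray(y, dtype=float)
    mask_a, mask_b, _ = _two_groups(condition)
    labels, inv, n_i, ybar, ssw = _subject_stats(y, subjects)
    x_subj = np.array(
        [float(np.asarray(condition, object)[inv == i][0] ==
               sorted(set(np.asarray(condition, object)))[1]) for i in range(len(labels))]
    )
    for i in range(len(labels)):
        cs = set(np.asarray(condition, object)[inv == i])
        if len(cs) > 1:
            raise ValidationError(f"subject {labels[i]!r} spans both conditions")
    X = np.column_stack([np.ones(len(labels)), x_subj])
    lam, m2ll = _optimize_lambda(n_i, ybar, ssw, X, reml)
    _, beta, s2 = _profiled_m2ll(lam, n_i, ybar, ssw, X, reml)
    return {
        "intercept": float(beta[0]),
        "condition_effect": float(beta[1]),
        "lambda": lam,
        "sigma2_resid": float(s2),
        "sigma2_subject": float(lam * s2),
        "m2ll": float(m2ll),
    }


def lmm_random_intercept_test(normalized, groups, subjects, gene_ids=None) -> TestResult:
    """Gaussian random-intercept mixed model per gene; LRT on condition.

    Variance components come from a profiled likelihood over the ratio
    sigma_b^2 / sigma_e^2; the p-value is the chi-square (df 1)
    likelihood-ratio test of the condition term using maximum-likelihood
    fits.  When the fitted subject variance is zero the test falls back to
    the ordinary two-sample t-test.
    """
    normalized = np.asarray(normalized, dtype=float)
    mask_a, mask_b, _ = _two_groups(groups)
    G = normalized.shape[0]
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(G)]
    subjects = np.asarray(subjects, dtype=object)
    labels, inv = np.unique(subjects, return_inverse=True)
    n_i = np.bincount(inv).astype(float)
    subj_is_b = np.zeros(len(labels))
    for i in range(len(labels)):
        vals = mask_b[inv == i]
        if vals.min() != vals.max():
            raise ValidationError(f"subject {labels[i]!r} spans both conditions")
        subj_is_b[i] = float(vals[0])
    if subj_is_b.sum() < 2 or (len(labels) - subj_is_b.sum()) < 2:
        raise ValidationError("need >= 2 subjects per group")

    X_full = np.column_stack([np.ones(len(labels)), subj_is_b])
    X_null = np.ones((len(labels), 1))
    p = np.empty(G)
    effect = np.empty(G)
    lam_full = np.empty(G)
    for g in range(G):
        y = normalized[g]
        sums = np.bincount(inv, weights=y)
        ybar = sums / n_i
        ssw = float(np.sum((y - ybar[inv]) ** 2))
        lam1, m2ll1 = _optimize_lambda(n_i, ybar, ssw, X_full, reml=False)
        lam_full[g] = lam1
        _, beta, _ = _profiled_m2ll(lam1, n_i, ybar, ssw, X_full, reml=False)
        effect[g] = beta[1]
        if lam1 < 1e-8:
            # singular fit: ordinary two-sample t-test
            res = stats.ttest_ind(y[mask_a], y[mask_b], equal_var=True)
            p[g] = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
            continue
        _, m2ll0 = _optimize_lambda(n_i, ybar, ssw, X_null, reml=False)
        p[g] = _chi2_sf(m2ll0 - m2ll1, 1)
    return TestResult(
        method="lmm", gene_ids=gene_ids, p_value=p, effect=effect,
        tested=np.ones(G, dtype=bool),
        metadata={"family": "mixed", "lambda": lam_full},
    )


# ---------------------------------------------------------------------------
# pseudobulk tests
# ---------------------------------------------------------------------------

def _pb_log_values(pb: PseudobulkMatrix) -> np.ndarray:
    """Log-scale matrix for linear-model pseudobulk tests."""
    if pb.aggregation == "sum" and pb.normalization == "raw":
        f = normagg.tmm_factors(pb)
        return normagg.cpm_log2(pb, f)
    return pb.values


def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = max(x + dif, 1e-8)
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def estimate_prior_df(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled-F law of gene-wise variances.

    Works on log variances: the excess spread of ``log s2`` over the
    chi-square sampling spread determines the prior df d0 (infinite when the
    observed spread is no larger than expected under a common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    z = np.log(s2[ok])
    e = z - polygamma(0, df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    n = len(e)
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0sq = float(np.exp(emean + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def pb_moderated_t(pb: PseudobulkMatrix, d0_override=None, s0sq_override=None) -> TestResult:
    """Gene-wise linear model with empirical-Bayes variance moderation.

    Residual variances are shrunk to the posterior
    ``(d0 * s0^2 + dg * s_g^2) / (d0 + dg)`` with the prior ``(d0, s0^2)``
    estimated by moment matching; the moderated t has ``dg + d0`` degrees of
    freedom.  Sum aggregation is normalized TMM + CPM + log2 first; mean
    aggregation is tested on its values directly.
    """
    cond = pb.conditions
    mask_a, mask_b, _ = _two_groups(cond)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na + nb < 3 or na < 2 or nb < 2:
        raise ValidationError("moderated t needs >= 2 samples per group, >= 3 total")
    values = _pb_log_values(pb)
    ma = values[:, mask_a].mean(axis=1)
    mb = values[:, mask_b].mean(axis=1)
    diff = mb - ma
    df = na + nb - 2
    rss = (
        ((values[:, mask_a] - ma[:, None]) ** 2).sum(axis=1)
        + ((values[:, mask_b] - mb[:, None]) ** 2).sum(axis=1)
    )
    s2 = rss / df
    if d0_override is None:
        d0, s0sq = estimate_prior_df(s2, df)
    else:
        d0 = d0_override
        s0sq = s0sq_override if s0sq_override is not None else float(np.median(s2))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        total_df = np.inf
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        total_df = df + d0
    v = 1.0 / na + 1.0 / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2_post * v)
    p = np.where(
        np.isfinite(t),
        2.0 * stats.t.sf(np.abs(t), total_df),
        np.where(diff == 0, 1.0, 0.0),
    )
    return TestResult(
        method="pb_modt", gene_ids=list(pb.gene_ids), p_value=np.minimum(p, 1.0),
        effect=diff, tested=np.ones(len(pb.gene_ids), dtype=bool),
        metadata={
            "family": "pseudobulk", "aggregation": pb.aggregation,
            "d0": d0, "s0sq": s0sq, "residual_df": df,
        },
    )


def _nb_mom_dispersion(z: np.ndarray, mask_a, mask_b) -> np.ndarray:
    """Pooled within-group method-of-moments NB2 dispersion per gene."""
    na, nb = mask_a.sum(), mask_b.sum()
    ma = z[:, mask_a].mean(axis=1)
    mb = z[:, mask_b].mean(axis=1)
    va = z[:, mask_a].var(axis=1, ddof=1)
    vb = z[:, mask_b].var(axis=1, ddof=1)
    pooled_var = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    mean = (na * ma + nb * mb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (pooled_var - mean) / mean**2
    return np.where(np.isfinite(disp), np.maximum(disp, 0.0), 0.0)


def _dispersion_trend(log_mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Lowess trend of dispersion against log mean abundance."""
    ok = np.isfinite(log_mean)
    if ok.sum() < 10:
        return np.full_like(disp, float(np.median(disp[ok])) if ok.any() else 0.0)
    fit = sm.nonparametric.lowess(
        disp[ok], log_mean[ok], frac=0.5, return_sorted=True
    )
    trend = np.interp(log_mean, fit[:, 0], fit[:, 1])
    trend = np.maximum(trend, 1e-6)
    trend[~ok] = float(np.median(trend[ok]))
    return trend


def pb_nbglm(pb: PseudobulkMatrix, norm: str = "tmm", fixed_dispersion=None) -> TestResult:
    """Per-gene NB GLM on sum pseudobulks with a Wald test on the group term.

    Normalization offsets come from TMM factors times library size or from
    median-of-ratios size factors.  The gene dispersion is a weighted average
    of the gene's method-of-moments estimate and a lowess trend over
    abundance (prior weight equivalent to 10 samples).
    """
    if pb.aggregation != "sum" or pb.normalization != "raw":
        raise ValidationError("pb_nbglm expects sum-aggregated raw counts")
    cond = pb.conditions
    mask_a, mask_b, _ = _two_groups(cond)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValidationError("need >= 2 samples per group")
    if norm == "tmm":
        offset = np.log(pb.library_sizes() * normagg.tmm_factors(pb))
    elif norm == "median_of_ratios":
        offset = np.log(normagg.median_of_ratios_factors(pb))
    else:
        raise ValidationError(f"unknown normalization {norm!r}")

    v = pb.values
    G = v.shape[0]
    size = np.exp(offset - offset.mean())
    z = v / size[None, :]
    if fixed_dispersion is None:
        disp_mom = _nb_mom_dispersion(z, mask_a, mask_b)
        log_mean = np.log(np.maximum(z.mean(axis=1), 1e-8))
        trend = _dispersion_trend(log_mean, disp_mom)
        df = v.shape[1] - 2
        disp = (df * disp_mom + _NB_PRIOR_WEIGHT * trend) / (df + _NB_PRIOR_WEIGHT)
    else:
        disp = np.full(G, float(fixed_dispersion))

    X = np.column_stack([np.ones(v.shape[1]), mask_b.astype(float)])
    p = np.full(G, np.nan)
    effect = np.full(G, np.nan)
    for g in range(G):
        y = v[g]
        if y.sum() == 0:
            continue  # all-zero gene: missing p
        fam = (sm.families.Poisson() if disp[g] <= 1e-10
               else sm.families.NegativeBinomial(alpha=float(disp[g])))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=fam, offset=offset).fit()
            zstat = fit.params[1] / fit.bse[1]
            p[g] = 2.0 * stats.norm.sf(abs(zstat))
            effect[g] = fit.params[1] / np.log(2.0)
        except Exception:
            logger.debug("pb_nbglm: gene %s failed", pb.gene_ids[g])
    return TestResult(
        method=f"pb_nbglm_{norm}", gene_ids=list(pb.gene_ids), p_value=p,
        effect=effect, tested=np.ones(G, dtype=bool),
        metadata={"family": "pseudobulk", "normalization": norm, "dispersion": disp},
    )


def _rots_stat(values, mask_a, mask_b, a1, a2):
    ma = values[:, mask_a].mean(axis=1)
    mb = values[:, mask_b].mean(axis=1)
    na, nb = mask_a.sum(), mask_b.sum()
    rss = (
        ((values[:, mask_a] - ma[:, None]) ** 2).sum(axis=1)
        + ((values[:, mask_b] - mb[:, None]) ** 2).sum(axis=1)
    )
    s = np.sqrt(rss / (na + nb - 2) * (1.0 / na + 1.0 / nb))
    denom = a1 + a2 * s
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.abs(mb - ma) / denom
    return np.where(denom > 0, d, 0.0)


def _topk_overlap(d1, d2, k):
    top1 = np.argpartition(-d1, k - 1)[:k]
    top2 = np.argpartition(-d2, k - 1)[:k]
    return len(np.intersect1d(top1, top2)) / k


def pb_rots(
    pb: PseudobulkMatrix,
    n_bootstrap: int = ROTS_N_BOOTSTRAP,
    toplist_sizes=None,
    seed: int = 0,
) -> TestResult:
    """Reproducibility-optimized test statistic on pseudobulk values.

    The statistic ``|mean_A - mean_B| / (a1 + a2 * s)`` is tuned by choosing
    ``(a1, a2)`` (and the top-list size) to maximize the reproducibility
    Z-score of top-k gene lists between group-preserving bootstrap pairs,
    relative to label-permuted pairs.  P-values come from pooled permutation
    of the selected statistic.
    """
    cond = pb.conditions
    mask_a, mask_b, _ = _two_groups(cond)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na < 3 or nb < 3:
        raise ValidationError("ROTS needs >= 3 samples per group")
    values = _pb_log_values(pb)
    G = values.shape[0]
    if toplist_sizes is None:
        toplist_sizes = [k for k in ROTS_TOPLIST_SIZES if k <= max(G // 2, 1)]
        if not toplist_sizes:
            toplist_sizes = [max(G // 4, 1)]
    rng = np.random.default_rng(seed)
    ia_all = np.flatnonzero(mask_a)
    ib_all = np.flatnonzero(mask_b)
    n = na + nb
    combos = [(a1, a2) for a1 in ROTS_A1_GRID for a2 in ROTS_A2_GRID
              if not (a1 == 0 and a2 == 0)]

    def masks_from(ia, ib):
        cols = np.concatenate([ia, ib])
        sub = values[:, cols]
        m_a = np.zeros(len(cols), dtype=bool)
        m_a[: len(ia)] = True
        return sub, m_a, ~m_a

    obs_overlap = np.zeros((len(combos), len(toplist_sizes), n_bootstrap))
    null_overlap = np.zeros_like(obs_overlap)
    labels = np.concatenate([ia_all, ib_all])
    for b in range(n_bootstrap):
        pair_d = []
        for _ in range(2):
            ia = rng.choice(ia_all, na, replace=True)
            ib = rng.choice(ib_all, nb, replace=True)
            sub, m_a, m_b = masks_from(ia, ib)
            pair_d.append([_rots_stat(sub, m_a, m_b, a1, a2) for a1, a2 in combos])
        perm = rng.permutation(labels)
        pia, pib = perm[:na], perm[na:]
        null_d = []
        for _ in range(2):
            ia = rng.choice(pia, na, replace=True)
            ib = rng.choice(pib, nb, replace=True)
            sub, m_a, m_b = masks_from(ia, ib)
            null_d.append([_rots_stat(sub, m_a, m_b, a1, a2) for a1, a2 in combos])
        for ci in range(len(combos)):
            for ki, k in enumerate(toplist_sizes):
                obs_overlap[ci, ki, b] = _topk_overlap(pair_d[0][ci], pair_d[1][ci], k)
                null_overlap[ci, ki, b] = _topk_overlap(null_d[0][ci], null_d[1][ci], k)

    r_obs = obs_overlap.mean(axis=2)
    r_null = null_overlap.mean(axis=2)
    s_null = null_overlap.std(axis=2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        zscores = (r_obs - r_null) / s_null
    zscores = np.where(np.isfinite(zscores), zscores, -np.inf)
    ci, ki = np.unravel_index(np.argmax(zscores), zscores.shape)
    a1, a2 = combos[ci]

    d_obs = _rots_stat(values, mask_a, mask_b, a1, a2)
    pooled = []
    for _ in range(n_bootstrap):
        perm = rng.permutation(labels)
        sub, m_a, m_b = masks_from(perm[:na], perm[na:])
        pooled.append(_rots_stat(sub, m_a, m_b, a1, a2))
    pooled = np.sort(np.concatenate(pooled))
    n_null = pooled.size
    ge = n_null - np.searchsorted(pooled, d_obs, side="left")
    p = (1.0 + ge) / (1.0 + n_null)

    ma = values[:, mask_a].mean(axis=1)
    mb = values[:, mask_b].mean(axis=1)
    return TestResult(
        method="pb_rots", gene_ids=list(pb.gene_ids), p_value=np.minimum(p, 1.0),
        effect=mb - ma, tested=np.ones(G, dtype=bool),
        metadata={
            "family": "pseudobulk", "aggregation": pb.aggregation,
            "a1": a1, "a2": a2, "toplist_size": toplist_sizes[ki],
            "z": float(zscores[ci, ki]),
        },
    )


# ---------------------------------------------------------------------------
# method registry: name -> (filter, pipeline)
# ---------------------------------------------------------------------------

def _expand_result(res: TestResult, all_gene_ids: list[str], method: str) -> TestResult:
    """Map a result on filtered genes back onto the full gene universe."""
    pos = {g: i for i, g in enumerate(res.gene_ids)}
    G = len(all_gene_ids)
    p = np.full(G, np.nan)
    eff = np.full(G, np.nan)
    tested = np.zeros(G, dtype=bool)
    for i, g in enumerate(all_gene_ids):
        j = pos.get(g)
        if j is not None:
            p[i], eff[i], tested[i] = res.p_value[j], res.effect[j], res.tested[j]
    meta = dict(res.metadata)
    return TestResult(method=method, gene_ids=list(all_gene_ids),
                      p_value=p, effect=eff, tested=tested, metadata=meta)


_METHOD_FILTERS = {
    "wilcoxon": ("nonexpressed", {}),
    "lr": ("nonexpressed", {}),
    "lr_latent": ("nonexpressed", {}),
    "hurdle": ("nonexpressed", {}),
    "hurdle_latent": ("nonexpressed", {}),
    "poisson": ("min_cells_expressing", {"k": 3}),
    "poisson_latent": ("min_cells_expressing", {"k": 3}),
    "negbinom": ("min_cells_expressing", {"k": 3}),
    "negbinom_latent": ("min_cells_expressing", {"k": 3}),
    "lmm": ("min_cells_expressing_and_min_cells_per_sample", {"k": 20, "m": 10}),
    "pb_modt_sum": ("nonexpressed", {}),
    "pb_modt_mean": ("nonexpressed", {}),
    "pb_nbglm_tmm": ("nonexpressed", {}),
    "pb_nbglm_mor": ("nonexpressed", {}),
    "pb_rots_sum": ("nonexpressed", {}),
    "pb_rots_mean": ("nonexpressed", {}),
}

METHOD_NAMES = tuple(_METHOD_FILTERS)


def run_method(data: CellCountMatrix, name: str, seed: int = 0) -> TestResult:
    """Run one named method end to end: filter, normalize, aggregate, test.

    The result covers every gene of ``data``; genes removed by the method's
    filter carry a missing p-value and ``tested = False``.
    """
    if name not in _METHOD_FILTERS:
        raise ValidationError(f"unknown method {name!r}; known: {sorted(_METHOD_FILTERS)}")
    rule, params = _METHOD_FILTERS[name]
    sub, _ = normagg.apply_gene_filter(data, rule, **params)
    groups = sub.condition_of_cells()
    gene_ids = list(sub.gene_ids)

    if name in ("wilcoxon", "lr", "lr_latent", "hurdle", "hurdle_latent", "lmm"):
        norm = normagg.lognormalize(sub)
    if name == "wilcoxon":
        res = wilcoxon_test(norm, groups, gene_ids)
    elif name in ("lr", "lr_latent"):
        latent = subject_dummies(sub.cell_to_sample) if name.endswith("latent") else None
        res = lr_test(norm, groups, latent=latent, gene_ids=gene_ids)
    elif name in ("hurdle", "hurdle_latent"):
        latent = subject_dummies(sub.cell_to_sample) if name.endswith("latent") else None
        res = hurdle_test(norm, groups, latent=latent, gene_ids=gene_ids)
    elif name in ("poisson", "poisson_latent"):
        latent = subject_dummies(sub.cell_to_sample) if name.endswith("latent") else None
        res = poisson_glm_test(sub.counts, groups, latent=latent, gene_ids=gene_ids)
    elif name in ("negbinom", "negbinom_latent"):
        latent = subject_dummies(sub.cell_to_sample) if name.endswith("latent") else None
        res = negbinom_glm_test(sub.counts, groups, latent=latent, gene_ids=gene_ids)
    elif name == "lmm":
        res = lmm_random_intercept_test(norm, groups, sub.cell_to_sample, gene_ids)
    elif name in ("pb_modt_sum", "pb_nbglm_tmm", "pb_nbglm_mor", "pb_rots_sum"):
        pbm = normagg.aggregate_sum(sub)
        if name == "pb_modt_sum":
            res = pb_moderated_t(pbm)
        elif name == "pb_nbglm_tmm":
            res = pb_nbglm(pbm, norm="tmm")
        elif name == "pb_nbglm_mor":
            res = pb_nbglm(pbm, norm="median_of_ratios")
        else:
            res = pb_rots(pbm, seed=seed)
    elif name in ("pb_modt_mean", "pb_rots_mean"):
        pbm = normagg.aggregate_mean(normagg.lognormalize(sub), sub)
        res = pb_moderated_t(pbm) if name == "pb_modt_mean" else pb_rots(pbm, seed=seed)
    else:  # pragma: no cover
        raise AssertionError(name)
    out = _expand_result(res, list(data.gene_ids), method=name)
    out.metadata["filter_rule"] = rule
    return out
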