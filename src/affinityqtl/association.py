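"""Association testing between CRM affinity variants and gene expression.

Two approaches are implemented, both fitting one regression per gene on
rank-transformed expression residuals with one predictor per linked
(CRM, TF) affinity variant:

*Thresholded*: haplotypes are classified low/high affinity around a
dynamic threshold derived from the hard cut-off -0.3 (canonical log FCA,
affinity-reducing negative), individuals are encoded as the number of
low-affinity allele copies, and an OLS model is tested gene-wise by an
ANOVA F-test with Benjamini-Hochberg FDR across genes; per-variant
coefficient t-tests identify the driving variants.

*Threshold-free*: each individual's predictor is the sum of log FCA over
their two haplotypes; the gene-level screen is the same OLS ANOVA + FDR,
and for significant genes with multiple (often collinear) predictors the
per-variant calls come from an elastic-net path (quadratic penalty
weight lambda2 fixed at 0.5, solved as a lasso on ridge-augmented data)
with the covariance test for adaptive linear models, whose statistic for
each predictor entering the path is compared to an Exp(1) reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lars_path
from statsmodels.stats.multitest import multipletests

from .affinity import AffinityVariant
from .crm import HaplotypeSet

logger = logging.getLogger(__name__)

HARD_THRESHOLD = -0.3
DEFAULT_GENE_FDR = 0.10
DEFAULT_COEF_ALPHA = 0.05
DEFAULT_LAMBDA2 = 0.5
COLLAPSE_R = 0.99

__all__ = [
    "HaplotypeClass",
    "GeneAssociationResult",
    "filter_expressed",
    "rank_transform",
    "classify_haplotypes",
    "encode_dosage",
    "collapse_correlated",
    "fit_gene_model_thresholded",
    "fdr_and_coefficients",
    "build_threshold_free_predictors",
    "elastic_net_covariance_test",
    "fit_gene_model_elastic_net",
]


# ---------------------------------------------------------------------------
# expression preprocessing


def filter_expressed(counts: pd.DataFrame) -> list:
    """Genes with zero counts in at most 50% of samples (strict > removed)."""
    n = counts.shape[1]
    zero_frac = (counts == 0).sum(axis=1) / n
    return list(counts.index[zero_frac <= 0.5])


def rank_transform(values) -> np.ndarray:
    """Rank-transform a vector to the standard normal scale.

    ``value_i = Phi^-1((rank_i - 0.5) / n)`` with average ranks for ties;
    a monotone transform of the input leaves the output unchanged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("rank transform needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant vector cannot be rank-transformed")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / x.size)


# ---------------------------------------------------------------------------
# thresholded approach


@dataclass(frozen=True)
class HaplotypeClass:
    """Low/high/unclassified labels for one affinity variant's haplotypes."""

    crm_id: str
    tf: str
    labels: tuple  # "low" | "high" | "unclassified" per haplotype
    threshold: float  # dynamic threshold log FCA_0 (canonical scale)


def classify_haplotypes(
    variant: AffinityVariant, hard_threshold: float = HARD_THRESHOLD
) -> HaplotypeClass | None:
    """Classify haplotypes as low/high affinity around a dynamic threshold.

    On the canonical scale (affinity-reducing negative), the dynamic
    threshold is ``log FCA_0 = 0.8 * P85({s : s <= hard_threshold})``
    (85th percentile, linear interpolation).  Low: ``s <= log FCA_0``.
    High: ``s > log FCA_0 / 4`` when ``log FCA_0 / 4 > hard_threshold``,
    otherwise ``s > hard_threshold``.  Anything between stays
    unclassified.  Returns None when no haplotype reaches the hard
    threshold (the variant is dropped).
    """
    if variant.sign_convention != "canonical":
        raise ValueError("classification expects canonical-sign scores")
    scores = np.asarray(variant.log_fca, dtype=float)
    if scores.size < 2:
        return None
    below = scores[scores <= hard_threshold]
    if below.size == 0:
        return None
    log_fca0 = 0.8 * float(np.percentile(below, 85))
    high_cut = log_fca0 / 4 if log_fca0 / 4 > hard_threshold else hard_threshold
    labels = tuple(
        "low" if s <= log_fca0 else ("high" if s > high_cut else "unclassified")
        for s in scores
    )
    return HaplotypeClass(variant.crm_id, variant.tf, labels, log_fca0)


def encode_dosage(classes: HaplotypeClass, hapset: HaplotypeSet) -> np.ndarray:
    """Per-individual count of low-affinity alleles (NaN = excluded).

    Individuals carrying at least one unclassified haplotype are excluded
    (NaN) for this variant, and thereby from any gene model containing it.
    """
    hap_of_chrom = hapset.haplotype_of_chromosome()
    n_ind = hap_of_chrom.size // 2
    out = np.empty(n_ind)
    for i in range(n_ind):
        labs = (
            classes.labels[hap_of_chrom[2 * i]],
            classes.labels[hap_of_chrom[2 * i + 1]],
        )
        if "unclassified" in labs:
            out[i] = np.nan
        else:
            out[i] = labs.count("low")
    return out


def collapse_correlated(X: pd.DataFrame, r_max: float = COLLAPSE_R):
    """Collapse predictor columns in near-perfect correlation (|r| > r_max).

    Greedy left-to-right: each column joins the group of the first earlier
    representative it correlates with beyond ``r_max`` in absolute value.
    Returns the reduced matrix and a ``representative -> members`` map.
    """
    reps: list[str] = []
    groups: dict[str, list] = {}
    for col in X.columns:
        x = X[col].to_numpy()
        joined = None
        for rep in reps:
            r = np.corrcoef(X[rep].to_numpy(), x)[0, 1]
            if np.isfinite(r) and abs(r) > r_max:
                joined = rep
                break
        if joined is None:
            reps.append(col)
            groups[col] = [col]
        else:
            groups[joined].append(col)
    return X[reps], groups


@dataclass
class GeneAssociationResult:
    gene: str
    approach: str  # "thresholded" | "threshold_free"
    n: int
    anova_p: float
    variant_stats: pd.DataFrame = field(repr=False)  # variant, beta, p
    groups: dict = field(default_factory=dict, repr=False)
    fdr_q: float = np.nan


def _drop_rank_deficient(X: pd.DataFrame) -> pd.DataFrame:
    """Greedily drop columns that do not increase the design rank."""
    Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    keep: list[int] = []
    rank = 0
    for j in range(Xc.shape[1]):
        cand = Xc[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > rank:
            keep.append(j)
            rank += 1
        else:
            logger.warning("dropping rank-deficient predictor %s", X.columns[j])
    return X.iloc[:, keep]


def _ols_fit(y: np.ndarray, X: pd.DataFrame):
    """OLS with intercept: returns (betas, coef p-values, ANOVA F p, sigma2)."""
    n, k = X.shape
    design = np.column_stack([np.ones(n), X.to_numpy()])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    df_resid = n - (k + 1)
    rss = float(resid @ resid)
    sigma2 = rss / df_resid
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    coef_p = 2 * stats.t.sf(np.abs(tvals), df_resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0 or rss >= tss:
        f_p = 1.0
    else:
        f = ((tss - rss) / k) / (rss / df_resid)
        f_p = float(stats.f.sf(f, k, df_resid))
    return beta[1:], coef_p[1:], f_p, sigma2


def fit_gene_model_thresholded(
    y: np.ndarray, X: pd.DataFrame, gene: str = ""
) -> GeneAssociationResult:
    """OLS of expression on low-affinity dosages with gene-level ANOVA.

    Columns of ``X`` are per-variant dosages (ordered by genomic
    position); near-duplicate predictors (|Pearson r| > 0.99) are first
    collapsed to their leftmost representative.  Rows with any missing
    dosage (excluded individuals) are dropped (complete-case).
    """
    mask = ~X.isna().any(axis=1).to_numpy()
    y = np.asarray(y, dtype=float)[mask]
    Xm = X.loc[mask]
    Xr, groups = collapse_correlated(Xm)
    Xr = _drop_rank_deficient(Xr)
    n, k = Xr.shape
    if k == 0 or n <= k + 1:
        raise ValueError(
            f"gene {gene}: {n} complete cases cannot support {k} predictors"
        )
    betas, coef_p, f_p, _ = _ols_fit(y, Xr)
    variant_stats = pd.DataFrame(
        {"variant": list(Xr.columns), "beta": betas, "p": coef_p}
    )
    return GeneAssociationResult(
        gene=gene,
        approach="thresholded",
        n=n,
        anova_p=f_p,
        variant_stats=variant_stats,
        groups=groups,
    )


def fdr_and_coefficients(
    gene_results,
    gene_fdr: float = DEFAULT_GENE_FDR,
    coef_alpha: float = DEFAULT_COEF_ALPHA,
) -> pd.DataFrame:
    """BH q-values over gene ANOVA p; report variant hits in passing genes.

    Fills ``fdr_q`` on each result in place and returns the significant
    (gene, variant) table: genes with ``q <= gene_fdr`` contribute every
    variant with unadjusted coefficient ``p < coef_alpha``.
    """
    results = list(gene_results)
    if not results:
        return pd.DataFrame(columns=["gene", "variant", "beta", "p", "q"])
    pvals = np.array([r.anova_p for r in results])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    rows = []
    for r, q in zip(results, qvals):
        r.fdr_q = float(q)
        if q <= gene_fdr:
            hits = r.variant_stats[r.variant_stats["p"] < coef_alpha]
            for h in hits.itertuples():
                rows.append(
                    {
                        "gene": r.gene,
                        "variant": h.variant,
                        "beta": h.beta,
                        "p": h.p,
                        "q": float(q),
                    }
                )
    return pd.DataFrame(rows, columns=["gene", "variant", "beta", "p", "q"])


# ---------------------------------------------------------------------------
# threshold-free approach


def build_threshold_free_predictors(
    variant: AffinityVariant, hapset: HaplotypeSet
) -> np.ndarray:
    """Per-individual sum of log FCA over the two carried haplotypes."""
    scores = np.asarray(variant.log_fca, dtype=float)
    hap_of_chrom = hapset.haplotype_of_chromosome()
    per_chrom = scores[hap_of_chrom]
    return per_chrom[0::2] + per_chrom[1::2]


def _interp_coefs(alphas: np.ndarray, coefs: np.ndarray, alpha: float) -> np.ndarray:
    """Piecewise-linear path coefficients at penalty ``alpha``.

    ``alphas`` decreasing as returned by :func:`lars_path`; beyond the
    first knot coefficients are zero (edge clamp handles it as the first
    knot's coefficients are zero for entering variables).
    """
    xs = alphas[::-1]
    return np.array(
        [np.interp(alpha, xs, coefs[j, ::-1]) for j in range(coefs.shape[0])]
    )


def elastic_net_covariance_test(
    y: np.ndarray,
    X: pd.DataFrame,
    lambda2: float = DEFAULT_LAMBDA2,
    sigma2: float | None = None,
    max_steps: int | None = None,
) -> pd.DataFrame:
    """Covariance test along the elastic-net path with fixed lambda2.

    The elastic net with quadratic penalty weight ``lambda2`` is solved
    as a lasso on ridge-augmented data (``sqrt(lambda2) * I`` rows
    appended to the standardized design, zeros to the response).  At
    every path knot where a predictor enters, the covariance statistic

        T = (1 + lambda2) * (<y_a, X_a b(l_next)> - <y_a, X_A b_A(l_next)>) / sigma^2

    is computed, where ``b_A`` is the path fitted on the previously
    active set only; the ``1 + lambda2`` factor undoes the naive
    elastic-net shrinkage so that T matches the lasso statistic exactly
    in orthogonal designs and follows its Exp(1) null reference.
    ``sigma2`` defaults to the residual variance of the full OLS fit
    (requires n > K + 1).  ``max_steps`` truncates the path after that
    many LARS steps (useful when only the first entries matter).

    Returns one row per entry event: variant, order, T, p (Exp(1) tail),
    and whether the predictor is active at the path end.
    """
    y = np.asarray(y, dtype=float)
    n, K = X.shape
    if K < 1:
        raise ValueError("need at least one predictor")
    if sigma2 is None:
        if n <= K + 1:
            raise ValueError(
                f"cannot estimate sigma^2 with n={n} <= K+1={K + 1}; "
                "reduce predictors or supply sigma2"
            )
        _, _, _, sigma2 = _ols_fit(y, X)
    yc = y - y.mean()
    Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    if (norms == 0).any():
        raise ValueError("constant predictor column")
    Xs = Xc / norms
    Xa = np.vstack([Xs, np.sqrt(lambda2) * np.eye(K)])
    ya = np.concatenate([yc, np.zeros(K)])

    lars_kwargs = {} if max_steps is None else {"max_iter": max_steps}
    alphas, _, coefs = lars_path(
        Xa, ya, method="lasso", alpha_min=0.0, **lars_kwargs
    )

    rows = []
    order = 0
    seen: set[int] = set()
    for k in range(len(alphas) - 1):
        prev_active = set(np.flatnonzero(coefs[:, k]))
        next_active = set(np.flatnonzero(coefs[:, k + 1]))
        new = sorted((next_active - prev_active) - seen)
        if not new:
            continue
        seen.update(new)
        alpha_next = alphas[k + 1]
        full_fit = float(ya @ (Xa @ coefs[:, k + 1]))
        if prev_active:
            A = sorted(prev_active)
            a_alphas, _, a_coefs = lars_path(
                Xa[:, A], ya, method="lasso", alpha_min=0.0
            )
            beta_a = _interp_coefs(a_alphas, a_coefs, alpha_next)
            reduced_fit = float(ya @ (Xa[:, A] @ beta_a))
        else:
            reduced_fit = 0.0
        T = (1.0 + lambda2) * (full_fit - reduced_fit) / sigma2
        T = max(T, 0.0)
        for j in new:
            order += 1
            rows.append(
                {
                    "variant": X.columns[j],
                    "order": order,
                    "T": T,
                    "p": float(np.exp(-T)),
                }
            )
    final_active = set(np.flatnonzero(coefs[:, -1]))
    final_beta = coefs[:, -1] / norms * (1.0 + lambda2)
    out = pd.DataFrame(rows, columns=["variant", "order", "T", "p"])
    out["in_final_model"] = [
        X.columns.get_loc(v) in final_active for v in out["variant"]
    ]
    out["beta"] = [final_beta[X.columns.get_loc(v)] for v in out["variant"]]
    return out


def fit_gene_model_elastic_net(
    y: np.ndarray,
    X: pd.DataFrame,
    gene: str = "",
    lambda2: float = DEFAULT_LAMBDA2,
    coef_alpha: float = DEFAULT_COEF_ALPHA,
) -> GeneAssociationResult:
    """Per-variant significance for one threshold-free gene model.

    With a single predictor the OLS coefficient t-test is used; with
    several, predictors entering the elastic-net path with covariance
    test ``p < coef_alpha`` *and* active in the final model are reported.
    The gene-level ANOVA is always the full OLS screen.
    """
    y = np.asarray(y, dtype=float)
    n, K = X.shape
    betas, coef_p, f_p, _ = _ols_fit(y, X)
    if K == 1:
        variant_stats = pd.DataFrame(
            {"variant": list(X.columns), "beta": betas, "p": coef_p}
        )
    else:
        path = elastic_net_covariance_test(y, X, lambda2=lambda2)
        sig = path[path["in_final_model"]]
        variant_stats = sig[["variant", "beta", "p"]].reset_index(drop=True)
    return GeneAssociationResult(
        gene=gene,
        approach="threshold_free",
        n=n,
        anova_p=f_p,
        variant_stats=variant_stats,
    )
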