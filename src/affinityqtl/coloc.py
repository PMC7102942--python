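"""Bayesian colocalization of two association signals over one region.

Given per-SNP summary statistics (effect, standard error) for two
quantitative traits over the same variant set, approximate Bayes factors
(ABFs) for each SNP being causal are combined into posterior
probabilities of five mutually exclusive hypotheses: no causal variant
for either trait (H0), a causal variant for the first trait only (H1),
for the second only (H2), two distinct causal variants (H3), and one
shared causal variant (H4).  The model assumes at most one causal
variant per trait in the region; multiple independent signals are
handled by conditioning each signal's trait on the lead variants of the
other signals before re-running the colocalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

#: default prior SD of a standardized quantitative-trait effect
DEFAULT_PRIOR_SD = 0.15
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # p1, p2, p12

__all__ = [
    "ColocResult",
    "abf",
    "snp_summaries",
    "coloc_pp",
    "condition_out",
    "binomial_prior_expectation",
    "simulate_shared_individuals",
]


@dataclass(frozen=True)
class ColocResult:
    pp: tuple  # PP0..PP4
    priors: tuple  # (p1, p2, p12)

    def __post_init__(self) -> None:
        pp = np.asarray(self.pp)
        if pp.size != 5 or not np.isclose(pp.sum(), 1.0, atol=1e-9):
            raise ValueError("posterior probabilities must be 5 values summing to 1")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def modal_hypothesis(self) -> int:
        return int(np.argmax(self.pp))


def abf(beta, se, prior_sd: float = DEFAULT_PRIOR_SD):
    """Log approximate Bayes factor for a causal effect at one SNP.

    ``log ABF = 0.5 * (log(1 - r) + r * z^2)`` with ``z = beta / se``
    and ``r = prior_sd^2 / (prior_sd^2 + se^2)``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    z = beta / se
    r = prior_sd**2 / (prior_sd**2 + se**2)
    return 0.5 * (np.log1p(-r) + r * z**2)


def snp_summaries(y: np.ndarray, genotypes: np.ndarray, trait: str = "") -> pd.DataFrame:
    """Marginal per-SNP regression summaries of ``y`` on dosage columns.

    ``genotypes`` is (n individuals, m SNPs) of 0/1/2 dosages.  Returns a
    DataFrame with columns snp, beta, se, maf, n (one row per SNP).
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    yc = y - y.mean()
    Gc = G - G.mean(axis=0)
    var_g = (Gc**2).sum(axis=0)
    if (var_g == 0).any():
        raise ValueError("monomorphic SNP in summary computation")
    beta = Gc.T @ yc / var_g
    resid_ss = (yc**2).sum() - beta**2 * var_g
    se = np.sqrt(np.maximum(resid_ss / (n - 2), 0) / var_g)
    freq = G.mean(axis=0) / 2
    return pd.DataFrame(
        {
            "snp": [f"snp_{j}" for j in range(m)],
            "beta": beta,
            "se": se,
            "maf": np.minimum(freq, 1 - freq),
            "n": n,
        }
    )


def coloc_pp(
    summary1: pd.DataFrame,
    summary2: pd.DataFrame,
    priors: tuple = DEFAULT_PRIORS,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> ColocResult:
    """Posterior probabilities of hypotheses H0..H4 for two traits.

    ``summary1``/``summary2`` need columns ``snp``, ``beta``, ``se`` over
    an identical SNP set; ``priors = (p1, p2, p12)`` are the per-SNP
    prior probabilities of association with trait 1 only, trait 2 only,
    and both.
    """
    if len(summary1) != len(summary2) or len(summary1) < 2:
        raise ValueError("need matched summaries over >= 2 SNPs")
    if not (summary1["snp"].to_numpy() == summary2["snp"].to_numpy()).all():
        raise ValueError("SNP sets of the two traits must match")
    p1, p2, p12 = priors
    lbf1 = abf(summary1["beta"].to_numpy(), summary1["se"].to_numpy(), prior_sd)
    lbf2 = abf(summary2["beta"].to_numpy(), summary2["se"].to_numpy(), prior_sd)
    l1 = logsumexp(lbf1)
    l2 = logsumexp(lbf2)
    l12 = logsumexp(lbf1 + lbf2)
    # sum over i != j of exp(lbf1_i + lbf2_j) = exp(l1 + l2) - exp(l12)
    both = l1 + l2
    if both > l12:
        l3 = both + np.log1p(-np.exp(l12 - both))
    else:  # degenerate two-SNP corner: no mass off the diagonal
        l3 = -np.inf
    lh = np.array(
        [
            0.0,
            np.log(p1) + l1,
            np.log(p2) + l2,
            np.log(p1) + np.log(p2) + l3,
            np.log(p12) + l12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    return ColocResult(pp=tuple(pp / pp.sum()), priors=tuple(priors))


def condition_out(y: np.ndarray, leads: np.ndarray) -> np.ndarray:
    """Residualize ``y`` on lead-variant columns (plus intercept).

    Collinear lead columns are dropped with a warning; the returned
    residuals are used to recompute per-SNP summaries before re-running
    :func:`coloc_pp` for a secondary signal.
    """
    import logging

    y = np.asarray(y, dtype=float)
    L = np.atleast_2d(np.asarray(leads, dtype=float))
    if L.shape[0] != y.size:
        L = L.T
    design = np.column_stack([np.ones(y.size), L])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logging.getLogger(__name__).warning(
            "collinear lead variants; dropping dependent columns"
        )
        keep = [0]
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, keep + [j]]) > len(keep):
                keep.append(j)
        design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def binomial_prior_expectation(n: int) -> float:
    """Expected causal-variant count under a Bin(n, 2/n) prior: exactly 2.

    Documents the fine-mapping prior on the number of causal variants per
    region (n = variants in the window), whose expectation is n * (2/n).
    """
    if n < 2:
        raise ValueError("prior requires at least 2 variants in the region")
    return n * (2.0 / n)


def _ld_genotypes(rng, n: int, m: int, maf_low=0.1, maf_high=0.5, ld_rho=0.0):
    """Phased-haplotype dosages with optional adjacent-SNP LD."""
    freqs = rng.uniform(maf_low, maf_high, size=m)
    haps = np.empty((2 * n, m), dtype=np.int8)
    haps[:, 0] = rng.random(2 * n) < freqs[0]
    for j in range(1, m):
        copy = rng.random(2 * n) < ld_rho
        fresh = rng.random(2 * n) < freqs[j]
        haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
    return (haps[0::2] + haps[1::2]).astype(float)


def simulate_shared_individuals(
    n: int,
    effect_size: float,
    error_correlations,
    n_snps: int = 200,
    n_reps: int = 50,
    seed: int = 0,
    shared_causal: bool = True,
    priors: tuple = DEFAULT_PRIORS,
) -> pd.DataFrame:
    """Robustness of colocalization to correlated errors on shared samples.

    Two quantitative traits are measured on the *same* ``n`` individuals
    with residuals correlated at each level in ``error_correlations``
    (each in [0, 1)); with ``shared_causal`` a single SNP carries
    ``effect_size`` in both traits.  Returns one row per (correlation,
    replicate) with the PP0..PP4 posteriors, from which the PP4
    distribution across correlation levels can be compared.
    """
    rows = []
    for rho in error_correlations:
        if not 0 <= rho < 1:
            raise ValueError("error correlation must lie in [0, 1)")
        for rep in range(n_reps):
            rng = np.random.default_rng(seed * 100_003 + rep * 101 + int(rho * 1000))
            G = _ld_genotypes(rng, n, n_snps, ld_rho=0.3)
            cov = np.array([[1.0, rho], [rho, 1.0]])
            eps = rng.multivariate_normal([0, 0], cov, size=n)
            if shared_causal:
                causal = rng.integers(n_snps)
                g = (G[:, causal] - G[:, causal].mean()) / G[:, causal].std()
                y1 = effect_size * g + eps[:, 0]
                y2 = effect_size * g + eps[:, 1]
            else:
                y1, y2 = eps[:, 0], eps[:, 1]
            res = coloc_pp(
                snp_summaries(y1, G), snp_summaries(y2, G), priors=priors
            )
            rows.append(
                {
                    "correlation": rho,
                    "rep": rep,
                    **{f"pp{h}": res.pp[h] for h in range(5)},
                }
            )
    return pd.DataFrame(rows)
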