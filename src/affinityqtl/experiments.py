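"""Validation experiments for the whole pipeline.

Each function runs one self-contained experiment at a fixed problem size
and returns a dict of plain-float metrics.  They are used both by the
acceptance test-suite and by ``scripts/acceptance.py``; the problem
sizes are chosen so the full set completes in minutes on one CPU (the
methods note records them).
"""

from __future__ import annotations

import collections

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import genextreme

from . import association as assoc
from .affinity import (
    fit_gev_scores,
    trap_affinity,
    trap_affinity_naive,
)
from .coloc import (
    _ld_genotypes,
    binomial_prior_expectation,
    coloc_pp,
    simulate_shared_individuals,
    snp_summaries,
)
from .enrichment import matched_permutation_enrichment
from .pipeline import driver_snp_table, evaluate_recovery, run_pipeline
from .pwm import BASES, PWM
from .synthetic import (
    SyntheticConfig,
    generate_accessibility_fixture,
    generate_pwms,
)

__all__ = [
    "trap_oracle_experiment",
    "gev_calibration_experiment",
    "classification_hand_cases",
    "anova_type1_experiment",
    "pipeline_null_fdr_experiment",
    "covariance_test_calibration_experiment",
    "recovery_experiment",
    "enrichment_experiment",
    "coloc_experiment",
    "prior_expectation_check",
]


def _random_pwm(rng) -> PWM:
    width = int(rng.integers(4, 13))
    freqs = rng.dirichlet(np.ones(4), size=width).T
    if rng.random() < 0.3:  # exercise exact zeros
        j = int(rng.integers(width))
        col = freqs[:, j]
        col[int(np.argmin(col))] = 0.0
        freqs[:, j] = col / col.sum()
    return PWM(tf="t", motif_id="m", freqs=freqs)


def trap_oracle_experiment(seed: int = 0, n_pairs: int = 100) -> dict:
    """Vectorized TRAP affinity vs the brute-force double loop."""
    rng = np.random.default_rng(seed)
    max_rel_err = 0.0
    for _ in range(n_pairs):
        pwm = _random_pwm(rng)
        length = int(rng.integers(pwm.width, 120))
        seq = "".join(rng.choice(list(BASES), size=length))
        fast = trap_affinity(seq, pwm)
        slow = trap_affinity_naive(seq, pwm)
        denom = max(abs(slow), 1e-300)
        max_rel_err = max(max_rel_err, abs(fast - slow) / denom)
    return {"max_rel_err": max_rel_err, "n": n_pairs}


def _echo_genome(rng, pwms, length: int, spacing: int = 1500) -> str:
    """Random genome with degraded motif copies (background realism)."""
    genome = rng.integers(0, 4, size=length)
    for _ in range(length // spacing):
        pwm = pwms[int(rng.integers(len(pwms)))]
        echo = pwm.freqs.argmax(axis=0).copy()
        for j in rng.choice(pwm.width, size=int(rng.integers(2, 5)), replace=False):
            echo[j] = rng.integers(0, 4)
        pos = int(rng.integers(0, length - pwm.width))
        genome[pos : pos + pwm.width] = echo
    return "".join(BASES[int(b)] for b in genome)


def gev_calibration_experiment(
    seed: int = 0,
    lengths=(100, 200, 500),
    n_sequences: int = 5000,
    n_motifs: int = 2,
) -> dict:
    """Empirical exceedance calibration of the fitted GEV background.

    For each motif and standard length, ``n_sequences`` genomic
    background segments are scored, the GEV is fitted, and the fraction
    of scores with A < q is compared with q for q in {0.01, 0.05, 0.1}.
    """
    rng = np.random.default_rng(seed)
    pwms = generate_pwms(max(n_motifs, 2), (8, 12), seed=seed + 1)
    pwms = [p for p in pwms if p.motif_id.endswith("m0")][:n_motifs]
    genome = _echo_genome(rng, pwms, 400_000)
    qs = (0.01, 0.05, 0.1)
    max_dev = 0.0
    for pwm in pwms:
        for L in lengths:
            starts = rng.integers(0, len(genome) - L, size=n_sequences)
            scores = np.array(
                [trap_affinity(genome[s : s + L], pwm) for s in starts]
            )
            log_scores = np.log(scores[scores > 0])
            c, loc, scale = fit_gev_scores(log_scores)
            A = genextreme.sf(log_scores, c, loc=loc, scale=scale)
            for q in qs:
                max_dev = max(max_dev, abs(float((A < q).mean()) - q))
    return {"max_abs_calibration_dev": max_dev, "n": n_sequences}


def classification_hand_cases() -> dict:
    """The three worked dynamic-threshold classification examples."""
    from .affinity import AffinityVariant

    def classify(scores):
        av = AffinityVariant(
            crm_id="c",
            tf="t",
            log_fca=tuple(scores),
            ref_best_a=0.01,
            ref_best_haplotype=0,
            invariant=False,
        )
        return assoc.classify_haplotypes(av)

    c1 = classify([0.0, -1.0])
    ok1 = c1.labels == ("high", "low") and np.isclose(c1.threshold, -0.8)
    c2 = classify([0.0, -0.5])
    ok2 = c2.labels == ("high", "low") and np.isclose(c2.threshold, -0.4)
    c3 = classify([0.0, -0.25, -1.0])
    ok3 = c3.labels == ("high", "unclassified", "low")
    return {"hand_cases_passed": float(sum(int(bool(k)) for k in (ok1, ok2, ok3))), "n": 3}


def anova_type1_experiment(
    seed: int = 0, n_genes: int = 1000, n: int = 200, k: int = 2
) -> dict:
    """Gene-level ANOVA rejection rate on independent null genes."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_genes):
        X = pd.DataFrame(
            {f"v{j}": rng.binomial(2, 0.3, size=n).astype(float) for j in range(k)}
        )
        y = rng.normal(size=n)
        res = assoc.fit_gene_model_thresholded(y, X, gene="null")
        rejections += res.anova_p < 0.05
    return {"anova_rejection_rate": rejections / n_genes, "n": n_genes}


def _null_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(
        seed=seed,
        n_individuals=200,
        n_crm_regions=40,
        genome_length=160_000,
        n_planted_effects=0,
        n_null_genes=14,
        noise_sd=0.5,
    )


def pipeline_null_fdr_experiment(seed: int = 0, n_seeds: int = 6) -> dict:
    """Fraction of genes passing 10% FDR on all-null cohorts."""
    passing = tested = 0
    per_seed = []
    for s in range(n_seeds):
        res = run_pipeline(_null_config(seed * 1000 + s))
        results = res.thresholded_results + res.threshold_free_results
        n_pass = sum(r.fdr_q <= 0.10 for r in results)
        passing += n_pass
        tested += len(results)
        per_seed.append(n_pass / max(len(results), 1))
    frac = passing / max(tested, 1)
    se = float(np.std(per_seed, ddof=1) / np.sqrt(n_seeds)) if n_seeds > 1 else 0.0
    return {
        "null_fraction_genes_passing_fdr": frac,
        "null_fraction_se": se,
        "n": tested,
    }


def covariance_test_calibration_experiment(
    seed: int = 0, n_fits: int = 500, n: int = 100, k: int = 50
) -> dict:
    """KS comparison of first-entry covariance statistics with Exp(1).

    Global-null elastic-net fits (lambda2 = 0.5) on Gaussian designs;
    the asymptotic Exp(1) reference applies as the predictor count
    grows, so a many-predictor design is used.
    """
    rng = np.random.default_rng(seed)
    stats_t1 = []
    for _ in range(n_fits):
        X = pd.DataFrame(rng.normal(size=(n, k)))
        y = rng.normal(size=n)
        path = assoc.elastic_net_covariance_test(y, X, max_steps=2)
        stats_t1.append(float(path.loc[path["order"] == 1, "T"].iloc[0]))
    ks = stats.kstest(np.array(stats_t1), "expon")
    return {
        "covtest_ks_p": float(ks.pvalue),
        "covtest_mean_t1": float(np.mean(stats_t1)),
        "n": n_fits,
    }


def _recovery_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(
        seed=seed,
        n_individuals=200,
        n_crm_regions=40,
        genome_length=160_000,
        n_planted_effects=6,
        n_null_genes=10,
        noise_sd=0.5,
    )


def recovery_experiment(seed: int = 0, n_seeds: int = 20) -> dict:
    """Planted-effect recovery with correct sign at 10% FDR across seeds."""
    thr_all_ok = tf_all_ok = 0
    thr_effects = tf_effects = total_effects = 0
    for s in range(n_seeds):
        res = run_pipeline(_recovery_config(seed * 1000 + s))
        rec = evaluate_recovery(res)
        total_effects += len(rec)
        thr_effects += int(rec["thresholded_sign_ok"].sum())
        tf_effects += int(rec["threshold_free_sign_ok"].sum())
        thr_all_ok += bool(rec["thresholded_sign_ok"].all())
        tf_all_ok += bool(rec["threshold_free_sign_ok"].all())
    return {
        "recovery_seed_rate_thresholded": thr_all_ok / n_seeds,
        "recovery_seed_rate_threshold_free": tf_all_ok / n_seeds,
        "recovery_effect_rate_thresholded": thr_effects / total_effects,
        "recovery_effect_rate_threshold_free": tf_effects / total_effects,
        "n": n_seeds,
    }


def enrichment_experiment(
    seed: int = 0, n_null_seeds: int = 100, b_alt: int = 1000
) -> dict:
    """Matched-permutation enrichment: null uniformity and alternative."""
    cfg = SyntheticConfig(
        seed=seed + 3,
        n_individuals=80,
        n_crm_regions=220,
        genome_length=880_000,
        n_planted_effects=8,
        n_null_genes=10,
        noise_sd=0.5,
        # keep driver MAFs strictly inside the top matching bin so no
        # singleton edge bin can starve the control draw
        maf_range=(0.10, 0.44),
    )
    res = run_pipeline(cfg)
    table = driver_snp_table(res)
    thr_null = float(np.quantile(table["driver_effect"], 0.90))
    null_p = []
    for s in range(n_null_seeds):
        wins = generate_accessibility_fixture(
            table,
            cfg.genome_length,
            seed=seed * 10_000 + s,
            effect_threshold=thr_null,
            frac_effect=0.10,
            frac_background=0.10,
        )
        r = matched_permutation_enrichment(
            table, wins, thresholds=[thr_null], B=199, seed=s
        )
        null_p.append(r[0].p)
    null_p = np.array(null_p)

    thr_alt = float(np.quantile(table["driver_effect"], 0.75))
    wins_alt = generate_accessibility_fixture(
        table,
        cfg.genome_length,
        seed=seed + 9,
        effect_threshold=thr_alt,
        frac_effect=0.5,
        frac_background=0.05,
    )
    r_alt = matched_permutation_enrichment(
        table, wins_alt, thresholds=[thr_alt], B=b_alt, seed=seed + 4
    )[0]
    return {
        "enrichment_null_frac_p_lt_05": float((null_p < 0.05).mean()),
        "enrichment_alt_p": float(r_alt.p),
        "enrichment_alt_n_test": float(r_alt.n_test),
        "n": n_null_seeds,
    }


def coloc_experiment(seed: int = 0, n_reps: int = 25, n: int = 500) -> dict:
    """Colocalization behaviour under shared/distinct/absent causal SNPs."""
    shared = simulate_shared_individuals(
        n=n,
        effect_size=0.5,
        error_correlations=[0.0, 0.5],
        n_snps=200,
        n_reps=n_reps,
        seed=seed,
    )
    med = shared.groupby("correlation")["pp4"].median()
    frac_pp4 = float((shared.loc[shared["correlation"] == 0.0, "pp4"] > 0.9).mean())

    rng = np.random.default_rng(seed + 77)
    modal = []
    for _ in range(n_reps):
        G = _ld_genotypes(rng, n, 200, ld_rho=0.3)
        g1 = (G[:, 50] - G[:, 50].mean()) / G[:, 50].std()
        g2 = (G[:, 150] - G[:, 150].mean()) / G[:, 150].std()
        y1 = 0.5 * g1 + rng.normal(size=n)
        y2 = 0.5 * g2 + rng.normal(size=n)
        r = coloc_pp(snp_summaries(y1, G), snp_summaries(y2, G))
        modal.append(r.modal_hypothesis())
    counts = collections.Counter(modal)
    return {
        "coloc_shared_frac_pp4_gt_09": frac_pp4,
        "coloc_median_pp4_rho0": float(med[0.0]),
        "coloc_median_pp4_rho05": float(med[0.5]),
        "coloc_pp4_shift": float(abs(med[0.0] - med[0.5])),
        "coloc_distinct_frac_h3_modal": counts[3] / n_reps,
        "n": n_reps,
    }


def prior_expectation_check(n_variants: int = 1000) -> dict:
    """Expected causal count of the Bin(n, 2/n) fine-mapping prior."""
    return {
        "finemapping_prior_expected_causal": binomial_prior_expectation(n_variants),
        "n": n_variants,
    }
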