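"""Enrichment of predicted affinity variants in accessibility-QTL regions.

For each CRM, the SNP whose single-allele substitution causes the
largest change in any TF's binding affinity is its *driver SNP*.  CRMs
whose driver effect exceeds increasing thresholds are overlapped
(>= 1 bp) with 100 bp differential-accessibility windows, and the
observed overlap proportion is compared with control CRM sets sampled to
match the test set's size and driver-SNP minor-allele-frequency
distribution (binned matching), giving an empirical permutation p-value
``(1 + #{control >= observed}) / (B + 1)`` that is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .affinity import (
    log_fca,
    normalize_affinity,
    pool_tf_logfca,
    trap_affinity,
)
from .crm import CRM, HaplotypeSet, patch_sequence, variant_maf

DEFAULT_MAF_BINS = np.arange(0.05, 0.5001, 0.05)

__all__ = [
    "DriverSNP",
    "EnrichmentResult",
    "single_snp_effects",
    "find_driver_snp",
    "matched_permutation_enrichment",
]


@dataclass(frozen=True)
class DriverSNP:
    crm_id: str
    tf: str
    snp_id: str
    effect: float  # |log FCA| of substituting this SNP alone
    maf: float


@dataclass(frozen=True)
class EnrichmentResult:
    threshold: float
    n_test: int
    observed: float
    perm_mean: float
    perm_q05: float
    perm_q95: float
    p: float


def single_snp_effects(
    crm: CRM,
    hapset: HaplotypeSet,
    variants,
    pwms,
    backgrounds: dict,
    floors: dict,
    ref_best_haplotype: int,
) -> list[tuple[str, float]]:
    """|log FCA| from toggling each SNP alone on the reference best haplotype.

    Each variant's *other* allele (relative to the one carried by the
    reference best haplotype) is substituted alone and the pooled log
    fold change against that haplotype recomputed; the absolute value is
    the variant's single-SNP effect for this TF.
    """
    variants = sorted(variants, key=lambda v: v.pos)
    ref_hap = hapset.haplotypes[ref_best_haplotype]
    crm_len = len(crm.interval)
    base_alleles = (
        ref_hap.alleles if ref_hap.alleles else tuple(0 for _ in variants)
    )
    ref_a = {
        p.motif_id: normalize_affinity(
            trap_affinity(ref_hap.sequence, p), crm_len, backgrounds[p.motif_id]
        )
        for p in pwms
    }
    out = []
    for i, v in enumerate(variants):
        alleles = list(base_alleles)
        alleles[i] = 1 - alleles[i]
        try:
            seq = patch_sequence(
                crm.reference_sequence, crm.interval.start, variants, alleles
            )
        except ValueError:  # conflicting overlap with a carried indel
            continue
        per_pwm = {}
        for p in pwms:
            a_alt = normalize_affinity(
                trap_affinity(seq, p), crm_len, backgrounds[p.motif_id]
            )
            per_pwm[p.motif_id] = log_fca(
                a_alt, ref_a[p.motif_id], floors[p.motif_id]
            )
        out.append((v.id, abs(pool_tf_logfca(per_pwm))))
    return out


def find_driver_snp(effects_by_tf: dict, variants) -> DriverSNP | None:
    """Largest single-SNP effect across TFs; ties break to the lower position.

    ``effects_by_tf`` maps tf -> list of (snp_id, effect) as produced by
    :func:`single_snp_effects`; ``variants`` supply positions and MAFs.
    """
    pos = {v.id: v.pos for v in variants}
    maf = {v.id: variant_maf(v.genotypes) for v in variants}
    best = None
    for tf, effects in effects_by_tf.items():
        for snp_id, effect in effects:
            key = (-effect, pos[snp_id])
            if best is None or key < best[0]:
                best = (key, tf, snp_id, effect)
    if best is None:
        return None
    _, tf, snp_id, effect = best
    return DriverSNP(
        crm_id="", tf=tf, snp_id=snp_id, effect=effect, maf=maf[snp_id]
    )


def _overlaps_any(crm_table: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Boolean per CRM row: overlaps (>= 1 bp) any feature window."""
    out = np.zeros(len(crm_table), dtype=bool)
    by_chrom = {c: g for c, g in windows.groupby("chrom")}
    for i, row in enumerate(crm_table.itertuples()):
        w = by_chrom.get(row.chrom)
        if w is None:
            continue
        out[i] = bool(((row.start < w["end"]) & (w["start"] < row.end)).any())
    return out


def matched_permutation_enrichment(
    crm_table: pd.DataFrame,
    windows: pd.DataFrame,
    thresholds,
    B: int = 1000,
    seed: int = 0,
    min_driver_maf: float = 0.05,
    maf_bins: np.ndarray = DEFAULT_MAF_BINS,
) -> list[EnrichmentResult]:
    """MAF-matched permutation enrichment over effect-size thresholds.

    ``crm_table`` needs columns chrom, start, end, driver_effect,
    driver_maf (one row per CRM).  At each threshold the test set is
    CRMs with ``driver_effect >= t`` and ``driver_maf >= min_driver_maf``;
    B control draws sample the same number of CRMs from the complement,
    matching the test set's binned driver-MAF histogram (without
    replacement within a draw, independently across draws).
    """
    rng = np.random.default_rng(seed)
    overlap = _overlaps_any(crm_table, windows)
    effect = crm_table["driver_effect"].to_numpy()
    maf = crm_table["driver_maf"].to_numpy()
    bin_idx = np.clip(
        np.digitize(maf, maf_bins) - 1, 0, len(maf_bins) - 2
    )
    results = []
    for t in thresholds:
        test = (effect >= t) & (maf >= min_driver_maf)
        n_test = int(test.sum())
        if n_test == 0:
            continue
        observed = float(overlap[test].mean())
        pool = ~test
        # required control count per MAF bin
        need = np.bincount(bin_idx[test], minlength=len(maf_bins) - 1)
        pool_by_bin = [
            np.flatnonzero(pool & (bin_idx == b)) for b in range(len(maf_bins) - 1)
        ]
        for b, cnt in enumerate(need):
            if cnt > len(pool_by_bin[b]):
                lo, hi = maf_bins[b], maf_bins[b + 1]
                raise ValueError(
                    f"MAF bin [{lo:.2f}, {hi:.2f}) needs {cnt} controls but "
                    f"only {len(pool_by_bin[b])} CRMs are available"
                )
        stats = np.empty(B)
        for b_rep in range(B):
            picks = [
                rng.choice(pool_by_bin[b], size=cnt, replace=False)
                for b, cnt in enumerate(need)
                if cnt
            ]
            idx = np.concatenate(picks)
            stats[b_rep] = overlap[idx].mean()
        p = (1 + int((stats >= observed).sum())) / (B + 1)
        results.append(
            EnrichmentResult(
                threshold=float(t),
                n_test=n_test,
                observed=observed,
                perm_mean=float(stats.mean()),
                perm_q05=float(np.quantile(stats, 0.05)),
                perm_q95=float(np.quantile(stats, 0.95)),
                p=float(p),
            )
        )
    return results
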