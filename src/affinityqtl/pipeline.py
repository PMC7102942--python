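"""End-to-end synthetic-cohort pipeline.

Wires the stages together on a generated cohort: CRM definition from
per-TF peaks, variant filtering and haplotype enumeration, GEV
background fitting, the affinity-variant atlas, CRM-gene linking,
expression generation from the planted truth, and both association
approaches.  Used by the validation experiments and usable as a worked
example of the library's intended composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd

from . import association as assoc
from .affinity import (
    STANDARD_LENGTHS,
    build_affinity_atlas,
    fit_gev_background,
    nearest_standard_length,
)
from .crm import (
    GenomicInterval,
    define_crms,
    enumerate_haplotypes,
    filter_variants,
    merge_intervals,
    merge_replicate_peaks,
    variant_maf,
)
from .enrichment import find_driver_snp, single_snp_effects
from .linking import combine_links, filter_baits, link_distal, link_proximal
from .synthetic import Cohort, SyntheticConfig, generate_cohort, generate_expression

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "evaluate_recovery", "driver_snp_table"]


@dataclass
class PipelineResult:
    cohort: Cohort
    crms: list
    haplotype_sets: dict
    variants_by_crm: dict
    backgrounds: dict
    floors: dict
    atlas: list  # filtered affinity variants (ref allele A < 0.1)
    atlas_unfiltered: list
    links: list
    counts: pd.DataFrame = field(repr=False)
    residuals: pd.DataFrame = field(repr=False)
    thresholded_results: list = field(default_factory=list)
    thresholded_hits: pd.DataFrame | None = None
    threshold_free_results: list = field(default_factory=list)
    threshold_free_hits: pd.DataFrame | None = None

    def atlas_variant(self, crm_id: str, tf: str):
        for av in self.atlas:
            if av.crm_id == crm_id and av.tf == tf:
                return av
        return None


def _background_regions(cohort: Cohort, bound_spans, rng, n_needed: int):
    """Peak-free CRM-sized segments to top up a TF's background pool."""
    cfg = cohort.config
    occupied = merge_intervals(bound_spans) if bound_spans else []
    out = []
    attempts = 0
    while len(out) < n_needed and attempts < 50 * n_needed:
        attempts += 1
        length = int(rng.integers(180, 351))
        start = int(rng.integers(0, max(1, cfg.genome_length - length)))
        end = start + length
        if any(s < end and start < e for s, e in occupied):
            continue
        out.append(
            SimpleNamespace(interval=GenomicInterval(cohort.chrom, start, end))
        )
    return out


def run_pipeline(
    config: SyntheticConfig,
    cohort: Cohort | None = None,
    gene_fdr: float = assoc.DEFAULT_GENE_FDR,
    min_background: int = 300,
) -> PipelineResult:
    """Run every stage on one synthetic cohort and return all artifacts."""
    if cohort is None:
        cohort = generate_cohort(config)
    cfg = cohort.config
    n_chrom = 2 * cfg.n_individuals

    # --- CRM atlas
    merged_peaks = {
        tf: merge_replicate_peaks(reps, tf) for tf, reps in cohort.peaks.items()
    }
    crms = define_crms(merged_peaks, cohort.genome, chrom=cohort.chrom)
    variants = filter_variants(cohort.variants, genome=cohort.genome)
    variants_by_crm = {
        crm.id: [
            v
            for v in variants
            if v.start < crm.interval.end and v.end > crm.interval.start
        ]
        for crm in crms
    }
    hapsets = {
        crm.id: enumerate_haplotypes(
            crm, variants_by_crm[crm.id], n_chromosomes=n_chrom
        )
        for crm in crms
    }

    # --- backgrounds: per motif, CRMs not bound by its TF, topped up with
    # peak-free genome segments; only the standard lengths actually used
    lengths_needed = sorted(
        {nearest_standard_length(len(c.interval), STANDARD_LENGTHS) for c in crms}
    )
    pwms_by_tf: dict = {}
    for p in cohort.pwms:
        pwms_by_tf.setdefault(p.tf, []).append(p)
    rng_bg = np.random.default_rng(cfg.seed + 7)
    all_peak_spans = [iv for c in crms for iv in [(c.interval.start, c.interval.end)]]
    backgrounds = {}
    for tf, pwms in pwms_by_tf.items():
        unbound = [c for c in crms if tf not in c.bound_tfs]
        if len(unbound) < min_background:
            unbound = unbound + _background_regions(
                cohort, all_peak_spans, rng_bg, min_background - len(unbound)
            )
        for pwm in pwms:
            backgrounds[pwm.motif_id] = fit_gev_background(
                pwm,
                unbound,
                cohort.genome,
                lengths=lengths_needed,
                min_sequences=min_background,
            )

    # --- affinity atlas (unfiltered once; the filter is on the stored A)
    atlas_unfiltered, floors = build_affinity_atlas(
        crms,
        hapsets,
        pwms_by_tf,
        backgrounds,
        reference_individual=cfg.reference_individual,
        a_max_ref=np.inf,
        return_floors=True,
    )
    atlas = [av for av in atlas_unfiltered if av.ref_best_a < 0.1]

    # --- linking
    frag_genes: dict = {}
    frag_lookup = {
        row.fragment_id: (int(row.start), int(row.end))
        for row in cohort.fragments.itertuples()
    }
    for row in cohort.tss.itertuples():
        for frag_id, (fs, fe) in frag_lookup.items():
            if fs <= row.tss < fe:
                frag_genes.setdefault(frag_id, set()).add(row.gene)
                break
    baits = filter_baits(frag_genes.items())
    links = combine_links(
        link_distal(crms, cohort.interactions, cohort.fragments, baits),
        link_proximal(crms, cohort.fragments, baits),
    )

    # --- expression from the planted truth
    av_by_key = {(av.crm_id, av.tf): av for av in atlas_unfiltered}
    crm_of_region = {}
    for p in cohort.truth.planted:
        region = GenomicInterval(p.chrom, p.region_start, p.region_end)
        match = next(
            (c for c in crms if c.interval.overlaps(region)), None
        )
        if match is None:
            raise RuntimeError(f"planted region {region} produced no CRM")
        crm_of_region[(p.gene, p.tf)] = match.id
    pred_rows = {}
    individuals = cohort.individuals
    for p in cohort.truth.planted:
        crm_id = crm_of_region[(p.gene, p.tf)]
        av = av_by_key.get((crm_id, p.tf))
        if av is None:
            raise RuntimeError(
                f"planted ({crm_id}, {p.tf}) missing from the unfiltered atlas"
            )
        pred_rows[p.gene] = assoc.build_threshold_free_predictors(
            av, hapsets[crm_id]
        )
    predictors = pd.DataFrame(
        pred_rows.values(), index=list(pred_rows.keys()), columns=individuals
    )
    if predictors.empty:
        predictors = pd.DataFrame(columns=individuals)
    counts, residuals = generate_expression(
        cohort.truth, predictors, cfg.noise_sd, seed=cfg.seed + 3
    )

    # --- association
    expressed = assoc.filter_expressed(counts)
    residuals_kept = residuals.loc[expressed]
    links_by_gene: dict = {}
    for link in links:
        links_by_gene.setdefault(link.gene, []).append(link)
    crm_start = {c.id: c.interval.start for c in crms}

    thr_results, tf_results = [], []
    for gene in residuals_kept.index:
        gene_links = links_by_gene.get(gene)
        if not gene_links:
            continue
        try:
            y = assoc.rank_transform(residuals_kept.loc[gene].to_numpy())
        except ValueError:
            continue
        gene_avs = []
        for link in gene_links:
            for av in atlas:
                if av.crm_id == link.crm_id:
                    gene_avs.append(av)
        gene_avs.sort(key=lambda av: (crm_start[av.crm_id], av.tf))

        # thresholded
        cols = {}
        for av in gene_avs:
            if av.max_abs_logfca <= 0.3:
                continue
            classes = assoc.classify_haplotypes(av)
            if classes is None:
                continue
            cols[f"{av.crm_id}:{av.tf}"] = assoc.encode_dosage(
                classes, hapsets[av.crm_id]
            )
        if cols:
            X = pd.DataFrame(cols, index=individuals)
            if X.nunique(dropna=True).gt(1).any():
                X = X.loc[:, X.nunique(dropna=True) > 1]
                try:
                    thr_results.append(
                        assoc.fit_gene_model_thresholded(y, X, gene=gene)
                    )
                except ValueError as err:
                    logger.warning("thresholded model for %s skipped: %s", gene, err)

        # threshold-free
        cols = {}
        for av in gene_avs:
            if av.max_abs_logfca <= 0.0:
                continue
            x = assoc.build_threshold_free_predictors(av, hapsets[av.crm_id])
            if np.ptp(x) > 0:
                cols[f"{av.crm_id}:{av.tf}"] = x
        if cols:
            X = pd.DataFrame(cols, index=individuals)
            try:
                tf_results.append(
                    assoc.fit_gene_model_elastic_net(y, X, gene=gene)
                )
            except ValueError as err:
                logger.warning("threshold-free model for %s skipped: %s", gene, err)

    thr_hits = assoc.fdr_and_coefficients(thr_results, gene_fdr=gene_fdr)
    tf_hits = assoc.fdr_and_coefficients(tf_results, gene_fdr=gene_fdr)

    return PipelineResult(
        cohort=cohort,
        crms=crms,
        haplotype_sets=hapsets,
        variants_by_crm=variants_by_crm,
        backgrounds=backgrounds,
        floors=floors,
        atlas=atlas,
        atlas_unfiltered=atlas_unfiltered,
        links=links,
        counts=counts,
        residuals=residuals,
        thresholded_results=thr_results,
        thresholded_hits=thr_hits,
        threshold_free_results=tf_results,
        threshold_free_hits=tf_hits,
    )


def evaluate_recovery(result: PipelineResult) -> pd.DataFrame:
    """Per planted effect: was it found, with the right effect direction?

    A planted (gene, CRM, TF) counts as recovered by an approach when the
    gene passes 10% FDR and the matching predictor — or a statistically
    indistinguishable proxy: a collapsed-group member (thresholded) or a
    predictor correlated with the planted one at |r| > 0.99
    (threshold-free, where the same SNP perturbs several TFs' affinities
    in lockstep and the elastic net keeps one of them) — is called
    significant.  Expected coefficient signs: the threshold-free
    predictor (summed canonical log FCA) carries the planted beta's own
    sign times the sign of its correlation with the reported proxy; the
    low-affinity dosage is anti-correlated with the canonical predictor,
    so the thresholded coefficient carries the opposite sign.
    """
    crm_by_key = {}
    for p in result.cohort.truth.planted:
        region = GenomicInterval(p.chrom, p.region_start, p.region_end)
        match = next(
            (c for c in result.crms if c.interval.overlaps(region)), None
        )
        crm_by_key[(p.gene, p.tf)] = match.id if match else None

    group_lookup = {}
    for r in result.thresholded_results:
        for rep, members in r.groups.items():
            for m in members:
                group_lookup[(r.gene, m)] = rep

    av_by_key = {(av.crm_id, av.tf): av for av in result.atlas_unfiltered}

    def predictor_of(name: str) -> np.ndarray:
        crm_id, tf = name.rsplit(":", 1)
        av = av_by_key[(crm_id, tf)]
        return assoc.build_threshold_free_predictors(
            av, result.haplotype_sets[crm_id]
        )

    rows = []
    for p in result.cohort.truth.planted:
        crm_id = crm_by_key[(p.gene, p.tf)]
        name = f"{crm_id}:{p.tf}"
        out = {"gene": p.gene, "crm_id": crm_id, "tf": p.tf, "beta": p.beta}

        # thresholded: the planted predictor or its collapsed-group rep
        rep = group_lookup.get((p.gene, name), name)
        sub = result.thresholded_hits[
            (result.thresholded_hits["gene"] == p.gene)
            & (result.thresholded_hits["variant"] == rep)
        ]
        out["thresholded_recovered"] = bool(len(sub))
        out["thresholded_sign_ok"] = bool(
            len(sub) and np.sign(sub["beta"].iloc[0]) == -np.sign(p.beta)
        )

        # threshold-free: the planted predictor or a |r| > 0.99 proxy
        x_planted = predictor_of(name)
        gene_hits = result.threshold_free_hits[
            result.threshold_free_hits["gene"] == p.gene
        ]
        recovered = sign_ok = False
        for h in gene_hits.itertuples():
            if h.variant == name:
                r = 1.0
            else:
                x_proxy = predictor_of(h.variant)
                r = float(np.corrcoef(x_planted, x_proxy)[0, 1])
                if not (np.isfinite(r) and abs(r) > 0.99):
                    continue
            recovered = True
            sign_ok = np.sign(h.beta) == np.sign(r) * np.sign(p.beta)
            if sign_ok:
                break
        out["threshold_free_recovered"] = recovered
        out["threshold_free_sign_ok"] = bool(sign_ok)
        rows.append(out)
    return pd.DataFrame(rows)


def driver_snp_table(result: PipelineResult) -> pd.DataFrame:
    """Per-CRM driver SNP (largest single-SNP affinity effect) and its MAF.

    Covers CRMs with at least one affinity variant in the unfiltered
    atlas and at least one SNP; columns are ready for the matched
    permutation enrichment test.
    """
    pwms_by_tf: dict = {}
    for p in result.cohort.pwms:
        pwms_by_tf.setdefault(p.tf, []).append(p)
    rows = []
    avs_by_crm: dict = {}
    for av in result.atlas_unfiltered:
        avs_by_crm.setdefault(av.crm_id, []).append(av)
    for crm in result.crms:
        variants = result.variants_by_crm[crm.id]
        snps = [v for v in variants if not v.is_indel]
        avs = avs_by_crm.get(crm.id, [])
        if not snps or not avs:
            continue
        effects_by_tf = {}
        for av in avs:
            effects_by_tf[av.tf] = single_snp_effects(
                crm,
                result.haplotype_sets[crm.id],
                snps,
                pwms_by_tf[av.tf],
                result.backgrounds,
                result.floors,
                av.ref_best_haplotype,
            )
        driver = find_driver_snp(effects_by_tf, snps)
        if driver is None:
            continue
        rows.append(
            {
                "crm_id": crm.id,
                "chrom": crm.interval.chrom,
                "start": crm.interval.start,
                "end": crm.interval.end,
                "driver_snp": driver.snp_id,
                "driver_tf": driver.tf,
                "driver_effect": driver.effect,
                "driver_maf": driver.maf,
            }
        )
    return pd.DataFrame(rows)
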