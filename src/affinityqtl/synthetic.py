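"""Seed-reproducible synthetic cohorts with planted regulatory effects.

The generator emulates the statistical structure of the real inputs the
pipeline was designed around — a reference genome, per-TF ChIP peak
sets, a phased biallelic variant panel with MAF >= 5%, a restriction
fragment map with promoter-capture interaction scores straddling the
significance cut-off, TSS annotations, and expression residuals — while
planting known (gene, CRM, TF) affinity effects so that downstream
association testing can be validated against ground truth.

Expression is generated by inverting the association model: for a
planted gene, residuals are ``beta * x + N(0, noise_sd^2)`` where ``x``
is the individual's diploid affinity predictor (sum of log FCA over the
two haplotypes) computed by the affinity engine on the emitted cohort.
Null genes are pure noise.  The raw count matrix is a monotone transform
of the residuals and exists only to exercise the expressed-gene filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crm import VariantRecord
from .pwm import BASES, PWM

__all__ = [
    "SyntheticConfig",
    "PlantedEffect",
    "SyntheticTruth",
    "Cohort",
    "generate_pwms",
    "generate_cohort",
    "generate_expression",
    "generate_accessibility_fixture",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of one synthetic cohort; the seed fixes everything."""

    seed: int = 0
    n_individuals: int = 359
    n_tfs: int = 6
    n_crm_regions: int = 60
    genome_length: int = 300_000
    motif_width_range: tuple = (8, 12)
    maf_range: tuple = (0.10, 0.45)
    n_planted_effects: int = 6
    effect_size_range: tuple = (0.6, 1.2)
    noise_sd: float = 0.5
    interaction_score_range: tuple = (1.0, 12.0)
    n_null_genes: int = 12
    frac_two_pwm_tfs: float = 0.3
    frac_disrupting: float = 0.5
    fragment_length: int = 3_000
    frac_unexpressed: float = 0.15
    motif_echo_spacing: int = 1_500
    reference_individual: int = 0

    def __post_init__(self) -> None:
        if self.maf_range[0] < 0.05 or self.maf_range[1] > 0.5:
            raise ValueError("maf_range must lie within [0.05, 0.5]")
        if self.maf_range[0] > self.maf_range[1]:
            raise ValueError("maf_range must be (min, max)")
        for name in ("n_individuals", "n_tfs", "genome_length", "fragment_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_crm_regions < 0 or self.n_planted_effects < 0:
            raise ValueError("counts must be non-negative")
        if self.n_planted_effects > self.n_crm_regions:
            raise ValueError("cannot plant more effects than CRM regions")
        if self.motif_width_range[0] < 4:
            raise ValueError("motif widths below 4 are not supported")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class PlantedEffect:
    gene: str
    chrom: str
    region_start: int
    region_end: int
    tf: str
    beta: float
    variant_id: str
    link_class: str  # how the generator wires CRM to gene: distal | proximal


@dataclass(frozen=True)
class SyntheticTruth:
    planted: tuple
    null_genes: tuple
    unexpressed_genes: tuple = ()

    def planted_genes(self) -> list:
        return [p.gene for p in self.planted]


@dataclass
class Cohort:
    """Everything :func:`generate_cohort` emits, in memory."""

    config: SyntheticConfig
    pwms: list
    genome: str
    chrom: str
    peaks: dict  # tf -> list of replicate interval lists [(start, end), ...]
    variants: list  # VariantRecord
    fragments: pd.DataFrame  # chrom, start, end, fragment_id
    interactions: pd.DataFrame  # bait_id, other_end_id, score
    tss: pd.DataFrame  # gene, chrom, tss, strand
    truth: SyntheticTruth

    @property
    def individuals(self) -> list:
        return [f"IND{i:04d}" for i in range(self.config.n_individuals)]


# ---------------------------------------------------------------------------
# motifs


def generate_pwms(
    n: int,
    width_range: tuple,
    seed: int,
    frac_second_pwm: float = 0.0,
    force_uniform: bool = False,
) -> list[PWM]:
    """Random informative motifs, one or two per TF.

    About a third of the columns of each motif are "anchor" columns
    carrying an exact-zero frequency for one base (pseudocount is
    deliberately zero downstream), so that a substitution to that base
    at an anchor voids every placement using it; the remaining columns
    are moderately informative (Dirichlet-drawn), emulating the
    information content of typical curated frequency matrices.  A ``frac_second_pwm``
    fraction of TFs receive a perturbed second motif to exercise
    median pooling.  ``force_uniform`` emits flat 0.25 matrices instead.
    """
    if n < 1:
        raise ValueError("need at least one motif")
    wmin, wmax = width_range
    if wmin < 4 or wmin > wmax:
        raise ValueError(f"invalid motif width range {width_range}")
    rng = np.random.default_rng(seed)
    pwms: list[PWM] = []
    for t in range(n):
        tf = f"TF{t:02d}"
        width = int(rng.integers(wmin, wmax + 1))
        if force_uniform:
            freqs = np.full((4, width), 0.25)
            pwms.append(PWM(tf=tf, motif_id=f"{tf}_m0", freqs=freqs))
            continue
        consensus = rng.integers(0, 4, size=width)
        n_anchor = max(2, width // 3)
        anchors = set(rng.choice(width, size=n_anchor, replace=False).tolist())
        freqs = np.zeros((4, width))
        for j in range(width):
            others = [b for b in range(4) if b != consensus[j]]
            rng.shuffle(others)
            if j in anchors:
                # one base is strictly forbidden at anchor columns
                freqs[consensus[j], j] = 0.75
                freqs[others[0], j] = 0.15
                freqs[others[1], j] = 0.10
                freqs[others[2], j] = 0.0
            else:
                w = rng.dirichlet([6.0, 2.0, 2.0, 2.0])
                freqs[consensus[j], j] = w[0]
                for b, x in zip(others, w[1:]):
                    freqs[b, j] = x
        pwms.append(PWM(tf=tf, motif_id=f"{tf}_m0", freqs=freqs))
        if rng.random() < frac_second_pwm:
            jitter = rng.uniform(0.0, 0.05, size=freqs.shape)
            jitter[freqs == 0] = 0.0  # keep exact zeros exact
            f2 = freqs + jitter
            f2 /= f2.sum(axis=0, keepdims=True)
            pwms.append(PWM(tf=tf, motif_id=f"{tf}_m1", freqs=f2))
    return pwms


def _anchor_column(pwm: PWM):
    """(column, consensus base idx, zero base idx) of the most informative
    zero-carrying column, or None."""
    best = None
    for j in range(pwm.width):
        col = pwm.freqs[:, j]
        zeros = np.flatnonzero(col == 0.0)
        if zeros.size == 0:
            continue
        key = -col.max()
        if best is None or key < best[0]:
            best = (key, j, int(col.argmax()), int(zeros[0]))
    if best is None:
        return None
    return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# cohort


def _draw_genotypes(rng, n_chrom, maf_range, forbidden=()):
    f = rng.uniform(*maf_range)
    lo = int(np.ceil(n_chrom * maf_range[0]))
    hi = int(np.floor(n_chrom * maf_range[1]))
    m = int(np.clip(round(n_chrom * f), lo, hi))
    available = np.array([c for c in range(n_chrom) if c not in forbidden])
    if m > available.size:
        raise ValueError("too few chromosomes to place the requested MAF")
    gt = np.zeros(n_chrom, dtype=np.int8)
    gt[rng.choice(available, size=m, replace=False)] = 1
    return gt


def generate_cohort(config: SyntheticConfig, pwms=None) -> Cohort:
    """Generate the full synthetic input set for one cohort.

    Guarantees: variants are biallelic with empirical MAF inside
    ``maf_range``; haplotypes are phased; the first
    ``n_planted_effects`` CRM regions carry a motif-disrupting variant
    at a maximally informative motif column (the reference individual
    stays homozygous reference there, so the reference alleles retain
    the high-affinity motif); interaction scores straddle the
    significance cut-off of 5; one bait fragment carries two TSSs; at
    least one indel is emitted.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"
    if pwms is None:
        pwms = generate_pwms(
            cfg.n_tfs,
            cfg.motif_width_range,
            seed=cfg.seed + 1,
            frac_second_pwm=cfg.frac_two_pwm_tfs,
        )
    tf_names = sorted({p.tf for p in pwms})
    first_pwm = {tf: next(p for p in pwms if p.tf == tf) for tf in tf_names}

    genome = rng.integers(0, 4, size=cfg.genome_length)
    # degraded motif copies scattered genome-wide: real genomic background
    # is full of partial motif matches, which gives background affinity
    # distributions their right tail (and keeps the fitted extreme-value
    # law's support above even perfect-match scores)
    for _ in range(cfg.genome_length // cfg.motif_echo_spacing):
        pwm = pwms[int(rng.integers(len(pwms)))]
        echo = pwm.freqs.argmax(axis=0).copy()
        # 2-4 mismatches: enough decay that no echo rivals a real site
        for j in rng.choice(pwm.width, size=int(rng.integers(2, 5)), replace=False):
            echo[j] = rng.integers(0, 4)
        pos = int(rng.integers(0, cfg.genome_length - pwm.width))
        genome[pos : pos + pwm.width] = echo
    n_chrom = 2 * cfg.n_individuals
    ref_chroms = (
        2 * cfg.reference_individual,
        2 * cfg.reference_individual + 1,
    )

    peaks: dict = {tf: [] for tf in tf_names}
    variants: list[VariantRecord] = []
    planted: list[PlantedEffect] = []

    if cfg.n_crm_regions > 0:
        slot = cfg.genome_length // cfg.n_crm_regions
        if slot < 600:
            raise ValueError(
                "genome too short for the requested number of CRM regions"
            )

    var_counter = 0
    indel_emitted = False
    region_records = []  # (start, end, [(tf, motif_start, pwm)], region_tfs)
    for k in range(cfg.n_crm_regions):
        slot_start = k * slot
        if k < cfg.n_planted_effects:
            # planted regions: one compact single-TF site so the planted
            # variant's effect on that TF's occupancy is unambiguous
            region_len = int(rng.integers(150, 181))
            n_here = 1
        else:
            region_len = int(rng.integers(150, 261))
            n_here = int(rng.integers(1, min(3, len(tf_names)) + 1))
        start = slot_start + int(rng.integers(60, slot - region_len - 60))
        end = start + region_len
        region_tfs = list(rng.choice(tf_names, size=n_here, replace=False))
        # embed one motif instance per bound TF, spaced left to right
        cursor = start + 10
        instances = []
        for tf in region_tfs:
            pwm = first_pwm[tf]
            if cursor + pwm.width > end - 10:
                break
            cons = [int(b) for b in pwm.freqs.argmax(axis=0)]
            genome[cursor : cursor + pwm.width] = cons
            instances.append((tf, cursor, pwm))
            cursor += pwm.width + int(rng.integers(8, 25))
        region_records.append((start, end, instances, region_tfs))

    # peaks: every bound TF's peak covers the region with small jitter;
    # the first TF name gets two replicates wherever it is bound
    for start, end, instances, region_tfs in region_records:
        for tf in region_tfs:
            j1 = int(rng.integers(0, 25))
            j2 = int(rng.integers(0, 25))
            iv = (max(0, start - j1), min(cfg.genome_length, end + j2))
            if tf == tf_names[0]:
                rep2 = (max(0, start - int(rng.integers(0, 25))), iv[1])
                if not peaks[tf]:
                    peaks[tf] = [[], []]
                peaks[tf][0].append(iv)
                peaks[tf][1].append(rep2)
            else:
                if not peaks[tf]:
                    peaks[tf] = [[]]
                peaks[tf][0].append(iv)

    # variants
    used_positions: set[int] = set()
    for k, (start, end, instances, region_tfs) in enumerate(region_records):
        want_disrupting = k < cfg.n_planted_effects or (
            instances and rng.random() < cfg.frac_disrupting
        )
        if want_disrupting and instances:
            if k < cfg.n_planted_effects:
                # plant in the widest motif: wider motifs make stronger
                # sites (higher R0), so the disruption is unambiguous
                tf, mstart, pwm = max(instances, key=lambda inst: inst[2].width)
            else:
                tf, mstart, pwm = instances[int(rng.integers(0, len(instances)))]
            anchor = _anchor_column(pwm)
            if anchor is not None:
                j, cons_b, zero_b = anchor
                pos0 = mstart + j
                if pos0 not in used_positions:
                    gt = _draw_genotypes(
                        rng, n_chrom, cfg.maf_range, forbidden=ref_chroms
                    )
                    vid = f"var_{var_counter:04d}"
                    var_counter += 1
                    variants.append(
                        VariantRecord(
                            vid,
                            chrom,
                            pos0 + 1,
                            BASES[int(genome[pos0])],
                            BASES[zero_b],
                            gt,
                        )
                    )
                    used_positions.add(pos0)
                    if k < cfg.n_planted_effects:
                        beta = float(
                            rng.uniform(*cfg.effect_size_range)
                            * rng.choice([-1.0, 1.0])
                        )
                        planted.append(
                            PlantedEffect(
                                gene=f"gene_P{k:03d}",
                                chrom=chrom,
                                region_start=start,
                                region_end=end,
                                tf=tf,
                                beta=beta,
                                variant_id=vid,
                                link_class="distal" if k % 2 == 0 else "proximal",
                            )
                        )
        # background variants outside motif instances
        motif_spans = [
            (ms, ms + p.width) for _, ms, p in instances
        ]
        for _ in range(int(rng.integers(1, 3))):
            for _attempt in range(20):
                pos0 = int(rng.integers(start, end))
                if pos0 in used_positions:
                    continue
                if any(s <= pos0 < e for s, e in motif_spans):
                    continue
                break
            else:
                continue
            ref_b = int(genome[pos0])
            if not indel_emitted and pos0 + 3 < end and not any(
                p in used_positions for p in (pos0 + 1, pos0 + 2)
            ):
                ref = "".join(BASES[int(b)] for b in genome[pos0 : pos0 + 3])
                alt = ref[0]
                used = {pos0, pos0 + 1, pos0 + 2}
                indel_emitted = True
            else:
                ref = BASES[ref_b]
                alt = BASES[int((ref_b + int(rng.integers(1, 4))) % 4)]
                used = {pos0}
            gt = _draw_genotypes(rng, n_chrom, cfg.maf_range)
            vid = f"var_{var_counter:04d}"
            var_counter += 1
            variants.append(VariantRecord(vid, chrom, pos0 + 1, ref, alt, gt))
            used_positions.update(used)
    variants.sort(key=lambda v: v.pos)

    # fragment map
    n_frags = max(1, int(np.ceil(cfg.genome_length / cfg.fragment_length)))
    frag_rows = [
        {
            "chrom": chrom,
            "start": i * cfg.fragment_length,
            "end": min((i + 1) * cfg.fragment_length, cfg.genome_length),
            "fragment_id": f"frag_{i:04d}",
        }
        for i in range(n_frags)
    ]
    fragments = pd.DataFrame(frag_rows)

    def frag_of(pos: int) -> str:
        return f"frag_{min(pos // cfg.fragment_length, n_frags - 1):04d}"

    # genes, TSSs and interactions
    tss_rows = []
    inter_rows = []
    occupied_frags: set[str] = set()
    # fragments holding planted CRM regions are reserved for their own
    # proximal genes: a stray TSS there would create a multi-gene bait and
    # knock out the link through bait filtering
    reserved_frags = {
        frag_of(p.region_start) for p in planted
    } | {frag_of(max(0, p.region_end - 1)) for p in planted}

    def pick_fragment(rng, predicate) -> int:
        for _attempt in range(200):
            idx = int(rng.integers(0, n_frags))
            if predicate(idx):
                return idx
        raise RuntimeError(
            "could not place a TSS fragment; genome too crowded for the "
            "requested gene count"
        )

    def place_tss(gene: str, frag_idx: int) -> str:
        fs = frag_idx * cfg.fragment_length
        fe = min(fs + cfg.fragment_length, cfg.genome_length)
        pos = int((fs + fe) // 2)
        tss_rows.append(
            {
                "gene": gene,
                "chrom": chrom,
                "tss": pos,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
        return f"frag_{frag_idx:04d}"

    for p in planted:
        crm_frag_idx = p.region_start // cfg.fragment_length
        if p.link_class == "proximal":
            bait = place_tss(p.gene, crm_frag_idx)
            occupied_frags.add(bait)
        else:
            # a far fragment, then an explicit significant interaction
            idx = pick_fragment(
                rng,
                lambda i: abs(i - crm_frag_idx) > 4
                and f"frag_{i:04d}" not in occupied_frags
                and f"frag_{i:04d}" not in reserved_frags,
            )
            bait = place_tss(p.gene, idx)
            occupied_frags.add(bait)
            inter_rows.append(
                {
                    "bait_id": bait,
                    "other_end_id": frag_of(p.region_start),
                    "score": float(rng.uniform(6.0, cfg.interaction_score_range[1])),
                }
            )

    null_genes = []
    region_frag_ids = [frag_of(s) for s, _, _, _ in region_records]
    for g in range(cfg.n_null_genes):
        gene = f"gene_N{g:03d}"
        null_genes.append(gene)
        idx = pick_fragment(
            rng,
            lambda i: f"frag_{i:04d}" not in occupied_frags
            and f"frag_{i:04d}" not in reserved_frags,
        )
        bait = place_tss(gene, idx)
        occupied_frags.add(bait)
        # wire null genes to CRM fragments so they are tested downstream
        if region_frag_ids:
            for target in rng.choice(
                region_frag_ids,
                size=min(2, len(region_frag_ids)),
                replace=False,
            ):
                if target != bait:
                    inter_rows.append(
                        {
                            "bait_id": bait,
                            "other_end_id": target,
                            "score": float(rng.uniform(5.5, 10.0)),
                        }
                    )

    # a bait carrying two TSSs (must be excluded downstream)
    if n_frags > 2:
        idx = pick_fragment(
            rng,
            lambda i: f"frag_{i:04d}" not in occupied_frags
            and f"frag_{i:04d}" not in reserved_frags,
        )
        place_tss("gene_X000", idx)
        place_tss("gene_X001", idx)

    # background interactions straddling the cut-off
    lo, hi = cfg.interaction_score_range
    for _ in range(max(4, cfg.n_crm_regions // 4)):
        a, b = rng.integers(0, n_frags, size=2)
        if a == b:
            continue
        inter_rows.append(
            {
                "bait_id": f"frag_{a:04d}",
                "other_end_id": f"frag_{b:04d}",
                "score": float(rng.uniform(lo, min(hi, 4.99))),
            }
        )

    interactions = pd.DataFrame(
        inter_rows, columns=["bait_id", "other_end_id", "score"]
    )
    tss = pd.DataFrame(tss_rows, columns=["gene", "chrom", "tss", "strand"])
    genome_str = "".join(BASES[int(b)] for b in genome)

    n_unexpr = int(np.ceil(cfg.frac_unexpressed * cfg.n_null_genes))
    truth = SyntheticTruth(
        planted=tuple(planted),
        null_genes=tuple(null_genes),
        unexpressed_genes=tuple(null_genes[-n_unexpr:]) if n_unexpr else (),
    )
    return Cohort(
        config=cfg,
        pwms=list(pwms),
        genome=genome_str,
        chrom=chrom,
        peaks={tf: reps for tf, reps in peaks.items() if reps},
        variants=variants,
        fragments=fragments,
        interactions=interactions,
        tss=tss,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    truth: SyntheticTruth,
    predictors: pd.DataFrame,
    noise_sd: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Invert the association model to produce expression matrices.

    ``predictors`` holds one row per planted gene (index = gene id) of
    per-individual diploid predictor values.  Returns ``(counts,
    residuals)`` as genes x individuals DataFrames covering planted and
    null genes; genes flagged unexpressed get > 50% zero counts.
    """
    rng = np.random.default_rng(seed)
    genes = [p.gene for p in truth.planted] + list(truth.null_genes)
    n_ind = predictors.shape[1]
    if n_ind == 0:
        raise ValueError("predictors must carry one column per individual")
    beta_by_gene: dict = {}
    for p in truth.planted:
        if p.gene not in predictors.index:
            raise ValueError(f"no predictor row for planted gene {p.gene}")
        beta_by_gene.setdefault(p.gene, []).append(p.beta)

    resid = np.empty((len(genes), n_ind))
    for g, gene in enumerate(genes):
        noise = rng.normal(0.0, noise_sd, size=n_ind) if noise_sd > 0 else 0.0
        if gene in beta_by_gene:
            x = predictors.loc[gene].to_numpy(dtype=float)
            if x.size != n_ind:
                raise ValueError("predictor/individual dimension mismatch")
            resid[g] = beta_by_gene[gene][0] * x + noise
        else:
            resid[g] = noise
    cols = list(predictors.columns)
    residuals = pd.DataFrame(resid, index=genes, columns=cols)

    counts = np.rint(50.0 * np.exp(0.5 * resid)).astype(int)
    for gene in truth.unexpressed_genes:
        g = genes.index(gene)
        mask = rng.random(n_ind) < 0.6
        while mask.mean() <= 0.5:  # guarantee strictly > 50% zeros
            mask[int(rng.integers(n_ind))] = True
        counts[g, mask] = 0
    counts = pd.DataFrame(counts, index=genes, columns=cols)
    return counts, residuals


# ---------------------------------------------------------------------------
# accessibility fixture


def generate_accessibility_fixture(
    crm_table: pd.DataFrame,
    genome_length: int,
    seed: int,
    effect_threshold: float = 0.3,
    frac_effect: float = 0.5,
    frac_background: float = 0.05,
    window: int = 100,
    graded_scale: float | None = None,
) -> pd.DataFrame:
    """Differential-accessibility windows over the genome.

    The genome is tiled into non-overlapping ``window`` bp tiles.  For
    each CRM in ``crm_table`` (columns chrom, start, end, driver_effect)
    the tile containing the CRM midpoint is labelled differential with
    probability ``frac_effect`` when the driver effect reaches
    ``effect_threshold`` and ``frac_background`` otherwise; CRM-free
    tiles are labelled at ``frac_background``.  Setting the two rates
    equal makes labels independent of effect (an exchangeable null
    fixture).  With ``graded_scale`` set, the per-CRM rate instead rises
    linearly with the driver effect from ``frac_background`` to
    ``frac_effect`` at ``graded_scale`` (a dose-response fixture;
    ``effect_threshold`` is ignored).  Returns the differential windows
    (chrom, start, end).
    """
    rng = np.random.default_rng(seed)
    n_win = genome_length // window
    crm_tiles = set()
    for row in crm_table.itertuples():
        s, e = int(row.start), int(row.end)
        crm_tiles.update(range(s // window, min(e // window, n_win - 1) + 1))
    differential = np.zeros(n_win, dtype=bool)
    free = np.array([t not in crm_tiles for t in range(n_win)])
    differential[free] = rng.random(int(free.sum())) < frac_background
    for row in crm_table.itertuples():
        if graded_scale is not None:
            frac = min(float(row.driver_effect) / graded_scale, 1.0)
            rate = frac_background + (frac_effect - frac_background) * frac
        else:
            rate = (
                frac_effect
                if row.driver_effect >= effect_threshold
                else frac_background
            )
        if rng.random() < rate:
            mid = (int(row.start) + int(row.end)) // 2
            differential[min(mid // window, n_win - 1)] = True
    starts = np.flatnonzero(differential) * window
    chrom = crm_table["chrom"].iloc[0] if len(crm_table) else "chr1"
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + window}
    )
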