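"""Cis-regulatory modules (CRMs) from multi-TF ChIP peaks and their haplotypes.

CRMs are the connected components of the union of all TFs' peak intervals
(two peaks merge iff they share at least one base).  All coordinates are
BED-style 0-based half-open internally; VCF-style 1-based positions are
converted on construction of :class:`VariantRecord`.  Touching half-open
intervals share zero bases and therefore do not merge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "CRM",
    "VariantRecord",
    "Haplotype",
    "HaplotypeSet",
    "merge_intervals",
    "intersect_interval_sets",
    "merge_replicate_peaks",
    "define_crms",
    "variant_maf",
    "filter_variants",
    "patch_sequence",
    "enumerate_haplotypes",
]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CRM:
    """A merged multi-TF binding interval with its reference sequence."""

    id: str
    interval: GenomicInterval
    bound_tfs: frozenset
    reference_sequence: str

    def __post_init__(self) -> None:
        if not self.bound_tfs:
            raise ValueError("CRM must be bound by at least one TF")
        if len(self.reference_sequence) != len(self.interval):
            raise ValueError("CRM sequence length must equal interval length")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant with phased genotypes over 2N chromosomes.

    ``pos`` is 1-based as in VCF; ``start``/``end`` expose the 0-based
    half-open span of the reference allele.  ``genotypes`` holds one
    0/1 entry per chromosome copy, individuals contributing copies
    ``2i`` and ``2i + 1``.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("VCF positions are 1-based")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError("variant must be biallelic with ref != alt")
        gt = np.asarray(self.genotypes, dtype=np.int8)
        if gt.ndim != 1 or gt.size % 2 != 0:
            raise ValueError("genotypes must be one flat 0/1 vector over 2N chromosomes")
        if not np.isin(gt, (0, 1)).all():
            raise ValueError("genotypes must be 0/1")
        object.__setattr__(self, "genotypes", gt)

    @property
    def start(self) -> int:
        return self.pos - 1

    @property
    def end(self) -> int:
        return self.pos - 1 + len(self.ref)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class Haplotype:
    sequence: str
    alleles: tuple
    carriers: tuple  # chromosome-copy indices in 0..2N-1


@dataclass(frozen=True)
class HaplotypeSet:
    crm_id: str
    haplotypes: tuple
    reference_index: int | None  # index of the all-reference haplotype, if carried

    def __len__(self) -> int:
        return len(self.haplotypes)

    def haplotype_of_chromosome(self) -> np.ndarray:
        """Map each chromosome copy to its haplotype index."""
        n_chrom = sum(len(h.carriers) for h in self.haplotypes)
        out = np.empty(n_chrom, dtype=int)
        for k, hap in enumerate(self.haplotypes):
            out[list(hap.carriers)] = k
        return out


# ---------------------------------------------------------------------------
# interval algebra


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of half-open intervals on one chromosome; touching stays split.

    Returns disjoint intervals sorted by start.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def intersect_interval_sets(a, b) -> list[tuple[int, int]]:
    """Per-base intersection of two half-open interval sets (one chromosome)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def merge_replicate_peaks(peak_sets, tf: str, union_exception: bool = False):
    """Combine replicate peak sets for one TF.

    The per-base intersection is taken across replicates, unless
    ``union_exception`` is set (the atlas on which this design is based
    took the union for one TF whose replicates differed greatly in depth),
    in which case the per-base union is returned.  Intervals are
    ``(start, end)`` pairs on a single chromosome.
    """
    if not peak_sets:
        raise ValueError(f"no peak sets supplied for TF {tf}")
    if len(peak_sets) == 1:
        return merge_intervals(peak_sets[0])
    if union_exception:
        return merge_intervals([iv for ps in peak_sets for iv in ps])
    result = merge_intervals(peak_sets[0])
    for ps in peak_sets[1:]:
        result = intersect_interval_sets(result, ps)
    return result


def define_crms(per_tf_peaks: dict, genome: str, chrom: str = "chr1") -> list[CRM]:
    """Build CRMs as connected components of the union of all TFs' peaks.

    Two peaks merge iff they share >= 1 bp; each CRM's bound-TF set is
    every TF with >= 1 bp of peak overlapping the CRM.  ``genome`` is the
    reference sequence of ``chrom`` used to attach each CRM's sequence.
    """
    all_ivs = [iv for ivs in per_tf_peaks.values() for iv in ivs]
    crm_spans = merge_intervals(all_ivs)
    crms: list[CRM] = []
    for k, (s, e) in enumerate(crm_spans):
        bound = frozenset(
            tf
            for tf, ivs in per_tf_peaks.items()
            if any(ps < e and s < pe for ps, pe in ivs)
        )
        crms.append(
            CRM(
                id=f"crm_{k:05d}",
                interval=GenomicInterval(chrom, s, e),
                bound_tfs=bound,
                reference_sequence=genome[s:e],
            )
        )
    return crms


# ---------------------------------------------------------------------------
# variant panel


def variant_maf(genotypes: np.ndarray) -> float:
    """Minor allele frequency over all 2N chromosome copies."""
    f = float(np.mean(genotypes))
    return min(f, 1.0 - f)


def filter_variants(
    records,
    genome: str | None = None,
    min_maf: float = 0.05,
) -> list[VariantRecord]:
    """Retain phased biallelic variants with panel MAF >= ``min_maf``.

    ``records`` may be :class:`VariantRecord` instances or raw tuples
    ``(id, chrom, pos, ref, alt_field, genotypes)`` where a comma in
    ``alt_field`` marks a multi-allelic record (dropped).  The MAF
    threshold keeps records at exactly ``min_maf`` (only strictly rarer
    alleles are removed).  If ``genome`` is given, the ref allele is
    checked against it and mismatches raise.
    """
    kept: list[VariantRecord] = []
    for rec in records:
        if not isinstance(rec, VariantRecord):
            vid, chrom, pos, ref, alt, gt = rec
            if "," in alt:
                continue
            rec = VariantRecord(vid, chrom, int(pos), ref, alt, np.asarray(gt))
        if variant_maf(rec.genotypes) < min_maf:
            continue
        if genome is not None:
            observed = genome[rec.start : rec.end]
            if observed != rec.ref:
                raise ValueError(
                    f"variant {rec.id}: ref allele {rec.ref!r} does not match "
                    f"reference sequence {observed!r} at pos {rec.pos}"
                )
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# haplotype enumeration


def patch_sequence(reference: str, offset: int, variants, alleles) -> str:
    """Apply alt alleles to ``reference`` (whose genomic start is ``offset``).

    Variants are applied left to right; an indel shifts downstream
    coordinates within the patched sequence only.  Overlapping reference
    spans of two applied variants conflict and raise.
    """
    events = sorted(
        (v for v, a in zip(variants, alleles) if a == 1), key=lambda v: v.start
    )
    out: list[str] = []
    cursor = 0
    prev = None
    for v in events:
        s, e = v.start - offset, v.end - offset
        if s < cursor:
            raise ValueError(
                f"conflicting overlapping variants {prev.id} and {v.id} "
                "on one haplotype"
            )
        out.append(reference[cursor:s])
        out.append(v.alt)
        cursor = e
        prev = v
    out.append(reference[cursor:])
    return "".join(out)


def enumerate_haplotypes(
    crm: CRM, variants, n_chromosomes: int | None = None
) -> HaplotypeSet:
    """Enumerate unique haplotypes of a CRM over all 2N chromosome copies.

    Unique haplotypes are unique combinations of SNP/indel alleles over
    the CRM's variants; each combination's sequence is the reference
    patched with its alt alleles.  Combinations that patch to an
    identical sequence (possible only with compensating indels) are
    merged so sequences stay pairwise distinct.
    """
    variants = sorted(variants, key=lambda v: v.pos)
    for v in variants:
        if v.chrom != crm.interval.chrom or not (
            v.start < crm.interval.end and v.end > crm.interval.start
        ):
            raise ValueError(f"variant {v.id} does not overlap CRM {crm.id}")
    if variants:
        n_chrom = len(variants[0].genotypes)
        if n_chromosomes is not None and n_chromosomes != n_chrom:
            raise ValueError("n_chromosomes disagrees with genotype vectors")
        combos = np.stack([v.genotypes for v in variants], axis=1)
    else:
        n_chrom = n_chromosomes or 0
        combos = None

    ref = crm.reference_sequence
    offset = crm.interval.start
    by_seq: dict[str, tuple[tuple, list[int]]] = {}
    if combos is None:
        by_seq[ref] = ((), [])
    else:
        order: dict[tuple, str] = {}
        for c in range(n_chrom):
            key = tuple(int(x) for x in combos[c])
            if key not in order:
                order[key] = patch_sequence(ref, offset, variants, key)
            seq = order[key]
            if seq in by_seq:
                by_seq[seq][1].append(c)
            else:
                by_seq[seq] = (key, [c])

    haplotypes = tuple(
        Haplotype(sequence=seq, alleles=key, carriers=tuple(carr))
        for seq, (key, carr) in by_seq.items()
    )
    ref_index = next(
        (k for k, h in enumerate(haplotypes) if not any(h.alleles)), None
    )
    if combos is None:
        # invariant CRM: single reference haplotype carried by everyone
        haplotypes = (
            Haplotype(sequence=ref, alleles=(), carriers=tuple(range(n_chrom))),
        )
        ref_index = 0
    return HaplotypeSet(crm_id=crm.id, haplotypes=haplotypes, reference_index=ref_index)
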