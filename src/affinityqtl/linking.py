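"""Assign CRMs to putative target genes.

Two evidence classes are used: *distal* links through significant
promoter-capture interactions (a CRM overlapping the promoter-interacting
other-end fragment of an interaction with score >= 5 whose bait promoter
maps to a single gene), and *proximal* links through a fixed +/- 9 kb
window around the midpoint of the promoter-containing fragment (the
capture assay excludes fragments adjacent to the bait, creating a blind
window that the proximal rule covers).  Overlap everywhere means >= 1 bp
under half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DEFAULT_SCORE_MIN = 5.0
DEFAULT_PROXIMAL_WINDOW = 9_000

__all__ = [
    "CRMGeneLink",
    "filter_baits",
    "link_distal",
    "link_proximal",
    "combine_links",
]


@dataclass(frozen=True)
class CRMGeneLink:
    crm_id: str
    gene: str
    link_class: str  # "distal" | "proximal"
    evidence: float  # interaction score (distal) or bp distance (proximal)


def filter_baits(baits) -> dict:
    """Keep promoter baits annotated with exactly one gene.

    ``baits`` is an iterable of ``(fragment_id, gene_ids)``; fragments
    with zero or multiple annotated TSS genes are dropped.  Returns a
    ``fragment_id -> gene`` mapping.
    """
    kept = {}
    for frag_id, genes in baits:
        genes = set(genes)
        if len(genes) == 1:
            kept[frag_id] = next(iter(genes))
    return kept


def _fragment_lookup(fragment_map: pd.DataFrame) -> dict:
    return {
        row.fragment_id: (row.chrom, int(row.start), int(row.end))
        for row in fragment_map.itertuples()
    }


def link_distal(
    crms,
    interactions: pd.DataFrame,
    fragment_map: pd.DataFrame,
    baits: dict,
    score_min: float = DEFAULT_SCORE_MIN,
) -> list[CRMGeneLink]:
    """Links via significant interactions (score >= ``score_min``).

    ``interactions`` needs columns ``bait_id``, ``other_end_id``,
    ``score``; ``baits`` is the filtered single-gene bait map.
    """
    frags = _fragment_lookup(fragment_map)
    chroms = {f[0] for f in frags.values()}
    links: dict[tuple, CRMGeneLink] = {}
    sig = interactions[interactions["score"] >= score_min]
    for crm in crms:
        if crm.interval.chrom not in chroms:
            raise ValueError(
                f"CRM chromosome {crm.interval.chrom} absent from fragment map"
            )
        for row in sig.itertuples():
            gene = baits.get(row.bait_id)
            if gene is None:
                continue
            chrom, fs, fe = frags[row.other_end_id]
            if (
                chrom == crm.interval.chrom
                and crm.interval.start < fe
                and fs < crm.interval.end
            ):
                key = (crm.id, gene)
                score = float(row.score)
                if key not in links or score > links[key].evidence:
                    links[key] = CRMGeneLink(crm.id, gene, "distal", score)
    return list(links.values())


def link_proximal(
    crms,
    fragment_map: pd.DataFrame,
    baits: dict,
    window: int = DEFAULT_PROXIMAL_WINDOW,
) -> list[CRMGeneLink]:
    """Links via the +/- ``window`` bp span around bait-fragment midpoints.

    The window around midpoint ``m = floor((start + end) / 2)`` is the
    half-open interval ``[m - window, m + window)``; a CRM is linked iff
    it overlaps it by >= 1 bp.
    """
    frags = _fragment_lookup(fragment_map)
    links: dict[tuple, CRMGeneLink] = {}
    for frag_id, gene in baits.items():
        chrom, fs, fe = frags[frag_id]
        mid = (fs + fe) // 2
        ws, we = mid - window, mid + window
        for crm in crms:
            if (
                crm.interval.chrom == chrom
                and crm.interval.start < we
                and ws < crm.interval.end
            ):
                crm_mid = (crm.interval.start + crm.interval.end) // 2
                dist = float(abs(crm_mid - mid))
                key = (crm.id, gene)
                if key not in links or dist < links[key].evidence:
                    links[key] = CRMGeneLink(crm.id, gene, "proximal", dist)
    return list(links.values())


def combine_links(distal, proximal) -> list[CRMGeneLink]:
    """De-duplicate (crm, gene) pairs; a pair in both classes stays proximal."""
    out = {(l.crm_id, l.gene): l for l in distal}
    for l in proximal:
        out[(l.crm_id, l.gene)] = l
    return list(out.values())
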