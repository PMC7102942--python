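"""Readers and writers for the plain-text interchange formats.

All tables are tab-delimited; coordinates in BED-like files are 0-based
half-open, the variant panel uses VCF-style 1-based positions with
phased ``0|1`` genotype fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .crm import VariantRecord

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_bed",
    "write_variant_panel",
    "read_variant_panel",
    "write_table",
    "write_atlas_table",
    "write_manifest",
]


def write_fasta(sequences: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> dict:
    """Read a FASTA file into a name -> sequence dict (via pyfaidx)."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed(intervals, path, chrom: str = "chr1") -> None:
    """Write (start, end[, name]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [chrom, str(iv[0]), str(iv[1])] + [str(x) for x in iv[2:]]
            fh.write("\t".join(fields) + "\n")


def write_variant_panel(variants, individuals, path) -> None:
    """Write a VCF-like panel with phased GT columns per individual."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCF-like\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "FORMAT"] + list(individuals)
        fh.write("\t".join(header) + "\n")
        for v in variants:
            gts = [
                f"{v.genotypes[2 * i]}|{v.genotypes[2 * i + 1]}"
                for i in range(len(individuals))
            ]
            row = [v.chrom, str(v.pos), v.id, v.ref, v.alt, "GT"] + gts
            fh.write("\t".join(row) + "\n")


def read_variant_panel(path) -> list[VariantRecord]:
    """Read a panel written by :func:`write_variant_panel`.

    Unphased genotype fields (``/`` separator) are rejected: haplotype
    enumeration requires phase.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, vid, ref, alt = fields[:5]
            gts = []
            for cell in fields[6:]:
                if "|" not in cell:
                    raise ValueError(
                        f"unphased genotype {cell!r} for variant {vid}: "
                        "the panel must be phased"
                    )
                a, b = cell.split("|")
                gts.extend([int(a), int(b)])
            records.append(
                VariantRecord(vid, chrom, int(pos), ref, alt, np.array(gts))
            )
    return records


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_atlas_table(atlas, path) -> None:
    """Write the affinity-variant atlas as a tab-delimited table."""
    rows = []
    for av in atlas:
        for h, s in enumerate(av.log_fca):
            rows.append(
                {
                    "crm_id": av.crm_id,
                    "tf": av.tf,
                    "haplotype": h,
                    "log_fca": s,
                    "sign_convention": av.sign_convention,
                    "ref_best_a": av.ref_best_a,
                    "ref_best_haplotype": av.ref_best_haplotype,
                }
            )
    write_table(pd.DataFrame(rows), path)


def write_manifest(truth, path) -> None:
    """Record the synthetic ground truth (planted effects, null genes)."""
    payload = {
        "planted": [
            {
                "gene": p.gene,
                "chrom": p.chrom,
                "region_start": p.region_start,
                "region_end": p.region_end,
                "tf": p.tf,
                "beta": p.beta,
                "variant_id": p.variant_id,
                "link_class": p.link_class,
            }
            for p in truth.planted
        ],
        "null_genes": list(truth.null_genes),
        "unexpressed_genes": list(truth.unexpressed_genes),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
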