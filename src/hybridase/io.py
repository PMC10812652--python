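"""File-format helpers: FASTA, variant TSV, minimal VCF export."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqvar import HaplotypeSet, Variant, format_variant


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    with open(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def variants_to_dataframe(variants: Iterable[Variant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        row = {
            "label": v.label,
            "position": v.position,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
            "vclass": v.vclass,
            "rendering": format_variant(v),
        }
        row.update(v.genotypes)
        rows.append(row)
    return pd.DataFrame(rows)


def write_variants_tsv(variants: Iterable[Variant], path: str | Path) -> None:
    variants_to_dataframe(variants).to_csv(path, sep="\t", index=False)


def write_vcf(
    variants: Iterable[Variant],
    reference: HaplotypeSet,
    path: str | Path,
    contig: str | None = None,
) -> None:
    """Minimal VCF 4.2 export on a synthetic contig named after the region.

    TSS-relative positions map to 1-based contig POS as
    ``POS = index_of_pos(position) + 1``; for promoters that places -L at
    POS 1 and -1 at POS L (the mapping is recorded in the header).  Indels
    are anchored on the preceding reference base as VCF requires.
    """
    contig = contig or reference.region
    seq = reference.sequence
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={len(seq)}>",
        "##INFO=<ID=TSSPOS,Number=1,Type=Integer,"
        'Description="TSS-relative position (+1 = transcription start, no zero)">',
        f"##tss_mapping=POS=0-based_index_of_TSS_position+1;tss_offset={reference.tss_offset}",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in sorted(variants, key=lambda v: v.position):
        idx = reference.index_of_pos(v.position)
        ref_b, alt_b = v.ref_bases, v.alt_bases
        if v.vclass == "substitution":
            pos, ref, alt = idx + 1, ref_b, alt_b
        else:
            # anchor on the preceding base
            if idx == 0:
                anchor = ""
                pos = 1
            else:
                anchor = seq[idx - 1]
                pos = idx
            if v.vclass == "insertion":
                ref, alt = anchor, anchor + alt_b
            else:  # deletion or complex
                ref, alt = anchor + ref_b, anchor + alt_b
            if not ref or not alt:
                ref, alt = ref or ".", alt or "."
        lines.append(
            f"{contig}\t{pos}\t{v.label or '.'}\t{ref}\t{alt}\t.\t.\t"
            f"TSSPOS={v.position}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
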