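"""Promoter-allele comparison: variants in negative TSS coordinates and
transcription-factor binding-site (TFBS) gains/losses.

The scanner is an exact IUPAC-consensus matcher (the field's printed motif
descriptions are consensus octamers, not matrices); PWM scoring is out of
scope.  Site presence is compared across alleles through the
homologous-coordinate map of the pairwise alignment, so indels between the
alleles do not misalign sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import seqvar
from .seqvar import (
    PROMOTER,
    HaplotypeSet,
    SeqVarError,
    Variant,
    _AMBIG,
    align_pair,
    alignment_index_maps,
    shift_pos,
)

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDef:
    """A named IUPAC consensus motif (e.g. Hoxb6 TTAAGTAC)."""

    name: str
    consensus: str
    strand_policy: str = "forward"

    def __post_init__(self) -> None:
        cons = self.consensus.upper()
        object.__setattr__(self, "consensus", cons)
        if len(cons) < 4:
            raise ValueError("motif consensus must be at least 4 nt")
        bad = set(cons) - set(_AMBIG)
        if bad:
            raise ValueError(f"non-IUPAC letters in consensus: {sorted(bad)}")
        if self.strand_policy not in ("forward", "both"):
            raise ValueError(f"unknown strand_policy {self.strand_policy!r}")


@dataclass(frozen=True)
class MotifHit:
    """One consensus occurrence; start/end are inclusive TSS positions."""

    motif: str
    start: int
    end: int
    strand: str
    sequence: str
    start_index: int  # 0-based index into the scanned allele


@dataclass(frozen=True)
class MotifDiff:
    """A binding site present in exactly one allele of the pair."""

    motif: str
    allele_with_site: str
    site_span: tuple[int, int]
    overlapping_variant: str | None
    direction: str  # "gained-in-P1" | "gained-in-P2"
    overlapping_variants: tuple[str, ...] = ()


def load_motifs(path: str | Path) -> list[MotifDef]:
    """Read a motif TSV with columns ``name, consensus, strand_policy``."""
    df = pd.read_csv(path, sep="\t")
    return [
        MotifDef(
            name=str(r["name"]),
            consensus=str(r["consensus"]),
            strand_policy=str(r.get("strand_policy", "forward") or "forward"),
        )
        for _, r in df.iterrows()
    ]


def _matches(window: str, consensus: str) -> bool:
    return all(b in _AMBIG[c] for b, c in zip(window, consensus))


def scan_motifs(
    allele: HaplotypeSet, motifs: Iterable[MotifDef]
) -> list[MotifHit]:
    """Report every IUPAC-consensus occurrence with its TSS-relative span.

    Overlapping hits are all reported.  The scanned sequence must be
    unambiguous (consensus ambiguity belongs to the motif side only).
    """
    if allele.is_ambiguous:
        raise SeqVarError("cannot scan an ambiguous sequence for motifs")
    seq = allele.sequence
    hits: list[MotifHit] = []
    for motif in motifs:
        patterns = [(motif.consensus, "+")]
        if motif.strand_policy == "both":
            patterns.append((revcomp(motif.consensus), "-"))
        w = len(motif.consensus)
        for pattern, strand in patterns:
            for i in range(len(seq) - w + 1):
                window = seq[i : i + w]
                if _matches(window, pattern):
                    start = allele.pos_of_index(i)
                    hits.append(
                        MotifHit(
                            motif=motif.name,
                            start=start,
                            end=shift_pos(start, w - 1),
                            strand=strand,
                            sequence=window,
                            start_index=i,
                        )
                    )
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


def call_promoter_variants(
    p1: HaplotypeSet,
    p2: HaplotypeSet,
    hybrid: HaplotypeSet | Sequence[HaplotypeSet] | None = None,
    genotype_table: pd.DataFrame | None = None,
) -> list[Variant]:
    """Call variants between two promoter alleles (negative coordinates).

    Thin wrapper over :func:`hybridase.seqvar.call_variants` that enforces
    the promoter coordinate frame (3'-most base is -1) and labels variants
    ``S'1..S'k``.
    """
    for hap in (p1, p2):
        if hap.region != PROMOTER:
            raise SeqVarError(
                f"{hap.group_id!r} is not a promoter region haplotype"
            )
    return seqvar.call_variants(
        p1, p2, hybrid=hybrid, genotype_table=genotype_table, label_prefix="S'"
    )


def _overlapping_labels(
    span: tuple[int, int], variants: Iterable[Variant]
) -> list[str]:
    lo, hi = span
    out = []
    for v in variants:
        vlo, vhi = v.span
        # adjacency counts: a variant immediately flanking the site can
        # still create or destroy it
        if vhi >= shift_pos(lo, -1) and vlo <= shift_pos(hi, 1):
            out.append(v.label or f"g.{v.position}")
    return out


def diff_tfbs(
    p1: HaplotypeSet,
    p2: HaplotypeSet,
    variants: Sequence[Variant],
    motifs: Iterable[MotifDef],
) -> list[MotifDiff]:
    """Detect binding sites present in exactly one of two promoter alleles.

    Hits are paired across alleles by the homologous start coordinate from
    the pairwise alignment; a site whose homologous window in the other
    allele no longer matches the consensus is emitted as a gain in the
    allele that has it, annotated with the overlapping variant(s).
    """
    motifs = list(motifs)
    r1, r2 = align_pair(p1.sequence, p2.sequence)
    map12, map21 = alignment_index_maps(r1, r2)
    hits1 = scan_motifs(p1, motifs)
    hits2 = scan_motifs(p2, motifs)
    keys2 = {(h.motif, h.strand, h.start_index) for h in hits2}
    keys1 = {(h.motif, h.strand, h.start_index) for h in hits1}

    diffs: list[MotifDiff] = []
    for h in hits1:
        j = map12.get(h.start_index)
        if j is not None and (h.motif, h.strand, j) in keys2:
            continue
        labels = _overlapping_labels((h.start, h.end), variants)
        diffs.append(
            MotifDiff(
                motif=h.motif,
                allele_with_site=p1.group_id,
                site_span=(h.start, h.end),
                overlapping_variant=labels[0] if labels else None,
                direction="gained-in-P1",
                overlapping_variants=tuple(labels),
            )
        )
    for h in hits2:
        i = map21.get(h.start_index)
        if i is not None and (h.motif, h.strand, i) in keys1:
            continue
        # express the span in the p1 frame for variant overlap; fall back to
        # the nearest mapped base when the start sits inside an insertion
        i_anchor = i
        k = h.start_index
        while i_anchor is None and k > 0:
            k -= 1
            i_anchor = map21.get(k)
        if i_anchor is None:
            i_anchor = 0
        p1_start = p1.pos_of_index(i_anchor)
        w = h.end - h.start + (0 if (h.start < 0 <= h.end) else 1)
        labels = _overlapping_labels(
            (p1_start, shift_pos(p1_start, w - 1)), variants
        )
        diffs.append(
            MotifDiff(
                motif=h.motif,
                allele_with_site=p2.group_id,
                site_span=(h.start, h.end),
                overlapping_variant=labels[0] if labels else None,
                direction="gained-in-P2",
                overlapping_variants=tuple(labels),
            )
        )
    diffs.sort(key=lambda d: (d.site_span[0], d.motif))
    return diffs
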