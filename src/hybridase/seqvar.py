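"""Variant discovery and coding annotation on TSS-anchored haplotypes.

Sequences are anchored to the transcription start site (TSS): the first
transcribed base is position +1 and the base immediately upstream is -1.
There is no position 0.  Transcript-side variants therefore carry positive
positions and promoter-side variants negative ones.  Internally all
sequences use ordinary 0-based indices; the conversion happens only at the
coordinate helpers on :class:`HaplotypeSet`.

Variant calling is pairwise global alignment (Needleman-Wunsch; match +1,
mismatch -1, gap open -4, gap extend -1) followed by extraction of maximal
runs of difference columns.  Indels are left-normalised and rendered in a
compact gap-padded dialect, e.g. ``g. -314 TTT > ---`` for a 3-bp deletion
or ``g. -238 C-- > AAG`` for a mixed substitution/insertion run.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Data import CodonTable, IUPACData

TRANSCRIPT = "transcript"
PROMOTER = "promoter"

# genotype call vocabulary
HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"
POLY = "polymorphic"

_AMBIG: dict[str, frozenset[str]] = {
    code.upper(): frozenset(bases.upper())
    for code, bases in IUPACData.ambiguous_dna_values.items()
    if code.upper() != "X"
}
_IUPAC_OF: dict[frozenset[str], str] = {}
for _code, _bases in _AMBIG.items():
    _IUPAC_OF.setdefault(_bases, _code)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_STANDARD_TABLE.stop_codons)


class SeqVarError(ValueError):
    """Base error for sequence/variant validation problems."""


class AlignmentError(SeqVarError):
    """Raised when two sequences cannot be sensibly aligned."""


class GenotypeConflictError(SeqVarError):
    """Hybrid consensus base is inconsistent with both parental alleles."""


def iupac_code(bases: Iterable[str]) -> str:
    """Return the IUPAC ambiguity code covering ``bases`` (e.g. {G,A} -> R)."""
    key = frozenset(b.upper() for b in bases)
    try:
        return _IUPAC_OF[key]
    except KeyError:  # pragma: no cover - defensive
        raise SeqVarError(f"no IUPAC code for base set {sorted(key)}")


@dataclass(frozen=True)
class HaplotypeSet:
    """One group's consensus sequence for one region, anchored to the TSS.

    Parameters
    ----------
    group_id:
        Sample group label, e.g. ``NL`` (parent 1), ``AR`` (parent 2), ``HY``.
    region:
        ``"transcript"`` (5'UTR+CDS+3'UTR, starts at +1) or ``"promoter"``
        (ends at -1, the base immediately 5' of the TSS).
    sequence:
        Upper-case nucleotides.  Parental consensus sequences must be plain
        ACGT; only hybrids may carry IUPAC ambiguity codes (diploid Sanger
        consensus).
    tss_offset:
        0-based index of the base that is position +1.  Defaults to 0 for
        transcripts and ``len(sequence)`` for promoters (whose last base is
        position -1).
    """

    group_id: str
    region: str
    sequence: str
    tss_offset: int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise SeqVarError("sequence must be non-empty")
        bad = set(seq) - set(_AMBIG)
        if bad:
            raise SeqVarError(f"illegal characters in sequence: {sorted(bad)}")
        if self.region not in (TRANSCRIPT, PROMOTER):
            raise SeqVarError(f"unknown region {self.region!r}")
        if self.tss_offset is None:
            off = 0 if self.region == TRANSCRIPT else len(seq)
            object.__setattr__(self, "tss_offset", off)
        if not (0 <= self.tss_offset <= len(seq)):
            raise SeqVarError("tss_offset out of bounds")
        if self.region == PROMOTER and self.tss_offset != len(seq):
            raise SeqVarError("promoter regions must end at position -1")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_ambiguous(self) -> bool:
        return any(c not in "ACGT" for c in self.sequence)

    def pos_of_index(self, i: int) -> int:
        """TSS-relative position of 0-based index ``i`` (never 0)."""
        d = i - self.tss_offset
        return d + 1 if d >= 0 else d

    def index_of_pos(self, p: int) -> int:
        """0-based index of TSS-relative position ``p``."""
        if p == 0:
            raise SeqVarError("position 0 does not exist in TSS coordinates")
        i = p - 1 + self.tss_offset if p > 0 else p + self.tss_offset
        if not (0 <= i < len(self.sequence)):
            raise SeqVarError(f"position {p} outside sequence")
        return i


def shift_pos(p: int, k: int) -> int:
    """Advance a TSS-relative position ``k`` bases 3'-ward, skipping 0."""
    q = p + k
    if p < 0 <= q:
        q += 1
    return q


@dataclass
class Variant:
    """One polymorphic site between two haplotypes.

    ``ref_allele`` is the parent-1 allele and ``alt_allele`` the parent-2
    allele; both are gap-padded to equal length (``-`` marks absent bases)
    so that deletions render as ``TTT > ---`` and mixed runs as
    ``C-- > AAG``.  ``position`` labels the 5'-most reference base of the
    site (for pure insertions, the reference base immediately 3' of the
    inserted material).
    """

    position: int
    ref_allele: str
    alt_allele: str
    vclass: str
    genotypes: dict[str, str] = field(default_factory=dict)
    label: str | None = None

    def __post_init__(self) -> None:
        if self.position == 0:
            raise SeqVarError("variant position 0 is illegal")
        ref, alt = self.ref_allele.upper(), self.alt_allele.upper()
        width = max(len(ref), len(alt))
        ref, alt = ref.ljust(width, "-"), alt.ljust(width, "-")
        self.ref_allele, self.alt_allele = ref, alt
        if ref == alt:
            raise SeqVarError("ref_allele and alt_allele must differ")
        if not (self.ref_bases or self.alt_bases):
            raise SeqVarError("at least one allele must contain bases")
        if self.vclass not in ("substitution", "insertion", "deletion", "complex"):
            raise SeqVarError(f"unknown vclass {self.vclass!r}")

    @property
    def ref_bases(self) -> str:
        return self.ref_allele.replace("-", "")

    @property
    def alt_bases(self) -> str:
        return self.alt_allele.replace("-", "")

    @property
    def span(self) -> tuple[int, int]:
        """Inclusive TSS positions covered by the reference bases."""
        n = max(1, len(self.ref_bases))
        return (self.position, shift_pos(self.position, n - 1))


@dataclass
class CodingAnnotation:
    """Effect of a coding substitution on the encoded protein.

    ``ref_aa``/``alt_aa`` use one-letter amino-acid codes with ``*`` for a
    stop codon; a stop-to-stop change counts as synonymous.
    """

    codon_index: int
    codon_position: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    synonymous: bool


_VARIANT_RE = re.compile(
    r"^g\.\s*([−-]?)(\d+)\s+([ACGTN-]+)\s*>\s*([ACGTN-]+)$"
)


def format_variant(v: Variant) -> str:
    """Render a variant in the field's compact dialect, e.g. ``g. -314 TTT > ---``."""
    return f"g. {v.position} {v.ref_allele} > {v.alt_allele}"


def parse_variant(text: str) -> Variant:
    """Parse ``g. <pos> <ref> > <alt>`` (ASCII hyphen or Unicode minus)."""
    m = _VARIANT_RE.match(text.strip())
    if not m:
        raise SeqVarError(f"cannot parse variant string {text!r}")
    sign, digits, ref, alt = m.groups()
    pos = -int(digits) if sign else int(digits)
    vclass = _classify_alleles(ref, alt)
    return Variant(position=pos, ref_allele=ref, alt_allele=alt, vclass=vclass)


def _classify_alleles(ref: str, alt: str) -> str:
    refb, altb = ref.replace("-", ""), alt.replace("-", "")
    if not altb:
        return "deletion"
    if not refb:
        return "insertion"
    if len(refb) == len(altb) and "-" not in ref and "-" not in alt:
        return "substitution"
    return "complex"


# ---------------------------------------------------------------------------
# alignment


def make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -4.0
    a.extend_gap_score = -1.0
    return a


def align_pair(
    s1: str, s2: str, *, min_identity: float = 0.7
) -> tuple[str, str]:
    """Globally align two sequences; return the gapped rows.

    Raises :class:`AlignmentError` when the sequences are of grossly
    different length or align with identity below ``min_identity``.
    Indel placement within repeats is normalised downstream at the variant
    level (left alignment), not by rewriting alignment columns.
    """
    if not s1 or not s2:
        raise AlignmentError("cannot align empty sequences")
    if abs(len(s1) - len(s2)) > 0.2 * max(len(s1), len(s2)):
        raise AlignmentError(
            f"sequence lengths {len(s1)} and {len(s2)} are too different for "
            "a global alignment"
        )
    aln = make_aligner().align(s1, s2)[0]
    r1, r2 = str(aln[0]), str(aln[1])
    matches = sum(1 for a, b in zip(r1, r2) if a == b and a != "-")
    if matches / len(r1) < min_identity:
        raise AlignmentError(
            f"alignment identity {matches / len(r1):.2f} below {min_identity}"
        )
    return r1, r2


def alignment_index_maps(
    r1: str, r2: str
) -> tuple[dict[int, int | None], dict[int, int | None]]:
    """Homologous-coordinate maps (0-based index in seq1 <-> seq2).

    Indices falling inside an indel map to ``None``.
    """
    map12: dict[int, int | None] = {}
    map21: dict[int, int | None] = {}
    i1 = i2 = 0
    for c1, c2 in zip(r1, r2):
        if c1 != "-" and c2 != "-":
            map12[i1] = i2
            map21[i2] = i1
        if c1 != "-":
            if c2 == "-":
                map12[i1] = None
            i1 += 1
        if c2 != "-":
            if c1 == "-":
                map21[i2] = None
            i2 += 1
    return map12, map21


# ---------------------------------------------------------------------------
# variant calling


def _glue_gap_runs(r1: str, r2: str) -> tuple[str, str]:
    """Shift gap runs rightward (score-equivalently) onto an adjacent
    difference column, so a substitution with a neighbouring indel forms a
    single complex run instead of two records split by a spurious match.
    Isolated indels are left untouched (they are left-aligned later at the
    variant level)."""
    rows = [list(r1), list(r2)]
    n = len(rows[0])

    def is_diff(c: int) -> bool:
        return rows[0][c] != rows[1][c]

    for g in (0, 1):  # row carrying the gaps
        gapped, other = rows[g], rows[1 - g]
        a = 0
        while a < n:
            if gapped[a] != "-":
                a += 1
                continue
            b = a
            while b < n and gapped[b] == "-":
                b += 1
            if b < n and not is_diff(b) and (a == 0 or not is_diff(a - 1)):
                # find the smallest valid right shift k landing next to a diff
                k = 0
                while (
                    b + k < n
                    and not is_diff(b + k)
                    and gapped[b + k] != "-"
                    and other[a + k] == other[b + k]
                ):
                    k += 1
                if k > 0 and b + k < n and is_diff(b + k):
                    for i in range(k):
                        gapped[a + i] = gapped[b + i]
                        gapped[b + i] = "-"
                    a, b = a + k, b + k
            a = b
    return "".join(rows[0]), "".join(rows[1])


def _runs_to_variants(r1: str, r2: str, p1: HaplotypeSet) -> list[Variant]:
    variants: list[Variant] = []
    n = len(r1)
    i1 = 0  # bases of seq1 consumed
    c = 0
    while c < n:
        if r1[c] == r2[c]:
            if r1[c] != "-":
                i1 += 1
            c += 1
            continue
        # maximal run of difference columns
        start = c
        i1_start = i1
        first_ref_index: int | None = None
        while c < n and r1[c] != r2[c]:
            if r1[c] != "-":
                if first_ref_index is None:
                    first_ref_index = i1
                i1 += 1
            c += 1
        ref = "".join(ch for ch in r1[start:c] if ch != "-")
        alt = "".join(ch for ch in r2[start:c] if ch != "-")
        anchor = first_ref_index if first_ref_index is not None else i1_start
        if anchor >= len(p1.sequence):  # pure insertion at the 3' end
            anchor = len(p1.sequence) - 1
        # left-align pure indels within repeat context (the 5'-most
        # equivalent placement is the canonical one)
        s1 = p1.sequence
        if ref and not alt:  # deletion
            while anchor > 0 and s1[anchor - 1] == ref[-1]:
                anchor -= 1
                ref = s1[anchor] + ref[:-1]
        elif alt and not ref:  # insertion
            while anchor > 0 and s1[anchor - 1] == alt[-1]:
                anchor -= 1
                alt = s1[anchor] + alt[:-1]
        variants.append(
            Variant(
                position=p1.pos_of_index(anchor),
                ref_allele=ref,
                alt_allele=alt,
                vclass=_classify_alleles(
                    ref.ljust(max(len(ref), len(alt)), "-"),
                    alt.ljust(max(len(ref), len(alt)), "-"),
                ),
            )
        )
    return variants


def _diff_positions(p1: HaplotypeSet, hap: HaplotypeSet) -> set[tuple[int, str, str]]:
    r1, r2 = _glue_gap_runs(*align_pair(p1.sequence, hap.sequence))
    return {
        (v.position, v.ref_allele, v.alt_allele)
        for v in _runs_to_variants(r1, r2, p1)
    }


def _hybrid_genotype_from_consensus(
    v: Variant, p1: HaplotypeSet, hybrid_char_at: Mapping[int, str | None]
) -> str | None:
    if v.vclass != "substitution":
        return None  # indel heterozygosity is not decidable from one consensus
    calls = []
    idx = p1.index_of_pos(v.position)
    for k, (rc, ac) in enumerate(zip(v.ref_bases, v.alt_bases)):
        h = hybrid_char_at.get(idx + k)
        if h is None:
            return None
        bases = _AMBIG[h]
        if bases == {rc} or h == rc:
            calls.append(HOM_REF)
        elif bases == {ac} or h == ac:
            calls.append(HOM_ALT)
        elif rc in bases and ac in bases:
            calls.append(HET)
        else:
            raise GenotypeConflictError(
                f"hybrid base {h!r} at position {shift_pos(v.position, k)} is "
                f"inconsistent with parental alleles {rc}/{ac}"
            )
    if all(c == calls[0] for c in calls):
        return calls[0]
    raise GenotypeConflictError(
        f"inconsistent hybrid genotype across the site at position {v.position}"
    )


def call_variants(
    p1: HaplotypeSet,
    p2: HaplotypeSet,
    hybrid: HaplotypeSet | Sequence[HaplotypeSet] | None = None,
    genotype_table: pd.DataFrame | None = None,
    label_prefix: str = "S",
) -> list[Variant]:
    """Call every variant between two parental haplotypes.

    Parameters
    ----------
    p1, p2:
        Unambiguous parental consensus sequences over the same region.
    hybrid:
        Either a single consensus :class:`HaplotypeSet` (IUPAC ambiguity
        codes mark heterozygous sites) or a pair of phased haplotypes (used
        for promoters, where indel heterozygosity cannot be expressed in a
        single consensus).  Hybrid genotypes are attached where decidable.
    genotype_table:
        Optional per-group genotype overrides with columns
        ``position, group, genotype`` (genotype one of ``hom_ref``,
        ``hom_alt``, ``het``, ``polymorphic``).  Used to mark within-line
        polymorphisms that a single consensus per line cannot encode.
    label_prefix:
        Variants are labelled ``{prefix}1..{prefix}k`` in position order.

    Returns
    -------
    list of :class:`Variant`, sorted by position, ref allele = parent-1.
    """
    if p1.region != p2.region:
        raise SeqVarError("parental haplotypes must cover the same region")
    for hap in (p1, p2):
        if hap.is_ambiguous:
            raise SeqVarError(
                f"parental sequence {hap.group_id!r} contains ambiguity codes"
            )
    r1, r2 = _glue_gap_runs(*align_pair(p1.sequence, p2.sequence))
    variants = _runs_to_variants(r1, r2, p1)

    for v in variants:
        v.genotypes[p1.group_id] = HOM_REF
        v.genotypes[p2.group_id] = HOM_ALT

    if hybrid is not None:
        if isinstance(hybrid, HaplotypeSet):
            rh1, rh2 = align_pair(p1.sequence, hybrid.sequence)
            m12, _ = alignment_index_maps(rh1, rh2)
            char_at = {
                i: (hybrid.sequence[j] if j is not None else None)
                for i, j in m12.items()
            }
            for v in variants:
                call = _hybrid_genotype_from_consensus(v, p1, char_at)
                if call is not None:
                    v.genotypes[hybrid.group_id] = call
        else:
            hap_a, hap_b = hybrid
            in_a = _diff_positions(p1, hap_a)
            in_b = _diff_positions(p1, hap_b)
            for v in variants:
                key = (v.position, v.ref_allele, v.alt_allele)
                n_alt = (key in in_a) + (key in in_b)
                v.genotypes[hap_a.group_id] = (
                    HOM_REF, HET, HOM_ALT)[n_alt]

    if genotype_table is not None:
        _apply_genotype_table(variants, genotype_table, p1)

    variants.sort(key=lambda v: v.position)
    for k, v in enumerate(variants, start=1):
        v.label = f"{label_prefix}{k}"
    return variants


def _apply_genotype_table(
    variants: list[Variant], table: pd.DataFrame, p1: HaplotypeSet
) -> None:
    required = {"position", "group", "genotype"}
    if not required.issubset(table.columns):
        raise SeqVarError(f"genotype table must have columns {sorted(required)}")
    by_pos = {v.position: v for v in variants}
    for row in table.itertuples(index=False):
        pos = int(row.position)
        v = by_pos.get(pos)
        if v is None:
            # within-line polymorphism at a site where the consensuses agree;
            # requires explicit alleles to be representable
            if hasattr(row, "ref") and hasattr(row, "alt") and pd.notna(row.ref):
                v = Variant(
                    position=pos,
                    ref_allele=str(row.ref),
                    alt_allele=str(row.alt),
                    vclass=_classify_alleles(str(row.ref), str(row.alt)),
                )
                variants.append(v)
                by_pos[pos] = v
            else:
                continue
        v.genotypes[str(row.group)] = str(row.genotype)


def classify_fixed_differences(
    variants: Iterable[Variant], p1_group: str, p2_group: str
) -> dict[str, list[Variant]]:
    """Partition variants into fixed inter-parental differences vs polymorphic.

    A variant is *fixed* iff parent 1 is homozygous for one allele and
    parent 2 homozygous for the other.  The partition is exhaustive and
    disjoint; variants lacking a genotype for either parent raise.
    """
    fixed: list[Variant] = []
    poly: list[Variant] = []
    for v in variants:
        try:
            g1, g2 = v.genotypes[p1_group], v.genotypes[p2_group]
        except KeyError as exc:
            raise SeqVarError(
                f"missing genotype for group {exc.args[0]!r} at position "
                f"{v.position}"
            ) from None
        homs = {HOM_REF, HOM_ALT}
        if g1 in homs and g2 in homs and g1 != g2:
            fixed.append(v)
        else:
            poly.append(v)
    return {"fixed": fixed, "polymorphic": poly}


# ---------------------------------------------------------------------------
# coding annotation and translation


def _codon_aa(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    try:
        return _STANDARD_TABLE.forward_table[codon]
    except KeyError:
        raise SeqVarError(f"cannot translate codon {codon!r}")


def annotate_coding(
    variant: Variant,
    cds_start: int,
    cds_end: int,
    sequence: HaplotypeSet,
) -> CodingAnnotation | None:
    """Annotate a substitution inside the CDS as synonymous or not.

    Returns ``None`` for variants entirely outside ``[cds_start, cds_end]``
    (non-coding marker).  Indels inside the CDS raise (frameshifts are not
    supported).  ``sequence`` carries the reference (parent-1) alleles.
    """
    if (cds_end - cds_start + 1) % 3 != 0:
        raise SeqVarError("CDS length must be divisible by 3")
    lo, hi = variant.span
    if hi < cds_start or lo > cds_end:
        return None
    if lo < cds_start or hi > cds_end:
        raise SeqVarError(
            f"variant at {variant.position} straddles the CDS boundary"
        )
    if variant.vclass != "substitution":
        raise SeqVarError(
            f"indel at {variant.position} inside the CDS: frameshift "
            "annotation is unsupported"
        )
    offset = variant.position - cds_start
    codon_index = offset // 3 + 1
    codon_position = offset % 3 + 1
    cds_lo = sequence.index_of_pos(cds_start)
    cds_hi = sequence.index_of_pos(cds_end)
    ref_cds = sequence.sequence[cds_lo : cds_hi + 1]
    if ref_cds[offset : offset + len(variant.ref_bases)] != variant.ref_bases:
        raise SeqVarError(
            f"reference allele mismatch at position {variant.position}"
        )
    alt_cds = (
        ref_cds[:offset]
        + variant.alt_bases
        + ref_cds[offset + len(variant.ref_bases) :]
    )
    first = offset // 3
    last = (offset + len(variant.ref_bases) - 1) // 3
    ref_codon = ref_cds[first * 3 : (last + 1) * 3]
    alt_codon = alt_cds[first * 3 : (last + 1) * 3]
    ref_aa = "".join(_codon_aa(ref_codon[i : i + 3]) for i in range(0, len(ref_codon), 3))
    alt_aa = "".join(_codon_aa(alt_codon[i : i + 3]) for i in range(0, len(alt_codon), 3))
    return CodingAnnotation(
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        synonymous=ref_aa == alt_aa,
    )


def translate(cds: str) -> str:
    """Translate a complete ORF; returns residues without the terminal stop.

    Validates that the sequence length is divisible by 3, starts with ATG,
    ends with a stop codon, and contains no internal stop; each violation
    raises :class:`SeqVarError` naming the rule.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise SeqVarError("ORF length not divisible by 3")
    if not cds.startswith("ATG"):
        raise SeqVarError("ORF does not start with ATG")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] not in _STOPS:
        raise SeqVarError("ORF does not end with a stop codon")
    body = codons[:-1]
    for k, codon in enumerate(body):
        if codon in _STOPS:
            raise SeqVarError(f"internal stop codon at codon {k + 1}")
    return "".join(_codon_aa(c) for c in body)


def apply_variants(hap: HaplotypeSet, variants: Iterable[Variant]) -> str:
    """Apply alt alleles onto a parent-1 sequence (reconstructs parent 2)."""
    seq = list(hap.sequence)
    for v in sorted(variants, key=lambda v: v.position, reverse=True):
        idx = hap.index_of_pos(v.position)
        ref = v.ref_bases
        if v.vclass == "insertion":
            seq[idx:idx] = v.alt_bases
            continue
        if "".join(seq[idx : idx + len(ref)]) != ref:
            raise SeqVarError(
                f"reference allele mismatch applying variant at {v.position}"
            )
        seq[idx : idx + len(ref)] = v.alt_bases
    return "".join(seq)
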