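"""Variant calling, fixedness partition, coding annotation, translation."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridase import seqvar
from hybridase.seqvar import (
    HET,
    HOM_ALT,
    HOM_REF,
    POLY,
    TRANSCRIPT,
    HaplotypeSet,
    SeqVarError,
    Variant,
    annotate_coding,
    apply_variants,
    call_variants,
    classify_fixed_differences,
    format_variant,
    parse_variant,
    translate,
)


def test_fixture_trio_yields_seven_coding_variants(fx):
    nl, ar, hy = (fx.haplotypes[k] for k in ("NL_cds", "AR_cds", "HY_cds"))
    variants = call_variants(nl, ar, hy, fx.genotype_table())
    assert [v.position for v in variants] == [325, 601, 817, 841, 1142, 1270, 1357]
    assert all(v.vclass == "substitution" for v in variants)
    assert all(v.genotypes["HY"] == HET for v in variants)
    # every coding variant is synonymous
    for v in variants:
        ann = annotate_coding(v, fx.cds_start, fx.cds_end, nl)
        assert ann is not None and ann.synonymous


def test_fixed_differences_are_s4_and_s7(fx):
    nl, ar = fx.haplotypes["NL_cds"], fx.haplotypes["AR_cds"]
    variants = call_variants(nl, ar, fx.haplotypes["HY_cds"], fx.genotype_table())
    part = classify_fixed_differences(variants, "NL", "AR")
    assert [v.label for v in part["fixed"]] == ["S4", "S7"]
    assert len(part["fixed"]) + len(part["polymorphic"]) == len(variants)


def test_identical_sequences_give_no_variants():
    h = HaplotypeSet("A", TRANSCRIPT, "ACGTACGTACGTACGTAAACCC")
    h2 = HaplotypeSet("B", TRANSCRIPT, h.sequence)
    assert call_variants(h, h2) == []


def test_grossly_different_lengths_fail_alignment():
    h1 = HaplotypeSet("A", TRANSCRIPT, "ACGT" * 100)
    h2 = HaplotypeSet("B", TRANSCRIPT, "ACGT" * 30)
    with pytest.raises(seqvar.AlignmentError):
        call_variants(h1, h2)


def test_genotype_conflict_detected():
    # hybrid carries W = A/T at a G/A site: inconsistent with both alleles
    p1 = HaplotypeSet("P1", TRANSCRIPT, "ACGTACGGACGT")
    p2 = HaplotypeSet("P2", TRANSCRIPT, "ACGTACGAACGT")
    hy = HaplotypeSet("HY", TRANSCRIPT, "ACGTACGWACGT")
    with pytest.raises(seqvar.GenotypeConflictError):
        call_variants(p1, p2, hy)


def _plant_random_variants(rng, length=1500, n_variants=12):
    """Plant well-separated substitutions and indels; return (s1, s2, truth).

    Contexts are chosen so the left-aligned representation is unique, which
    makes the planted records an exact brute-force oracle for the caller.
    """
    bases = "ACGT"
    s1 = [bases[i] for i in rng.integers(0, 4, size=length)]
    positions = sorted(rng.choice(np.arange(20, length - 20, 14), size=n_variants,
                                  replace=False))
    truth = []
    edits = []  # (index, ref, alt)
    for idx in positions:
        idx = int(idx)
        kind = rng.integers(0, 3)
        if kind == 0:  # substitution
            ref = s1[idx]
            alt = bases[(bases.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            edits.append((idx, ref, alt))
            truth.append((idx + 1, ref, alt))
        elif kind == 1:  # deletion of k bases
            k = int(rng.integers(1, 4))
            ref = "".join(s1[idx : idx + k])
            if s1[idx - 1] == ref[-1] or s1[idx + k] == ref[0]:
                continue  # ambiguous placement; skip this site
            edits.append((idx, ref, ""))
            truth.append((idx + 1, ref, "-" * k))
        else:  # insertion of k bases
            k = int(rng.integers(1, 4))
            ins = "".join(bases[i] for i in rng.integers(0, 4, size=k))
            if ins[-1] == s1[idx - 1] or ins[0] == s1[idx]:
                continue
            edits.append((idx, "", ins))
            truth.append((idx + 1, "-" * k, ins))
    s2 = list(s1)
    for idx, ref, alt in reversed(edits):
        s2[idx : idx + len(ref)] = list(alt)
    return "".join(s1), "".join(s2), truth


@pytest.mark.parametrize("seed", [11, 23, 57])
def test_caller_matches_planted_truth(seed):
    rng = np.random.default_rng(seed)
    s1, s2, truth = _plant_random_variants(rng)
    h1 = HaplotypeSet("P1", TRANSCRIPT, s1)
    h2 = HaplotypeSet("P2", TRANSCRIPT, s2)
    called = call_variants(h1, h2)
    got = [(v.position, v.ref_allele, v.alt_allele) for v in called]
    assert got == truth
    # round-trip: applying alt alleles to p1 reconstructs p2
    assert apply_variants(h1, called) == s2


def test_caller_symmetry_under_parent_swap():
    rng = np.random.default_rng(99)
    s1 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=800))
    s2 = list(s1)
    for idx in (100, 300, 500, 700):
        s2[idx] = {"A": "G", "C": "T", "G": "A", "T": "C"}[s2[idx]]
    s2 = "".join(s2)
    h1 = HaplotypeSet("P1", TRANSCRIPT, s1)
    h2 = HaplotypeSet("P2", TRANSCRIPT, s2)
    fwd = call_variants(h1, h2)
    rev = call_variants(h2, h1)
    assert [v.position for v in fwd] == [v.position for v in rev]
    assert [(v.ref_allele, v.alt_allele) for v in fwd] == [
        (v.alt_allele, v.ref_allele) for v in rev
    ]
    assert all(v.genotypes["P1"] == HOM_REF and v.genotypes["P2"] == HOM_ALT
               for v in fwd)
    assert all(v.genotypes["P2"] == HOM_REF and v.genotypes["P1"] == HOM_ALT
               for v in rev)


def test_fixedness_by_exhaustive_genotype_enumeration():
    """A site is fixed iff the parents are homozygous for different alleles."""
    calls = [HOM_REF, HOM_ALT, HET, POLY]
    for g1 in calls:
        for g2 in calls:
            v = Variant(position=10, ref_allele="A", alt_allele="G",
                        vclass="substitution", genotypes={"P1": g1, "P2": g2})
            part = classify_fixed_differences([v], "P1", "P2")
            expect_fixed = {g1, g2} == {HOM_REF, HOM_ALT}
            assert (len(part["fixed"]) == 1) == expect_fixed


def test_missing_genotype_raises():
    v = Variant(position=5, ref_allele="A", alt_allele="G",
                vclass="substitution", genotypes={"P1": HOM_REF})
    with pytest.raises(SeqVarError, match="missing genotype"):
        classify_fixed_differences([v], "P1", "P2")


def test_stop_codon_third_position_annotation(fx):
    nl = fx.haplotypes["NL_cds"]
    v = Variant(position=1357, ref_allele="G", alt_allele="A",
                vclass="substitution")
    ann = annotate_coding(v, fx.cds_start, fx.cds_end, nl)
    assert (ann.codon_index, ann.codon_position) == (362, 3)
    assert (ann.ref_codon, ann.alt_codon) == ("TAG", "TAA")
    assert ann.ref_aa == ann.alt_aa == "*" and ann.synonymous


def test_noncoding_variant_returns_none_and_cds_indel_raises(fx):
    nl = fx.haplotypes["NL_cds"]
    utr = Variant(position=10, ref_allele="A", alt_allele="G",
                  vclass="substitution")
    assert annotate_coding(utr, fx.cds_start, fx.cds_end, nl) is None
    indel = Variant(position=500, ref_allele="C", alt_allele="-",
                    vclass="deletion")
    with pytest.raises(SeqVarError, match="frameshift"):
        annotate_coding(indel, fx.cds_start, fx.cds_end, nl)


def test_translate_minimal_orf_and_validation():
    assert translate("ATGTAA") == "M"
    with pytest.raises(SeqVarError, match="divisible"):
        translate("ATGAATAA")
    with pytest.raises(SeqVarError, match="start"):
        translate("TTGAAATAA")
    with pytest.raises(SeqVarError, match="stop codon$"):
        translate("ATGAAAAAA")
    with pytest.raises(SeqVarError, match="internal stop"):
        translate("ATGTAAATGTAA")


_SENSE = [
    "".join(c)
    for c in __import__("itertools").product("ACGT", repeat=3)
    if "".join(c) not in ("TAA", "TAG", "TGA")
]


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    st.lists(st.sampled_from(_SENSE), min_size=1, max_size=60),
    st.sampled_from(["TAA", "TAG", "TGA"]),
)
def test_translate_matches_codon_table_oracle(body, stop):
    """Authored translation equals an independent translation oracle."""
    cds = "ATG" + "".join(body) + stop
    assert translate(cds) == str(Seq(cds).translate())[:-1]


def test_variant_rendering_round_trips(fx):
    for v in list(fx.coding_variants) + list(fx.promoter_variants):
        text = format_variant(v)
        back = parse_variant(text)
        assert format_variant(back) == text
        assert (back.position, back.ref_allele, back.alt_allele) == (
            v.position, v.ref_allele, v.alt_allele)


def test_promoter_positions_negative_transcript_positive(fx):
    assert all(v.position > 0 for v in fx.coding_variants)
    assert all(-2000 <= v.position <= -1 for v in fx.promoter_variants)
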