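"""Synthetic data with planted ground truth for the whole pipeline.

Two kinds of artefact live here:

* :func:`make_paper_fixture` builds a fully deterministic trio of
  haplotypes (two parental tilapia lines, ``NL`` and ``AR``, and their F1
  hybrid ``HY``) whose variant content encodes the published tables for the
  *p38 mapk* study system: seven synonymous coding SNPs, eight promoter
  variants, and two transcription-factor binding sites (Hoxb6, Dlx2)
  present only on the NL promoter allele.

* the ``simulate_*`` forward models generate the assay readouts the
  downstream stages consume -- binomially sampled pyrosequencing allele
  counts, Ct values under a log2-linear noise model with a stable reference
  gene, and lognormal firefly/renilla luminescence pairs -- all driven by a
  single :class:`SimTruth` that fixes the planted cis effect, trans effect
  and promoter-activity ratio.

The decomposition identity ``log2(parental_fold) = cis + trans`` is
enforced at construction, so a noiseless run of the full pipeline recovers
the planted (A, B, T) triple exactly.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .promoter import MotifDef, scan_motifs
from .seqvar import (
    HET,
    HOM_ALT,
    HOM_REF,
    POLY,
    PROMOTER,
    TRANSCRIPT,
    HaplotypeSet,
    SeqVarError,
    Variant,
    iupac_code,
)

_FIXTURE_SEED = 20240115  # fixed: the fixture is deterministic by contract

P1_GROUP, P2_GROUP, HYBRID_GROUP = "NL", "AR", "HY"


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth for one simulated study.

    ``cis_effect`` and ``trans_effect`` are log2 ratios (parent-1 over
    parent-2); ``parental_fold`` is derived as ``2**(cis+trans)`` and
    ``allele_freq_p1`` as ``2**cis / (1 + 2**cis)``, so the generator obeys
    the decomposition identity by construction.
    """

    cis_effect: float
    trans_effect: float
    hybrid_fold_vs_p2: float
    promoter_activity_ratio: float
    seed: int = 0
    parental_fold: float = field(init=False)
    allele_freq_p1: float = field(init=False)

    def __post_init__(self) -> None:
        if self.hybrid_fold_vs_p2 <= 0 or self.promoter_activity_ratio <= 0:
            raise ValueError("fold parameters must be positive")
        object.__setattr__(
            self, "parental_fold", 2.0 ** (self.cis_effect + self.trans_effect)
        )
        r = 2.0 ** self.cis_effect
        object.__setattr__(self, "allele_freq_p1", r / (1.0 + r))

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(salt,))
        )


def paper_truth(seed: int = 0) -> SimTruth:
    """The study conditions: cis = log2(77/23), parental fold 1.48,
    hybrid fold 1.90, promoter activity ratio 3.3."""
    cis = math.log2(77 / 23)
    trans = math.log2(1.48) - cis
    return SimTruth(
        cis_effect=cis,
        trans_effect=trans,
        hybrid_fold_vs_p2=1.90,
        promoter_activity_ratio=3.3,
        seed=seed,
    )


def planted_category(
    cis: float, trans: float, epsilon: float = 0.5
) -> str:
    """Generator-side regulatory category for a planted (cis, trans) pair.

    Sign/nullity rules only (a component is null iff its magnitude is at
    most ``epsilon``); kept deliberately independent of the inference-side
    classifier so the two can be cross-checked.
    """
    a = cis + trans
    b_null = abs(cis) <= epsilon
    t_null = abs(trans) <= epsilon
    a_null = abs(a) <= epsilon
    if b_null and t_null:
        return "conserved"
    if not b_null and t_null:
        return "cis-only"
    if b_null and not t_null:
        return "trans-only"
    if cis * trans > 0:
        return "cis+trans enhancing"
    return "compensatory" if a_null else "cis×trans compensatory"


# ---------------------------------------------------------------------------
# paper fixture

# label, position, ref (NL), alt (AR), NL codon, AR codon, NL call, AR call.
# Within-line polymorphic sites carry the consensus allele in the sequence
# and a "polymorphic" group call in the genotype table.
_CODING_PLAN = [
    ("S1", 325, "G", "A", "GCG", "GCA", POLY, HOM_ALT),
    ("S2", 601, "C", "T", "GCC", "GCT", POLY, POLY),
    ("S3", 817, "C", "T", "GCC", "GCT", POLY, HOM_ALT),
    ("S4", 841, "A", "G", "GCA", "GCG", HOM_REF, HOM_ALT),
    ("S5", 1142, "C", "T", "CTA", "TTA", POLY, POLY),
    ("S6", 1270, "C", "T", "GCC", "GCT", POLY, POLY),
    ("S7", 1357, "G", "A", "TAG", "TAA", HOM_REF, HOM_ALT),
]

# label, position, ref (NL), alt (AR); all fixed between the lines
_PROMOTER_PLAN = [
    ("S'1", -314, "TTT", "---"),
    ("S'2", -297, "C", "T"),
    ("S'3", -241, "G", "C"),
    ("S'4", -238, "C--", "AAG"),
    ("S'5", -236, "G", "A"),
    ("S'6", -145, "T", "-"),
    ("S'7", -138, "T", "A"),
    ("S'8", -33, "T", "A"),
]

UTR5_LENGTH = 271
CDS_START = 272
CDS_END = 1357
UTR3_LENGTH = 73
PROMOTER_LENGTH = 2000
CORE_PROMOTER_POS = -100  # annotated landmark, not recomputed

HOXB6 = MotifDef(name="Hoxb6", consensus="TTAAGTAC")
DLX2 = MotifDef(name="Dlx2", consensus="TTAATTTT")
# motif spans on the NL promoter (TSS-relative, inclusive)
HOXB6_SPAN = (-245, -238)
DLX2_SPAN = (-142, -135)

_SENSE_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class PaperFixture:
    """Deterministic haplotype trio plus variant/motif ground truth."""

    haplotypes: Mapping[str, HaplotypeSet]
    coding_variants: tuple[Variant, ...]
    promoter_variants: tuple[Variant, ...]
    motifs: tuple[MotifDef, ...]
    utr5_length: int = UTR5_LENGTH
    cds_start: int = CDS_START
    cds_end: int = CDS_END
    core_promoter_pos: int = CORE_PROMOTER_POS

    def cds(self, group: str) -> str:
        hap = self.haplotypes[f"{group}_cds"]
        lo = hap.index_of_pos(self.cds_start)
        hi = hap.index_of_pos(self.cds_end)
        return hap.sequence[lo : hi + 1]

    def genotype_table(self) -> pd.DataFrame:
        rows = [
            {"position": v.position, "group": g, "genotype": call}
            for v in self.coding_variants
            for g, call in v.genotypes.items()
        ]
        return pd.DataFrame(rows, columns=["position", "group", "genotype"])


def _promoter_index(pos: int) -> int:
    return PROMOTER_LENGTH + pos  # pos is negative


def _count_hits(seq: str, motif: str) -> list[int]:
    return [
        i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif
    ]


def _build_promoters(rng: np.random.Generator) -> tuple[str, str]:
    bases = np.array(list("ACGT"))
    for _ in range(500):
        nl = list(rng.choice(bases, size=PROMOTER_LENGTH))
        def put(pos: int, s: str) -> None:
            i = _promoter_index(pos)
            nl[i : i + len(s)] = list(s)

        put(-245, HOXB6.consensus)       # spans S'3 (-241) and S'4 (-238)
        put(-236, "G")
        put(-314, "TTT")
        if nl[_promoter_index(-315)] == "T":
            nl[_promoter_index(-315)] = "A"
        if nl[_promoter_index(-311)] == "T":
            nl[_promoter_index(-311)] = "C"
        put(-297, "C")
        put(-145, "T")
        if nl[_promoter_index(-146)] == "T":
            nl[_promoter_index(-146)] = "A"
        if nl[_promoter_index(-144)] == "T":
            nl[_promoter_index(-144)] = "C"
        put(-142, DLX2.consensus)        # spans S'7 (-138)
        put(-33, "T")

        ar = list(nl)
        # apply NL -> AR edits right-to-left so indices stay valid
        ar[_promoter_index(-33)] = "A"
        ar[_promoter_index(-138)] = "A"
        del ar[_promoter_index(-145)]
        ar[_promoter_index(-236)] = "A"
        ar[_promoter_index(-238) : _promoter_index(-238) + 1] = list("AAG")
        ar[_promoter_index(-241)] = "C"
        ar[_promoter_index(-297)] = "T"
        del ar[_promoter_index(-314) : _promoter_index(-314) + 3]

        nl_s, ar_s = "".join(nl), "".join(ar)
        # screen: the planted motifs occur exactly once in NL (at the planted
        # spans) and never in AR
        if _count_hits(nl_s, HOXB6.consensus) != [_promoter_index(HOXB6_SPAN[0])]:
            continue
        if _count_hits(nl_s, DLX2.consensus) != [_promoter_index(DLX2_SPAN[0])]:
            continue
        if _count_hits(ar_s, HOXB6.consensus) or _count_hits(ar_s, DLX2.consensus):
            continue
        return nl_s, ar_s
    raise RuntimeError("could not generate a motif-clean promoter background")


def _build_transcripts(rng: np.random.Generator) -> tuple[str, str, str]:
    bases = np.array(list("ACGT"))
    utr5 = "".join(rng.choice(bases, size=UTR5_LENGTH))
    utr3 = "".join(rng.choice(bases, size=UTR3_LENGTH))
    n_codons = (CDS_END - CDS_START + 1) // 3  # 362 incl. stop
    body = list(rng.choice(np.array(_SENSE_CODONS), size=n_codons - 2))
    codons_nl = ["ATG", *body, "TAG"]
    codons_ar = list(codons_nl)
    for _, pos, _, _, nl_codon, ar_codon, _, _ in _CODING_PLAN:
        ci = (pos - CDS_START) // 3
        codons_nl[ci] = nl_codon
        codons_ar[ci] = ar_codon
    nl = utr5 + "".join(codons_nl) + utr3
    ar = utr5 + "".join(codons_ar) + utr3
    hy = list(nl)
    for _, pos, ref, alt, _, _, _, _ in _CODING_PLAN:
        hy[pos - 1] = iupac_code({ref, alt})
    return nl, ar, "".join(hy)


_fixture_cache: PaperFixture | None = None


def make_paper_fixture() -> PaperFixture:
    """Build the deterministic study fixture (no RNG exposed; byte-identical
    across calls and platforms).

    The trio encodes: a 1086-nt CDS (positions 272..1357, 361 residues plus
    stop) carrying seven synonymous SNPs; a 2000-nt promoter (-2000..-1)
    carrying eight variants; Hoxb6/Dlx2 consensus sites on the NL allele
    only.  The hybrid transcript is an IUPAC consensus; the hybrid promoter
    carries both parental haplotypes (indel heterozygosity is not
    representable in a single consensus).
    """
    global _fixture_cache
    if _fixture_cache is not None:
        return _fixture_cache
    rng = np.random.default_rng(_FIXTURE_SEED)
    nl_t, ar_t, hy_t = _build_transcripts(rng)
    nl_p, ar_p = _build_promoters(rng)

    haplotypes = {
        "NL_cds": HaplotypeSet(P1_GROUP, TRANSCRIPT, nl_t),
        "AR_cds": HaplotypeSet(P2_GROUP, TRANSCRIPT, ar_t),
        "HY_cds": HaplotypeSet(HYBRID_GROUP, TRANSCRIPT, hy_t),
        "NL_prom": HaplotypeSet(P1_GROUP, PROMOTER, nl_p),
        "AR_prom": HaplotypeSet(P2_GROUP, PROMOTER, ar_p),
        "HY_prom_nl": HaplotypeSet(HYBRID_GROUP, PROMOTER, nl_p),
        "HY_prom_ar": HaplotypeSet(HYBRID_GROUP, PROMOTER, ar_p),
    }

    coding = []
    for label, pos, ref, alt, _, _, nl_call, ar_call in _CODING_PLAN:
        coding.append(
            Variant(
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                vclass="substitution",
                genotypes={P1_GROUP: nl_call, P2_GROUP: ar_call, HYBRID_GROUP: HET},
                label=label,
            )
        )
    promoter = []
    for label, pos, ref, alt in _PROMOTER_PLAN:
        promoter.append(
            Variant(
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                vclass="substitution" if "-" not in ref + alt else
                ("deletion" if not alt.replace("-", "") else "complex"),
                genotypes={P1_GROUP: HOM_REF, P2_GROUP: HOM_ALT, HYBRID_GROUP: HET},
                label=label,
            )
        )
    _fixture_cache = PaperFixture(
        haplotypes=haplotypes,
        coding_variants=tuple(coding),
        promoter_variants=tuple(promoter),
        motifs=(HOXB6, DLX2),
    )
    return _fixture_cache


# ---------------------------------------------------------------------------
# forward models


def simulate_pyro_counts(
    truth: SimTruth,
    n_individuals: int = 20,
    depth: int = 500,
    marker: str = "S7",
    seed: int | None = None,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Simulate per-individual pyrosequencing allele counts at a marker SNP.

    Each individual's parent-1 allele count is Binomial(depth, f1) with
    ``f1 = truth.allele_freq_p1``.  With ``noiseless=True`` the exact
    expected (possibly fractional) counts are emitted instead, which lets a
    noise-free pipeline run recover the planted cis effect to machine
    precision.
    """
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals}")
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    f1 = truth.allele_freq_p1
    if noiseless:
        c1 = np.full(n_individuals, f1 * depth)
    else:
        rng = truth.rng(1) if seed is None else np.random.default_rng(seed)
        c1 = rng.binomial(depth, f1, size=n_individuals).astype(float)
    return pd.DataFrame(
        {
            "individual_id": [f"HY{i + 1:02d}" for i in range(n_individuals)],
            "marker": marker,
            "count_p1": c1 if noiseless else c1.astype(int),
            "count_p2": (depth - c1) if noiseless else (depth - c1).astype(int),
            "group": HYBRID_GROUP,
            "depth": depth,
        }
    )


def simulate_ct_table(
    truth: SimTruth,
    p1: str = P1_GROUP,
    p2: str = P2_GROUP,
    hybrid: str = HYBRID_GROUP,
    groups: Sequence[str] | None = None,
    n_samples: int = 20,
    n_replicates: int = 3,
    sigma: float = 0.2,
    target_gene: str = "p38",
    reference_gene: str = "beta_actin",
    base_ct: float = 22.0,
    reference_ct: float = 15.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a qRT-PCR Ct table for the three groups.

    Target-gene Ct is ``base_ct - log2(group relative expression) +
    N(0, sigma)`` per technical replicate; the reference gene sits at
    ``reference_ct`` with the same noise level (a stable reference).
    Relative expressions are p2 = 1, p1 = ``truth.parental_fold``, hybrid =
    ``truth.hybrid_fold_vs_p2``.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    expr = {p2: 1.0, p1: truth.parental_fold, hybrid: truth.hybrid_fold_vs_p2}
    use = list(expr) if groups is None else list(groups)
    unknown = [g for g in use if g not in expr]
    if unknown:
        raise ValueError(f"unknown group label(s) {unknown}; expected {list(expr)}")
    rng = truth.rng(2) if seed is None else np.random.default_rng(seed)
    rows = []
    for g in use:
        mu_t = base_ct - math.log2(expr[g])
        for s in range(n_samples):
            sid = f"{g}{s + 1:02d}"
            for gene, mu in ((target_gene, mu_t), (reference_gene, reference_ct)):
                noise = rng.normal(0.0, sigma, size=n_replicates) if sigma else (
                    np.zeros(n_replicates)
                )
                for r in range(n_replicates):
                    rows.append(
                        {
                            "sample_id": sid,
                            "group": g,
                            "gene": gene,
                            "replicate": r + 1,
                            "ct": mu + noise[r],
                        }
                    )
    return pd.DataFrame(rows)


def simulate_luminescence(
    truth: SimTruth,
    n_wells: int = 6,
    cv: float = 0.15,
    constructs: Sequence[str] = (P1_GROUP, P2_GROUP),
    baseline: float = 1000.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate firefly/renilla luminescence pairs for promoter constructs.

    Renilla is lognormal around ``baseline``; firefly is renilla times the
    construct's promoter activity times a lognormal noise of coefficient of
    variation ``cv``.  The parent-1 construct's activity over parent-2's
    equals ``truth.promoter_activity_ratio``.
    """
    if n_wells < 1:
        raise ValueError(f"n_wells must be >= 1, got {n_wells}")
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv}")
    sigma = math.sqrt(math.log1p(cv * cv))
    activity = {P2_GROUP: 1.0, P1_GROUP: truth.promoter_activity_ratio,
                "empty-vector": 0.05}
    rng = truth.rng(3) if seed is None else np.random.default_rng(seed)
    rows = []
    for construct in constructs:
        if construct not in activity:
            raise ValueError(f"unknown construct label {construct!r}")
        for w in range(n_wells):
            renilla = baseline * rng.lognormal(0.0, sigma) if sigma else baseline
            noise = rng.lognormal(0.0, sigma) if sigma else 1.0
            rows.append(
                {
                    "construct": construct,
                    "well": f"{construct}_w{w + 1}",
                    "firefly": renilla * activity[construct] * noise,
                    "renilla": renilla,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk emission


def write_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the fixture FASTA files, variant truth tables and motif TSV."""
    from . import io as hio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = make_paper_fixture()
    paths = {}
    paths["transcripts"] = outdir / "transcripts.fasta"
    hio.write_fasta(
        {k: h.sequence for k, h in fx.haplotypes.items() if k.endswith("_cds")},
        paths["transcripts"],
    )
    paths["promoters"] = outdir / "promoters.fasta"
    hio.write_fasta(
        {k: h.sequence for k, h in fx.haplotypes.items() if "_prom" in k},
        paths["promoters"],
    )
    paths["coding_truth"] = outdir / "coding_variants.tsv"
    hio.write_variants_tsv(fx.coding_variants, paths["coding_truth"])
    paths["promoter_truth"] = outdir / "promoter_variants.tsv"
    hio.write_variants_tsv(fx.promoter_variants, paths["promoter_truth"])
    paths["genotypes"] = outdir / "genotypes.tsv"
    fx.genotype_table().to_csv(paths["genotypes"], sep="\t", index=False)
    paths["motifs"] = outdir / "motifs.tsv"
    pd.DataFrame(
        [
            {"name": m.name, "consensus": m.consensus, "strand_policy": m.strand_policy}
            for m in fx.motifs
        ]
    ).to_csv(paths["motifs"], sep="\t", index=False)
    return paths


def write_simulation(
    truth: SimTruth,
    outdir: str | Path,
    n_individuals: int = 20,
    depth: int = 500,
    n_samples: int = 20,
    n_replicates: int = 3,
    sigma: float = 0.2,
    n_wells: int = 6,
    cv: float = 0.15,
) -> dict[str, Path]:
    """Write simulated assay tables plus a JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["counts"] = outdir / "pyro_counts.tsv"
    simulate_pyro_counts(truth, n_individuals, depth).to_csv(
        paths["counts"], sep="\t", index=False
    )
    paths["ct"] = outdir / "ct_values.tsv"
    simulate_ct_table(
        truth, n_samples=n_samples, n_replicates=n_replicates, sigma=sigma
    ).to_csv(paths["ct"], sep="\t", index=False)
    paths["luminescence"] = outdir / "luminescence.tsv"
    simulate_luminescence(truth, n_wells=n_wells, cv=cv).to_csv(
        paths["luminescence"], sep="\t", index=False
    )
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(asdict(truth), indent=2) + "\n")
    return paths
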