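# Methods

`hybridase` analyses allele-specific expression (ASE) and cis/trans
regulatory divergence of a single gene in an F1 hybrid (`HY`) and its two
parental lines (`NL`, parent 1; `AR`, parent 2). The study design it
models assays the parents by qRT-PCR, the hybrid's two alleles by
pyrosequencing at a marker SNP, and the two promoter alleles by a
dual-luciferase reporter. This note describes the models, the estimators,
the synthetic-data generator, and the design choices made where more than
one defensible option existed.

## Coordinate system and variant model

All sequences are anchored to the transcription start site: the first
transcribed base is +1, the base immediately upstream is −1, and position
0 does not exist. Transcript variants therefore have positive positions
and promoter variants negative ones. Internally sequences use 0-based
indices; conversion happens only in the coordinate helpers of
`HaplotypeSet`.

Variants are called from a Needleman–Wunsch global alignment (match +1,
mismatch −1, gap open −4, gap extend −1; `Bio.Align.PairwiseAligner`).
Maximal runs of difference columns become single records, which yields the
field's compact rendering directly: a 3-bp deletion is `g. -314 TTT > ---`
and a mixed substitution/insertion run is `g. -238 C-- > AAG`. Two
normalisations are applied:

- **Variant-level left alignment.** Pure indels inside repeats are slid to
  their 5′-most score-equivalent placement (the usual canonical form).
- **Gap gluing.** When the optimal alignment is degenerate, the aligner
  may separate an indel from an adjacent substitution by a spurious
  one-base match (e.g. rendering `C > AAG` as an `AA` insertion plus a
  `C > G` substitution). Gap runs are shifted rightward, score-equivalently,
  onto a neighbouring difference column so such sites stay one complex
  record. Isolated indels are unaffected.

The `ref` allele is always parent 1's; swapping the parents swaps alleles
and genotype labels but preserves positions and counts (tested).

A single consensus per line cannot encode within-line polymorphism, so the
caller accepts an optional genotype table (`position, group, genotype`)
that overrides the consensus-derived calls; the hybrid's genotype comes
either from IUPAC ambiguity codes in its consensus (transcripts) or from
its two phased promoter haplotypes (indel heterozygosity is not
representable in one consensus). A site is a *fixed* inter-parental
difference iff the parents are homozygous for different alleles.

Coding substitutions are annotated on the standard genetic code
(`Bio.Data.CodonTable`); a stop-to-stop change counts as synonymous.
`translate` validates a complete ORF (length ≡ 0 mod 3, ATG start,
terminal stop, no internal stop) and is checked in the tests against
Biopython's translation as an independent oracle.

## ASE and the cis effect

At a marker SNP the hybrid's two alleles share one trans environment, so
the allelic read ratio isolates cis divergence:

    B = log2(n_P1 / n_P2)

Default pooling sums counts over individuals before forming the frequency
(one pooled assay ratio is what the published table reports); a
per-individual-mean mode is kept for dispersion diagnostics. The bias test
is the exact two-sided binomial test against 0.5 and the interval is
Clopper–Pearson 95% (`scipy.stats.binomtest`) — counts may be small, so no
normal approximation is used. A pooled zero count on either allele
triggers a 0.5-read continuity correction with a flag rather than an
infinite estimate. Pyrogram peak heights, which are proportional to allele
dosage, convert to counts by largest-remainder rounding to a chosen depth.

## Relative expression (2^−ΔΔCt)

Pure Livak: amplification efficiency is fixed at 2 and no standard curves
are fitted. Technical replicates are averaged within a sample before
ΔCt = Ct(target) − Ct(reference); ΔΔCt subtracts the calibrator group's
mean ΔCt; the fold is 2^−ΔΔCt. Group summaries are arithmetic mean ± SD on
the linear fold scale (matching how such results are reported); on
noiseless data the calibrator group's mean fold is exactly 1, and fold
*ratios* between groups are calibrator-invariant (tested numerically).
Group significance is one-way ANOVA with Tukey HSD on log2 folds (the log
scale stabilises multiplicative variance), rendered as a compact letter
display computed from the maximal cliques of the non-significance graph.
The parental divergence handed to the decomposition is
A = log2(mean fold P1 / mean fold P2).

## Inheritance mode

The mid-parent value (MPV) is the arithmetic mean of the parental mean
folds. Hybrid-vs-parent comparisons are Welch t tests on log2 folds. The
hybrid-vs-MPV comparison is a linear-scale contrast,
mean(HY) − (mean(P1) + mean(P2))/2, with Welch–Satterthwaite degrees of
freedom: a one-sample log-scale test against the point MPV would both
ignore parental uncertainty and carry a Jensen bias under multiplicative
noise, inflating false non-additive calls; the contrast is exact at the
midpoint and calibrated under the null (both properties are tested).
Decision table: significantly above both parents → ELOD-Up (Expression
Level Over Dominance—Up, i.e. overdominant); below both → ELOD-Down; not
distinguishable from the MPV → additive; indistinguishable from exactly
one parent and off the MPV → dominant towards that parent; conflicting
patterns → ambiguous. With fewer than two samples in a group the tests
are skipped (flagged) and point estimates with the log2 threshold ε are
used.

## Cis/trans decomposition

With A the parental divergence and B the hybrid allelic imbalance, the
trans component is defined by subtraction, T = A − B. This design has no
direct trans assay, so no trans test is fabricated: T is non-null iff
|T| > ε (default ε = 0.5 log2 units), or — when both A and B carry tests —
when exactly one of the two is significant, in which case the subtraction
inherits the evidence. A and B are non-null by their own test (when
available) or by |·| > ε.

Categories: both components null → conserved; cis only → cis-only; trans
only → trans-only; same signs → cis+trans enhancing; opposite signs with
residual divergence (A non-null) → cis×trans compensatory; opposite signs
that cancel (A null) → compensatory; anything else → ambiguous. A 5×5
noiseless grid of planted (cis, trans) values is recovered 25/25 by the
full pipeline (tested), and the generator-side category rule is coded
independently of the inference-side classifier.

A note on internal consistency of the published figures this mirrors: a
combined effect of 0.92 with a cis effect of 1.74 gives T = −0.82 by the
definition above, whereas the printed parental fold of 1.48 would give
A = log2(1.48) = 0.57 (0.92 is close to log2 of the printed hybrid fold
1.90), and a printed trans value of −0.98 satisfies neither. The package
follows the stated definitions and does not treat any printed trans value
as ground truth; the qualitative call — a compensatory cis×trans
interaction — is reproduced either way.

## Promoter comparison

Promoter alleles are compared in negative TSS coordinates (−2000..−1).
Binding sites are found by exact IUPAC-consensus matching (forward strand
by default, both on request); the published motif information is a pair of
consensus octamers (Hoxb6 `TTAAGTAC`, Dlx2 `TTAATTTT`), not matrices, so
PWM scoring is deliberately out of scope and the motif file is
user-extensible. Sites are paired across alleles through the
homologous-coordinate map of the alignment (indel-aware), and a site whose
homologous window in the other allele no longer matches is emitted as a
gain in the allele that has it, annotated with the overlapping variant(s);
the 5′-most overlapping variant is reported as primary. The −100 bp core
promoter landmark is carried as an annotation constant only.

## Dual-luciferase activity

Per well, firefly/renilla normalises for transfection efficiency; the
promoter-activity fold is the ratio of group mean ratios (the ratio of
geometric means is available as an option, and whether background
subtraction of an empty-vector mean is applied is the caller's choice, off
by default). Significance is a Welch t test on log ratios. The fold is
scale-invariant in both channels and satisfies
fold(P1,P2)·fold(P2,P1) = 1 (tested).

## Synthetic data

The generator plays two roles.

**The deterministic fixture** (`make_paper_fixture`, no exposed RNG,
byte-identical across calls) encodes the study system's printed tables as
sequence: a 1430-nt transcript whose 1086-nt CDS spans positions 272–1357
and encodes 361 residues plus a stop, carrying seven synonymous SNPs at
g.325/601/817/841/1142/1270/1357; and a 2000-nt promoter carrying eight
variants (g.−314 TTT>---, −297 C>T, −241 G>C, −238 C-->AAG, −236 G>A,
−145 T>-, −138 T>A, −33 T>A) with the Hoxb6 and Dlx2 octamers present only
on the NL allele, spanning −241 and −138 respectively. The 5′UTR length is
not something the printed tables determine; 271 nt is the minimal
construction under which the CDS is 1086 nt ending at g.1357, six of the
seven sites fall on codon third positions (wobble pairs such as GCG/GCA),
g.1142 is a codon first position realised as the Leu CTA↔TTA exchange, and
g.1357 is the stop third base (TAG↔TAA) — making every planted coding
variant synonymous simultaneously. Background sequence comes from a
seeded uniform nucleotide stream, screened so the two motifs occur nowhere
except their planted spans and indel contexts admit a unique left-aligned
representation.

**The forward models** sample the assay readouts from a `SimTruth` that
fixes cis effect, trans effect, hybrid fold and promoter-activity ratio,
and enforces the identities `allele_freq_p1 = 2^cis/(1+2^cis)` and
`log2(parental_fold) = cis + trans` at construction:

- pyrosequencing counts: per individual, Binomial(depth, allele_freq_p1);
  a `noiseless` mode emits exact expected (possibly fractional) counts so
  a noise-free pipeline run recovers (A, B, T) to machine precision;
- Ct values: target Ct = C₀ − log2(relative expression) + N(0, σ) per
  technical replicate, reference gene flat at R₀ with the same σ
  (Gaussian noise on the Ct scale is the standard qPCR error model);
- luminescence: lognormal renilla baseline; firefly = renilla × construct
  activity × lognormal noise of coefficient of variation `cv`.

Default conditions mirror the study: 20 individuals and depth 500 for
pyrosequencing (read depth is not published; 500 is a routine PyroMark
depth and the pooled estimate is insensitive to the split between
individuals and depth), 20 samples × 3 technical replicates and σ = 0.2
cycles for qPCR, 6 wells per construct and cv = 0.15 for luciferase, a
cis effect of log2(77/23) (so the planted allele frequency is exactly
0.77), parental fold 1.48, hybrid fold 1.90, activity ratio 3.3.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: pyrogram signal processing and its
sequence-context biases, PCR amplification-efficiency differences between
alleles or genes, between-individual biological dispersion beyond
binomial/Gaussian sampling, plate and batch effects, and cross-well
contamination. The recovery tests demonstrate that the estimators invert
the stated forward models, not that those models capture every feature of
the assays.

## Numerical choices and degenerate inputs

- Exact binomial p-values and Clopper–Pearson intervals throughout the ASE
  stage; no continuity-corrected normal approximations.
- Zero within-group variance (noiseless data) makes t/F statistics
  degenerate; the limits are resolved explicitly: identical means → p = 1,
  separated constant samples → p = 0.
- ε defaults to 0.5 log2 units for point-estimate nullity calls; α
  defaults to 0.05 everywhere.
- Ties in largest-remainder rounding of peak heights go to the parent-1
  allele.
- All stochastic generators draw from `numpy.random.default_rng` seeded
  from a single integer; identical seed and parameters give byte-identical
  tables.

## Problem sizes in the shipped checks

The bundled verification runs use 500-replicate Monte-Carlo loops for the
fold-recovery checks, 1000 replicates for binomial test calibration and
interval coverage, and 300 for the null inheritance calibration; these
sizes give Monte-Carlo standard errors comfortably inside the asserted
tolerances while keeping the suite quick on a laptop.

## Known limitations

- Single-gene design: no multiple-testing machinery, no genome-wide scan.
- Parents are purebred, so parental ASE is undefined; the trans component
  is only ever obtained by subtraction.
- Frameshift (indel) consequences inside a CDS are rejected rather than
  annotated.
- The motif scanner is consensus-exact; degenerate or low-information
  sites that a PWM would score partially are either hits or misses here.
- The exon structure of the locus is not modelled; all coordinates are
  transcript/promoter space.
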