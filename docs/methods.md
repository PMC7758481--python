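# Methods

## Problem and model

A-to-I RNA editing by ADAR deaminases creates transcript-level variants that
RNA-seq reports as A→G mismatches on the genomic plus strand and T→C on the
minus strand. When an edit is non-synonymous in a coding exon, the mutant
peptide can be presented on HLA class I and recognized by CD8⁺ T cells.
`editscan` detects such sites from aligned reads, removes the artifact
classes that dominate naive mismatch calling, generates the peptide windows
HLA class I presents, and scores candidate immunogenicity per peptide and
per sample.

## Site detection and editing level

Detection is a pileup over the reference: a position becomes a candidate
when at least one quality-passing read shows the editing substitution.
Observation quality thresholds are strict — base quality >25 and mapping
quality >20 — so an observation at exactly the threshold does not count,
on either side of the fraction. Only A→G and T→C rows are ever materialized:
any other substitution cannot be A-to-I editing in transcript space and
would be discarded by the strand rule anyway.

The editing level at a site is E = edited reads / total qualifying reads.
Two quality regimes exist deliberately: detection uses the strict >25
calling threshold, while the standalone `editing_level` function uses the
inclusive ≥20 threshold conventional for quantifying levels at known sites.
Both are parameters.

## Artifact filters

Applied in this order (the set-like filters commute; the read-edge filter
must precede the final level computation):

1. **Known variants** — positional (contig, position) match against any
   supplied dbSNP/1000G/HAPMAP-style list removes the site. Matching ignores
   the allele: a germline variant at the position disqualifies it regardless;
   this is the conservative choice for false-positive removal.
2. **Read edges** — observations within the first or last 3 aligned bases of
   a read (offsets 0–2 from either end of the soft-clip-free query) are
   discarded from **both** the edited and total counts, and E is recomputed;
   sites left without edited support are dropped. Removing edge observations
   from the denominator as well treats them as unobserved rather than as
   reference evidence, which is the self-consistent reading; it is exposed
   through the pileup API if a caller wants the alternative.
3. **Splice-proximal intronic** — a site inside a transcript span but outside
   all its coding intervals, lying within the first or last `splice_window`
   (default 4) bases of an intron, is removed unless it falls in a supplied
   Alu interval: Alu introns are genuinely and heavily edited, whereas
   near-junction intronic mismatches in unique sequence are usually reads
   spilling past exon boundaries. "Next to the junction" is not a precise
   width anywhere; 4 bp covers the canonical splice motifs and is
   configurable. Without an Alu annotation every site is treated as non-Alu
   (the stricter behaviour).
4. **Homopolymer** — a site immediately adjacent to a run of ≥5 identical
   reference bases on either flank is removed. Both flanks are scanned
   because slippage errors flank a run on both sides, and the run base need
   not equal ref or alt.
5. **Panel of normals** — sites recurrent in ≥2 normal-sample site lists are
   subtracted (by contig, position, allele) from the tumor calls; recurrent
   normal editing is tolerized and cannot yield an immunogenic peptide.

Two cohort-level operations are provided for multi-sample designs:
`somatic_re_filter` keeps sites edited in the tumor with level exactly zero
(or absent) in the matched normal, and `cohort_recurrence_filter` keeps
sites with ≥3 edited reads in ≥3 samples.

## Peptide generation

The strand rule admits only A→G on plus-strand transcripts and T→C on
minus-strand ones — both are A→G in transcript space. Annotation maps the
genomic position to a phase-adjusted CDS offset (reverse-complemented on the
minus strand), rewrites the codon, and translates with the standard genetic
code. Sites are annotated against **all** supplied transcripts and the
resulting short peptides deduplicated by sequence; choosing a single
canonical transcript would only lose candidates. Synonymous effects are
excluded; stop gains and losses are dropped with a log count (no peptide
contract is defined for them — and in fact A→G can never create a stop
codon, only destroy TGA).

A missense effect yields the window of up to 10 residues on each side of the
edited residue (21-mer when interior, truncated at protein termini — the
truncation behaviour near termini is this package's choice). The long pair
is chopped into every 9/10/11-mer window containing the edited residue; a
window without it would be a wild-type self peptide. A full 21-mer yields
9 + 10 + 11 = 30 short pairs.

## Binding and the candidate filter

Binding strength is a NetMHCpan-style %rank (percent scale, lower =
stronger). Predictors are pluggable `(peptide, allele) → rank` callables:
a precomputed-table predictor, a deterministic SHA-256-based mock for
testing, and an optional subprocess adapter for a local NetMHCpan binary.
Candidates keep mutant %rank < 2 **and** gene TPM > 1, both strict, matching
the keep-rule convention; the normal peptide's rank is never filtered on —
it only discounts the score. A gene missing from the expression table counts
as 0 TPM and is dropped with a warning. Neoantigen burden is the number of
distinct kept mutant peptide sequences; counting (peptide, allele) pairs
would inflate burden with HLA multiplicity.

## Scoring

Per candidate, p = [tanh(F)·E] · [L(Rm)·(1 − L(Rn)/2)·S] · [H] with
L(x) = 1/(1 + e^{5(x−2)}). The first bracket is abundance: tanh saturates
TPM toward 1 (no log transform — tanh is applied to the expression level
directly) while E enters untransformed. The second bracket is binding net of
tolerance: L(Rm) ≈ 1 for strong binders and 0.5 at the rank-2 threshold; the
(1 − L(Rn)/2) factor halves the score when the normal peptide binds equally
well; S is positionwise dissimilarity (the pairs are equal length by
construction, so 1 − identical/length; alignment would add nothing). H is a
recognition probability in [0,1]. Since tanh(F) < 1 and every other factor
is in [0,1], p ∈ [0,1) always. Out-of-range inputs raise rather than clamp.

The recognition model H is a logistic function of the mean Kyte–Doolittle
hydropathy of the TCR-contact residues (positions 4–8 of a 9-mer; the same
interior span — skip 3 N-terminal and 1 C-terminal residues — for other
lengths): H = 1/(1 + e^{−mean}). It is monotone in contact hydrophobicity
and bounded in (0,1); it is a documented stand-in behind a pluggable
contract, and any callable peptide → [0,1] can replace it. The logistic's
unit slope keeps H responsive over the full hydropathy range (−4.5 to 4.5).

Per sample: RENIS = Σ pᵢ; REscore = (abundance(CD8) + abundance(CTL)) ·
RENIS; CYT = √(TPM_GZMA · TPM_PRF1) with no pseudocount, so a zero
propagates. Immune-cell abundance is the mean of log2(TPM+1) over marker
genes (defaults: CD8 → CD8A, CD8B; CTL → GZMA, GZMB, PRF1, KLRD1), a
transparent reduction of signature-score methods; the marker sets are
editable config.

## Synthetic fixtures

The generator builds a 6 kb genome hosting three transcripts: a two-exon
plus-strand gene (200 codons with a 200 bp intron), a single-exon
minus-strand gene, and a second two-exon plus-strand gene whose intron
carries an Alu interval. Background sequence never repeats a base twice in
a row and CDS regions are drawn from non-stop codons with no internal
repeats, so no accidental homopolymer or premature stop can interact with a
plant. Plants are placed at least one read length apart so coverage from one
never dilutes another's editing level.

Default study conditions: read length 50, constant base quality 35 and
mapping quality 60, coverage 50 per plant; planted editing levels 0.1, 0.3,
0.5 and 1.0 on the plus strand plus a level-1.0 minus-strand edit and a
synonymous control; and one bait per artifact filter (a known-SNP position,
a site supported only at read offsets 0–2, an intronic site 2 bp into an
intron, its Alu-exempt twin 3 bp into the second gene's intron, a site after
a CCCCC run, and a site listed in two of three normal samples). Edited-read
counts are drawn Binomial(coverage, level) from the seeded generator, so the
realized level is exact at level 1.0 and binomially dispersed otherwise.
All outputs are byte-identical for identical (spec, seed).

What the fixture does **not** emulate: sequencing error, quality-score
variation within reads, spliced or soft-clipped alignments (generated reads
are all-M; the CIGAR walker is exercised separately), indels, coverage
fluctuation, and realistic transcript structure. Passing tests therefore
demonstrate the correctness of the counting, filtering, windowing and
scoring logic under clean conditions — not robustness to alignment noise in
real libraries, where upstream trimming, duplicate marking and realignment
are assumed to have been done.

## Numerical choices and degenerate inputs

- The logistic is evaluated in a branch-split form so extreme ranks saturate
  to 0/1 without overflow.
- `editing_level` raises on zero qualifying coverage rather than returning 0.
- Empty site tables flow through every stage and produce empty outputs and a
  zero RENIS/REscore with exit code 0.
- Site tables reject duplicate (contig, position, allele) rows and
  multi-base alleles at construction.
- Internal coordinates are 1-based inclusive everywhere; BED is converted at
  the I/O boundary in both directions.
- Transcripts whose CDS length (after phase) is not a multiple of 3 are
  dropped with a warning at GTF parse time; codons containing N are dropped
  per effect.
- The mock predictor maps a SHA-256 digest of (seed, peptide, allele) to
  (0, 100], so results are platform-independent and reproducible.

## Problem sizes

Tests and the example run on the 6 kb fixture genome with 12 plants × 50
reads (600 reads); the full pipeline completes in about a second, and the
whole suite in a few seconds. These sizes exercise every code path; the
per-position pileup is held in memory and scales linearly, which is adequate
for targeted or exome-scale regions but would want a streaming pileup for
whole-transcriptome BAMs.

## Known limitations

- No BAM/CRAM input (plain SAM only, by design of the text-only fixtures);
  the reader contract admits a BAM backend without API change.
- Duplicate handling honours the SAM flag only; no in-package duplicate
  marking, realignment or recalibration.
- The recognition model H is a transparent hydropathy logistic, not a
  trained classifier; treat absolute p values as a ranking device.
- MHC class II, proteasomal cleavage and TAP transport are out of scope.
- Editing level is per site; when a gene carries several edited sites each
  candidate uses its own site's level.
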