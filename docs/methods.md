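# Methods

This note documents the models, rules and numerical choices behind
`bhlhkit`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the procedure was
genuinely open.

## Canonical coordinates and the scoring profile

Every classification rule is defined over *canonical columns*: the
match columns of a reference multiple alignment of the bHLH domain,
numbered 1..n left to right. A column is a match column when its gap
fraction is below 0.5 (the profile-HMM convention). The default
geometry is a 61-column domain with the basic region at columns 1–17,
helix 1 at 18–28, the loop at 29–43 and helix 2 at 44–61; the 19
conserved positions and their allowed residue sets ship as a TSV rule
file (`bhlhkit/data/conserved_positions.tsv`) together with the
reported per-position residue frequencies, and are fully replaceable.

The scoring profile assigns column c and residue r the log-odds score
`log2((n_c(r) + w·b(r)) / (n_c + w) / b(r))` in bits, with `n_c(r)`
the residue count among non-gap residues of the column, `w` the
pseudocount weight (default 1) and `b` the background (default uniform
1/20). Defaults were chosen as the simplest standard values — they are
configuration, not estimates — and are recorded in every report
header through the configuration hash.

Domain location is a Smith–Waterman-style local alignment of profile
columns to the protein under affine gap penalties (open 4 bits,
extend 0.5 bits; a gap of length k costs `open + (k-1)·extend`). The
path model uses three states (match, residue insertion, column
deletion); insertions and deletions never abut, which the test-suite
oracle enumerates explicitly. Ties are broken toward the smallest
protein start, then the smallest end, making results bit-reproducible.
The hit threshold defaults to 0.8 × the minimum ungapped self-score of
the reference members, which guarantees that the family the profile
was built from passes its own search; the factor is configurable.

## Membership, binding, conservation

A candidate joins the family with at most nine mismatches over the 19
conserved positions. "Mismatch" means the residue is outside the
position's allowed set — not merely different from the single most
frequent residue — because several positions legitimately admit two to
four high-frequency residues. A gap at a conserved position counts as
a mismatch (the conservative reading of an incomplete domain), and a
structural region whose conserved positions are all gapped fails the
candidate outright as "incomplete domain"; no numeric completeness
rule beyond that is imposed.

DNA-binding prediction uses only the basic region. The basic-residue
tally defaults to {K, R, H}; whether histidine should count is not
settled usage, so the set is configurable. "More than five basic
residues" is implemented as a strict ≥ 6 threshold. The E-box
predicates are Glu-13 and Arg-16; the G-box predicates add His/Lys-9
and Arg-17 and are evaluated only within E-box binders, so the G-box
binders are a subset of the E-box binders by construction. A gap at a
predicate column fails the predicate (no residue, no contact).

Conservation statistics are residue frequencies over non-gap residues
per column, with the gap fraction reported separately. A column is
"conserved" when its consensus ratio strictly exceeds the threshold
(default 0.5). Integer percentages in summary tables round half-up;
all other frequencies are written in full precision and round-trip
through the TSV exports.

## Duplications and tandem arrays

Pairs are aligned globally with BLOSUM62, gap open 10, extend 0.5 and
free end gaps. Identity is identical aligned pairs over aligned
non-gap pairs; coverage is aligned non-gap pairs over the longer
sequence length. Both denominators were chosen to make the statistics
symmetric in the pair, since "covering ≥ x% of protein length" does
not say whose length; the choice is configurable. Class thresholds:
high-stringency at identity ≥ 50 and coverage ≥ 90, low-stringency at
≥ 30 and ≥ 70; a gene's class is the highest class of any pair it
participates in, so high and low gene counts are disjoint. Segmental
(whole-genome) duplication detection is out of scope.

Tandem arrays are maximal runs of family genes in per-chromosome gene
order (ranks derived by start-coordinate sort) in which consecutive
family members are separated by at most `max_spacers` non-family
genes. The spacer bound is genuinely open in common usage; the
default is 1 and every report flags the value used.

## Intron patterns

Intron positions are computed by pure coordinate arithmetic on the
CDS segments in transcript orientation — no spliced alignment is
performed. An exon boundary at `d` coding bases past the start of the
domain's first codon is reported as `(d // 3, d % 3)`: phase 0 means
between codons. The three reference intron positions default to codon
offsets 9, 27 and 45 (phases 0, 1, 0) from the domain start; they are
a documented, overridable anchor choice, as is the match tolerance
(default 0 codons — exact positional correspondence). Pattern labels
are catalogue-driven: a table maps (matched reference subset, count of
non-reference introns) to labels I–XI, with I pinned to all three
references and no extras, XI pinned to the intron-free key, and any
unknown key reported as "other" so classification is total. The
catalogue beyond those two pinned rows is a package default that users
with a concrete labelling in mind should replace.

## Expression rules and qPCR

Expressed: RPKM strictly above 1.4 in at least one tissue.
Tissue-specific: one tissue strictly above twice the *maximum* of the
other tissues (the strictest reading of "2 times higher than other
tissues"; comparison against the mean is available by configuration)
and above the expressed threshold — which makes the specific set a
subset of the expressed set, and makes the fold comparison
scale-invariant while the expressed threshold is not.
Fruit-development trends: Spearman rank correlation (average ranks on
ties) between stage index and expression across the ordered fruit
stages (default Fruit_1cm → Fruit_B+10), called increasing at
ρ ≥ 0.9, decreasing at ρ ≤ −0.9, both gated by a ≥ 2-fold max/min
span so ordered-but-flat noise does not qualify; constant rows are
"none" by contract. "Gradually increased/decreased" has no published
operational rule, so these defaults are declared rather than derived,
and the trend-gene count on real data should be read as indicative.

qPCR quantification is the textbook 2^–ΔΔCt: the target's Ct is
normalized to the reference gene within each sample and to the
calibrator condition per gene.

## Promoters

The promoter is the `length` (default 1500) bases immediately 5' of
the TSS in transcript orientation; the TSS base itself is excluded,
and offsets are reported with −1 the base adjacent to the TSS. Minus-
strand windows are reverse-complemented; windows truncated by a contig
edge shrink with a warning. Motifs are IUPAC strings matched exactly
(no PWM scoring); the minus strand is scanned by matching each motif's
reverse complement on the forward sequence, so a hit's coordinate is
always its 5'-most forward base. Overlapping and nested hits are all
reported — a planted I-box necessarily implies an I-box-core hit at
the same start. Only the five named fruit-development elements ship as
defaults; the library is a TSV and extensible.

## The synthetic-data generator

The generator's role is to produce every input the pipeline consumes
with planted, machine-readable truth. Design principles:

- **Hierarchical seeding.** Every entity draws from a substream keyed
  by (master seed, stream, entity index): adding an entity never
  reshuffles the others, and regeneration is byte-identical.
- **Checked feasibility.** Wherever realized properties could drift
  from planted ones, the generator verifies with the pipeline's own
  operations and redraws or fails loudly: decoys are re-scanned
  exhaustively to contain no 19-position window within nine mismatches
  of the consensus; members are re-searched with the same-seed profile
  and must return their planted span, mismatch count and category;
  duplicate pairs are re-measured and must land within ±2 points of
  target identity and coverage (for targets below the low-stringency
  identity threshold, where substitution mutagenesis cannot pin an
  aligner's statistics to a point value, the pair is built from an
  unrelated sequence and verified to classify as "none" with identity
  at least 5 points under the threshold); promoter backgrounds are
  mutated until a scan finds no hit outside the planted intervals.
- **Family realism where it matters.** Reference alignment rows draw
  conserved positions from the reported frequency distributions and
  vary the non-conserved basic-region columns between each column's
  dominant basic and dominant non-basic residue — the basic region's
  composition encodes binding type, not family identity, and this is
  exactly what makes locating the domain nontrivial. Members realize
  their planted binding category by pinning predicate columns and
  steering the basic count with a margin of one to two residues from
  the threshold; planted mismatches avoid the two first and the last
  conserved positions so a local alignment cannot trim them off the
  domain ends.
- **Separation of planted signal and background.** Expression
  backgrounds are low (below the expressed threshold) and flat
  (within-gene fold < 1.3); specific genes exceed the fold rule with
  ≥ 20% margin; trend genes are geometric series with stage ratio 1.7,
  monotone before noise but never twofold between adjacent stages, so
  they cannot masquerade as tissue-specific. Noise is multiplicative
  log-normal, `value · exp(σ·N(0,1))`.

What the generator does **not** emulate: phylogenetic correlation
between members (every member is drawn independently around one
template), codon-usage and splice-site realism beyond GT..AG ends,
overlapping genes, multi-domain proteins, and expression count noise
models (no mean–variance relationship). Passing the planted-truth
suites therefore shows the rules and coordinate arithmetic are
implemented correctly and recoverable under the stated noise — not
that the thresholds themselves are optimal for any particular real
data set.

## Problem sizes and verification strategy

The default test and reproduction runs use 10–12-member families with
3–4 decoys per seed over 20 seeds, four-gene intron bundles, 20–60
gene expression matrices, three duplicate pairs per seed placed at
least 5 points from every class threshold, and single-promoter motif
sets — sizes chosen so a full validation sweep completes in seconds
while every code path is exercised; all sizes are arguments.
Correctness anchors are dual-route: the local-alignment DP is compared
against exhaustive path enumeration on instances up to 5 columns × 8
residues; the duplication aligner against an independently written
memoized affine DP on 10-mers; intron mapping against a per-base
exon-walk; tandem arrays against a quadratic window scan; ΔΔCt against
direct formula evaluation.

## Known limitations

- The profile search reports a single best hit per protein;
  multi-domain proteins need repeated masking by the caller.
- Bit-score thresholds are calibrated from the reference set, not
  from an E-value model; scores are not comparable across profiles
  with different column counts.
- The duplication statistics depend on aligner parameters; published
  duplicate counts obtained with other aligners may differ near class
  boundaries, which is why reproduction checks carry a ±3 band and a
  per-protein diff table.
- GFF3 support covers the gene/mRNA/CDS subset with `Parent` links;
  exotic annotations (trans-splicing, shared CDS) are out of scope.
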