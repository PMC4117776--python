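# Methods

## The measurement problem

Replication-dependent histone mRNAs are normally processed by U7
snRNP-directed endonucleolytic cleavage just downstream of a conserved
16-nt stem-loop, guided by base-pairing between U7 snRNA and the
histone downstream element (HDE). They therefore carry no poly(A) tail and
are invisible to poly(A)-selected libraries. When the balance between the
stem-loop pathway and the default polyadenylation machinery shifts — for
example on loss of a 3′-end processing factor — a growing fraction of
histone transcripts is cleaved at the same site and then polyadenylated.
Two signals report this switch, and this package computes both:

1. in a strand-specific 3′-end sequencing library, reads from
   polyadenylated histone transcripts end at the cleavage site in
   untemplated adenosines, so per-site tailed-read counts rise;
2. in qPCR, oligo(dT)-primed (polyadenylated) quantities rise while
   random-primed (total) quantities stay flat.

## Cleavage-site calling

A sense-strand read is aligned by its 5′ prefix; the unaligned 3′ suffix is
the *tail*. Let `e` be the first unaligned genomic coordinate.

- If `genome[e] ≠ A`, the site is `e` (the first post-cleavage base).
- If a genomic A-run of length `r` begins at `e`, the first
  `min(r, a)` tail adenosines (where `a` is the tail's leading-A count)
  could be genome-templated. They are assigned to the genome and the site
  moves past them. Tail statistics use the remaining untemplated suffix.

**Why the maximal run, not a single A.** Any aligner will extend an
alignment through genome-matching adenosines arbitrarily far, so the
boundary between "aligned prefix" and "tail" at an A-rich junction is an
artifact of aligner scoring. Reassigning the *entire* matching A-prefix
yields the unique convention under which the called coordinate is
independent of how far the aligner happened to extend. The single-A variant
(`a_run="single"`) is kept behind a flag for comparison. The rule is
verified exhaustively against a brute-force oracle that enumerates every
templated-prefix/untemplated-suffix split of the tail over all 4⁶ downstream
contexts and tail lengths 1–4.

Degenerate inputs are no-calls rather than errors: empty tails (no evidence
of polyadenylation), tails that could be entirely templated (pure-A
junctions), multi-mapped reads, and antisense alignments. A tail whose
untemplated part is less than 80% A is dropped as a suspected artifact
(sequencing error or chimera); the threshold is configurable and 0 disables
it. No additional internal-priming filter on downstream genomic A content is
applied, and nearby sites are never clustered into peaks — sites are
single-nucleotide, with a ±2-nt tolerance used only when labeling calls
against a gene's canonical coordinate.

Identical read sequences are collapsed before alignment into one
representative with a multiplicity, reflecting PCR-duplicate handling in
3′-end protocols; site tables carry both the raw (multiplicity-weighted)
count and the collapsed distinct-sequence count.

## Built-in aligner and SAM import

The built-in aligner exists so the toy pipeline runs with no external
dependency: exact 20-nt prefix seed, extension with at most 2 mismatches,
and trimming back to the best-scoring prefix (match +1, mismatch −4). The
score-based trim is essential: a plain "longest prefix with ≤ k mismatches"
rule would absorb the first tail adenosines as terminal mismatches and
corrupt the site coordinate; trimming to the score optimum reproduces how
soft-clipping aligners behave. Among equal-length loci the leftmost is
reported and the read flagged multi-mapped (excluded from site calling).
It handles substitutions only — the simulated reads are unspliced and
indel-free — and is not intended for real genomes; pre-aligned SAM is the
supported entry point there, with a trailing soft-clip on a plus-strand
record taken as the tail, and reverse/secondary/supplementary records
dropped under the sense-strand convention.

Coordinates are 0-based half-open everywhere internally (BED native, GFF3
converted on I/O) to keep single-nucleotide site arithmetic free of
off-by-one drift.

## Motif annotation

The stem-loop is detected *structurally*: a window of 6 + 4 + 6 nt whose
first six bases are the reverse complement of its last six (Watson–Crick;
G·U wobble behind a flag, off by default because the canonical histone stem
is fully Watson–Crick paired). No consensus string or PWM scoring is used,
and no free-energy minimization — detection, not thermodynamics, is the
goal. The HDE is scanned as the DNA transliteration `AAAGAGCTGT` of the RNA
consensus with a Hamming budget of 2 mismatches, reflecting the few-base
deviations real histone genes show from the consensus. Per-gene layout
validation checks stem-loop and HDE within their annotated intervals and
the cleavage coordinate strictly between them, reporting flags and spacings
rather than raising.

## Differential polyadenylation

With library sizes s₁, s₂ and per-gene counts c₁, c₂, the null of equal
normalized expression makes c₂ | (c₁+c₂) binomial with success probability
s₂/(s₁+s₂); the exact two-sided test is used per gene (scipy), adjusted by
Benjamini–Hochberg (statsmodels; an independent step-up-formula oracle
backs the tests). Classification is up/down/nc with an *inclusive* 2-fold
threshold on the size-factor-normalized fold change plus q ≤ 0.05;
`fold_only` reproduces classification by fold change alone. Size factors
are total-count: library size over the geometric mean of library sizes. A
0.5 pseudocount enters the reported log₂ fold change only when a count is
zero, and never affects the test.

Normalization caution: when the count matrix covers only histone genes (as
on the synthetic fixture), normalizing by the subset's own totals would
cancel a genuine global shift in histone polyadenylation; the per-library
sequencing depth is the appropriate denominator and can be passed
explicitly. Replicate-aware dispersion modeling (negative binomial across
biological replicates) is deliberately out of scope — the test conditions
on one library per condition — and the test function is pluggable for
callers who want a different count model.

## Comparative Ct

ΔCt = Ct_target − Ct_reference within each sample; ΔΔCt subtracts the
control sample's ΔCt; rq = (1+E)^(−ΔΔCt) with E = 1 (100% amplification
efficiency, the standard assumption of the comparative-Ct method) unless an
efficiency is supplied. Replicate scatter propagates into an rq standard
deviation by the delta method but is reported only — significance testing
across biological replicates is left to the caller. A −RT control passes
only when its mean Ct is *strictly* above 33 cycles; Ct = 33 exactly counts
as contaminated. Pairing the oligo(dT)-primed and random-primed rq values
for one gene flags the selective-polyadenylation pattern: poly rq beyond
the 2-fold threshold in either direction while total rq stays within
[1/2, 2].

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed and the
tests run against them:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 20 | the scale of a replication-dependent histone family panel |
| `contig_length` | 20 kb | holds 20 non-overlapping ~100-nt gene layouts with margins |
| `read_length` | 50 nt | SE50-style single-end 3′-end reads |
| `tail_length_range` | 1–15 | untemplated A count; fragment (prefix+tail) always = read length |
| `error_rate` | 0 | substitutions opt-in (0.001 in the noisy recovery checks) |
| `duplicate_rate` | 0.1 | a realistic PCR-duplicate load for an amplified library |
| `depth_per_condition` | 10,000 | enough for ~25–100 tailed reads/gene; seconds to analyze |
| `polyA_fraction` | 0.05 | wild-type-like: a small minority of histone mRNAs polyadenylated |
| `effect_size` | 4.0 | knockout-like elevation of the polyadenylated fraction |

Each gene's 3′ region is planted 5′→3′ as: random 6-nt stem arm + random
4-nt loop + reverse-complement arm (the hairpin), a cleavage coordinate
4–6 nt later, and the HDE 9–13 nt after the cleavage coordinate; all other
sequence is uniform over {A,C,G,T}. Genes sit on one plus-strand contig
(the sense-strand convention; minus-strand handling is exercised through
SAM import tests). Per-condition per-gene read counts are multinomial and
sum to the depth exactly.

Each read samples a polyadenylated transcript (the library is
poly(A)-selected, so stem-loop-processed ends never appear): with
probability `polyA_fraction` it is the 3′-terminal fragment — a genomic
suffix ending exactly at the cleavage coordinate followed by k untemplated
A's — and otherwise an internal, fully templated fragment that contributes
no site evidence. Substitution errors are applied after tail construction;
PCR duplicates are byte-identical copies (errors included) drawn within the
gene's read stream so per-gene truth counts stay exact.

Two generator choices make the planted truth *identifiable*: the first
post-cleavage base is never A, and the ~20 nt after the cut are redrawn in
the rare case an all-A tail could out-score the soft-clip under the
aligner's scoring (or create a second HDE match). Real histone loci do have
A's after the cut — that is exactly what the A-run reassignment rule is
for — but a fixture whose truth coordinate were ambiguous could not be used
for exact-recovery testing; the rule itself is exercised separately against
the exhaustive oracle. Consequently, passing the recovery tests shows the
pipeline machinery is correct under unambiguous junctions, not that every
real A-rich junction resolves to a unique coordinate (it cannot, which is
why the convention matters). Other real-data features the simulator does
not model: ligation and RNase digestion biases, fragment-size selection
chemistry, spliced reads, indels, non-histone background transcripts, and
batch effects between libraries.

The qPCR simulator inverts the comparative-Ct model by construction:
Ct = −log₂(quantity)/log₂(1+E) + a per-(gene, priming) baseline offset +
Gaussian replicate noise, with oligo(dT) quantities equal to the condition's
polyadenylated fraction, random-primed and reference quantities fixed at 1,
and −RT rows near Ct 36. Noise-free tables therefore invert to the exact
simulated ratio, a closed-form correctness check of the ΔΔCt code.

## Numerical and testing notes

- All randomness flows from integer seeds through numpy `SeedSequence`
  spawning; a fixed seed reproduces genome, reads and Ct tables byte for
  byte.
- The stem-loop scanner is checked against a brute-force window oracle:
  complete enumeration over the two-letter alphabet {A,T} at lengths 16–18
  (every length class around the 16-nt window, ~459k strings) and seeded
  random strings at lengths 19–30; random 4-letter sequences are checked
  separately. Exhaustive enumeration of *all* binary strings to length 30
  (2³¹ strings) is not feasible at interactive timescales, and the
  length-capped enumeration already covers every structural case the
  window rule distinguishes.
- Test problem sizes (20 genes × 10k reads; 100 differential replicates at
  depth 200; 2,000 null genes at depth 10⁵) were chosen so the full suite
  and the acceptance script each finish in well under a minute while
  keeping Monte-Carlo error far from the asserted margins.
- Known limitations: no spliced or indel alignment; sense-strand plus-only
  site calling; no peak clustering or alternative-polyadenylation usage
  indices beyond the stem-loop/downstream/other labels; binomial (not
  replicate-dispersion) differential testing; qPCR efficiency assumed
  shared between target and reference.
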