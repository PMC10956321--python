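# Methods

## Coordinate conventions

All in-memory interval arithmetic is 0-based half-open. `StructuralVariant`
records are the one deliberate exception: they carry 1-based inclusive
`pos`/`end` with `length = end − pos + 1` for DEL/DUP/INV (so a deletion
spanning X:53,609,703–53,609,995 is 293 bp) and `end == pos` for insertions,
whose `pos` is the last reference base before the inserted sequence.
Conversion happens only at the record boundary (`start0`/`end0`
properties) and at I/O. VCF output follows the htslib-enforced symbolic-SV
convention — POS is the base *preceding* the affected interval, so
`END = POS + |SVLEN|` equals the 1-based inclusive end — and the reader
undoes the shift, making write→read lossless.

Distances to gene bodies are closed at the flank boundary: a variant or
breakpoint with exactly `flank` bases between itself and the gene body is
still assigned (4,999 bases in, 5,001 out, 5,000 in, for the default 5-kb
flank).

## Anchor alignment

`anchor_align` indexes the k-mers (default k = 21, odd so no k-mer is its
own reverse complement) that occur exactly once in each genome, matches
them on both strands, and chains anchors that advance on both genomes by at
most `max_gap` (default 30) while staying within `diag_slack` (default 20)
of the chain diagonal. Two consequences matter:

* any indel of ≥ `diag_slack` bases breaks the chain and surfaces as an
  inter-block gap — so the caller can size it;
* `max_gap` must stay *below* the minimum SV length of interest. A
  length-neutral event (a small inversion) leaves a symmetric anchor desert
  of `span + k − 1` bases on both genomes; if that fits inside `max_gap`
  the flanking chain silently bridges it and the event is lost.

Blocks need ≥ 10 anchors (noise floor). Overlapping blocks are reduced
greedily by descending match count, tolerating ≤ 25 bp of edge overlap —
anchor-boundary effects routinely produce 1–2 bp overlaps between
legitimate adjacent blocks, and discarding such blocks outright fragments
synteny chains.

The aligner assumes i.i.d. (repeat-free) sequence, which the generator
guarantees; on repetitive genomes the unique-k-mer assumption removes
anchors rather than creating false ones, degrading sensitivity, not
precision. Real-data workflows should supply minimap2/LASTZ PAF instead.

## SV calling

Within each run of collinear blocks on a reference chromosome, a gap of
`g_t` target and `g_q` query bases is classified by the *net* difference
`g_q − g_t`, which is invariant to junction micro-homology (a 1-bp homology
shifts both block edges and would otherwise shrink a 50-bp event below the
calling floor): net ≥ 50 → INS, net ≤ −50 → DEL, both sides ≥ 50 → a
DEL+INS replacement pair (the caller has no substitution type; the pair
conserves length bookkeeping). Placement of a homology-shifted call is
ambiguous by the homology length (≤ 2 bp in practice); truth matching uses
a 50-bp / 0.8-reciprocal-overlap convention.

Tandem duplications are recognized geometrically: the flanking blocks each
extend `c = (L − g_t)/2` bases into the source copy, so the assembly gap
must read `ref[left_end:src_end] + ref[src_start:right_start]`; identity is
verified with edlib at ≥ 0.90. The degenerate `c = 0` case — external
aligners that report the extra copy as a pure insertion at the source end —
reduces to the inserted sequence matching the reference window immediately
preceding it, and is kept as a fallback. Dispersed duplications are out of
scope; DUP coordinates are the source locus.

Inversions are interior runs of blocks oriented against the chromosome
backbone (the dominant strand by aligned span). Flanking-run comparison
alone is wrong: a backbone-oriented run sandwiched between two *separate*
small inversions would be flagged. Terminal discordant runs (breakend-like
signatures) are never emitted.

## Synteny blocks and breakpoint regions

"Resolution" is interpreted as the minimum reference span of a synteny
chain (the upstream tool's parameter semantics are not published);
chains below it are noise at that resolution. Chains are merged across
intervening sub-resolution material when still collinear (gap discrepancy
≤ the resolution), then filtered. Breakpoint regions are the gaps between
adjacent surviving chains with different identities; zero-length gaps are
kept as point breakpoints because the junction position is informative.
Regions are computed on the reference by default; `side="query"` reports
them on the assembly. On simulated data every junction of a planted
≥-resolution rearrangement is recovered with positional error ≤ max_gap + k.

## Breed-specific filtering

The subtraction is positional: any ≥ 1-bp overlap with any comparator SV
removes a focal SV, regardless of type — the minimal reading of
"positions overlapped". Insertions are points on the reference, so a pad
(default ± 100 bp) makes insertion-vs-insertion subtraction meaningful;
same-type-only and reciprocal-overlap-fraction policies are provided for
sensitivity analysis. Filtering is anti-monotone in the comparator set and
the output is always a subset of the input (property-tested).

## GRM and PCA

The GRM is the standardized cross-product averaged over polymorphic
variants, with pairwise-complete missing handling (per-pair variant count
M; a mean-imputation mode is provided). Allele frequencies come from
non-missing calls. Eigendecomposition uses `scipy.linalg.eigh`; PCs are
ordered by descending eigenvalue, coordinates are eigenvector ×
√eigenvalue, and each PC's sign is fixed so its largest-magnitude loading
is positive (reproducibility only). The autosome restriction is a
chromosome include-list.

## DEG and regulatory integration

DEG thresholds are applied exactly as printed: |log2FC| **≥** 1 and
adjusted P **<** 0.05. Common DEGs are the per-tissue intersection of the
two breed comparisons, requiring a consistent direction by default (the
toggle exists because the source analysis is ambiguous on this point; the
intersection reading is implemented, the "exclusive to the focal breed"
reading is not). Linked triples require the gene to be a common DEG of the
tissue and the NSV to lie within gene body ± flank; the chromatin overlay
reports every state under the NSV in the linked tissue, with promoter
({TssA, TssAFlnk}) and enhancer ({Enh, EnhG}) class flags (vocabularies
configurable). Rows without regulatory overlap are retained.

## The generator: what it emulates, and what it does not

Defaults model the study design at desk scale: a reference breed (duroc), a
focal breed (nanchukmacdon) and a comparator (landrace) on 3 × 1 Mb
chromosomes; 100 private SVs per non-reference breed and 30 shared, mixed
40/40/10/10 % DEL/INS/DUP/INV with lengths 50–500 bp (DUP 60–400, INV
50–1000); two 300–360-kb inversions as rearrangements, placed with margins
≥ the 300-kb synteny resolution so both flanks can form synteny blocks
(this is what makes "breakpoint recall at resolution" measurable on a 1-Mb
chromosome); a 10/6/13-sample genotype panel; and genotype frequencies of
0.9 (owning breed), 0.5 (shared, non-reference breeds) and 0.02
(background) — generator conventions, not reported values. Events are
guard-separated by ≥ 1 kb, applied right-to-left per chromosome, and
recorded in a truth set; re-applying the truth reproduces each assembly
byte-for-byte (tested against an independent re-implementation).

The default genotyping rate is 0.9. The observed per-sample genotyping rate
of ~42% that motivates the genotyping emulation is exercised explicitly
(tests and the acceptance script set `genotyping_rate=0.4173`), but is not
the default: at 42% genotyping essentially no variant in a 29-sample panel
passes the missing ≤ 0.1 filter, and the filtered PCA would be undefined.

Background expression statistics draw log2FC ~ N(0, 0.75) and padj ~
U(0,1); planted genes get |log2FC| = 1 + Exp(0.8) with one sign across both
comparisons and padj = 10^U(−6,−2). The analytic null rate for common DEGs
is therefore `(0.05 · P(|N(0, 0.75)| ≥ 1))²` per gene and tissue (≈ 8.3 ×
10⁻⁵) — the padj filter alone does not determine DEG status — and the
calibration test checks the observed count against this rate within
4-σ Poisson bounds. Chromatin tracks cover every TSS with a promoter-class
segment, scatter enhancers per tissue, resolve overlaps by priority
(planted placements > promoters > enhancers) and fill the rest with Quies.

What the generator does *not* emulate — and hence what green tests do not
establish about real data: repeat families and segmental duplications (the
dominant source of SV-calling error in real genomes), read-level evidence
and genotyping error structure, LD between variants, isoform-level
annotation, count-based DE inference (statistics are drawn, not estimated
from counts — re-implementing a negative-binomial DE model is out of
scope), and correlated chromatin states across tissues.

## Problem sizes

The default acceptance simulation is 3 × 1 Mb with ~230 planted events per
genome pair; the test suite's shared dataset is 2 × 300 kb with a scaled
50-kb resolution and one 60–80-kb rearrangement. These sizes make every
stage's behaviour (including two full alignments) reproducible in seconds
while keeping all rates measurable; the algorithms are linear to
n-log-n in genome size apart from the O(n²) brute-force oracles, which
exist only in tests.
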