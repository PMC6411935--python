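# Methods

## The problem

Transposable elements (TEs) make up large fractions of animal genomes, and
loci of one subfamily descend from a shared consensus, so short RNA-seq
reads from a TE transcript often align equally well to many loci
("multi-mapped reads"). Discarding them under-counts young, active
elements; naive equal splitting misattributes them. `telocus` quantifies
TE expression at single-locus resolution by apportioning multi-mapped
read fractions from empirical evidence: unique alignments anchor an
initial assignment, which an expectation-maximization (EM) loop then
refines against length-normalized abundance estimates.

## Fragment classification

All reported placements of a fragment (a pair, or a single-end read) are
grouped by read name; uniqueness is decided from the *observed* placement
count, not the NH tag, which is only checked for consistency. Mate-rescue
rules:

- both mates placed once → unique;
- exactly one mate unique → the pair is unique, anchored at that mate's
  placement; the multi mate's other alignments are discarded;
- both mates multi but concordant (same chromosome, opposite strands,
  span ≤ a configurable bound, default 1 Mb to mirror splice-aware
  aligners) in exactly one place → the discordant placements are dropped
  and the fragment contributes a whole count there, but is *not* unique
  evidence: its positions never enter the uniquely alignable length.
  Internally these carry a separate counter (`c_full`) so that the
  invariant `L_U = 0 ⟺ C_U = 0` holds for true unique evidence while the
  whole count still enters the fixed base count;
- otherwise all concordant placements (or, failing any, all placements)
  are kept as multi.

A mate nominates a TE locus when its aligned reference span overlaps the
locus by at least `ceil(0.5 × aligned length)` — reads may dangle into
flanking sequence, which recovers unique alignments at TE edges. Soft
clips are excluded because the aligned span is what pysam reports.
With stranded libraries (`fr`: mate 1 carries the transcript strand;
`rf`: the opposite, the common dUTP protocol) the sense and antisense
directions of a locus are separate quantification keys; unstranded data
collapses to sense. An alignment-unique fragment overlapping several
co-located (nested) loci is routed to the fractional pool rather than
counted as certain for all of them — counting it whole at each would
fabricate reads and break conservation.

## Assignment model

Per key (locus, orientation): `C_U` = unique fragment count, `L_U` =
number of distinct leftmost unique-fragment start positions (the literal
"unique read start positions" reading; unique mappable bases would be an
alternative we did not take). For a multi fragment with candidate set `T`
of size `N`, of which `n` candidates have no unique reads:

- each zero-unique candidate receives `1/N`;
- the remainder `1 − n/N` is split over the others proportionally to
  `C_U/L_U`.

Fractions per fragment sum to exactly one.

Transcribed length `L_TE` is the span from the leftmost to the rightmost
aligned base of contributing fragments (every candidate contributes
initially, since all initial fractions are positive), so it may exceed or
undershoot the annotation. `l_avg` is the unweighted mean fragment span
at the locus. The effective length `l_TE = max(L_TE − l_avg + 1, 1)` is
the number of distinct start positions the transcript admits, clamped so
it can always normalize. Both are frozen after the initial assignment:
re-deriving them inside the loop would let the EM objective drift.

The E-step reassigns each multi fragment proportionally to `C/l_TE` over
its candidates; the M-step re-sums `C = C_U + c_full + Σ fractions`.
Candidates whose *total per-locus count* falls below one read are judged
unlikely to have produced any read: they are zeroed and removed from the
denominator (the per-locus reading is the only non-degenerate one — a
per-read fraction is almost always < 1). If zeroing empties a fragment's
candidate list it falls back to an equal `1/N` split. `--zeroing final`
instead iterates without the rule and applies it once at the end.
`auto` stops when every locus with ≥ 10 counts changes by < 1 % relative
(`|ΔC|/max(C_prev, 1)`), with a hard cap of 100 iterations;
non-convergence returns a warning flag, not an error.

Reported per key: `C_TE` (float, plus a half-up-rounded integer column),
`R_TE` (fragments touching the locus, each once), the confidence score
`100 × C_TE/R_TE` ∈ [0, 100] (100 ⟺ all fragments certain), and
`fpkm = C_TE / ((L_TE/1000)(library/10⁶))` with the library size counted
as fragments with ≥ 1 reported alignment anywhere. FPKM uses the
*transcribed* length, not the annotated one, since annotation-length
normalization under-estimates partially transcribed elements. The default
score threshold of 50 flags low-confidence loci (dropping is opt-in).

## Annotation handling

Coordinates are 0-based half-open everywhere; RepeatMasker `.out`
(1-based inclusive, strand `C` = minus, divergence in percent) is
converted on ingest, UCSC `rmsk` dumps (already half-open, per-mil
divergence, optional `bin` column autodetected) pass through. By default
only interspersed TE classes (LINE, SINE, LTR, DNA, Retroposon, RC,
Unknown/Other) are kept; `--all-repeats` retains simple repeats too.
Every RepeatMasker row is one locus — fragments of one interrupted
element are *not* collapsed, which may split old elements; nested entries
are distinct loci resolved by the quantifier like any multi-candidacy.
Non-reference TEs (expression constructs, polymorphic insertions) merge
from a BED + FASTA pair onto their own contigs, flagged
`is_reference=False`.

## Synthetic benchmark

`simfix` emulates the structure the algorithm adjudicates, not the full
complexity of a transcriptome:

- one random consensus per subfamily; each locus is the consensus with
  independent per-base substitutions at its divergence (no indels — this
  keeps the oracle aligner ungapped and provably complete), inserted at
  recorded coordinates on random background, random strand;
- subfamily divergences evenly spaced over `divergence_range`
  (default 2–25 %), so accuracy stratifies by element age;
- stranded (fr) 100 bp paired reads; fragment length Normal(250, 25)
  truncated at the read length; uniform 0.5 % per-base error; fragments
  uniform along the transcript (annotated span, optionally extended by a
  flank switch to emulate transcription past the boundary);
- expression: 80 % of loci at 20× coverage, 10 % of those deviating by a
  2–100× factor up or down (log-uniform), the rest silent. Silent and
  low-coverage loci are required for detection metrics (TPR/PPV at the
  ≥ 10-count rule) to be non-vacuous. Fragment counts are Poisson around
  `coverage × length / (2 × read length)`;
- one seeded generator threads genome, expression and error sampling, so
  every artifact is byte-reproducible from the seed.

The oracle aligner reports *every* ungapped placement of each mate within
a mismatch budget (default 5 per 100 bp mate, comparable to a splice-aware
aligner's tolerance), using pigeonhole seeding: with seed length
`⌊L/(m+1)⌋`, a placement with ≤ m mismatches must contain an exact seed,
so exhaustive lookup plus vectorized verification finds all of them.
Mates are paired concordantly within 2 kb; NH/HI tags are emitted. Because
the aligner is exhaustive and deterministic, test failures implicate the
quantifier, never alignment heuristics.

What the benchmark does **not** model: splicing, indels and structural
variation, quality-score-dependent errors, GC/positional coverage bias,
genes and intergenic transcription, and genome-scale annotation (10⁵–10⁶
loci). Passing tests therefore demonstrate the correctness of the
assignment arithmetic and its behavior under controlled homology, not
end-to-end accuracy on real libraries.

## Benchmark problem sizes

The recovery benchmark uses 5 subfamilies × 20 loci of 2.5 kb on a
~300 kb genome (≈ 50–60 k fragments after coverage deviation) — large
enough for stable percentages while keeping the full pipeline in tens of
seconds. The EM-benefit benchmark is a minimal pair: two loci 1 % diverged
from a shared consensus, one expressed at 20×, sequencing error off and a
tight mismatch budget (2), so residual ambiguity stems purely from
homology; the unique-informed initial assignment leaves the silent twin
with half of each shared read, and EM reassigns ≥ 90 % of the shared
fragments to the expressed locus.

## Numerical and design notes

- Counts are plain floats; proportional splits need no tie-breaking
  (equal weights split equally by construction).
- Output tables are TSV with fixed column order, floats printed to six
  decimals with a C-locale decimal point; rerunning a command yields
  byte-identical files.
- Bedgraphs: unique track = read-level coverage at depth 1; multi track =
  candidate fragment-span coverage at the assigned fraction; values below
  1e-6 are suppressed.
- Degenerate inputs: a locus with no aligned fragment is omitted (its
  score `C/R` is undefined); a fragment with no TE candidate is excluded
  from quantification but still counts toward the FPKM library size; an
  unpaired mate in a paired library is kept as single-end with a warning.

## Known limitations

- **Expression-asymmetric homology.** When a locus is expressed far more
  highly (e.g. 100×) than near-identical siblings, the EM posterior
  assigns shared reads overwhelmingly to it; siblings keep their unique
  reads but can lose most shared ones, and their recovered counts
  overshoot downward even as the highly expressed locus and the aggregate
  improve. This is inherent to abundance-proportional reassignment plus
  hard zeroing, and is the regime where the confidence score matters:
  affected siblings score low and are flagged at the default threshold.
- Interrupted elements split across RepeatMasker rows are quantified as
  separate loci.
- The 50 %-overlap rule uses the aligned reference span; heavily
  soft-clipped alignments contribute less overlap than their read length.
- Single-cell data is accepted only insofar as it arrives as one
  alignment stream; no per-cell demultiplexing is performed.
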