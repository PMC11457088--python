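# Methods

## The artifact model

An inbred line is expected to be homozygous, but heterozygosity can persist
— most stubbornly where a segregating inversion suppresses recombination.
Over such a region a long-read assembler sees two haplotypes diverged by
roughly the line's residual heterozygosity (order 1% substitutions/bp) and
may emit both, one as part of a chromosome-scale scaffold and the other as
a separate, smaller scaffold (a haplotig). The haplotig is diagnosable by
two signatures used here jointly: every benchmark single-copy ortholog on
it is *Duplicated* (the alternate copy sits on the partner scaffold), and
it aligns nearly end-to-end to the partner at high identity. Genuine
segmental or tandem duplications share the first signature but not the
second, which is why coverage of the *candidate* — not of the partner — is
the removal criterion, and why removal is all-or-nothing per scaffold
(no trimming).

## Duplicate-scaffold procedure

* **Profiling.** One profile per scaffold: `n_busco` placements (Fragmented
  counts toward the denominator by default; a `denominator="complete"`
  mode restricts it to Complete + Duplicated), `n_dup` Duplicated
  placements, `pct_dup = 100·n_dup/n_busco` (0 when no placements), and the
  partner set linked through shared Duplicated benchmark ids. Profiles are
  sorted by `pct_dup` descending, ties by length ascending, so the most
  suspicious (small, fully duplicated) scaffolds lead.
* **Candidates** are all scaffolds with `n_dup ≥ 1`. Zero-busco scaffolds
  can never become candidates and are always kept.
* **Verification.** All partner alignments are pooled and the candidate's
  merged (union) coverage computed; `status=remove` requires coverage ≥
  threshold. The threshold defaults to 0.95: "complete alignment" is a
  judgment call in practice, and 0.95 tolerates scaffold-end fraying while
  still rejecting partial (regional) duplications, which cover well under
  that at realistic region fractions. It is configurable.
* **Keeper rule.** If two candidates cover each other above threshold
  (near-identical twins), the longer one is kept; ties break by more
  single-copy benchmark genes, then lexicographic id. This makes
  "never remove both members of a partner pair" a structural invariant.

## Anchor aligner

A minimal nucmer-like aligner supplies alignments when no external PAF or
show-coords table is given. Maximal exact matches are found by k-mer
seeding (`seed_k` 21) with bidirectional extension; a per-diagonal
high-water mark ensures each maximal run is extended once, making the scan
near-linear even for near-identical sequences. All maximal matches are
reported (maxmatch-like, no uniqueness constraint), on both strands, with
antisense coordinates mapped back to the query's forward strand. N matches
nothing, including N: seeds containing N are skipped and extension stops at
N. Correctness is asserted against a quadratic diagonal-run oracle on
sequences ≤ 2 kb.

Chaining merges same-strand collinear blocks whose ref and qry gaps are
each ≤ `max_gap` (sense: both coordinates increasing; antisense: ref
increasing while forward-strand query coordinates decrease). A merged
block spans the union; its identity is matched bp over the span.

**Parameter logic.** At divergence *d* the maximal exact runs between two
haplotypes average 1/*d* bp. The match floor must therefore sit well below
1/*d* and the chain gap well above it. Two presets are used:

| context | min_match | max_gap |
|---|---|---|
| whole-genome, between-species comparison (`AnchorParams` default, `hapcull align`) | 500 | 5,000 |
| candidate-vs-partner haplotype comparison (dedup stage, `RunConfig`) | 100 | 10,000 |

With the haplotype preset, chained coverage of a 1–2%-diverged copy is
96–100% in seeded simulations; with a 500 bp floor it collapses above
~0.5% divergence (runs ≥ 500 bp have probability e^(−500·d) per run),
which is why the dedup stage does not use the whole-genome preset.

## Duplicate-gene labeling

Strand-oriented `gene` regions (minus-strand reverse-complemented) are
scored all-vs-all; multiple hits to one subject collapse to the maximum
bit score. The default reading of "pairs matching each other better than
anything in the outgroup" is **reciprocal best hit**: A's best focal
subject is B, B's is A, and both directions strictly exceed the respective
best outgroup scores (ties with the outgroup fail). Under this reading a
gene joins at most one pair. A `require_reciprocal=False` mode implements
the weaker mutual-above-outgroup reading, under which a gene may join
several pairs; the default is the stricter one because it is deterministic
and conservative, without claiming it is the only defensible reading. Best
-focal ties break by greater alignment length, then lexicographic subject
id. The reported duplicate fraction counts genes, 2·|pairs|/|genes|, and
both counts are emitted.

When no external blast-tabular file is supplied, an internal surrogate
scorer is used: 2 bits per exactly matched bp, where matched bp is the
union of maximal exact matches ≥ 20 bp (seed 11) projected on the query.
This is *not* a blast substitute for real data — it has no mismatch or gap
model — but it preserves the ordering the classifier needs (identical ≫
lightly diverged ≫ outgroup-diverged ≫ unrelated) and keeps the whole
pipeline executable with no external tool.

## Repeat accounting

Per-base, per-class accounting by sweep line: same-class overlaps are
merged first; a base under exactly one distinct class counts toward that
class, a base under ≥ 2 distinct classes counts toward Multiclass only,
and Total is the union — so single-class rows + Multiclass = Total holds
exactly (verified against a per-base bitmap oracle). Multiclass is defined
over distinct *classes*, not families, so two overlapping LTR families do
not create Multiclass bases. Tandem/Simple/Satellite intervals participate
in the same accounting as transposon classes; a tandem interval inside an
LTR copy contributes Multiclass bases.

Family identity across independent discovery runs, and against comparator
species libraries, uses an 80/80-style rule: the shorter consensus aligns
within the longer (edlib infix mode, which spans the whole shorter
sequence, satisfying the coverage leg) with an edit-distance budget of
(1 − identity)·len(shorter), identity default 0.8. Clusters form by
union-find over cross-run matches (within-run families stay distinct);
cluster class is the majority vote, ties → Unknown; `run_support` counts
distinct runs, and support 1/5 is carried as a "further evidence required"
caveat on lineage-specific calls. Both thresholds are configurable; the
rule is a declared convention, not an inherited one.

## Statistics

Nx is the length of the scaffold at which the descending cumulative sum
first reaches x% of the total; Lx the count through that scaffold, with
ties resolved by a stable descending sort (deterministic, matches common
tooling). GC% excludes ambiguity codes from numerator and denominator.
Transcript length is the genomic span of the mRNA feature (end − start
+ 1), not summed exon length, so intron-containing transcripts report
their full footprint; the median of an even count is the mean of the two
central values. Orphan mRNAs warn and count toward transcripts only.
The cumulative-length curve excludes scaffolds < 1 kb by default.

## Synthetic study conditions

The generator's defaults are the study conditions every planted-truth test
runs under: 10 primary scaffolds of 30–80 kb random sequence; 40 benchmark
ids of which 2 are never planted (Missing) and 2 demoted to Fragmented;
3 haplotig scaffolds copying 50–85% of a source scaffold at 1%
substitution divergence, each spanning an internal inversion
(`inversion_prob` 1.0) whose breakpoints avoid cutting planted markers;
8 tandem duplicate gene pairs at 0.5% mutual divergence plus 20 singleton
genes (1.2–2 kb, gene → mRNA → exon/CDS hierarchies, 25% non-coding);
one outgroup ortholog per focal gene family at 8% divergence; four repeat
families (LTR/LINE/DNA/Tandem) with every fifth LTR copy carrying a nested
tandem interval to create genuine Multiclass bases; and five per-run family
libraries perturbed at 0.5%, with two extra families present in a single
run and absent from both comparator libraries. All randomness flows from
one integer seed through named substreams, so a seed fixes every output
byte. Mutation is substitution-only by default (counts are binomial, used
by the 3σ statistical test); an indel option exists for stress tests.

Scale: the emitted genome is ~0.6 Mb. This is the deliberate desk-scale
regime — large enough that anchor statistics, coverage fractions and score
orderings behave as they do at genome scale for the *relative* quantities
tested (coverage fractions, recovery rates, class percentages), while the
whole pipeline runs in seconds. Benchmark "genes" are 1 kb unique tags with
no codon structure: BUSCO semantics are emulated at the table level
(status follows planted geometry), not by sequence search. Gene features
are annotated on primary scaffolds only; haplotigs carry the duplicated
*sequence* (and duplicated benchmark rows) but no gene features, keeping
the planted duplicate-pair truth unambiguous. Consequences for
interpretation: passing tests show the procedures are correct under the
stated artifact model (substitution divergence, whole-region haplotigs,
table-level BUSCO semantics); they do not exercise indel-rich divergence,
partial/rearranged haplotigs, codon-structured genes, blast score
statistics, or real repeat-model discovery noise.

## Degenerate inputs and tie-breaks

Empty FASTA, unknown BUSCO status, coordinates beyond declared lengths,
features on unknown scaffolds, and blocks naming non-partner scaffolds are
hard errors; unmappable repeat classes become Unknown with a warning,
never dropped. Candidates with no partner alignment are
`candidate_unresolved` (kept). An empty comparator set trivially marks all
families lineage-specific and warns. Config validation reports every
problem at once; pipeline exit codes are 0/2/3 for success/validation
error/stage failure.

## Known limitations

* The surrogate gene scorer and the anchor aligner are exact-match based;
  real blast bit scores and affine-gap alignments will differ in absolute
  value (the classifier only needs ordering).
* The aligner is maxmatch-like; no mum/mumreference uniqueness modes.
* Removal is whole-scaffold only; intra-scaffold (regional) duplications
  are detected as duplicate genes but never excised.
* Distinguishing biologically real duplications from assembly artifacts is
  out of scope: the duplicate-gene list is a flag for caution, not a
  verdict.
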