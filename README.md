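# hapcull

Post-assembly curation for draft genome assemblies of inbred lines.

When residual heterozygosity persists through inbreeding — for instance when
a segregating inversion keeps a stretch of the genome heterozygous — a
long-read assembler can emit both haplotypes of that region as separate
scaffolds. The redundant copy inflates assembly size, doubles benchmark
single-copy orthologs (BUSCOs), and seeds spurious "duplicate genes" in the
annotation. `hapcull` implements the curation steps a genome project applies
after scaffolding:

1. **Duplicate-scaffold purging.** Each scaffold is profiled for benchmark
   gene content; scaffolds carrying at least one *Duplicated* benchmark gene
   become candidates. A candidate is aligned (maximal-exact-match anchors,
   chained) against the *partner* scaffolds that carry the alternate copies
   of its duplicated benchmark genes; if the merged alignment coverage of
   the candidate reaches a threshold (default 0.95) it is considered fully
   duplicated and split — whole scaffold, sequence and annotation — into a
   removed set. Within a mutually covered pair the longer member (ties: more
   single-copy benchmark genes, then id) is always kept.
2. **Duplicate-gene labeling.** Strand-oriented regions of all `gene`
   features are extracted from the focal and an outgroup genome and scored
   all-vs-all. A pair (A, B) is labeled duplicate when A and B are
   reciprocal best hits and each direction's bit score strictly exceeds
   that gene's best hit to any outgroup gene region — a within-species match
   beating every between-species match.
3. **Repeat accounting.** Per-base class accounting over RepeatMasker-style
   and Tandem-Repeat-Finder-style tables: bases annotated by exactly one
   repeat class count toward that class, bases under two or more distinct
   classes count toward **Multiclass** only, and **Total** is the plain
   union — so the rows are disjoint and sum to Total. Family models from
   independent discovery runs are clustered by an 80/80-style identity rule
   to get per-family run support, and families with no match in any
   comparator species library are flagged lineage-specific.
4. **Assembly/annotation statistics.** N50/L50/N90/L90 (descending
   cumulative-sum definition), GC% over unambiguous bases, cumulative-length
   curves, and gene/transcript counts from the GFF3 hierarchy.

A deterministic synthetic-genome generator plants all of these artifacts
(haplotigs at 1% divergence spanning inversions, tandem gene duplicates,
an 8%-diverged outgroup, repeat families with cross-class overlaps) with a
machine-readable truth set, so every stage is tested against known ground
truth end to end.

## Worked example

Run the full pipeline on the default synthetic study conditions:

```sh
hapcull run --seed 42 --out run42
```

which prints (abridged):

```
| metric | before dedup | after dedup |
| Total length (bp) | 628,512 | 530,792 |
| Scaffolds | 13 | 10 |
| N50 (bp) | 51,030 | 54,870 |
| L50 | 5 | 4 |

## Duplicate scaffolds
- candidates with >=1 duplicated benchmark gene: 6 (scaffold_1, scaffold_1_hap, ...)
- removed as fully duplicated: 3 (scaffold_1_hap, scaffold_7_hap, scaffold_8_hap)
- removed bp: 97,720
- duplicated benchmark genes remaining after removal: 0

## Duplicate genes
- pairs: 8; genes: 16 (44.44% of annotated genes)

## Repeats
- total repeat content: 4.05% (21,500 bp)
- families: 6 (low run support: 2, lineage-specific: 2)
```

Reading: of the 13 emitted scaffolds, the 6 candidates are the 3 planted
haplotigs *and* their 3 source scaffolds (benchmark genes inside a
duplicated region are Duplicated on both copies). Only the haplotigs reach
coverage ≥ 0.95 against their partners — the sources are each covered only
over the copied region — so exactly the 3 planted haplotigs are removed,
and no duplicated benchmark genes remain afterwards. The 8 recovered gene
pairs are exactly the 8 planted tandem duplications (16 of 36 genes), and
the 2 lineage-specific repeat families are the two planted singleton-run
models absent from both comparator libraries.

The same analysis is broken into narrative steps under `analysis/`
(`01_simulate.py` … `06_full_pipeline.py`); each writes its tables under
`results/` and large regenerable artifacts under `scratch/`. Subcommands
(`hapcull simulate|stats|align|dedup|genedup|repeats|run|compare`) expose
each stage on files.

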