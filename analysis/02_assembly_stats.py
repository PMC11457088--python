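#!/usr/bin/env python
"""Contiguity and annotation statistics of the raw (pre-dedup) assembly.

Computes N50/L50/N90/L90, GC% and the cumulative-length curve, plus
gene/transcript counts from the annotation; writes both tables under
results/.
"""

from pathlib import Path

import pandas as pd

from hapcull.assembly_metrics import annotation_stats, assembly_metrics, length_cdf
from hapcull.formats_io import read_fasta, read_gff, write_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

assembly = read_fasta(SCRATCH / "simdata" / "assembly.fa")
features = read_gff(SCRATCH / "simdata" / "annotation.gff3")

m = assembly_metrics(assembly)
a = annotation_stats(features)
rows = [
    ("total_length_bp", m.total_length), ("n_scaffolds", m.n_scaffolds),
    ("n50_bp", m.nx[50]), ("l50", m.lx[50]),
    ("n90_bp", m.nx[90]), ("l90", m.lx[90]),
    ("gc_pct", round(m.gc_pct, 3)),
    ("n_genes", a.n_genes), ("n_protein_coding", a.n_protein_coding),
    ("n_exons", a.n_exons),
    ("median_transcript_len", a.median_transcript_len),
    ("longest_transcript_len", a.longest_transcript_len),
]
write_tsv(ROOT / "assembly_stats_raw.tsv", pd.DataFrame(rows, columns=["metric", "value"]))

cdf = length_cdf([len(r) for r in assembly], min_len=1000)
write_tsv(
    ROOT / "length_cdf_raw.tsv",
    pd.DataFrame(cdf, columns=["scaffold_rank", "cumulative_fraction"]),
)

for k, v in rows:
    print(f"{k}\t{v}")
print(f"cumulative-length curve: {len(cdf)} scaffolds >= 1 kb, "
      f"L50 rank {m.lx[50]}, L90 rank {m.lx[90]}")
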