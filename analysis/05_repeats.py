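#!/usr/bin/env python
"""Repeat-content accounting and multi-run family consensus.

Reads the RepeatMasker-style and TRF-style tables, resolves per-base
class overlaps (Multiclass), profiles repeat content per scaffold on the
deduplicated assembly, clusters family models across the five discovery
runs, and flags lineage-specific families against the comparator
libraries.
"""

from pathlib import Path

import pandas as pd

from hapcull.formats_io import read_fasta, read_repeat_table, write_tsv
from hapcull.repeat_summary import (
    RepeatFamily,
    classify_bases,
    consensus_families,
    lineage_specific,
    per_scaffold_profiles,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SIM = SCRATCH / "simdata"


def read_library(path):
    fams = []
    for rec in read_fasta(path):
        name, _, rclass = rec.id.partition("#")
        fams.append(RepeatFamily(name, rclass or "Unknown", rec.sequence))
    return fams


assembly = read_fasta(SCRATCH / "kept.fa")
kept_ids = {r.id for r in assembly}
annos = [
    a
    for a in (
        read_repeat_table(SIM / "repeats.out", "rmout", run_id="rm")
        + read_repeat_table(SIM / "repeats.dat", "trf", run_id="trf")
    )
    if a.seqid in kept_ids
]

summary = classify_bases(annos, {r.id: len(r) for r in assembly})
write_tsv(ROOT / "repeat_summary.tsv", summary.to_dataframe())
write_tsv(ROOT / "repeat_per_scaffold.tsv", per_scaffold_profiles(annos, assembly))

runs = [
    (p.stem.replace("replib_", ""), read_library(p))
    for p in sorted(SIM.glob("replib_*.fa"))
]
families = consensus_families(runs)
comparators = {
    p.stem.replace("comparator_", ""): read_library(p)
    for p in sorted(SIM.glob("comparator_*.fa"))
}
specific = lineage_specific(families, comparators)
write_tsv(
    ROOT / "repeat_families.tsv",
    pd.DataFrame(
        [
            {
                "family": f.family, "rclass": f.rclass,
                "run_support": f.run_support, "low_support": f.low_support,
                "lineage_specific": bool(f.lineage_specific),
                "evidence": f.evidence,
            }
            for f in families
        ]
    ),
)

print(f"total repeat content: {summary.pct('Total'):.2f}% "
      f"({summary.total_bp:,} bp of {summary.genome_bp:,})")
for c in ("LTR", "LINE", "DNA", "Tandem", "Multiclass"):
    print(f"  {c}: {summary.pct(c):.2f}%")
print(f"family clusters across {len(runs)} runs: {len(families)} "
      f"({sum(1 for f in families if f.low_support)} low-support)")
print(f"lineage-specific families: {[f.family for f in specific]}")
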