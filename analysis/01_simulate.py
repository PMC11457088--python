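#!/usr/bin/env python
"""Generate the default synthetic genome with planted truth.

Emulates a Hi-C-scaffolded assembly of an inbred line with residual
heterozygosity: 10 primary scaffolds, 3 haplotig scaffolds at 1%
divergence (each spanning an inversion), 8 tandem duplicate gene pairs,
20 singleton genes, planted repeat families, and an 8%-diverged outgroup.
Writes every artifact plus the truth tables under scratch/simdata/.
"""

from pathlib import Path

from hapcull.synthetic_data import SimConfig, generate

OUT = Path(__file__).resolve().parent.parent / "scratch" / "simdata"

cfg = SimConfig(seed=42)
sim = generate(cfg)
paths = sim.write(OUT)

print(f"wrote {len(paths)} artifacts to {OUT}")
print(f"scaffolds emitted: {len(sim.assembly)} "
      f"({cfg.n_scaffolds} primary + {len(sim.truth.haplotig_ids)} haplotigs)")
print(f"planted haplotigs: {dict(sim.truth.haplotig_ids)}")
print(f"planted duplicate gene pairs: {len(sim.truth.dup_gene_pairs)}")
print(f"planted repeat intervals: {len(sim.truth.repeat_truth)}")
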