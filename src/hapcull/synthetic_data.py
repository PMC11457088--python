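"""Deterministic generator of toy assemblies with planted ground truth.

The generator emulates the artifact model of a Hi-C-scaffolded assembly of
an inbred but residually heterozygous line:

* primary scaffolds of random sequence carrying unique 1 kb benchmark-gene
  tags (BUSCO semantics are emulated at the table level, not by sequence
  search);
* haplotig scaffolds — a copy of a region of a primary scaffold mutated at
  a low divergence, optionally spanning an internal inversion — whose
  benchmark tags are emitted as Duplicated on both copies;
* genuine tandem gene duplications at low mutual divergence, plus
  singleton genes, all annotated as gene/mRNA/exon/CDS hierarchies;
* a diverged outgroup genome carrying a single ortholog per focal gene;
* planted repeat families (LTR/LINE/DNA/Tandem) with deliberate cross-class
  overlaps, emitted as RepeatMasker .out- and TRF .dat-style tables, and
  five perturbed per-run family libraries with a couple of low-support
  lineage-specific families absent from the comparator libraries.

The mutation model is substitution-only by default (an indel rate exists
for stress tests); one global integer seed drives all randomness through
named per-stage streams, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats_io import (
    BuscoRecord,
    GffFeature,
    RepeatAnnotation,
    SeqRecord,
    write_busco_full_table,
    write_fasta,
    write_gff,
    write_rmout,
    write_trf_dat,
)
from .anchor_align import revcomp
from .repeat_summary import RepeatFamily

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome."""

    seed: int = 42
    n_scaffolds: int = 10                      # primary scaffolds
    scaffold_len_range: tuple[int, int] = (30_000, 80_000)
    n_benchmark_genes: int = 40
    n_haplotig_scaffolds: int = 3
    haplotig_divergence: float = 0.01          # substitutions / bp
    haplotig_region_frac: tuple[float, float] = (0.5, 0.85)
    inversion_prob: float = 1.0
    n_dup_gene_pairs: int = 8
    n_singleton_genes: int = 20
    dup_gene_divergence: float = 0.005
    outgroup_divergence: float = 0.08
    n_fragmented: int = 2
    n_missing: int = 2
    indel_rate: float = 0.0
    n_repeat_runs: int = 5
    # (class, family, copy count, unit length)
    repeat_spec: list[tuple[str, str, int, int]] = field(
        default_factory=lambda: [
            ("LTR", "Gypsy-1", 25, 400),
            ("LINE", "R1-1", 15, 300),
            ("DNA", "Tc1-1", 10, 200),
            ("Tandem", "TRF_period5", 20, 250),
        ]
    )

    def __post_init__(self) -> None:
        if self.outgroup_divergence <= self.haplotig_divergence:
            raise ValueError(
                "outgroup_divergence must exceed haplotig_divergence"
            )
        for name in (
            "n_scaffolds", "n_benchmark_genes", "n_haplotig_scaffolds",
            "n_dup_gene_pairs", "n_singleton_genes", "n_fragmented", "n_missing",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_haplotig_scaffolds > self.n_scaffolds:
            raise ValueError("more haplotigs than primary scaffolds")


@dataclass
class HaplotigInfo:
    partner: str
    region_start: int
    region_end: int
    n_substitutions: int
    inversion: tuple[int, int] | None  # haplotig-local coordinates


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside the synthetic genome."""

    haplotig_ids: dict[str, str] = field(default_factory=dict)  # hap -> partner
    haplotig_info: dict[str, HaplotigInfo] = field(default_factory=dict)
    dup_gene_pairs: list[tuple[str, str]] = field(default_factory=list)
    repeat_truth: list[RepeatAnnotation] = field(default_factory=list)
    # busco_id -> {seqid: status}; Missing entries map to {}
    benchmark_truth: dict[str, dict[str, str]] = field(default_factory=dict)


@dataclass
class SimResult:
    config: SimConfig
    assembly: list[SeqRecord]
    annotation: list[GffFeature]
    busco_table: list[BuscoRecord]
    outgroup_assembly: list[SeqRecord]
    outgroup_annotation: list[GffFeature]
    repeat_annotations: list[RepeatAnnotation]
    repeat_runs: list[tuple[str, list[RepeatFamily]]]
    comparator_libraries: dict[str, list[RepeatFamily]]
    truth: TruthSet

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every emitted artifact; returns a name -> path manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "assembly": outdir / "assembly.fa",
            "annotation": outdir / "annotation.gff3",
            "busco": outdir / "busco_full_table.tsv",
            "outgroup_assembly": outdir / "outgroup.fa",
            "outgroup_annotation": outdir / "outgroup.gff3",
            "rmout": outdir / "repeats.out",
            "trf": outdir / "repeats.dat",
        }
        write_fasta(paths["assembly"], self.assembly)
        write_gff(paths["annotation"], self.annotation)
        write_busco_full_table(paths["busco"], self.busco_table)
        write_fasta(paths["outgroup_assembly"], self.outgroup_assembly)
        write_gff(paths["outgroup_annotation"], self.outgroup_annotation)
        interspersed = [a for a in self.repeat_annotations if a.rclass != "Tandem"]
        tandem = [a for a in self.repeat_annotations if a.rclass == "Tandem"]
        write_rmout(paths["rmout"], interspersed)
        write_trf_dat(paths["trf"], tandem)
        for run_id, fams in self.repeat_runs:
            p = outdir / f"replib_{run_id}.fa"
            write_fasta(p, [SeqRecord(f"{f.family}#{f.rclass}", f.consensus) for f in fams])
            paths[f"replib_{run_id}"] = p
        for species, fams in self.comparator_libraries.items():
            p = outdir / f"comparator_{species}.fa"
            write_fasta(p, [SeqRecord(f"{f.family}#{f.rclass}", f.consensus) for f in fams])
            paths[f"comparator_{species}"] = p
        self._write_truth(outdir, paths)
        return paths

    def _write_truth(self, outdir: Path, paths: dict[str, Path]) -> None:
        import pandas as pd

        from .formats_io import write_tsv

        t = self.truth
        paths["truth_haplotigs"] = outdir / "truth_haplotigs.tsv"
        write_tsv(
            paths["truth_haplotigs"],
            pd.DataFrame(
                [
                    {
                        "haplotig": h, "partner": info.partner,
                        "region_start": info.region_start,
                        "region_end": info.region_end,
                        "n_substitutions": info.n_substitutions,
                        "inversion_start": info.inversion[0] if info.inversion else -1,
                        "inversion_end": info.inversion[1] if info.inversion else -1,
                    }
                    for h, info in sorted(t.haplotig_info.items())
                ]
            ),
        )
        paths["truth_dup_genes"] = outdir / "truth_dup_gene_pairs.tsv"
        write_tsv(
            paths["truth_dup_genes"],
            pd.DataFrame(t.dup_gene_pairs, columns=["gene_a", "gene_b"]),
        )
        paths["truth_repeats"] = outdir / "truth_repeats.tsv"
        write_tsv(
            paths["truth_repeats"],
            pd.DataFrame(
                [
                    {"seqid": a.seqid, "start": a.start, "end": a.end,
                     "rclass": a.rclass, "family": a.family}
                    for a in t.repeat_truth
                ]
            ),
        )
        paths["truth_benchmark"] = outdir / "truth_benchmark.tsv"
        rows = []
        for bid, placements in sorted(t.benchmark_truth.items()):
            if not placements:
                rows.append({"busco_id": bid, "seqid": "", "status": "Missing"})
            for sid, status in sorted(placements.items()):
                rows.append({"busco_id": bid, "seqid": sid, "status": status})
        write_tsv(paths["truth_benchmark"], pd.DataFrame(rows))


# --------------------------------------------------------------------------
# sequence helpers
# --------------------------------------------------------------------------

def random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n, dtype=np.uint8)].tobytes().decode()


def mutate(
    seq: str, rate: float, rng: np.random.Generator, indel_rate: float = 0.0
) -> tuple[str, int]:
    """Substitute bases at the given per-base rate; returns (seq, n_subs).

    Substitutions always change the base.  Optional indels (half insertions,
    half 1-bp deletions) are applied after substitution.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.flatnonzero(rng.random(len(arr)) < rate)
    codes = _BASE_INDEX[arr[idx]]
    valid = codes != 255  # never touch N
    idx, codes = idx[valid], codes[valid]
    arr[idx] = _BASES[(codes + rng.integers(1, 4, len(idx), dtype=np.uint8)) % 4]
    out = arr.tobytes().decode()
    n_subs = len(idx)
    if indel_rate > 0:
        pieces: list[str] = []
        prev = 0
        for pos in np.flatnonzero(rng.random(len(out)) < indel_rate):
            pieces.append(out[prev:pos])
            if rng.random() < 0.5:
                pieces.append(out[pos] + random_seq(rng, 1))  # insertion
            prev = pos + 1  # else deletion
        pieces.append(out[prev:])
        out = "".join(pieces)
    return out, n_subs


class _Placer:
    """Sequential non-overlapping element placement across scaffolds."""

    def __init__(
        self,
        scaffold_lens: dict[str, int],
        rng: np.random.Generator,
        margin: int = 500,
        gap_range: tuple[int, int] = (200, 800),
    ) -> None:
        self.lens = scaffold_lens
        self.cursor = {sid: margin for sid in scaffold_lens}
        self.order = list(scaffold_lens)
        self.rng = rng
        self.margin = margin
        self.gap_range = gap_range
        self._next = 0

    def place(self, length: int) -> tuple[str, int]:
        """Place one element round-robin; returns (seqid, start)."""
        for _ in range(len(self.order)):
            sid = self.order[self._next % len(self.order)]
            self._next += 1
            gap = int(self.rng.integers(*self.gap_range))
            start = self.cursor[sid] + gap
            if start + length + self.margin <= self.lens[sid]:
                self.cursor[sid] = start + length
                return sid, start
        raise ValueError(
            f"cannot place element of {length} bp; scaffolds exhausted"
        )


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------

def _gene_features(
    gene_id: str, seqid: str, start0: int, length: int, strand: str,
    coding: bool, source: str = "hapcull_sim",
) -> list[GffFeature]:
    """gene -> mRNA -> exon(s)(+CDS) hierarchy over a half-open interval."""
    start, end = start0 + 1, start0 + length  # to 1-based inclusive
    exon1_end = start + int(length * 0.6) - 1
    exon2_start = start + int(length * 0.7)
    feats = [
        GffFeature(seqid, source, "gene", start, end, strand,
                   {"ID": gene_id}),
        GffFeature(seqid, source, "mRNA", start, end, strand,
                   {"ID": f"{gene_id}.t1", "Parent": gene_id}),
        GffFeature(seqid, source, "exon", start, exon1_end, strand,
                   {"ID": f"{gene_id}.e1", "Parent": f"{gene_id}.t1"}),
        GffFeature(seqid, source, "exon", exon2_start, end, strand,
                   {"ID": f"{gene_id}.e2", "Parent": f"{gene_id}.t1"}),
    ]
    if coding:
        feats.append(
            GffFeature(seqid, source, "CDS", start, exon1_end, strand,
                       {"ID": f"{gene_id}.cds", "Parent": f"{gene_id}.t1"},
                       phase="0")
        )
    return feats


def generate(config: SimConfig) -> SimResult:
    """Build one synthetic genome with planted truth (deterministic per seed)."""
    ss = np.random.SeedSequence(config.seed)
    (seq_ss, tag_ss, gene_ss, rep_ss, hap_ss, status_ss, out_ss, run_ss) = ss.spawn(8)
    seq_rng = np.random.default_rng(seq_ss)
    tag_rng = np.random.default_rng(tag_ss)
    gene_rng = np.random.default_rng(gene_ss)
    rep_rng = np.random.default_rng(rep_ss)
    hap_rng = np.random.default_rng(hap_ss)
    status_rng = np.random.default_rng(status_ss)
    out_rng = np.random.default_rng(out_ss)
    run_rng = np.random.default_rng(run_ss)

    truth = TruthSet()

    # primary scaffolds
    lo, hi = config.scaffold_len_range
    scaffold_seqs: dict[str, list[str]] = {}
    scaffold_lens: dict[str, int] = {}
    for i in range(1, config.n_scaffolds + 1):
        sid = f"scaffold_{i}"
        n = int(seq_rng.integers(lo, hi + 1))
        scaffold_seqs[sid] = list(random_seq(seq_rng, n))
        scaffold_lens[sid] = n

    def plant(sid: str, start: int, seq: str) -> None:
        scaffold_seqs[sid][start:start + len(seq)] = list(seq)

    placer = _Placer(scaffold_lens, tag_rng)

    # benchmark tags (1 kb unique markers); the last n_missing ids are never planted
    tag_len = 1000
    n_planted_tags = max(config.n_benchmark_genes - config.n_missing, 0)
    tag_pos: dict[str, tuple[str, int]] = {}
    for i in range(1, config.n_benchmark_genes + 1):
        bid = f"busco{i:04d}"
        if i <= n_planted_tags:
            sid, start = placer.place(tag_len)
            plant(sid, start, random_seq(tag_rng, tag_len))
            tag_pos[bid] = (sid, start)
        else:
            truth.benchmark_truth[bid] = {}

    # genes: tandem duplicate pairs then singletons
    annotation: list[GffFeature] = []
    focal_gene_ids: list[str] = []
    gene_seqs: dict[str, str] = {}
    for i in range(1, config.n_dup_gene_pairs + 1):
        glen = int(gene_rng.integers(1200, 2001))
        base = random_seq(gene_rng, glen)
        copy_b, _ = mutate(base, config.dup_gene_divergence, gene_rng)
        gap = int(gene_rng.integers(100, 301))
        sid, start = placer.place(2 * glen + gap)
        ga, gb = f"dupg{i:03d}a", f"dupg{i:03d}b"
        for gid, seq, s0 in ((ga, base, start), (gb, copy_b, start + glen + gap)):
            strand = "+" if gene_rng.random() < 0.5 else "-"
            plant(sid, s0, revcomp(seq) if strand == "-" else seq)
            annotation.extend(_gene_features(gid, sid, s0, len(seq), strand, True))
            focal_gene_ids.append(gid)
            gene_seqs[gid] = seq
        truth.dup_gene_pairs.append(tuple(sorted((ga, gb))))
    for i in range(1, config.n_singleton_genes + 1):
        glen = int(gene_rng.integers(1200, 2001))
        seq = random_seq(gene_rng, glen)
        sid, start = placer.place(glen)
        gid = f"gene{i:03d}"
        strand = "+" if gene_rng.random() < 0.5 else "-"
        coding = gene_rng.random() < 0.75
        plant(sid, start, revcomp(seq) if strand == "-" else seq)
        annotation.extend(_gene_features(gid, sid, start, glen, strand, coding))
        focal_gene_ids.append(gid)
        gene_seqs[gid] = seq

    # repeats; every few LTR copies get a tandem interval planted inside
    # them so the accounting sees genuine cross-class (Multiclass) overlap
    consensi: dict[str, tuple[str, str]] = {}  # family -> (class, consensus)
    for rclass, family, n_copies, unit_len in config.repeat_spec:
        if rclass == "Tandem":
            motif = random_seq(rep_rng, 5)
            cons = (motif * (unit_len // len(motif) + 1))[:unit_len]
        else:
            cons = random_seq(rep_rng, unit_len)
        consensi[family] = (rclass, cons)
        for c in range(n_copies):
            copy, _ = mutate(cons, 0.05, rep_rng)
            sid, start = placer.place(len(copy))
            plant(sid, start, copy)
            truth.repeat_truth.append(
                RepeatAnnotation(sid, start, start + len(copy), rclass, family, "truth")
            )
            if rclass == "LTR" and c % 5 == 0 and len(copy) >= 200:
                # nested tandem: overlaps the LTR interval -> Multiclass bases
                ts = start + 50
                te = ts + 100
                motif = random_seq(rep_rng, 5)
                plant(sid, ts, (motif * 21)[:100])
                truth.repeat_truth.append(
                    RepeatAnnotation(sid, ts, te, "Tandem", "TRF_period5", "truth")
                )

    # haplotig scaffolds: copy a tag-containing region of a primary scaffold
    primary = [SeqRecord(sid, "".join(chars)) for sid, chars in scaffold_seqs.items()]
    by_id = {r.id: r for r in primary}
    tag_by_scaffold: dict[str, list[tuple[str, int]]] = {}
    for bid, (sid, start) in tag_pos.items():
        tag_by_scaffold.setdefault(sid, []).append((bid, start))
    eligible = sorted(tag_by_scaffold, key=lambda s: s)
    chosen = [
        str(s)
        for s in hap_rng.choice(
            eligible, size=config.n_haplotig_scaffolds, replace=False
        )
    ]
    haplotigs: list[SeqRecord] = []
    dup_placements: dict[str, list[tuple[str, int, str]]] = {}  # bid -> [(sid, start0, strand)]
    for sid in chosen:
        src = by_id[sid].sequence
        frac = hap_rng.uniform(*config.haplotig_region_frac)
        region_len = int(len(src) * frac)
        tags_here = sorted(tag_by_scaffold[sid], key=lambda t: t[1])
        # window anchored to contain at least one full tag
        anchor_bid, anchor_start = tags_here[int(hap_rng.integers(len(tags_here)))]
        a_lo = max(0, anchor_start + tag_len - region_len)
        a_hi = min(anchor_start, len(src) - region_len)
        a = int(hap_rng.integers(a_lo, a_hi + 1)) if a_hi >= a_lo else 0
        b = a + region_len
        mutated, n_subs = mutate(
            src[a:b], config.haplotig_divergence, hap_rng,
            indel_rate=config.indel_rate,
        )
        inside = [
            (bid, s) for bid, s in tags_here if s >= a and s + tag_len <= b
        ]
        inversion: tuple[int, int] | None = None
        if hap_rng.random() < config.inversion_prob:
            inversion = _pick_inversion(
                len(mutated), [(s - a, s - a + tag_len) for _, s in inside], hap_rng
            )
            if inversion is not None:
                ia, ib = inversion
                mutated = (
                    mutated[:ia] + revcomp(mutated[ia:ib]) + mutated[ib:]
                )
        hap_id = f"{sid}_hap"
        haplotigs.append(SeqRecord(hap_id, mutated))
        truth.haplotig_ids[hap_id] = sid
        truth.haplotig_info[hap_id] = HaplotigInfo(
            partner=sid, region_start=a, region_end=b,
            n_substitutions=n_subs, inversion=inversion,
        )
        for bid, s in inside:
            ls = s - a
            strand = "+"
            if inversion is not None:
                ia, ib = inversion
                if ls >= ia and ls + tag_len <= ib:
                    ls = ia + (ib - (ls + tag_len))
                    strand = "-"
            dup_placements.setdefault(bid, []).append((hap_id, ls, strand))

    assembly = primary + haplotigs
    all_lens = {r.id: len(r) for r in assembly}

    # BUSCO table from geometry; Fragmented drawn from single-copy tags
    duplicated_bids = set(dup_placements)
    single_bids = sorted(set(tag_pos) - duplicated_bids)
    frag_bids = set(
        status_rng.choice(
            single_bids,
            size=min(config.n_fragmented, len(single_bids)),
            replace=False,
        )
    )
    busco_table: list[BuscoRecord] = []
    for bid in sorted(tag_pos):
        sid, start = tag_pos[bid]
        if bid in duplicated_bids:
            placements = [(sid, start, "+")] + dup_placements[bid]
            truth.benchmark_truth[bid] = {p[0]: "Duplicated" for p in placements}
            for psid, ps, pstrand in placements:
                busco_table.append(
                    BuscoRecord(bid, "Duplicated", psid, ps + 1, ps + tag_len,
                                pstrand, 500.0, tag_len)
                )
        elif bid in frag_bids:
            truth.benchmark_truth[bid] = {sid: "Fragmented"}
            busco_table.append(
                BuscoRecord(bid, "Fragmented", sid, start + 1,
                            start + tag_len // 2, "+", 150.0, tag_len // 2)
            )
        else:
            truth.benchmark_truth[bid] = {sid: "Complete"}
            busco_table.append(
                BuscoRecord(bid, "Complete", sid, start + 1, start + tag_len,
                            "+", 500.0, tag_len)
            )
    for bid in sorted(truth.benchmark_truth):
        if not truth.benchmark_truth[bid]:
            busco_table.append(BuscoRecord(bid, "Missing"))
    busco_table.sort(key=lambda r: r.busco_id)

    # outgroup: one ortholog per focal gene at outgroup_divergence
    og_records: list[SeqRecord] = []
    og_features: list[GffFeature] = []
    n_og_scaffolds = 2
    og_chunks: list[list[str]] = [[] for _ in range(n_og_scaffolds)]
    og_cursor = [0] * n_og_scaffolds
    og_gene_spans: list[tuple[int, str, int, int, str]] = []  # (scaf, gid, s0, len, strand)
    ortholog_sources = sorted(
        {p[0] for p in truth.dup_gene_pairs}
        | {g for g in focal_gene_ids if g.startswith("gene")}
    )
    for k, gid in enumerate(ortholog_sources):
        seq, _ = mutate(gene_seqs[gid], config.outgroup_divergence, out_rng)
        scaf = k % n_og_scaffolds
        spacer = random_seq(out_rng, int(out_rng.integers(300, 1000)))
        og_chunks[scaf].append(spacer)
        og_cursor[scaf] += len(spacer)
        strand = "+" if out_rng.random() < 0.5 else "-"
        og_chunks[scaf].append(revcomp(seq) if strand == "-" else seq)
        og_gene_spans.append((scaf, f"og_{gid}", og_cursor[scaf], len(seq), strand))
        og_cursor[scaf] += len(seq)
    for j in range(n_og_scaffolds):
        og_chunks[j].append(random_seq(out_rng, 500))
        og_records.append(SeqRecord(f"og_scaffold_{j + 1}", "".join(og_chunks[j])))
    for scaf, gid, s0, glen, strand in og_gene_spans:
        og_features.append(
            GffFeature(f"og_scaffold_{scaf + 1}", "hapcull_sim", "gene",
                       s0 + 1, s0 + glen, strand, {"ID": gid})
        )

    # per-run repeat family libraries + comparator libraries
    specific_extras = [("RTE-X", "LINE"), ("Crypton-V", "DNA")]
    repeat_runs: list[tuple[str, list[RepeatFamily]]] = []
    for r in range(1, config.n_repeat_runs + 1):
        fams: list[RepeatFamily] = []
        for family, (rclass, cons) in sorted(consensi.items()):
            perturbed, _ = mutate(cons, 0.005, run_rng)
            fams.append(
                RepeatFamily(f"{family}_r{r}", rclass, perturbed, runs={f"run{r}"})
            )
        if r == 1:
            for name, rclass in specific_extras:
                fams.append(
                    RepeatFamily(
                        f"{name}_r{r}", rclass, random_seq(run_rng, 350),
                        runs={f"run{r}"},
                    )
                )
        repeat_runs.append((f"run{r}", fams))
    comparators: dict[str, list[RepeatFamily]] = {}
    for species in ("comparatorA", "comparatorB"):
        fams = []
        for family, (rclass, cons) in sorted(consensi.items()):
            diverged, _ = mutate(cons, 0.10, run_rng)
            fams.append(RepeatFamily(f"{family}_{species}", rclass, diverged))
        comparators[species] = fams

    return SimResult(
        config=config,
        assembly=assembly,
        annotation=annotation,
        busco_table=busco_table,
        outgroup_assembly=og_records,
        outgroup_annotation=og_features,
        repeat_annotations=list(truth.repeat_truth),
        repeat_runs=repeat_runs,
        comparator_libraries=comparators,
        truth=truth,
    )


def _pick_inversion(
    region_len: int,
    forbidden: list[tuple[int, int]],
    rng: np.random.Generator,
    tries: int = 50,
) -> tuple[int, int] | None:
    """Internal inversion segment whose ends avoid cutting any planted tag."""
    for _ in range(tries):
        ln = int(rng.integers(region_len // 5, max(region_len // 3, region_len // 5 + 1)))
        ia = int(rng.integers(0, region_len - ln + 1))
        ib = ia + ln
        ok = all(
            e <= ia or s >= ib or (s >= ia and e <= ib) for s, e in forbidden
        )
        if ok:
            return ia, ib
    return None


def emit_hits(
    focal_regions,
    outgroup_regions,
    path: str | Path | None = None,
    min_match: int = 20,
    seed_k: int = 11,
):
    """All-vs-all surrogate hit table for the planted gene set.

    Scores come from the anchor-based surrogate scorer; planted duplicate
    pairs (mutual divergence well below the outgroup divergence) score
    above their outgroup hits by construction.
    """
    from .formats_io import write_hits
    from .gene_dup import score_all

    hits = score_all(
        focal_regions, outgroup_regions, min_match=min_match, seed_k=seed_k
    )
    if path is not None:
        write_hits(path, hits)
    return hits
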