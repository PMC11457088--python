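"""Assembly contiguity/composition statistics and annotation statistics.

Implements the classical Nx/Lx contiguity measures, GC content over
unambiguous bases, the cumulative-length curve used to visualize scaffold
size distributions, and gene/transcript counts from a GFF3 hierarchy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import median

import numpy as np

from .formats_io import GffFeature, SeqRecord


@dataclass
class AssemblyMetrics:
    total_length: int
    n_scaffolds: int
    nx: dict[int, int] = field(default_factory=dict)  # x -> scaffold length (bp)
    lx: dict[int, int] = field(default_factory=dict)  # x -> scaffold count
    gc_pct: float = 0.0


@dataclass
class AnnotationMetrics:
    n_genes: int
    n_protein_coding: int
    n_exons: int
    median_transcript_len: float
    longest_transcript_len: int


def compute_nx_lx(lengths: list[int], x: float) -> tuple[int, int]:
    """Nx/Lx of a set of scaffold lengths.

    Nx is the length of the scaffold at which the descending cumulative sum
    first reaches >= x% of the total; Lx is the number of scaffolds up to
    and including it.  Ties at the boundary length are resolved by a stable
    descending sort, matching common assembly tooling.
    """
    if not (0 < x <= 100):
        raise ValueError(f"x must be in (0, 100], got {x}")
    if not lengths:
        raise ValueError("empty length list")
    if min(lengths) < 1:
        raise ValueError("scaffold lengths must be >= 1")
    ordered = sorted(lengths, reverse=True)
    threshold = sum(ordered) * x / 100.0
    acc = 0
    for i, ln in enumerate(ordered, 1):
        acc += ln
        if acc >= threshold:
            return ln, i
    raise AssertionError("unreachable")  # pragma: no cover


def gc_percent(records: list[SeqRecord]) -> float:
    """GC content as 100*(G+C)/(A+C+G+T); ambiguity codes excluded entirely."""
    if not records:
        raise ValueError("no sequences")
    gc = at = 0
    for r in records:
        s = r.sequence
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("assembly has zero unambiguous bases")
    return 100.0 * gc / (gc + at)


def length_cdf(
    lengths: list[int], min_len: int = 1000
) -> list[tuple[int, float]]:
    """Cumulative-length curve: (scaffold rank, cumulative fraction of total).

    Scaffolds shorter than ``min_len`` are excluded; ranks follow descending
    length order and fractions are of the filtered total, ending at 1.0.
    """
    kept = sorted((ln for ln in lengths if ln >= min_len), reverse=True)
    if not kept:
        return []
    total = sum(kept)
    cum = np.cumsum(kept)
    return [(i + 1, float(c) / total) for i, c in enumerate(cum)]


def assembly_metrics(records: list[SeqRecord]) -> AssemblyMetrics:
    """Full contiguity/composition summary for one assembly."""
    lengths = [len(r) for r in records]
    m = AssemblyMetrics(
        total_length=sum(lengths),
        n_scaffolds=len(records),
        gc_pct=gc_percent(records),
    )
    for x in (50, 90):
        nx, lx = compute_nx_lx(lengths, x)
        m.nx[x], m.lx[x] = nx, lx
    return m


def annotation_stats(features: list[GffFeature]) -> AnnotationMetrics:
    """Gene/transcript statistics over a gene -> mRNA -> exon/CDS hierarchy.

    Transcript length is the genomic span of the mRNA feature (end - start
    + 1), not the summed exon length, so intron-containing transcripts
    report their full footprint.  An orphan mRNA (Parent missing from the
    gene set) warns and counts toward transcripts only.
    """
    gene_ids = {
        f.feature_id for f in features if f.ftype == "gene" and f.feature_id
    }
    n_genes = sum(1 for f in features if f.ftype == "gene")
    n_exons = sum(1 for f in features if f.ftype == "exon")

    mrna_by_id: dict[str, GffFeature] = {}
    transcript_lens: list[int] = []
    coding_genes: set[str] = set()
    for f in features:
        if f.ftype == "mRNA":
            transcript_lens.append(f.span())
            if f.feature_id:
                mrna_by_id[f.feature_id] = f
            if f.parent and f.parent not in gene_ids:
                warnings.warn(
                    f"mRNA {f.feature_id!r} has no gene parent {f.parent!r}; "
                    "counted toward transcripts only",
                    stacklevel=2,
                )
    for f in features:
        if f.ftype == "CDS" and f.parent:
            parent_mrna = mrna_by_id.get(f.parent)
            if parent_mrna is not None and parent_mrna.parent in gene_ids:
                coding_genes.add(parent_mrna.parent)

    return AnnotationMetrics(
        n_genes=n_genes,
        n_protein_coding=len(coding_genes),
        n_exons=n_exons,
        median_transcript_len=float(median(transcript_lens)) if transcript_lens else 0.0,
        longest_transcript_len=max(transcript_lens, default=0),
    )
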