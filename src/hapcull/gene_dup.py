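"""Duplicate-gene labeling against an outgroup.

A pair of focal genes is called duplicate when each member matches the
other with a higher score than it matches any gene region of a diverged
outgroup genome: a within-species match beating every between-species
match indicates a duplication postdating the species split (or an
assembly artifact — the method does not distinguish the two).

Scores come either from an external blast-tabular hit file or from an
internal anchor-based surrogate scorer (2 * matched bp; a non-blast
surrogate intended for testing, not a blast replacement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .anchor_align import AnchorParams, coverage, find_exact_matches
from .formats_io import GffFeature, SeqRecord, SimilarityHit
from .anchor_align import revcomp


@dataclass
class GeneRegion:
    """Strand-oriented genomic region of one gene feature.

    Coordinates are half-open 0-based; the sequence is reverse-complemented
    for minus-strand genes so it always reads 5'->3' on the coding strand.
    """

    gene_id: str
    seqid: str
    start: int
    end: int
    strand: str
    sequence: str


@dataclass
class DuplicatePair:
    """A focal gene pair passing the reciprocal outgroup test."""

    gene_a: str
    gene_b: str
    score_ab: float
    score_ba: float
    best_outgroup_a: float = 0.0
    best_outgroup_b: float = 0.0


@dataclass
class GeneScores:
    best_focal_subject: str | None = None
    best_focal_score: float = 0.0
    best_focal_aln_len: int = 0
    best_outgroup: float = 0.0


@dataclass
class ScoreTable:
    focal_ids: set[str]
    outgroup_ids: set[str]
    per_gene: dict[str, GeneScores] = field(default_factory=dict)
    # max bitscore per (query, subject) after collapsing multiple HSPs
    pair_scores: dict[tuple[str, str], float] = field(default_factory=dict)


def extract_gene_regions(
    assembly: list[SeqRecord], features: list[GffFeature]
) -> list[GeneRegion]:
    """One strand-oriented region per ftype=gene feature."""
    by_id = {r.id: r for r in assembly}
    regions: list[GeneRegion] = []
    for f in features:
        if f.ftype != "gene":
            continue
        gid = f.feature_id or f"{f.seqid}:{f.start}-{f.end}"
        scaffold = by_id.get(f.seqid)
        if scaffold is None:
            raise ValueError(f"gene {gid} on unknown scaffold {f.seqid!r}")
        if f.end > len(scaffold):
            raise ValueError(
                f"gene {gid} extends beyond scaffold {f.seqid} "
                f"({f.end} > {len(scaffold)})"
            )
        start, end = f.start - 1, f.end  # GFF 1-based inclusive -> half-open
        seq = scaffold.sequence[start:end]
        if f.strand == "-":
            seq = revcomp(seq)
        regions.append(
            GeneRegion(
                gene_id=gid, seqid=f.seqid, start=start, end=end,
                strand=f.strand, sequence=seq,
            )
        )
    return regions


def best_scores(
    hits: list[SimilarityHit],
    focal_ids: set[str],
    outgroup_ids: set[str],
) -> ScoreTable:
    """Aggregate hits into per-gene best focal / best outgroup scores.

    Multiple hits (HSPs) to one subject collapse to the max bitscore.
    Self-hits are excluded.  Ties for best focal subject break by greater
    aln_len, then lexicographic subject id.  A gene with no outgroup hit
    gets best_outgroup = 0.
    """
    table = ScoreTable(focal_ids=set(focal_ids), outgroup_ids=set(outgroup_ids))
    best_aln: dict[tuple[str, str], int] = {}
    for h in hits:
        if h.query_id not in focal_ids:
            raise ValueError(f"hit query {h.query_id!r} is not a focal gene")
        if h.subject_id not in focal_ids and h.subject_id not in outgroup_ids:
            raise ValueError(
                f"hit subject {h.subject_id!r} in neither focal nor outgroup set"
            )
        key = (h.query_id, h.subject_id)
        if h.bitscore > table.pair_scores.get(key, -1.0):
            table.pair_scores[key] = h.bitscore
            best_aln[key] = h.aln_len
        elif h.bitscore == table.pair_scores.get(key) and h.aln_len > best_aln.get(key, -1):
            best_aln[key] = h.aln_len

    for gid in sorted(focal_ids):
        gs = GeneScores()
        for (q, s), score in table.pair_scores.items():
            if q != gid or s == gid:
                continue
            if s in table.outgroup_ids:
                gs.best_outgroup = max(gs.best_outgroup, score)
                continue
            aln = best_aln[(q, s)]
            better = (
                gs.best_focal_subject is None
                or score > gs.best_focal_score
                or (
                    score == gs.best_focal_score
                    and (
                        aln > gs.best_focal_aln_len
                        or (aln == gs.best_focal_aln_len and s < gs.best_focal_subject)
                    )
                )
            )
            if better:
                gs.best_focal_subject = s
                gs.best_focal_score = score
                gs.best_focal_aln_len = aln
        table.per_gene[gid] = gs
    return table


def classify_duplicates(
    table: ScoreTable, require_reciprocal: bool = True
) -> list[DuplicatePair]:
    """Assign duplicate status to focal gene pairs.

    Default (reciprocal-best) reading: (A, B) is a pair iff A's best focal
    subject is B, B's best focal subject is A, and each direction's score
    strictly exceeds that gene's best outgroup score — so each gene appears
    in at most one pair.  With require_reciprocal=False the weaker reading
    is used: any mutual pair of hits both strictly above the respective
    outgroup bests qualifies (a gene may then join several pairs).
    """
    pairs: list[DuplicatePair] = []
    seen: set[tuple[str, str]] = set()
    if require_reciprocal:
        for gid, gs in table.per_gene.items():
            b = gs.best_focal_subject
            if b is None:
                continue
            other = table.per_gene.get(b)
            if other is None or other.best_focal_subject != gid:
                continue
            if not (
                gs.best_focal_score > gs.best_outgroup
                and other.best_focal_score > other.best_outgroup
            ):
                continue
            a, bb = sorted((gid, b))
            if (a, bb) in seen:
                continue
            seen.add((a, bb))
            pairs.append(
                DuplicatePair(
                    gene_a=a, gene_b=bb,
                    score_ab=table.pair_scores[(a, bb)],
                    score_ba=table.pair_scores[(bb, a)],
                    best_outgroup_a=table.per_gene[a].best_outgroup,
                    best_outgroup_b=table.per_gene[bb].best_outgroup,
                )
            )
    else:
        for (q, s), score_ab in table.pair_scores.items():
            if s in table.outgroup_ids or q == s:
                continue
            score_ba = table.pair_scores.get((s, q))
            if score_ba is None:
                continue
            a, b = sorted((q, s))
            if (a, b) in seen:
                continue
            out_a = table.per_gene[a].best_outgroup
            out_b = table.per_gene[b].best_outgroup
            if table.pair_scores[(a, b)] > out_a and table.pair_scores[(b, a)] > out_b:
                seen.add((a, b))
                pairs.append(
                    DuplicatePair(
                        gene_a=a, gene_b=b,
                        score_ab=table.pair_scores[(a, b)],
                        score_ba=table.pair_scores[(b, a)],
                        best_outgroup_a=out_a, best_outgroup_b=out_b,
                    )
                )
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def duplicate_fraction(pairs: list[DuplicatePair], n_focal_genes: int) -> float:
    """Fraction of focal genes in a duplicate pair: 2*|pairs| / |genes|."""
    return 2 * len(pairs) / n_focal_genes if n_focal_genes else 0.0


def surrogate_score(
    query: GeneRegion,
    subject: GeneRegion,
    min_match: int = 20,
    seed_k: int = 11,
) -> SimilarityHit | None:
    """Anchor-based similarity surrogate: 2 bits per exactly matched bp.

    Matched bp is the union of maximal exact matches (>= min_match, both
    strands) projected onto the query.  Returns None when no anchors are
    found; intended for testing without an external similarity search.
    """
    params = AnchorParams(min_match=min_match, seed_k=seed_k, max_gap=0)
    blocks = find_exact_matches(
        SeqRecord(subject.gene_id, subject.sequence),
        SeqRecord(query.gene_id, query.sequence),
        params,
    )
    if not blocks:
        return None
    cov = coverage(query.gene_id, len(query.sequence), blocks, side="qry")
    return SimilarityHit(
        query_id=query.gene_id,
        subject_id=subject.gene_id,
        identity=100.0 * cov.fraction,
        aln_len=cov.covered_bp,
        bitscore=2.0 * cov.covered_bp,
        evalue=0.0,
    )


def score_all(
    focal_regions: list[GeneRegion],
    outgroup_regions: list[GeneRegion],
    min_match: int = 20,
    seed_k: int = 11,
) -> list[SimilarityHit]:
    """All-vs-all surrogate hits: every focal gene against focal + outgroup."""
    subjects = focal_regions + outgroup_regions
    hits: list[SimilarityHit] = []
    for q in focal_regions:
        for s in subjects:
            if s.gene_id == q.gene_id:
                continue
            hit = surrogate_score(q, s, min_match=min_match, seed_k=seed_k)
            if hit is not None:
                hits.append(hit)
    return hits
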