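"""Duplicate-scaffold detection and removal.

Residual heterozygosity in an inbred line can make an assembler emit both
haplotypes of a region as separate scaffolds; the redundant copy shows up
as a scaffold whose benchmark genes are all Duplicated and which aligns
nearly end-to-end to the scaffold carrying the alternate copies.  This
module profiles benchmark-gene duplication per scaffold, selects candidate
scaffolds, verifies full duplication by merged alignment coverage against
the partner scaffolds, and splits the assembly and annotation.

Removal is all-or-nothing per scaffold; scaffolds are never trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .anchor_align import AnchorParams, align_pair, coverage
from .formats_io import (
    AlignmentBlock,
    BuscoRecord,
    GffFeature,
    SeqRecord,
)


# Anchor defaults for candidate-vs-partner alignment.  Haplotypes of an
# inbred line diverge by ~1%, so maximal exact runs average ~100 bp: the
# match floor must sit well below that and the chain gap well above it.
DEDUP_ANCHOR_PARAMS = AnchorParams(min_match=100, max_gap=10_000, seed_k=21)


@dataclass
class ScaffoldDupProfile:
    """Per-scaffold benchmark-gene duplication tally."""

    seqid: str
    seq_len: int
    n_busco: int = 0
    n_dup: int = 0
    partners: set[str] = field(default_factory=set)
    n_complete: int = 0

    @property
    def pct_dup(self) -> float:
        return 100.0 * self.n_dup / self.n_busco if self.n_busco else 0.0


@dataclass
class DedupDecision:
    seqid: str
    status: str  # remove | keep | candidate_unresolved
    coverage_fraction: float = 0.0
    partner_used: str = ""
    reason: str = ""


def profile_scaffolds(
    buscos: list[BuscoRecord],
    assembly: list[SeqRecord],
    denominator: str = "all",
) -> list[ScaffoldDupProfile]:
    """Tally benchmark-gene content and duplication per scaffold.

    One profile per assembly scaffold, including scaffolds with no
    benchmark placements.  Partners of a scaffold are the scaffolds
    carrying the alternate copies of its Duplicated benchmark genes.
    Output sorted by pct_dup descending, ties by seq_len ascending.

    denominator="all" counts Fragmented placements toward n_busco;
    "complete" restricts the denominator to Complete + Duplicated.
    """
    by_id = {r.id: r for r in assembly}
    profiles = {
        r.id: ScaffoldDupProfile(seqid=r.id, seq_len=len(r)) for r in assembly
    }
    placements_by_busco: dict[str, list[str]] = {}
    for b in buscos:
        if b.status == "Missing":
            continue
        if b.seqid not in by_id:
            raise ValueError(
                f"benchmark gene {b.busco_id} placed on unknown scaffold {b.seqid!r}"
            )
        p = profiles[b.seqid]
        if b.status == "Fragmented" and denominator == "complete":
            continue
        p.n_busco += 1
        if b.status == "Duplicated":
            p.n_dup += 1
            placements_by_busco.setdefault(b.busco_id, []).append(b.seqid)
        elif b.status == "Complete":
            p.n_complete += 1
    for seqids in placements_by_busco.values():
        for sid in seqids:
            profiles[sid].partners.update(s for s in seqids if s != sid)
    return sorted(
        profiles.values(), key=lambda p: (-p.pct_dup, p.seq_len, p.seqid)
    )


def select_candidates(
    profiles: list[ScaffoldDupProfile],
) -> list[ScaffoldDupProfile]:
    """Scaffolds with at least one Duplicated benchmark gene, order preserved."""
    return [p for p in profiles if p.n_dup >= 1]


def decide(
    candidate: ScaffoldDupProfile,
    blocks: list[AlignmentBlock],
    threshold: float = 0.95,
    is_keeper: bool = False,
) -> DedupDecision:
    """Coverage verdict for one candidate scaffold.

    All partner blocks are pooled (candidate on the qry side); the
    candidate is removed iff its merged coverage reaches the threshold and
    it is not the designated keeper of its partner pair.  partner_used
    records the partner contributing the most covered bp.
    """
    for b in blocks:
        if b.qry_id != candidate.seqid:
            raise ValueError(
                f"block qry {b.qry_id!r} is not candidate {candidate.seqid!r}"
            )
        if b.ref_id not in candidate.partners:
            raise ValueError(
                f"block ref {b.ref_id!r} is not a partner of {candidate.seqid!r}"
            )
    if not blocks:
        return DedupDecision(
            seqid=candidate.seqid, status="candidate_unresolved",
            reason="no partner alignments available",
        )
    cov = coverage(candidate.seqid, candidate.seq_len, blocks, side="qry")
    per_partner: dict[str, int] = {}
    for ref_id in {b.ref_id for b in blocks}:
        sub = [b for b in blocks if b.ref_id == ref_id]
        per_partner[ref_id] = coverage(
            candidate.seqid, candidate.seq_len, sub, side="qry"
        ).covered_bp
    best_partner = max(sorted(per_partner), key=lambda k: per_partner[k])
    if cov.fraction >= threshold and not is_keeper:
        return DedupDecision(
            seqid=candidate.seqid, status="remove",
            coverage_fraction=cov.fraction, partner_used=best_partner,
            reason=f"coverage {cov.fraction:.3f} >= {threshold}",
        )
    if cov.fraction >= threshold and is_keeper:
        return DedupDecision(
            seqid=candidate.seqid, status="keep",
            coverage_fraction=cov.fraction, partner_used=best_partner,
            reason="designated keeper of mutually covered pair",
        )
    return DedupDecision(
        seqid=candidate.seqid, status="keep",
        coverage_fraction=cov.fraction, partner_used=best_partner,
        reason=f"coverage {cov.fraction:.3f} < {threshold}",
    )


def _keeper_rank(p: ScaffoldDupProfile) -> tuple:
    # longer scaffold wins; ties by more single-copy buscos, then lexicographic id
    return (-p.seq_len, -p.n_complete, p.seqid)


def run_dedup(
    assembly: list[SeqRecord],
    buscos: list[BuscoRecord],
    threshold: float = 0.95,
    params: AnchorParams | None = None,
    external_blocks: list[AlignmentBlock] | None = None,
    denominator: str = "all",
) -> tuple[list[ScaffoldDupProfile], list[DedupDecision]]:
    """Full dedup pass: profile, select, align candidates to partners, decide.

    Alignments come either from the internal anchor aligner or from an
    external block table; the two sources are never mixed.  Within a pair
    of mutually covered scaffolds the keeper (longer; ties by more
    single-copy benchmark genes, then id) is retained, so both members of
    a partner pair can never be removed.
    """
    params = params or DEDUP_ANCHOR_PARAMS
    by_id = {r.id: r for r in assembly}
    profiles = profile_scaffolds(buscos, assembly, denominator=denominator)
    prof_by_id = {p.seqid: p for p in profiles}
    candidates = select_candidates(profiles)

    cand_blocks: dict[str, list[AlignmentBlock]] = {}
    for cand in candidates:
        if external_blocks is not None:
            blocks = [
                b for b in external_blocks
                if b.qry_id == cand.seqid and b.ref_id in cand.partners
            ]
        else:
            blocks = []
            for partner in sorted(cand.partners):
                blocks.extend(
                    align_pair(by_id[partner], by_id[cand.seqid], params)
                )
        cand_blocks[cand.seqid] = blocks

    # provisional coverage, then keeper designation within mutually covered pairs
    frac: dict[str, float] = {}
    for cand in candidates:
        blocks = cand_blocks[cand.seqid]
        frac[cand.seqid] = (
            coverage(cand.seqid, cand.seq_len, blocks, side="qry").fraction
            if blocks
            else 0.0
        )
    keepers: set[str] = set()
    for cand in candidates:
        if frac[cand.seqid] < threshold:
            continue
        for partner in cand.partners:
            if partner in frac and frac[partner] >= threshold:
                pair = sorted(
                    [prof_by_id[cand.seqid], prof_by_id[partner]],
                    key=_keeper_rank,
                )
                keepers.add(pair[0].seqid)

    decisions = [
        decide(
            cand, cand_blocks[cand.seqid], threshold,
            is_keeper=cand.seqid in keepers,
        )
        for cand in candidates
    ]
    decided = {d.seqid for d in decisions}
    decisions.extend(
        DedupDecision(seqid=p.seqid, status="keep", reason="no duplicated benchmark genes")
        for p in profiles
        if p.seqid not in decided
    )
    return profiles, decisions


def split_assembly(
    assembly: list[SeqRecord],
    features: list[GffFeature],
    decisions: list[DedupDecision],
) -> tuple[list[SeqRecord], list[GffFeature], list[SeqRecord], list[GffFeature]]:
    """Partition assembly and annotation into kept and removed sets by seqid."""
    status_by_id = {d.seqid: d.status for d in decisions}
    removed_ids = {s for s, st in status_by_id.items() if st == "remove"}
    known = {r.id for r in assembly}
    for f in features:
        if f.seqid not in known:
            raise ValueError(
                f"feature {f.feature_id or f.ftype} on scaffold {f.seqid!r} "
                "absent from the assembly"
            )
    kept_fa = [r for r in assembly if r.id not in removed_ids]
    removed_fa = [r for r in assembly if r.id in removed_ids]
    kept_gff = [f for f in features if f.seqid not in removed_ids]
    removed_gff = [f for f in features if f.seqid in removed_ids]
    return kept_fa, kept_gff, removed_fa, removed_gff
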