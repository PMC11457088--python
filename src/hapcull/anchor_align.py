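"""Minimal nucmer-like anchor aligner.

Finds maximal exact matches above a length floor on both strands by k-mer
seeding with bidirectional extension, chains collinear matches across small
gaps, and computes merged coverage of a scaffold by alignment blocks.  It
serves as the internal stand-in when no external PAF/show-coords table is
supplied; its output is validated against a brute-force maximal-common-
substring oracle in the test suite.

The matcher reports all maximal matches (maxmatch-like), not only matches
unique in either sequence.  N never matches anything, including N: seeds
containing N are skipped and extension stops at N on either sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats_io import AlignmentBlock, SeqRecord

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class AnchorParams:
    """Anchor-matching parameters.

    min_match: exact-match length floor in bp (>= 20); 500 suits closely
    related genomes, 1000 more diverged comparisons.  max_gap: largest
    ref/qry gap bridged when chaining collinear matches.  seed_k: k-mer
    size used to seed match detection (must not exceed min_match).
    """

    min_match: int = 500
    max_gap: int = 5000
    seed_k: int = 21

    def __post_init__(self) -> None:
        if self.min_match < 20:
            raise ValueError(f"min_match must be >= 20, got {self.min_match}")
        if self.min_match < self.seed_k:
            raise ValueError(
                f"min_match ({self.min_match}) < seed_k ({self.seed_k})"
            )


@dataclass
class CoverageResult:
    """Merged-coverage verdict on one scaffold side of a block set."""

    seqid: str
    covered_bp: int
    seq_len: int
    fraction: float
    blocks: list[tuple[int, int]] = field(default_factory=list)  # disjoint, sorted


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _matches_one_strand(
    ref: str, qry: str, k: int, min_match: int
) -> list[tuple[int, int, int]]:
    """Maximal exact matches >= min_match as (ref_start, qry_start, length).

    Seeds sharing a diagonal co-extend to the same maximal run; a per-
    diagonal high-water mark of the furthest extended qry position makes
    each run extended exactly once.
    """
    index = _kmer_index(ref, k)
    out: list[tuple[int, int, int]] = []
    covered: dict[int, int] = {}  # diagonal -> qry_end already extended
    n_q = len(qry)
    for qpos in range(n_q - k + 1):
        kmer = qry[qpos:qpos + k]
        if "N" in kmer:
            continue
        for rpos in index.get(kmer, ()):  # noqa: B020
            diag = rpos - qpos
            if covered.get(diag, -1) >= qpos + k:
                continue  # inside a run already extended on this diagonal
            # extend left
            i, j = rpos - 1, qpos - 1
            while i >= 0 and j >= 0 and ref[i] == qry[j] and ref[i] != "N":
                i -= 1
                j -= 1
            rs, qs = i + 1, j + 1
            # extend right
            i, j = rpos + k, qpos + k
            n_r = len(ref)
            while i < n_r and j < n_q and ref[i] == qry[j] and ref[i] != "N":
                i += 1
                j += 1
            covered[diag] = j
            length = j - qs
            if length >= min_match:
                out.append((rs, qs, length))
    return out


def find_exact_matches(
    ref: SeqRecord, qry: SeqRecord, params: AnchorParams
) -> list[AlignmentBlock]:
    """All maximal exact matches >= params.min_match, both strands.

    Antisense matches are found against the reverse complement of qry and
    reported with coordinates mapped back to qry's forward strand.
    """
    blocks: list[AlignmentBlock] = []
    for rs, qs, length in _matches_one_strand(
        ref.sequence, qry.sequence, params.seed_k, params.min_match
    ):
        blocks.append(
            AlignmentBlock(
                ref_id=ref.id, qry_id=qry.id,
                ref_start=rs, ref_end=rs + length,
                qry_start=qs, qry_end=qs + length,
                strand="sense", match_len=length, identity=1.0,
            )
        )
    qrc = revcomp(qry.sequence)
    n_q = len(qrc)
    for rs, qs, length in _matches_one_strand(
        ref.sequence, qrc, params.seed_k, params.min_match
    ):
        blocks.append(
            AlignmentBlock(
                ref_id=ref.id, qry_id=qry.id,
                ref_start=rs, ref_end=rs + length,
                qry_start=n_q - (qs + length), qry_end=n_q - qs,
                strand="antisense", match_len=length, identity=1.0,
            )
        )
    blocks.sort(key=lambda b: (b.strand, b.ref_start, b.qry_start))
    return blocks


def _chainable(cur: AlignmentBlock, nxt: AlignmentBlock, max_gap: int) -> bool:
    if nxt.ref_start - cur.ref_end > max_gap:
        return False
    if cur.strand == "sense":
        # both coordinates increasing along the chain
        return (
            nxt.qry_start >= cur.qry_start
            and nxt.qry_start - cur.qry_end <= max_gap
        )
    # antisense: ref increasing while forward-strand qry decreases
    return (
        nxt.qry_end <= cur.qry_end
        and cur.qry_start - nxt.qry_end <= max_gap
    )


def chain_blocks(
    blocks: list[AlignmentBlock], params: AnchorParams
) -> list[AlignmentBlock]:
    """Merge collinear same-strand blocks separated by gaps <= max_gap.

    The merged block spans the union of its members on both sides; its
    identity is matched bp over the ref span (a chain bridging gaps dilutes
    identity accordingly).  Sense and antisense blocks never merge.
    """
    if not blocks:
        return []
    pairs = {(b.ref_id, b.qry_id) for b in blocks}
    if len(pairs) > 1:
        raise ValueError(f"blocks span multiple (ref, qry) pairs: {sorted(pairs)}")
    out: list[AlignmentBlock] = []
    for strand in ("sense", "antisense"):
        group = sorted(
            (b for b in blocks if b.strand == strand),
            key=lambda b: (b.ref_start, b.qry_start),
        )
        if not group:
            continue
        chain = [group[0]]
        for b in group[1:]:
            if _chainable(chain[-1], b, params.max_gap):
                chain.append(b)
            else:
                out.append(_merge_chain(chain))
                chain = [b]
        out.append(_merge_chain(chain))
    out.sort(key=lambda b: (b.strand, b.ref_start, b.qry_start))
    return out


def _merge_chain(chain: list[AlignmentBlock]) -> AlignmentBlock:
    if len(chain) == 1:
        return chain[0]
    ref_start = min(b.ref_start for b in chain)
    ref_end = max(b.ref_end for b in chain)
    qry_start = min(b.qry_start for b in chain)
    qry_end = max(b.qry_end for b in chain)
    span = max(ref_end - ref_start, qry_end - qry_start)
    matched = min(sum(b.match_len for b in chain), span)
    return AlignmentBlock(
        ref_id=chain[0].ref_id, qry_id=chain[0].qry_id,
        ref_start=ref_start, ref_end=ref_end,
        qry_start=qry_start, qry_end=qry_end,
        strand=chain[0].strand, match_len=matched,
        identity=matched / span if span else 0.0,
    )


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    if not intervals:
        return []
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def coverage(
    seqid: str,
    seq_len: int,
    blocks: list[AlignmentBlock],
    side: str = "qry",
) -> CoverageResult:
    """Merged coverage of one scaffold by the given side of the blocks."""
    if side not in ("ref", "qry"):
        raise ValueError(f"side must be 'ref' or 'qry', got {side!r}")
    intervals: list[tuple[int, int]] = []
    for b in blocks:
        bid = b.ref_id if side == "ref" else b.qry_id
        if bid != seqid:
            raise ValueError(f"block {side} id {bid!r} does not match {seqid!r}")
        s, e = (b.ref_start, b.ref_end) if side == "ref" else (b.qry_start, b.qry_end)
        if e > seq_len:
            raise ValueError(f"block end {e} exceeds {seqid} length {seq_len}")
        intervals.append((s, e))
    merged = merge_intervals(intervals)
    covered = sum(e - s for s, e in merged)
    return CoverageResult(
        seqid=seqid, covered_bp=covered, seq_len=seq_len,
        fraction=covered / seq_len if seq_len else 0.0, blocks=merged,
    )


def align_pair(
    ref: SeqRecord, qry: SeqRecord, params: AnchorParams | None = None
) -> list[AlignmentBlock]:
    """Anchor-match then chain one (ref, qry) scaffold pair."""
    params = params or AnchorParams()
    return chain_blocks(find_exact_matches(ref, qry, params), params)
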