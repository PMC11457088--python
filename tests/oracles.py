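"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle deliberately avoids the implementation path it checks:
maximal common substrings come from a quadratic diagonal-run scan over the
full match matrix, duplicate-pair classification from explicit all-pairs
enumeration, and repeat accounting from a per-base bitmap.
"""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _diagonal_runs(ref: str, qry: str, min_match: int):
    """(ref_start, qry_start, length) of every maximal run per diagonal."""
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    q = np.frombuffer(qry.encode(), dtype=np.uint8)
    n_char = ord("N")
    match = (r[:, None] == q[None, :]) & (r[:, None] != n_char) & (q[None, :] != n_char)
    out = []
    for k in range(-(len(r) - 1), len(q)):
        diag = np.diagonal(match, offset=k)
        padded = np.concatenate(([False], diag, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_match:
                i0 = s + (0 if k >= 0 else -k)
                j0 = s + (k if k >= 0 else 0)
                out.append((int(i0), int(j0), int(e - s)))
    return out


def maximal_common_substrings(ref: str, qry: str, min_match: int):
    """All maximal exact matches >= min_match, both strands.

    Returns a set of (ref_start, qry_start_forward, length, strand) with
    antisense coordinates mapped back to qry's forward strand.
    """
    result = {
        (rs, qs, ln, "sense") for rs, qs, ln in _diagonal_runs(ref, qry, min_match)
    }
    qrc = _revcomp(qry)
    n_q = len(qry)
    for rs, qs, ln in _diagonal_runs(ref, qrc, min_match):
        result.add((rs, n_q - (qs + ln), ln, "antisense"))
    return result


def duplicate_pairs_bruteforce(pair_scores, aln_lens, focal_ids, outgroup_ids):
    """All-pairs enumeration of the reciprocal-best above-outgroup test.

    pair_scores: {(query, subject): bitscore} already collapsed to the max
    per subject; aln_lens: {(query, subject): aln_len} for tie-breaking.
    """
    def best_focal(g):
        cands = [
            (s, sc) for (q, s), sc in pair_scores.items()
            if q == g and s != g and s in focal_ids
        ]
        if not cands:
            return None, 0.0
        # max score; ties by greater aln_len, then lexicographically smaller id
        cands.sort(key=lambda t: (-t[1], -aln_lens.get((g, t[0]), 0), t[0]))
        return cands[0]

    def best_outgroup(g):
        scores = [
            sc for (q, s), sc in pair_scores.items()
            if q == g and s in outgroup_ids
        ]
        return max(scores, default=0.0)

    pairs = set()
    for a in focal_ids:
        for b in focal_ids:
            if a >= b:
                continue
            ba, sa = best_focal(a)
            bb, sb = best_focal(b)
            if ba != b or bb != a:
                continue
            if sa > best_outgroup(a) and sb > best_outgroup(b):
                pairs.add((a, b))
    return pairs


def repeat_bitmap(annotations, genome_len_by_scaffold, classes):
    """Per-base bitmap accounting: returns {class|Multiclass|Total: bp}."""
    idx = {c: i for i, c in enumerate(classes)}
    masked = {}
    for sid, length in genome_len_by_scaffold.items():
        cover = np.zeros((len(classes), length), dtype=bool)
        for a in annotations:
            if a.seqid == sid:
                cover[idx[a.rclass], a.start:a.end] = True
        n_classes = cover.sum(axis=0)
        for c, i in idx.items():
            single = cover[i] & (n_classes == 1)
            masked[c] = masked.get(c, 0) + int(single.sum())
        masked["Multiclass"] = masked.get("Multiclass", 0) + int((n_classes >= 2).sum())
        masked["Total"] = masked.get("Total", 0) + int((n_classes >= 1).sum())
    return {k: v for k, v in masked.items() if v}
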