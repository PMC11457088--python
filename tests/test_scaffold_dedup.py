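"""Duplicate-scaffold profiling, decisions and assembly splitting."""

import pytest

from hapcull.formats_io import AlignmentBlock, BuscoRecord, GffFeature, SeqRecord
from hapcull.scaffold_dedup import (
    ScaffoldDupProfile,
    decide,
    profile_scaffolds,
    run_dedup,
    select_candidates,
    split_assembly,
)


def _busco(bid, status, seqid, start=1, end=100):
    return BuscoRecord(bid, status, seqid, start, end, "+", 100.0, end - start + 1)


def _asm(*ids_lens):
    return [SeqRecord(i, "A" * n) for i, n in ids_lens]


def test_profile_hand_tally_with_partners():
    assembly = _asm(("s1", 1000), ("s2", 500))
    buscos = [
        _busco("b1", "Complete", "s1"),
        _busco("b2", "Duplicated", "s1"),
        _busco("b2", "Duplicated", "s2"),
        _busco("b3", "Fragmented", "s2"),
    ]
    profiles = {p.seqid: p for p in profile_scaffolds(buscos, assembly)}
    assert profiles["s1"].pct_dup == 50.0 and profiles["s1"].partners == {"s2"}
    # Fragmented counts toward the denominator by default
    assert profiles["s2"].n_busco == 2 and profiles["s2"].pct_dup == 50.0
    assert profiles["s2"].partners == {"s1"}


def test_profile_denominator_modes_and_zero_busco():
    assembly = _asm(("s1", 1000), ("s2", 500))
    buscos = [
        _busco("b1", "Duplicated", "s1"),
        _busco("b1", "Duplicated", "s2"),
        _busco("b2", "Fragmented", "s1"),
    ]
    default = {p.seqid: p for p in profile_scaffolds(buscos, assembly)}
    assert default["s1"].n_busco == 2 and default["s1"].pct_dup == 50.0
    strict = {
        p.seqid: p
        for p in profile_scaffolds(buscos, assembly, denominator="complete")
    }
    assert strict["s1"].n_busco == 1 and strict["s1"].pct_dup == 100.0
    empty = profile_scaffolds([], _asm(("lonely", 10)))
    assert empty[0].n_busco == 0 and empty[0].pct_dup == 0.0


def test_profile_sorted_by_pct_dup_then_length():
    assembly = _asm(("big", 1000), ("small", 100), ("none", 50))
    buscos = [
        _busco("b1", "Duplicated", "big"), _busco("b1", "Duplicated", "small"),
        _busco("b2", "Complete", "big"),
    ]
    order = [p.seqid for p in profile_scaffolds(buscos, assembly)]
    assert order == ["small", "big", "none"]  # 100% before 50%, zero last


def test_profile_unknown_scaffold_errors():
    with pytest.raises(ValueError, match="ghost"):
        profile_scaffolds([_busco("b1", "Complete", "ghost")], _asm(("s1", 10)))


def test_select_candidates_requires_duplicated():
    profiles = [
        ScaffoldDupProfile("a", 10, n_busco=2, n_dup=0),
        ScaffoldDupProfile("b", 10, n_busco=2, n_dup=1),
        ScaffoldDupProfile("c", 10, n_busco=3, n_dup=3),
    ]
    assert [p.seqid for p in select_candidates(profiles)] == ["b", "c"]
    assert select_candidates([]) == []


def _cand(seqid="cand", seq_len=100, partners=("p1",)):
    return ScaffoldDupProfile(seqid, seq_len, n_busco=1, n_dup=1,
                              partners=set(partners))


def _pblock(qs, qe, ref="p1"):
    return AlignmentBlock(ref, "cand", qs, qe, qs, qe, "sense", qe - qs)


def test_decide_full_coverage_removes():
    d = decide(_cand(), [_pblock(0, 60), _pblock(40, 100)])
    assert d.status == "remove" and d.coverage_fraction == 1.0
    assert d.partner_used == "p1"


def test_decide_partial_coverage_keeps_with_reason():
    d = decide(_cand(), [_pblock(0, 40)])
    assert d.status == "keep"
    assert d.coverage_fraction == pytest.approx(0.40)
    assert "0.400" in d.reason


def test_decide_no_blocks_unresolved_and_keeper_kept():
    assert decide(_cand(), []).status == "candidate_unresolved"
    d = decide(_cand(), [_pblock(0, 100)], is_keeper=True)
    assert d.status == "keep" and "keeper" in d.reason


def test_decide_non_partner_block_errors():
    with pytest.raises(ValueError, match="not a partner"):
        decide(_cand(partners=("p1",)), [_pblock(0, 50, ref="intruder")])


def test_split_assembly_partition_and_conservation():
    assembly = _asm(("s1", 100), ("s2", 50), ("s3", 70))
    feats = [
        GffFeature(s, "t", "gene", 1, 10, "+", {"ID": f"g_{s}"})
        for s in ("s1", "s2", "s3")
    ]
    from hapcull.scaffold_dedup import DedupDecision

    decisions = [
        DedupDecision("s1", "keep"), DedupDecision("s2", "remove", 1.0, "s1"),
        DedupDecision("s3", "keep"),
    ]
    kf, kg, rf, rg = split_assembly(assembly, feats, decisions)
    assert {r.id for r in kf} == {"s1", "s3"} and {r.id for r in rf} == {"s2"}
    assert len(kf) + len(rf) == len(assembly)
    assert len(kg) + len(rg) == len(feats)
    assert sum(len(r) for r in kf) + sum(len(r) for r in rf) == 220
    # empty removal set: kept identical to input
    kf2, kg2, rf2, _ = split_assembly(
        assembly, feats, [DedupDecision(s, "keep") for s in ("s1", "s2", "s3")]
    )
    assert [r.id for r in kf2] == [r.id for r in assembly] and not rf2


def test_split_assembly_orphan_feature_errors():
    with pytest.raises(ValueError, match="ghost"):
        split_assembly(
            _asm(("s1", 10)),
            [GffFeature("ghost", "t", "gene", 1, 5, "+", {"ID": "g"})],
            [],
        )


def test_run_dedup_recovers_planted_truth(default_sim):
    sim = default_sim
    profiles, decisions = run_dedup(sim.assembly, sim.busco_table)
    removed = {d.seqid for d in decisions if d.status == "remove"}
    assert removed == set(sim.truth.haplotig_ids)
    # never both members of a partner pair
    prof = {p.seqid: p for p in profiles}
    for sid in removed:
        assert not (prof[sid].partners & removed & {p for p in prof[sid].partners})


def test_reprofiling_kept_assembly_has_zero_duplicated(default_sim):
    sim = default_sim
    _, decisions = run_dedup(sim.assembly, sim.busco_table)
    kf, _, _, _ = split_assembly(sim.assembly, sim.annotation, decisions)
    kept_ids = {r.id for r in kf}
    kept_buscos = [b for b in sim.busco_table if b.seqid in kept_ids]
    # a benchmark gene still duplicated must appear on >= 2 kept scaffolds
    from collections import Counter

    counts = Counter(b.busco_id for b in kept_buscos if b.status == "Duplicated")
    assert sum(1 for c in counts.values() if c >= 2) == 0


def test_never_removes_both_members_of_identical_pair():
    """Two identical scaffolds covering each other: exactly one survives."""
    import numpy as np

    from hapcull.synthetic_data import random_seq

    seq = random_seq(np.random.default_rng(5), 5000)
    assembly = [SeqRecord("twin_a", seq), SeqRecord("twin_b", seq)]
    buscos = [
        _busco("b1", "Duplicated", "twin_a", 100, 1100),
        _busco("b1", "Duplicated", "twin_b", 100, 1100),
    ]
    from hapcull.anchor_align import AnchorParams

    _, decisions = run_dedup(
        assembly, buscos, params=AnchorParams(min_match=100)
    )
    statuses = {d.seqid: d.status for d in decisions}
    assert sorted(statuses.values()) == ["keep", "remove"]
    # keeper rule: ties on length fall back to id, so twin_a survives
    assert statuses["twin_a"] == "keep"
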