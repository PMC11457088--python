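"""Gene-region extraction, score aggregation and duplicate-pair classification."""

import numpy as np
import pytest

from oracles import duplicate_pairs_bruteforce

from hapcull.formats_io import GffFeature, SeqRecord, SimilarityHit
from hapcull.gene_dup import (
    best_scores,
    classify_duplicates,
    duplicate_fraction,
    extract_gene_regions,
    score_all,
    surrogate_score,
)


def _gene(seqid, start, end, strand, gid):
    return GffFeature(seqid, "t", "gene", start, end, strand, {"ID": gid})


def test_extract_plus_strand_region():
    asm = [SeqRecord("s1", "ACGTTT")]
    (r,) = extract_gene_regions(asm, [_gene("s1", 1, 4, "+", "g1")])
    assert r.sequence == "ACGT" and (r.start, r.end) == (0, 4)


def test_extract_minus_strand_reverse_complements():
    asm = [SeqRecord("s1", "ACGTTT")]
    # span 2..5 is "CGTT"; minus strand reads its reverse complement
    (r,) = extract_gene_regions(asm, [_gene("s1", 2, 5, "-", "g1")])
    assert r.sequence == "AACG"
    assert len(r.sequence) == r.end - r.start


def test_extract_skips_non_gene_and_errors_beyond_end():
    asm = [SeqRecord("s1", "ACGT")]
    feats = [GffFeature("s1", "t", "exon", 1, 2, "+", {"ID": "e"})]
    assert extract_gene_regions(asm, feats) == []
    with pytest.raises(ValueError, match="toolong"):
        extract_gene_regions(asm, [_gene("s1", 1, 10, "+", "toolong")])


def _hit(q, s, score, aln=100):
    return SimilarityHit(q, s, 95.0, aln, score)


def test_best_scores_collapses_hsps_and_splits_outgroup():
    hits = [
        _hit("A", "B", 500), _hit("A", "B", 450),  # second HSP collapses
        _hit("A", "X", 300),
    ]
    table = best_scores(hits, {"A", "B"}, {"X"})
    gs = table.per_gene["A"]
    assert (gs.best_focal_subject, gs.best_focal_score) == ("B", 500.0)
    assert gs.best_outgroup == 300.0
    assert table.pair_scores[("A", "B")] == 500.0


def test_best_scores_self_hit_excluded_and_no_outgroup_zero():
    table = best_scores([_hit("A", "A", 999)], {"A"}, set())
    gs = table.per_gene["A"]
    assert gs.best_focal_subject is None and gs.best_outgroup == 0.0


def test_best_scores_unknown_subject_errors():
    with pytest.raises(ValueError, match="neither"):
        best_scores([_hit("A", "mystery", 10)], {"A"}, {"X"})


def test_classify_reciprocal_pair():
    hits = [
        _hit("A", "B", 500), _hit("B", "A", 480),
        _hit("A", "X", 300), _hit("B", "X", 200),
    ]
    table = best_scores(hits, {"A", "B"}, {"X"})
    (p,) = classify_duplicates(table)
    assert (p.gene_a, p.gene_b) == ("A", "B")
    assert (p.score_ab, p.score_ba) == (500.0, 480.0)
    assert (p.best_outgroup_a, p.best_outgroup_b) == (300.0, 200.0)


def test_classify_outgroup_wins_no_pair():
    hits = [_hit("C", "D", 100), _hit("D", "C", 100), _hit("C", "X", 400)]
    table = best_scores(hits, {"C", "D"}, {"X"})
    assert classify_duplicates(table) == []


def test_classify_reciprocity_failure_no_pair():
    hits = [
        _hit("A", "B", 500), _hit("B", "C", 600), _hit("B", "A", 400),
        _hit("C", "B", 550),
    ]
    table = best_scores(hits, {"A", "B", "C"}, set())
    pairs = classify_duplicates(table)
    assert ("A", "B") not in {(p.gene_a, p.gene_b) for p in pairs}


def test_equality_with_outgroup_never_pairs():
    hits = [
        _hit("A", "B", 500), _hit("B", "A", 500),
        _hit("A", "X", 500),  # tie against outgroup fails strict inequality
    ]
    table = best_scores(hits, {"A", "B"}, {"X"})
    assert classify_duplicates(table) == []


def test_relaxed_mode_pairs_mutual_above_outgroup():
    # B's best focal subject is C, so reciprocal-best rejects (A,B);
    # the relaxed reading accepts it because both directions beat the outgroup
    hits = [
        _hit("A", "B", 500), _hit("B", "A", 400), _hit("B", "C", 600),
        _hit("C", "B", 100), _hit("A", "X", 100), _hit("B", "X", 100),
    ]
    table = best_scores(hits, {"A", "B", "C"}, {"X"})
    strict = {(p.gene_a, p.gene_b) for p in classify_duplicates(table)}
    relaxed = {
        (p.gene_a, p.gene_b)
        for p in classify_duplicates(table, require_reciprocal=False)
    }
    assert ("A", "B") not in strict and ("A", "B") in relaxed


def test_classifier_agrees_with_bruteforce_on_random_tables():
    """Random score tables (spot check; the acceptance suite runs 1,000)."""
    rng = np.random.default_rng(11)
    for _ in range(100):
        _random_table_check(rng)


def _random_table_check(rng):
    n_focal = int(rng.integers(2, 20))
    n_out = int(rng.integers(0, 5))
    focal = {f"g{i:02d}" for i in range(n_focal)}
    out = {f"og{i}" for i in range(n_out)}
    hits = []
    for q in focal:
        for s in focal | out:
            if s == q or rng.random() < 0.5:
                continue
            # integer scores provoke ties; several HSPs per subject
            for _ in range(int(rng.integers(1, 3))):
                hits.append(
                    SimilarityHit(q, s, 90.0, int(rng.integers(50, 500)),
                                  float(rng.integers(1, 12) * 50))
                )
    table = best_scores(hits, focal, out)
    mine = {(p.gene_a, p.gene_b) for p in classify_duplicates(table)}
    aln_lens = {}
    pair_scores = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        if h.bitscore > pair_scores.get(key, -1):
            pair_scores[key] = h.bitscore
            aln_lens[key] = h.aln_len
        elif h.bitscore == pair_scores.get(key) and h.aln_len > aln_lens.get(key, -1):
            aln_lens[key] = h.aln_len
    expected = duplicate_pairs_bruteforce(pair_scores, aln_lens, focal, out)
    assert mine == expected


def test_duplicate_fraction_counts_genes_not_pairs():
    from hapcull.gene_dup import DuplicatePair

    pairs = [DuplicatePair("a", "b", 10, 10)]
    assert duplicate_fraction(pairs, 40) == 0.05  # 2 genes of 40
    assert duplicate_fraction([], 40) == 0.0


def test_surrogate_scorer_symmetric_on_identical_sequences():
    from hapcull.gene_dup import GeneRegion

    rng = np.random.default_rng(12)
    from hapcull.synthetic_data import random_seq

    seq = random_seq(rng, 800)
    a = GeneRegion("a", "s", 0, 800, "+", seq)
    b = GeneRegion("b", "s", 0, 800, "+", seq)
    ab = surrogate_score(a, b)
    ba = surrogate_score(b, a)
    assert ab.bitscore == ba.bitscore == 2 * 800


def test_planted_pairs_recovered_with_no_false_positives(default_sim):
    sim = default_sim
    focal = extract_gene_regions(sim.assembly, sim.annotation)
    og = extract_gene_regions(sim.outgroup_assembly, sim.outgroup_annotation)
    hits = score_all(focal, og)
    table = best_scores(hits, {r.gene_id for r in focal}, {r.gene_id for r in og})
    pairs = {(p.gene_a, p.gene_b) for p in classify_duplicates(table)}
    planted = set(sim.truth.dup_gene_pairs)
    assert pairs == planted  # full sensitivity, zero false pairs
    frac = duplicate_fraction(classify_duplicates(table), len(focal))
    assert frac == 2 * len(planted) / len(focal)
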