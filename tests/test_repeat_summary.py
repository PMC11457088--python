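"""Repeat accounting against a per-base bitmap oracle; family consensus rules."""

import numpy as np
import pytest

from oracles import repeat_bitmap

from hapcull.formats_io import REPEAT_CLASSES, RepeatAnnotation, SeqRecord
from hapcull.repeat_summary import (
    RepeatFamily,
    classify_bases,
    consensus_families,
    families_match,
    lineage_specific,
    per_scaffold_profiles,
)
from hapcull.synthetic_data import mutate, random_seq


def _anno(seqid, start, end, rclass, family="f"):
    return RepeatAnnotation(seqid, start, end, rclass, family)


def test_multiclass_interval_arithmetic():
    annos = [_anno("g", 0, 100, "LTR"), _anno("g", 50, 150, "LINE")]
    s = classify_bases(annos, {"g": 1000})
    assert s.masked_bp == {"LTR": 50, "LINE": 50, "Multiclass": 50, "Total": 150}
    assert s.pct("LTR") == 5.0 and s.pct("Total") == 15.0


def test_same_class_overlaps_merge_before_accounting():
    annos = [_anno("g", 0, 100, "LTR"), _anno("g", 50, 150, "LTR")]
    s = classify_bases(annos, {"g": 1000})
    assert s.masked_bp == {"LTR": 150, "Total": 150}


def test_no_annotations_all_zero_and_unknown_scaffold_errors():
    s = classify_bases([], {"g": 100})
    assert s.total_bp == 0 and s.pct("Total") == 0.0
    with pytest.raises(ValueError, match="ghost"):
        classify_bases([_anno("ghost", 0, 10, "DNA")], {"g": 100})


def test_classify_matches_bitmap_oracle_on_random_sets():
    """Random annotation sets (spot check; acceptance runs the 100-set sweep)."""
    rng = np.random.default_rng(21)
    for _ in range(20):
        genome = {
            f"s{j}": int(rng.integers(1_000, 40_000))
            for j in range(rng.integers(1, 4))
        }
        annos = []
        for _ in range(int(rng.integers(0, 60))):
            sid = str(rng.choice(sorted(genome)))
            ln = genome[sid]
            start = int(rng.integers(0, ln - 10))
            end = int(rng.integers(start + 1, min(start + 5000, ln) + 1))
            annos.append(
                _anno(sid, start, end, str(rng.choice(REPEAT_CLASSES)))
            )
        s = classify_bases(annos, genome)
        assert s.masked_bp == repeat_bitmap(annos, genome, REPEAT_CLASSES)
        single = sum(
            v for k, v in s.masked_bp.items() if k not in ("Multiclass", "Total")
        )
        assert single + s.masked_bp.get("Multiclass", 0) == s.total_bp


def test_genome_summary_equals_lengthweighted_per_scaffold(default_sim):
    sim = default_sim
    genome = {r.id: len(r) for r in sim.assembly}
    whole = classify_bases(sim.repeat_annotations, genome)
    # aggregate per-scaffold bp
    agg: dict[str, int] = {}
    for rec in sim.assembly:
        sub = [a for a in sim.repeat_annotations if a.seqid == rec.id]
        s = classify_bases(sub, {rec.id: len(rec)})
        for k, v in s.masked_bp.items():
            agg[k] = agg.get(k, 0) + v
    assert agg == whole.masked_bp


# ---------------------------------------------------------------- families

def _fam(name, rclass, seq, run=None):
    return RepeatFamily(name, rclass, seq, runs={run} if run else set())


def test_families_match_80_80_rule():
    rng = np.random.default_rng(22)
    cons = random_seq(rng, 400)
    near, _ = mutate(cons, 0.10, rng)
    far, _ = mutate(cons, 0.35, rng)
    assert families_match(_fam("a", "LTR", cons), _fam("b", "LTR", near))
    assert not families_match(_fam("a", "LTR", cons), _fam("c", "LTR", far))
    assert not families_match(_fam("a", "LTR", cons), _fam("d", "LTR", ""))


def test_consensus_five_runs_full_support():
    rng = np.random.default_rng(23)
    cons = random_seq(rng, 400)
    libs = []
    for r in range(1, 6):
        perturbed, _ = mutate(cons, 0.005, rng)
        libs.append((f"run{r}", [_fam(f"famA_r{r}", "LTR", perturbed, f"run{r}")]))
    (fam,) = consensus_families(libs)
    assert fam.run_support == 5 and fam.rclass == "LTR" and not fam.low_support


def test_consensus_singleton_run_flagged_low_support():
    rng = np.random.default_rng(24)
    shared = random_seq(rng, 300)
    lone = random_seq(rng, 300)
    libs = [
        ("run1", [_fam("shared_r1", "LINE", shared, "run1"),
                  _fam("lone_r1", "LINE", lone, "run1")]),
        ("run2", [_fam("shared_r2", "LINE", shared, "run2")]),
    ]
    fams = {f.family: f for f in consensus_families(libs)}
    assert fams["shared_r1"].run_support == 2
    assert fams["lone_r1"].run_support == 1 and fams["lone_r1"].low_support


def test_consensus_disjoint_runs_and_order_invariance():
    rng = np.random.default_rng(25)
    a, b = random_seq(rng, 300), random_seq(rng, 300)
    libs = [("run1", [_fam("a_r1", "DNA", a, "run1")]),
            ("run2", [_fam("b_r2", "LTR", b, "run2")])]
    fams = consensus_families(libs)
    assert sorted(f.run_support for f in fams) == [1, 1]
    reordered = consensus_families(libs[::-1])
    assert {(f.family, f.run_support) for f in fams} == {
        (f.family, f.run_support) for f in reordered
    }


def test_consensus_class_tie_becomes_unknown():
    rng = np.random.default_rng(26)
    cons = random_seq(rng, 300)
    libs = [("run1", [_fam("x_r1", "LINE", cons, "run1")]),
            ("run2", [_fam("x_r2", "LTR", cons, "run2")])]
    (fam,) = consensus_families(libs)
    assert fam.rclass == "Unknown" and fam.run_support == 2


def test_lineage_specific_flags_and_caveats():
    rng = np.random.default_rng(27)
    shared = random_seq(rng, 300)
    unique = random_seq(rng, 300)
    shared_div, _ = mutate(shared, 0.1, rng)
    focal = [
        RepeatFamily("shared", "LTR", shared, run_support=5),
        RepeatFamily("unique", "LINE", unique, run_support=1),
    ]
    comp = {"spA": [RepeatFamily("spA_f", "LTR", shared_div)]}
    specific = lineage_specific(focal, comp)
    assert [f.family for f in specific] == ["unique"]
    assert focal[0].lineage_specific is False
    assert "low run support" in specific[0].evidence


def test_lineage_specific_empty_comparators_warns():
    focal = [RepeatFamily("f", "LTR", "ACGT" * 50)]
    with pytest.warns(UserWarning, match="trivially"):
        specific = lineage_specific(focal, {})
    assert len(specific) == 1


def test_synthetic_runs_cluster_to_expected_support(default_sim):
    sim = default_sim
    fams = consensus_families(sim.repeat_runs)
    n_shared = len(sim.config.repeat_spec)
    full = [f for f in fams if f.run_support == sim.config.n_repeat_runs]
    low = [f for f in fams if f.run_support == 1]
    assert len(full) == n_shared
    assert len(low) == 2  # the planted lineage-specific singletons
    specific = lineage_specific(fams, sim.comparator_libraries)
    assert {f.family.split("_")[0] for f in specific} == {"RTE-X", "Crypton-V"}


def test_per_scaffold_profiles_ordering_and_values():
    assembly = [SeqRecord("big", "A" * 2000), SeqRecord("small", "A" * 500)]
    annos = [_anno("small", 0, 500, "LTR")]
    df = per_scaffold_profiles(annos, assembly)
    assert list(df["seqid"]) == ["big", "small"]  # length-descending
    small_row = df[df.seqid == "small"].iloc[0]
    assert small_row["LTR"] == 100.0 and small_row["Total"] == 100.0
    big_row = df[df.seqid == "big"].iloc[0]
    assert big_row["Total"] == 0.0
    # repeat-rich small scaffold exceeds the large one
    assert small_row["Total"] > big_row["Total"]
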