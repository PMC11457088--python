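"""Repeat-content accounting and multi-run repeat-family consensus.

Repeat annotation of a new genome is noisy: de-novo family discovery is
stochastic run to run, and the same base can be annotated by several
classes (a tandem repeat inside an LTR element, say).  This module
resolves both problems at the accounting level: bases annotated by
exactly one class count toward that class, bases annotated by two or more
distinct classes count toward "Multiclass" only, and the Total row is the
plain union — so the class rows are disjoint and sum to Total.  Family
identity across independent discovery runs (and across species libraries)
uses an 80/80-style rule: the shorter consensus must align within the
longer at >= 80% identity; both thresholds are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .formats_io import REPEAT_CLASSES, RepeatAnnotation, SeqRecord


@dataclass
class RepeatFamily:
    """One repeat-family model, possibly merged across discovery runs."""

    family: str
    rclass: str
    consensus: str = ""
    run_support: int = 1
    n_members: int = 1
    runs: set[str] = field(default_factory=set)
    lineage_specific: bool | None = None
    evidence: str = ""

    @property
    def low_support(self) -> bool:
        return self.run_support <= 1


@dataclass
class RepeatSummary:
    """Per-class masked bp and percentages, plus Multiclass and Total rows."""

    genome_bp: int
    masked_bp: dict[str, int] = field(default_factory=dict)  # class -> bp

    def pct(self, rclass: str) -> float:
        return 100.0 * self.masked_bp.get(rclass, 0) / self.genome_bp if self.genome_bp else 0.0

    @property
    def total_bp(self) -> int:
        return self.masked_bp.get("Total", 0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"rclass": c, "masked_bp": self.masked_bp.get(c, 0), "pct": self.pct(c)}
            for c in (*REPEAT_CLASSES, "Multiclass", "Total")
        ]
        return pd.DataFrame(rows)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def classify_bases(
    annotations: list[RepeatAnnotation],
    genome_len_by_scaffold: dict[str, int],
) -> RepeatSummary:
    """Per-base repeat-class accounting with multiclass overlap resolution.

    Overlapping annotations of the same class are merged first; each base
    covered by exactly one distinct class counts toward that class, bases
    covered by >= 2 distinct classes toward Multiclass only, and Total is
    the union of all repeat intervals.
    """
    per_scaffold_class: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for a in annotations:
        if a.seqid not in genome_len_by_scaffold:
            raise ValueError(f"repeat annotation on unknown scaffold {a.seqid!r}")
        if a.end > genome_len_by_scaffold[a.seqid]:
            raise ValueError(
                f"repeat interval {a.start}-{a.end} beyond {a.seqid} length"
            )
        per_scaffold_class.setdefault(a.seqid, {}).setdefault(a.rclass, []).append(
            (a.start, a.end)
        )

    masked: dict[str, int] = {}
    for classes in per_scaffold_class.values():
        events: list[tuple[int, int, str]] = []
        for rclass, ivals in classes.items():
            for s, e in _merge(ivals):
                events.append((s, 1, rclass))
                events.append((e, -1, rclass))
        events.sort(key=lambda t: t[0])
        active: dict[str, int] = {}
        prev = None
        i = 0
        while i < len(events):
            pos = events[i][0]
            if prev is not None and pos > prev:
                k = sum(1 for v in active.values() if v > 0)
                if k == 1:
                    (cls,) = [c for c, v in active.items() if v > 0]
                    masked[cls] = masked.get(cls, 0) + (pos - prev)
                elif k >= 2:
                    masked["Multiclass"] = masked.get("Multiclass", 0) + (pos - prev)
                if k >= 1:
                    masked["Total"] = masked.get("Total", 0) + (pos - prev)
            while i < len(events) and events[i][0] == pos:
                _, delta, cls = events[i]
                active[cls] = active.get(cls, 0) + delta
                i += 1
            prev = pos
    return RepeatSummary(
        genome_bp=sum(genome_len_by_scaffold.values()), masked_bp=masked
    )


def families_match(
    a: RepeatFamily,
    b: RepeatFamily,
    min_identity: float = 0.8,
    min_cov: float = 0.8,
) -> bool:
    """80/80-style family identity: shorter consensus aligns within the longer.

    The shorter consensus must be matchable over >= min_cov of its length at
    >= min_identity; with infix (HW-mode) alignment the covered span is the
    whole shorter sequence, so the test reduces to an edit-distance budget
    of (1 - min_identity) * min_cov-adjusted length.
    """
    if not a.consensus or not b.consensus:
        return False
    short, long_ = sorted((a.consensus, b.consensus), key=len)
    # HW-mode alignment spans the whole shorter sequence, so coverage of the
    # shorter consensus is 100% and min_cov is satisfied for any value <= 1.
    del min_cov
    budget = int((1.0 - min_identity) * len(short))
    res = edlib.align(short, long_, mode="HW", task="distance", k=budget)
    return res["editDistance"] != -1


def consensus_families(
    run_libraries: list[tuple[str, list[RepeatFamily]]],
    min_identity: float = 0.8,
    min_cov: float = 0.8,
) -> list[RepeatFamily]:
    """Cluster family models across independent discovery runs.

    Families from different runs matching under the identity rule merge
    into one cluster; the cluster's class is the majority class across
    member runs (ties -> Unknown) and run_support counts distinct runs.
    Invariant to run order.
    """
    if not run_libraries:
        raise ValueError("at least one run library required")
    members: list[tuple[str, RepeatFamily]] = []
    for run_id, fams in sorted(run_libraries, key=lambda t: t[0]):
        for f in fams:
            members.append((run_id, f))
    parent = list(range(len(members)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if members[i][0] == members[j][0]:
                continue  # within-run families stay distinct
            if families_match(members[i][1], members[j][1], min_identity, min_cov):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[tuple[str, RepeatFamily]]] = {}
    for i, m in enumerate(members):
        clusters.setdefault(find(i), []).append(m)

    out: list[RepeatFamily] = []
    for root in sorted(clusters):
        group = clusters[root]
        runs = {run_id for run_id, _ in group}
        class_votes: dict[str, int] = {}
        for _, f in group:
            class_votes[f.rclass] = class_votes.get(f.rclass, 0) + 1
        top = max(class_votes.values())
        winners = sorted(c for c, v in class_votes.items() if v == top)
        rclass = winners[0] if len(winners) == 1 else "Unknown"
        rep = max((f for _, f in group), key=lambda f: len(f.consensus))
        names = sorted(f.family for _, f in group)
        out.append(
            RepeatFamily(
                family=names[0],
                rclass=rclass,
                consensus=rep.consensus,
                run_support=len(runs),
                n_members=sum(f.n_members for _, f in group),
                runs=runs,
            )
        )
    out.sort(key=lambda f: (-f.run_support, f.family))
    return out


def lineage_specific(
    focal: list[RepeatFamily],
    comparators: dict[str, list[RepeatFamily]],
    min_identity: float = 0.8,
    min_cov: float = 0.8,
) -> list[RepeatFamily]:
    """Flag focal families with zero matches in every comparator library.

    Low run_support is carried as an evidence caveat: a family seen in one
    discovery run only is weak evidence of a genuinely lineage-specific
    family.  An empty comparator set degenerately marks every family
    specific (warned).
    """
    if not comparators:
        warnings.warn(
            "no comparator libraries supplied; every family is trivially specific",
            stacklevel=2,
        )
    for f in focal:
        matched_in: list[str] = []
        for species, fams in sorted(comparators.items()):
            if any(families_match(f, c, min_identity, min_cov) for c in fams):
                matched_in.append(species)
        f.lineage_specific = not matched_in
        if matched_in:
            f.evidence = "matches " + ",".join(matched_in)
        elif f.low_support:
            f.evidence = "no comparator match; low run support, further evidence required"
        else:
            f.evidence = "no comparator match"
    return [f for f in focal if f.lineage_specific]


def per_scaffold_profiles(
    annotations: list[RepeatAnnotation],
    assembly: list[SeqRecord],
) -> pd.DataFrame:
    """Repeat-class percentage per scaffold, rows sorted by length descending."""
    rows = []
    by_scaffold: dict[str, list[RepeatAnnotation]] = {}
    for a in annotations:
        by_scaffold.setdefault(a.seqid, []).append(a)
    for rec in sorted(assembly, key=lambda r: (-len(r), r.id)):
        summary = classify_bases(
            by_scaffold.get(rec.id, []), {rec.id: len(rec)}
        )
        row: dict[str, object] = {"seqid": rec.id, "seq_len": len(rec)}
        for c in (*REPEAT_CLASSES, "Multiclass", "Total"):
            row[c] = summary.pct(c)
        rows.append(row)
    return pd.DataFrame(rows)
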