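"""End-to-end orchestration: simulate/load -> stats -> dedup -> genedup -> repeats.

One RunConfig drives a full reproducible run; every stage writes its table
under the run directory and the consolidated RunReport is recomputable
from those tables.  Identical config + inputs give an identical report
body (timestamps are excluded by design).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .anchor_align import AnchorParams
from .assembly_metrics import (
    AnnotationMetrics,
    AssemblyMetrics,
    annotation_stats,
    assembly_metrics,
)
from .formats_io import (
    read_alignments,
    read_busco_full_table,
    read_fasta,
    read_gff,
    read_hits,
    read_repeat_table,
    write_fasta,
    write_gff,
    write_tsv,
)
from .gene_dup import (
    best_scores,
    classify_duplicates,
    duplicate_fraction,
    extract_gene_regions,
)
from .repeat_summary import (
    RepeatSummary,
    classify_bases,
    consensus_families,
    lineage_specific,
    per_scaffold_profiles,
)
from .scaffold_dedup import run_dedup, split_assembly
from .synthetic_data import SimConfig, emit_hits, generate

log = logging.getLogger("hapcull")


class PipelineConfigError(ValueError):
    """Invalid run configuration; carries every problem found, not just the first."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


@dataclass
class RunConfig:
    outdir: str = "hapcull_run"
    seed: int = 42
    simulate: bool = True                     # generate inputs synthetically
    sim: SimConfig | None = None              # derived from seed when None
    # external inputs (used when simulate=False)
    fasta: str | None = None
    gff: str | None = None
    busco: str | None = None
    alignments: str | None = None             # PAF; None -> internal aligner
    outgroup_fasta: str | None = None
    outgroup_gff: str | None = None
    hits: str | None = None                   # blast tabular; None -> surrogate
    rm_out: list[str] = field(default_factory=list)
    trf: str | None = None
    # thresholds; anchor defaults suit intra-species haplotype comparison:
    # at divergence d the maximal exact runs average 1/d bp, so the match
    # floor must sit well below 1/d and the chain gap well above it
    min_match: int = 100
    max_gap: int = 10_000
    seed_k: int = 21
    coverage_threshold: float = 0.95
    require_reciprocal: bool = True
    repeat_min_identity: float = 0.8
    repeat_min_cov: float = 0.8
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim_data = data.pop("sim", None)
        cfg = cls(**data)
        if sim_data:
            cfg.sim = SimConfig(**sim_data)
        return cfg

    def validate(self) -> list[str]:
        problems: list[str] = []
        if not self.simulate:
            for name in ("fasta", "gff", "busco"):
                value = getattr(self, name)
                if value is None:
                    problems.append(f"missing required input: {name}")
                elif not Path(value).exists():
                    problems.append(f"{name} path does not exist: {value}")
            for name in ("alignments", "outgroup_fasta", "outgroup_gff", "hits", "trf"):
                value = getattr(self, name)
                if value is not None and not Path(value).exists():
                    problems.append(f"{name} path does not exist: {value}")
            for p in self.rm_out:
                if not Path(p).exists():
                    problems.append(f"rm_out path does not exist: {p}")
        if not (0 < self.coverage_threshold <= 1):
            problems.append("coverage_threshold must be in (0, 1]")
        if self.min_match < self.seed_k:
            problems.append("min_match must be >= seed_k")
        return problems

    def anchor_params(self) -> AnchorParams:
        return AnchorParams(
            min_match=self.min_match, max_gap=self.max_gap, seed_k=self.seed_k
        )


@dataclass
class RunReport:
    pre_metrics: AssemblyMetrics
    post_metrics: AssemblyMetrics
    pre_annotation: AnnotationMetrics
    post_annotation: AnnotationMetrics
    n_candidates: int
    candidate_ids: list[str]
    n_removed: int
    removed_ids: list[str]
    removed_bp: int
    n_dup_gene_pairs: int
    n_dup_genes: int
    dup_gene_fraction: float
    repeat_summary: RepeatSummary | None
    n_repeat_families: int
    n_low_support_families: int
    n_lineage_specific: int
    residual_duplicated_buscos: int
    provenance: dict = field(default_factory=dict)

    def to_markdown(self) -> str:
        m = self
        lines = [
            "# hapcull run report",
            "",
            "## Assembly",
            "| metric | before dedup | after dedup |",
            "|---|---|---|",
            f"| Total length (bp) | {m.pre_metrics.total_length:,} | {m.post_metrics.total_length:,} |",
            f"| Scaffolds | {m.pre_metrics.n_scaffolds} | {m.post_metrics.n_scaffolds} |",
            f"| N50 (bp) | {m.pre_metrics.nx[50]:,} | {m.post_metrics.nx[50]:,} |",
            f"| L50 | {m.pre_metrics.lx[50]} | {m.post_metrics.lx[50]} |",
            f"| N90 (bp) | {m.pre_metrics.nx[90]:,} | {m.post_metrics.nx[90]:,} |",
            f"| L90 | {m.pre_metrics.lx[90]} | {m.post_metrics.lx[90]} |",
            f"| GC% | {m.pre_metrics.gc_pct:.2f} | {m.post_metrics.gc_pct:.2f} |",
            "",
            "## Duplicate scaffolds",
            f"- candidates with >=1 duplicated benchmark gene: {m.n_candidates} ({', '.join(m.candidate_ids)})",
            f"- removed as fully duplicated: {m.n_removed} ({', '.join(m.removed_ids)})",
            f"- removed bp: {m.removed_bp:,}",
            f"- duplicated benchmark genes remaining after removal: {m.residual_duplicated_buscos}",
            "",
            "## Duplicate genes",
            f"- pairs: {m.n_dup_gene_pairs}; genes: {m.n_dup_genes} "
            f"({100 * m.dup_gene_fraction:.2f}% of annotated genes)",
            "",
            "## Repeats",
        ]
        if m.repeat_summary is not None:
            lines.append(
                f"- total repeat content: {m.repeat_summary.pct('Total'):.2f}% "
                f"({m.repeat_summary.total_bp:,} bp)"
            )
            lines.append(
                f"- Multiclass: {m.repeat_summary.pct('Multiclass'):.2f}%"
            )
        lines.append(
            f"- families: {m.n_repeat_families} "
            f"(low run support: {m.n_low_support_families}, "
            f"lineage-specific: {m.n_lineage_specific})"
        )
        lines += ["", "## Provenance"]
        for k, v in m.provenance.items():
            lines.append(f"- {k}: {v}")
        return "\n".join(lines) + "\n"


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full curation pipeline; see module docstring for stages."""
    problems = config.validate()
    if problems:
        raise PipelineConfigError(problems)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: list[dict[str, str]] = []

    def emit(name: str, path: Path) -> None:
        manifest.append({"artifact": name, "path": str(path)})

    # ---- inputs -----------------------------------------------------------
    truth = None
    run_libraries = None
    comparators: dict = {}
    if config.simulate:
        t0 = _stage("simulate")
        sim_cfg = config.sim or SimConfig(seed=config.seed)
        sim = generate(sim_cfg)
        sim_paths = sim.write(outdir / "sim")
        for k, p in sim_paths.items():
            emit(f"sim/{k}", p)
        assembly, features = sim.assembly, sim.annotation
        buscos = sim.busco_table
        og_assembly, og_features = sim.outgroup_assembly, sim.outgroup_annotation
        repeat_annos = sim.repeat_annotations
        run_libraries = sim.repeat_runs
        comparators = sim.comparator_libraries
        truth = sim.truth
        external_blocks = None
        hits = None
        log.info("simulate done in %.1fs", time.perf_counter() - t0)
    else:
        _stage("load")
        assembly = read_fasta(config.fasta)
        features = read_gff(config.gff)
        buscos = read_busco_full_table(config.busco)
        external_blocks = (
            read_alignments(config.alignments, "paf") if config.alignments else None
        )
        og_assembly = read_fasta(config.outgroup_fasta) if config.outgroup_fasta else []
        og_features = read_gff(config.outgroup_gff) if config.outgroup_gff else []
        hits = read_hits(config.hits) if config.hits else None
        repeat_annos = []
        for i, p in enumerate(config.rm_out, 1):
            repeat_annos.extend(read_repeat_table(p, "rmout", run_id=f"rmout{i}"))
        if config.trf:
            repeat_annos.extend(read_repeat_table(config.trf, "trf", run_id="trf"))

    # ---- pre-dedup statistics --------------------------------------------
    _stage("stats-pre")
    pre_metrics = assembly_metrics(assembly)
    pre_annotation = annotation_stats(features)

    # ---- dedup ------------------------------------------------------------
    t0 = _stage("dedup")
    profiles, decisions = run_dedup(
        assembly, buscos,
        threshold=config.coverage_threshold,
        params=config.anchor_params(),
        external_blocks=external_blocks,
    )
    dec_by_id = {d.seqid: d for d in decisions}
    prof_by_id = {p.seqid: p for p in profiles}
    rows = []
    for p in profiles:
        d = dec_by_id[p.seqid]
        rows.append(
            {
                "seqid": p.seqid, "len": p.seq_len, "n_busco": p.n_busco,
                "n_dup": p.n_dup, "pct_dup": round(p.pct_dup, 2),
                "coverage": round(d.coverage_fraction, 4), "status": d.status,
                "partner": d.partner_used, "reason": d.reason,
            }
        )
    write_tsv(outdir / "dedup_decisions.tsv", pd.DataFrame(rows))
    emit("dedup_decisions", outdir / "dedup_decisions.tsv")
    kept_fa, kept_gff, removed_fa, removed_gff = split_assembly(
        assembly, features, decisions
    )
    for name, obj, writer in (
        ("kept.fa", kept_fa, write_fasta),
        ("removed.fa", removed_fa, write_fasta),
    ):
        if obj:
            writer(outdir / name, obj)
            emit(name, outdir / name)
    write_gff(outdir / "kept.gff3", kept_gff)
    emit("kept.gff3", outdir / "kept.gff3")
    write_gff(outdir / "removed.gff3", removed_gff)
    emit("removed.gff3", outdir / "removed.gff3")
    log.info(
        "dedup removed %d scaffolds in %.1fs",
        len(removed_fa), time.perf_counter() - t0,
    )

    removed_ids = sorted(r.id for r in removed_fa)
    kept_ids = {r.id for r in kept_fa}
    residual_dup = len(
        {
            b.busco_id
            for b in buscos
            if b.status == "Duplicated"
            and sum(
                1 for bb in buscos
                if bb.busco_id == b.busco_id and bb.seqid in kept_ids
            ) >= 2
        }
    )

    # ---- post-dedup statistics -------------------------------------------
    _stage("stats-post")
    post_metrics = assembly_metrics(kept_fa)
    post_annotation = annotation_stats(kept_gff)
    stats_rows = []
    for label, m, a in (
        ("before_dedup", pre_metrics, pre_annotation),
        ("after_dedup", post_metrics, post_annotation),
    ):
        stats_rows.append(
            {
                "assembly": label, "total_length": m.total_length,
                "n_scaffolds": m.n_scaffolds, "n50": m.nx[50], "l50": m.lx[50],
                "n90": m.nx[90], "l90": m.lx[90], "gc_pct": round(m.gc_pct, 3),
                "n_genes": a.n_genes, "n_protein_coding": a.n_protein_coding,
                "n_exons": a.n_exons,
                "median_transcript_len": a.median_transcript_len,
                "longest_transcript_len": a.longest_transcript_len,
            }
        )
    write_tsv(outdir / "assembly_stats.tsv", pd.DataFrame(stats_rows))
    emit("assembly_stats", outdir / "assembly_stats.tsv")

    # ---- duplicate genes --------------------------------------------------
    t0 = _stage("genedup")
    focal_regions = extract_gene_regions(kept_fa, kept_gff)
    og_regions = extract_gene_regions(og_assembly, og_features) if og_assembly else []
    if hits is None:
        hits = emit_hits(focal_regions, og_regions, outdir / "hits.tsv")
        emit("hits", outdir / "hits.tsv")
    focal_ids = {r.gene_id for r in focal_regions}
    og_ids = {r.gene_id for r in og_regions}
    table = best_scores(hits, focal_ids, og_ids)
    pairs = classify_duplicates(table, require_reciprocal=config.require_reciprocal)
    frac = duplicate_fraction(pairs, len(focal_ids))
    write_tsv(
        outdir / "dup_gene_pairs.tsv",
        pd.DataFrame(
            [
                {
                    "gene_a": p.gene_a, "gene_b": p.gene_b,
                    "score_ab": p.score_ab, "score_ba": p.score_ba,
                    "best_outgroup_a": p.best_outgroup_a,
                    "best_outgroup_b": p.best_outgroup_b,
                }
                for p in pairs
            ]
        ),
    )
    emit("dup_gene_pairs", outdir / "dup_gene_pairs.tsv")
    dup_genes = sorted({g for p in pairs for g in (p.gene_a, p.gene_b)})
    write_tsv(outdir / "dup_genes.tsv", pd.DataFrame({"gene_id": dup_genes}))
    emit("dup_genes", outdir / "dup_genes.tsv")
    log.info("genedup found %d pairs in %.1fs", len(pairs), time.perf_counter() - t0)

    # ---- repeats -----------------------------------------------------------
    _stage("repeats")
    repeat_summary = None
    families = []
    specific = []
    if repeat_annos:
        kept_annos = [a for a in repeat_annos if a.seqid in kept_ids]
        repeat_summary = classify_bases(
            kept_annos, {r.id: len(r) for r in kept_fa}
        )
        write_tsv(outdir / "repeat_summary.tsv", repeat_summary.to_dataframe())
        emit("repeat_summary", outdir / "repeat_summary.tsv")
        profiles_df = per_scaffold_profiles(kept_annos, kept_fa)
        write_tsv(outdir / "repeat_per_scaffold.tsv", profiles_df)
        emit("repeat_per_scaffold", outdir / "repeat_per_scaffold.tsv")
    if run_libraries:
        families = consensus_families(
            run_libraries,
            min_identity=config.repeat_min_identity,
            min_cov=config.repeat_min_cov,
        )
        specific = lineage_specific(
            families, comparators,
            min_identity=config.repeat_min_identity,
            min_cov=config.repeat_min_cov,
        )
        write_tsv(
            outdir / "repeat_families.tsv",
            pd.DataFrame(
                [
                    {
                        "family": f.family, "rclass": f.rclass,
                        "run_support": f.run_support,
                        "low_support": f.low_support,
                        "lineage_specific": bool(f.lineage_specific),
                        "evidence": f.evidence,
                    }
                    for f in families
                ]
            ),
        )
        emit("repeat_families", outdir / "repeat_families.tsv")

    # ---- report ------------------------------------------------------------
    report = RunReport(
        pre_metrics=pre_metrics, post_metrics=post_metrics,
        pre_annotation=pre_annotation, post_annotation=post_annotation,
        n_candidates=sum(1 for p in profiles if p.n_dup >= 1),
        candidate_ids=sorted(p.seqid for p in profiles if p.n_dup >= 1),
        n_removed=len(removed_ids), removed_ids=removed_ids,
        removed_bp=sum(len(r) for r in removed_fa),
        n_dup_gene_pairs=len(pairs), n_dup_genes=len(dup_genes),
        dup_gene_fraction=frac,
        repeat_summary=repeat_summary,
        n_repeat_families=len(families),
        n_low_support_families=sum(1 for f in families if f.low_support),
        n_lineage_specific=len(specific),
        residual_duplicated_buscos=residual_dup,
        provenance={
            "hapcull_version": __version__,
            "seed": config.seed,
            "coverage_threshold": config.coverage_threshold,
            "min_match": config.min_match,
            "max_gap": config.max_gap,
            "require_reciprocal": config.require_reciprocal,
        },
    )
    (outdir / "report.md").write_text(report.to_markdown())
    emit("report", outdir / "report.md")
    effective = dataclasses.asdict(config)
    if config.sim is not None:
        effective["sim"] = dataclasses.asdict(config.sim)
    (outdir / "effective_config.yaml").write_text(yaml.safe_dump(effective))
    emit("effective_config", outdir / "effective_config.yaml")
    write_tsv(outdir / "manifest.tsv", pd.DataFrame(manifest))

    if truth is not None:
        planted = set(truth.haplotig_ids)
        if set(removed_ids) != planted:
            log.warning(
                "removed set %s differs from planted truth %s",
                removed_ids, sorted(planted),
            )
    return report


def compare_assemblies(
    entries: list[tuple[str, AssemblyMetrics, RepeatSummary | None]],
) -> pd.DataFrame:
    """Wide comparison table: one column per assembly, one row per metric."""
    if not entries:
        raise ValueError("at least one assembly required")
    rows = [
        "Total length (bp)", "Scaffolds", "N50 (bp)", "L50", "N90 (bp)",
        "L90", "GC%", "Repeat content (%)", "Multiclass (%)",
    ]
    data: dict[str, list] = {"metric": rows}
    for label, m, rs in entries:
        data[label] = [
            m.total_length, m.n_scaffolds, m.nx[50], m.lx[50], m.nx[90],
            m.lx[90], round(m.gc_pct, 2),
            round(rs.pct("Total"), 2) if rs else float("nan"),
            round(rs.pct("Multiclass"), 2) if rs else float("nan"),
        ]
    return pd.DataFrame(data)
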