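"""Readers and writers for every external format the pipeline touches.

All coordinates are normalized into one internal convention: half-open,
0-based intervals.  The only places 1-based inclusive coordinates survive
are the GFF3 / BUSCO full-table / show-coords boundaries, where the source
dialects define them; conversion happens exactly once, in the reader or
writer for that dialect.

Soft-masked (lowercase) sequence is uppercased on read; masking state is
re-derived from repeat tables, never from case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class SeqRecord:
    """One scaffold or gene-region sequence (uppercase A/C/G/T/N)."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


GFF_TYPES = ("gene", "mRNA", "exon", "CDS")


@dataclass
class GffFeature:
    """One GFF3 feature; coordinates stay 1-based inclusive at this boundary."""

    seqid: str
    source: str
    ftype: str  # gene | mRNA | exon | CDS | other
    start: int  # 1-based inclusive
    end: int
    strand: str  # + | - | .
    attributes: dict[str, str] = field(default_factory=dict)
    score: str = "."
    phase: str = "."
    raw_type: str = ""  # original type string for ftype == "other"

    @property
    def feature_id(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def parent(self) -> str | None:
        return self.attributes.get("Parent")

    def span(self) -> int:
        return self.end - self.start + 1


BUSCO_STATUSES = frozenset({"Complete", "Duplicated", "Fragmented", "Missing"})


@dataclass
class BuscoRecord:
    """One benchmark-gene placement from a BUSCO full_table row."""

    busco_id: str
    status: str
    seqid: str = ""           # empty for Missing
    start: int | None = None  # 1-based inclusive, None for Missing
    end: int | None = None
    strand: str = ""
    score: float | None = None
    length: int | None = None


@dataclass
class AlignmentBlock:
    """Strand-aware aligned segment between two scaffolds.

    Internal half-open 0-based coordinates on both sides; antisense blocks
    are normalized so qry_start < qry_end on the forward strand.
    """

    ref_id: str
    qry_id: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    strand: str  # "sense" | "antisense"
    match_len: int
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start or self.qry_end <= self.qry_start:
            raise ValueError(
                f"degenerate alignment block {self.ref_id}:{self.ref_start}-"
                f"{self.ref_end} / {self.qry_id}:{self.qry_start}-{self.qry_end}"
            )
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class SimilarityHit:
    """One scored match between gene regions (blast-tabular dialect)."""

    query_id: str
    subject_id: str
    identity: float  # percent
    aln_len: int
    bitscore: float
    evalue: float = 0.0


REPEAT_CLASSES = (
    "Tandem", "Simple", "Satellite", "DNA", "RC", "LINE", "LTR",
    "rRNA", "snRNA", "tRNA", "Unknown",
)

# RepeatMasker .out class strings -> internal repeat-class vocabulary.
# Anything not listed maps to Unknown (with a warning), never dropped.
RM_CLASS_MAP = {
    "DNA": "DNA",
    "RC": "RC",
    "Rolling-circle": "RC",
    "LINE": "LINE",
    "LTR": "LTR",
    "Simple_repeat": "Simple",
    "Low_complexity": "Simple",
    "Satellite": "Satellite",
    "rRNA": "rRNA",
    "snRNA": "snRNA",
    "tRNA": "tRNA",
    "Tandem": "Tandem",
    "Unknown": "Unknown",
    "Unspecified": "Unknown",
}


@dataclass
class RepeatAnnotation:
    """One masked interval with class/family/run provenance (half-open 0-based)."""

    seqid: str
    start: int
    end: int
    rclass: str
    family: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty repeat interval on {self.seqid}")
        if self.rclass not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.rclass!r}")


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords, uppercasing the sequence.

    Order is preserved; CRLF line endings are tolerated.  Duplicate ids and
    empty files raise FormatError.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            records.append(SeqRecord(rec.id, str(rec.seq).upper(), desc))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[SeqRecord], width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            attrs[k.strip()] = v.strip()
        else:
            attrs[chunk] = ""
    return attrs


def read_gff(path: str | Path) -> list[GffFeature]:
    """Read a GFF3 file; '##' directives and '#' comments skipped.

    Coordinates are kept 1-based inclusive at this boundary.  Unknown feature
    types are retained with ftype="other".
    """
    features: list[GffFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, source, ftype_raw, start_s, end_s, score, strand, phase, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start:
                raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
            strand = strand.replace("−", "-")
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            ftype = ftype_raw if ftype_raw in GFF_TYPES else "other"
            features.append(
                GffFeature(
                    seqid=seqid, source=source, ftype=ftype,
                    start=start, end=end, strand=strand,
                    attributes=_parse_attributes(attr_s),
                    score=score, phase=phase,
                    raw_type=ftype_raw if ftype == "other" else "",
                )
            )
    return features


def write_gff(path: str | Path, features: Iterable[GffFeature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            ftype = f.raw_type if f.ftype == "other" and f.raw_type else f.ftype
            attrs = ";".join(f"{k}={v}" if v else k for k, v in f.attributes.items())
            fh.write(
                "\t".join(
                    [f.seqid, f.source, ftype, str(f.start), str(f.end),
                     f.score, f.strand, f.phase, attrs or "."]
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# BUSCO full table
# --------------------------------------------------------------------------

def read_busco_full_table(path: str | Path) -> list[BuscoRecord]:
    """Read a BUSCO full_table TSV (v4/v5 dialects; '#' header lines skipped).

    Only the first eight columns are consumed, so v5 tables carrying OrthoDB
    url/description columns parse identically.  Missing rows are retained
    with an empty placement.
    """
    records: list[BuscoRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            busco_id, status = cols[0], cols[1]
            if status not in BUSCO_STATUSES:
                raise FormatError(
                    f"{path}:{lineno}: unknown BUSCO status {status!r}"
                )
            if status == "Missing" or len(cols) < 5 or not cols[2]:
                records.append(BuscoRecord(busco_id, status))
                continue
            records.append(
                BuscoRecord(
                    busco_id=busco_id,
                    status=status,
                    seqid=cols[2],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[5] if len(cols) > 5 else "",
                    score=float(cols[6]) if len(cols) > 6 and cols[6] else None,
                    length=int(float(cols[7])) if len(cols) > 7 and cols[7] else None,
                )
            )
    return records


def write_busco_full_table(path: str | Path, records: Iterable[BuscoRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("# Busco id\tStatus\tSequence\tGene Start\tGene End\tStrand\tScore\tLength\n")
        for r in records:
            if r.status == "Missing":
                fh.write(f"{r.busco_id}\tMissing\n")
            else:
                fh.write(
                    f"{r.busco_id}\t{r.status}\t{r.seqid}\t{r.start}\t{r.end}"
                    f"\t{r.strand}\t{'' if r.score is None else r.score}"
                    f"\t{'' if r.length is None else r.length}\n"
                )


# --------------------------------------------------------------------------
# pairwise alignments (PAF / show-coords)
# --------------------------------------------------------------------------

def read_alignments(
    path: str | Path, dialect: str = "paf"
) -> list[AlignmentBlock]:
    """Read pairwise alignments from PAF or nucmer show-coords -T tables.

    PAF is already 0-based half-open (query coordinates on the forward
    strand even for '-' hits).  show-coords rows are 1-based inclusive with
    antisense encoded as qry_start > qry_end; both are normalized to the
    internal convention with qry_start < qry_end and strand="antisense".
    """
    blocks: list[AlignmentBlock] = []
    if dialect == "paf":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\r\n")
                if not line:
                    continue
                c = line.split("\t")
                qname, qlen, qstart, qend = c[0], int(c[1]), int(c[2]), int(c[3])
                strand = "antisense" if c[4].replace("−", "-") == "-" else "sense"
                tname, tlen, tstart, tend = c[5], int(c[6]), int(c[7]), int(c[8])
                nmatch, alnlen = int(c[9]), int(c[10])
                if qend > qlen or tend > tlen:
                    raise FormatError(
                        f"{path}:{lineno}: coordinate beyond declared sequence length"
                    )
                blocks.append(
                    AlignmentBlock(
                        ref_id=tname, qry_id=qname,
                        ref_start=tstart, ref_end=tend,
                        qry_start=qstart, qry_end=qend,
                        strand=strand, match_len=nmatch,
                        identity=nmatch / alnlen if alnlen else 0.0,
                    )
                )
    elif dialect == "coords":
        # show-coords -T: S1 E1 S2 E2 LEN1 LEN2 %IDY REF QRY
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\r\n")
                if not line or line.startswith(("=", "/", "NUCMER")):
                    continue
                c = line.split("\t")
                if len(c) < 9 or not c[0].lstrip("-").isdigit():
                    continue  # header rows
                s1, e1, s2, e2 = int(c[0]), int(c[1]), int(c[2]), int(c[3])
                len1, pident = int(c[4]), float(c[6])
                ref_id, qry_id = c[7], c[8]
                if s2 <= e2:
                    strand, qs, qe = "sense", s2 - 1, e2
                else:
                    strand, qs, qe = "antisense", e2 - 1, s2
                blocks.append(
                    AlignmentBlock(
                        ref_id=ref_id, qry_id=qry_id,
                        ref_start=s1 - 1, ref_end=e1,
                        qry_start=qs, qry_end=qe,
                        strand=strand,
                        match_len=int(round(len1 * pident / 100.0)),
                        identity=pident / 100.0,
                    )
                )
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    return blocks


def write_paf(
    path: str | Path,
    blocks: Iterable[AlignmentBlock],
    seq_lens: dict[str, int],
) -> None:
    """Write alignment blocks as minimal PAF (12 mandatory columns)."""
    with open(path, "w") as fh:
        for b in blocks:
            alnlen = max(b.ref_end - b.ref_start, b.qry_end - b.qry_start)
            fh.write(
                "\t".join(
                    [
                        b.qry_id, str(seq_lens[b.qry_id]),
                        str(b.qry_start), str(b.qry_end),
                        "-" if b.strand == "antisense" else "+",
                        b.ref_id, str(seq_lens[b.ref_id]),
                        str(b.ref_start), str(b.ref_end),
                        str(b.match_len), str(alnlen), "255",
                    ]
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# blast-tabular hits
# --------------------------------------------------------------------------

def read_hits(path: str | Path) -> list[SimilarityHit]:
    """Read a 12-column blast-tabular hit file.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Self-hits are permitted on read and
    filtered downstream.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            c = line.split("\t")
            if len(c) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(c)}")
            hits.append(
                SimilarityHit(
                    query_id=c[0], subject_id=c[1],
                    identity=float(c[2]), aln_len=int(c[3]),
                    evalue=float(c[10]), bitscore=float(c[11]),
                )
            )
    return hits


def write_hits(path: str | Path, hits: Iterable[SimilarityHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity:.2f}\t{h.aln_len}"
                f"\t0\t0\t1\t{h.aln_len}\t1\t{h.aln_len}"
                f"\t{h.evalue:.2g}\t{h.bitscore:.1f}\n"
            )


# --------------------------------------------------------------------------
# repeat tables (RepeatMasker .out / TRF .dat)
# --------------------------------------------------------------------------

def map_rm_class(class_family: str) -> tuple[str, str]:
    """Map a RepeatMasker class/family string onto the internal vocabulary.

    "LINE/R1" -> ("LINE", "R1"); unmappable classes become Unknown with a
    warning, never dropped.
    """
    if "/" in class_family:
        cls, fam = class_family.split("/", 1)
    else:
        cls, fam = class_family, ""
    mapped = RM_CLASS_MAP.get(cls)
    if mapped is None:
        warnings.warn(
            f"repeat class {cls!r} not in vocabulary; recorded as Unknown",
            stacklevel=2,
        )
        mapped = "Unknown"
    return mapped, fam


def read_repeat_table(
    path: str | Path, dialect: str = "rmout", run_id: str = ""
) -> list[RepeatAnnotation]:
    """Read RepeatMasker .out-style or TRF .dat-style repeat tables.

    1-based inclusive source coordinates are converted to internal half-open
    0-based intervals.  TRF intervals are all class Tandem with the period
    recorded in the family name.
    """
    annos: list[RepeatAnnotation] = []
    if dialect == "rmout":
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) < 11 or not parts[0].isdigit():
                    continue  # banner / header / blank lines
                seqid, begin, end = parts[4], int(parts[5]), int(parts[6])
                family_name = parts[9]
                rclass, fam_from_class = map_rm_class(parts[10])
                annos.append(
                    RepeatAnnotation(
                        seqid=seqid, start=begin - 1, end=end,
                        rclass=rclass,
                        family=family_name or fam_from_class,
                        run_id=run_id,
                    )
                )
    elif dialect == "trf":
        seqid = ""
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("Sequence:"):
                    seqid = line.split(None, 1)[1].split()[0]
                    continue
                parts = line.split()
                if len(parts) < 14 or not parts[0].isdigit():
                    continue
                start, end, period = int(parts[0]), int(parts[1]), int(parts[2])
                annos.append(
                    RepeatAnnotation(
                        seqid=seqid, start=start - 1, end=end,
                        rclass="Tandem", family=f"TRF_period{period}",
                        run_id=run_id,
                    )
                )
    else:
        raise ValueError(f"unknown repeat table dialect {dialect!r}")
    return annos


def write_rmout(path: str | Path, annos: Iterable[RepeatAnnotation]) -> None:
    """Write annotations in RepeatMasker .out layout (round-trips with reader)."""
    inv_map = {"Simple": "Simple_repeat", "Unknown": "Unknown"}
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query      position in query     matching"
            "       repeat              position in  repeat\n"
            "score  div. del. ins.  sequence    begin     end    (left)"
            "    repeat         class/family         begin  end (left)   ID\n\n"
        )
        for i, a in enumerate(annos, 1):
            cls = inv_map.get(a.rclass, a.rclass)
            fh.write(
                f"{1000} 1.0 0.0 0.0 {a.seqid} {a.start + 1} {a.end} (0) + "
                f"{a.family or 'NA'} {cls}/{a.family or ''} 1 {a.end - a.start} (0) {i}\n"
            )


def write_trf_dat(path: str | Path, annos: Iterable[RepeatAnnotation]) -> None:
    """Write Tandem annotations in TRF .dat layout (round-trips with reader)."""
    by_seq: dict[str, list[RepeatAnnotation]] = {}
    for a in annos:
        by_seq.setdefault(a.seqid, []).append(a)
    with open(path, "w") as fh:
        fh.write("Tandem Repeats Finder Program\n\n")
        for seqid, group in by_seq.items():
            fh.write(f"Sequence: {seqid}\n\nParameters: 2 7 7 80 10 50 500\n\n")
            for a in group:
                period = 5
                if a.family.startswith("TRF_period"):
                    period = int(a.family[len("TRF_period"):])
                n_copies = (a.end - a.start) / period
                fh.write(
                    f"{a.start + 1} {a.end} {period} {n_copies:.1f} {period} "
                    f"95 0 1000 25 25 25 25 1.9 CONS SEQ\n"
                )


# --------------------------------------------------------------------------
# generic TSV
# --------------------------------------------------------------------------

def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
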