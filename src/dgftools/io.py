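"""Readers and writers for the plain-text genomics formats the pipeline touches.

BED3/BED6 and bedGraph/WIG are parsed line by line so that malformed input is
reported with its line number; "#" comment lines (including our provenance
headers) and "track"/"browser" lines are skipped. All writers emit a single
"#" provenance header carrying the tool version and any parameters supplied.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conservation import ConservationTrack
from .genes import GeneModel, exons_from_blocks
from .intervals import GenomicInterval, IntervalSet

__version__ = "0.1.0"


class ParseError(ValueError):
    pass


def _provenance(params: Optional[dict] = None) -> str:
    extra = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    return f"# dgftools v{__version__}" + (f" {extra}" if extra else "") + "\n"


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return (not s) or s.startswith("#") or s.startswith("track") or s.startswith("browser")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str, min_fields: int = 3, label: str = "") -> IntervalSet:
    """Read a BED file (0-based half-open, verbatim) into an IntervalSet."""
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < min_fields:
                raise ParseError(f"{path}:{lineno}: expected >= {min_fields} fields, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, strand=strand, name=name, score=score))
    return IntervalSet(intervals, label=label or os.path.basename(path))


def write_bed(ivset: IntervalSet, path: str, params: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(params))
        for iv in ivset:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Conservation: bedGraph and WIG

def read_conservation(path: str, default: float = 0.0) -> ConservationTrack:
    """Read a bedGraph or WIG conservation track (values in [0, 1])."""
    with open(path) as fh:
        head = fh.read(4096)
    if "fixedStep" in head or "variableStep" in head:
        return _read_wig(path, default)
    return _read_bedgraph(path, default)


def _read_bedgraph(path: str, default: float) -> ConservationTrack:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 fields")
            try:
                rec = (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph record") from exc
            records.append(rec)
    try:
        return ConservationTrack.from_records(records, default=default)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _read_wig(path: str, default: float) -> ConservationTrack:
    records = []
    chrom, pos, step, span = None, 0, 1, 1
    mode = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("track") or s.startswith("browser"):
                continue
            if s.startswith("fixedStep") or s.startswith("variableStep"):
                kv = dict(tok.split("=") for tok in s.split()[1:])
                mode = s.split()[0]
                chrom = kv["chrom"]
                span = int(kv.get("span", 1))
                if mode == "fixedStep":
                    pos = int(kv["start"]) - 1  # WIG declarations are 1-based
                    step = int(kv.get("step", 1))
                continue
            if mode is None or chrom is None:
                raise ParseError(f"{path}:{lineno}: data before step declaration")
            try:
                if mode == "fixedStep":
                    value = float(s)
                    records.append((chrom, pos, pos + span, value))
                    pos += step
                else:
                    p, v = s.split()
                    start = int(p) - 1
                    records.append((chrom, start, start + span, float(v)))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed WIG record") from exc
    try:
        return ConservationTrack.from_records(records, default=default)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: ConservationTrack, path: str, params: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(params))
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> Dict[str, str]:
    """Read sequences into a {name: uppercase string} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# Gene table (documented TSV dialect, BED12-style exon blocks)

GENE_TABLE_COLUMNS = (
    "gene_id", "chrom", "strand", "start", "end", "exon_sizes", "exon_starts", "utr3",
)


def read_gene_table(path: str, coordinate_base: int = 0) -> List[GeneModel]:
    """Read gene models from the package's TSV dialect.

    Columns: gene_id, chrom, strand, start, end, exon_sizes (comma list),
    exon_starts (comma list, relative to gene start), utr3 ("start-end"
    semicolon list or "."). ``coordinate_base=1`` converts a 1-based,
    end-inclusive dialect to the internal 0-based half-open convention.
    """
    genes: List[GeneModel] = []
    offset = coordinate_base
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line) or line.startswith("gene_id\t"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(GENE_TABLE_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(GENE_TABLE_COLUMNS)} fields")
            gene_id, chrom, strand = fields[0], fields[1], fields[2]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                start = int(fields[3]) - offset
                end = int(fields[4]) - offset + (1 if coordinate_base == 1 else 0)
                sizes = [int(x) for x in fields[5].split(",") if x]
                rel_starts = [int(x) for x in fields[6].split(",") if x]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field") from exc
            utr3: Tuple[Tuple[int, int], ...] = ()
            if fields[7] != ".":
                spans = []
                for token in fields[7].split(";"):
                    a, b = token.split("-")
                    spans.append((int(a) - offset, int(b) - offset + (1 if coordinate_base == 1 else 0)))
                utr3 = tuple(spans)
            genes.append(
                GeneModel(gene_id, chrom, strand, start, end,
                          exons=exons_from_blocks(start, sizes, rel_starts), utr3=utr3)
            )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str, params: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(params))
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            rel = ",".join(str(s - g.start) for s, _ in g.exons)
            utr3 = ";".join(f"{s}-{e}" for s, e in g.utr3) if g.utr3 else "."
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\t{sizes}\t{rel}\t{utr3}\n")


# ---------------------------------------------------------------------------
# Regulated-gene list (knockdown ranking, consumed as input)

def read_regulated_genes(path: str) -> List[Tuple[str, str, float]]:
    """Read (gene_id, direction, rank) triples; direction in {positive, negative}."""
    rows: List[Tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line) or line.startswith("gene_id\t"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected gene_id, direction[, rank]")
            direction = fields[1]
            if direction not in ("positive", "negative"):
                raise ParseError(f"{path}:{lineno}: direction must be positive/negative")
            rank = float(fields[2]) if len(fields) > 2 else 0.0
            rows.append((fields[0], direction, rank))
    return rows


def write_regulated_genes(rows: Iterable[Tuple[str, str, float]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance())
        fh.write("gene_id\tdirection\trank\n")
        for gene_id, direction, rank in rows:
            fh.write(f"{gene_id}\t{direction}\t{rank:g}\n")


# ---------------------------------------------------------------------------
# Peak manifest: factor name -> BED path

def read_peak_manifest(path: str) -> List[Tuple[str, str]]:
    rows: List[Tuple[str, str]] = []
    base = os.path.dirname(os.path.abspath(path))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line) or line.startswith("factor\t"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected factor, bed_path")
            bed = fields[1]
            if not os.path.isabs(bed):
                bed = os.path.join(base, bed)
            rows.append((fields[0], bed))
    return rows


def write_peak_manifest(rows: Iterable[Tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance())
        fh.write("factor\tbed_path\n")
        for factor, bed in rows:
            fh.write(f"{factor}\t{bed}\n")
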