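"""Reference genome model for Tn-seq analysis.

Loads replicon sequences and gene annotations, derives the "core" region of
each open reading frame (the central 80%, i.e. with the first and last 10%
of the ORF excluded, since insertions near the ends of a gene may not
abolish its function), the intergenic mask used for read-count
normalization, and the exact-match k-mer index used to place genomic tags.

Coordinate conventions
----------------------
External files (PTT, GFF3, reports) use 1-based inclusive coordinates;
internal arithmetic uses 0-based half-open intervals.  Every coordinate a
user sees is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "Replicon",
    "GeneRecord",
    "CoreRegion",
    "TagIndex",
    "AnnotationError",
    "FastaFormatError",
    "read_fasta",
    "read_annotation",
    "core_region",
    "intergenic_mask",
    "build_tag_index",
    "revcomp",
]

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


class AnnotationError(ValueError):
    """Raised for malformed PTT/GFF3 annotation rows."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Replicon:
    """One reference sequence (chromosome or plasmid)."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """An annotated ORF with 1-based inclusive coordinates."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"gene {self.gene_id}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CoreRegion:
    """Central 80% of an ORF; empty when core_start > core_end."""

    gene_id: str
    core_start: int
    core_end: int

    @property
    def is_empty(self) -> bool:
        return self.core_start > self.core_end


@dataclass
class TagIndex:
    """Exact-match index of all genomic k-mers on both strands.

    ``locations[kmer]`` lists every (replicon_id, 1-based forward-strand
    start of the occupied k bases, strand of origin).  A tag that reads off
    the reverse strand appears under the reverse complement of the forward
    k-mer.  k-mers containing N are unmappable and excluded.
    """

    k: int
    locations: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)

    def lookup(self, tag: str) -> list[tuple[str, int, str]]:
        return self.locations.get(tag, [])

    def multiplicity(self, tag: str) -> int:
        return len(self.locations.get(tag, ()))


def read_fasta(path: str | Path) -> list[Replicon]:
    """Read a multi-record FASTA file into Replicons.

    Sequences are upper-cased; characters outside {A,C,G,T,N} and duplicate
    record ids are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    replicons: list[Replicon] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} is empty")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FastaFormatError(
                f"{path}: record {rec.id!r} contains illegal characters {sorted(bad)}"
            )
        replicons.append(Replicon(id=rec.id, sequence=seq))
    return replicons


def _parse_ptt(path: Path, replicon_id: str) -> list[GeneRecord]:
    # NCBI protein-table dialect: two header lines then a column-header line;
    # we detect data rows by the "start..end" location in column 1.
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            loc = fields[0].strip()
            # data rows are tab-separated with a "start..end" first column;
            # anything else (title line, protein count, column headers) is
            # skipped
            if len(fields) < 2:
                continue
            if ".." not in loc:
                continue
            try:
                start_s, end_s = loc.split("..")
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError(f"{path}:{lineno}: bad location {loc!r}")
            if start > end:
                raise AnnotationError(
                    f"{path}:{lineno}: start > end in location {loc!r}"
                )
            strand = fields[1].strip() if len(fields) > 1 else "+"
            # Prefer Synonym (locus tag, col 5), then Gene (col 4), then PID.
            gene_id = ""
            for col in (5, 4, 3):
                if len(fields) > col and fields[col].strip() not in ("", "-"):
                    gene_id = fields[col].strip()
                    break
            if not gene_id:
                gene_id = f"{replicon_id}_{start}_{end}"
            product = fields[8].strip() if len(fields) > 8 else ""
            genes.append(
                GeneRecord(gene_id, replicon_id, start, end, strand, product)
            )
    return genes


def _gff3_attr(attrs: str, *keys: str) -> str | None:
    pairs = {}
    for item in attrs.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            pairs[k.strip()] = v.strip()
    for key in keys:
        if key in pairs:
            return pairs[key]
    return None


def _parse_gff3(path: Path, replicon_id: str) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = (
                fields[:9]
            )
            if ftype not in ("gene", "CDS"):
                continue
            if seqid != replicon_id:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates")
            if start > end:
                raise AnnotationError(f"{path}:{lineno}: start > end")
            gene_id = _gff3_attr(attrs, "locus_tag", "ID", "Name")
            if gene_id is None:
                gene_id = f"{replicon_id}_{start}_{end}"
            product = _gff3_attr(attrs, "product") or ""
            genes.append(
                GeneRecord(gene_id, replicon_id, start, end, strand, product)
            )
    return genes


def read_annotation(
    path: str | Path,
    format: str,
    replicon_id: str,
    replicon_length: int | None = None,
) -> list[GeneRecord]:
    """Read gene annotations for one replicon from a PTT or GFF3 file.

    Coordinates are kept 1-based inclusive; genes are returned sorted by
    start.  When *replicon_length* is given, genes extending beyond it are
    rejected.
    """
    path = Path(path)
    if format == "ptt":
        genes = _parse_ptt(path, replicon_id)
    elif format == "gff3":
        genes = _parse_gff3(path, replicon_id)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if replicon_length is not None:
        for g in genes:
            if g.end > replicon_length:
                raise AnnotationError(
                    f"gene {g.gene_id} ends at {g.end}, beyond replicon "
                    f"length {replicon_length}"
                )
    genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return genes


def core_region(gene: GeneRecord) -> CoreRegion:
    """Central 80% of a gene: trim floor(0.1 * length) from each end.

    For a gene spanning 1..1000 the core is 101..900.  Genes shorter than
    10 bp get a zero-width trim and keep their full extent.
    """
    edge = gene.length // 10
    return CoreRegion(gene.gene_id, gene.start + edge, gene.end - edge)


def intergenic_mask(
    replicons: Iterable[Replicon], genes: Iterable[GeneRecord]
) -> dict[str, list[tuple[int, int]]]:
    """Per-replicon sorted, disjoint 1-based intervals not covered by any gene.

    A position is intergenic iff it lies inside no annotated ORF (full gene
    interval, edges included in the gene).  Together the gene union and the
    mask tile each replicon exactly.
    """
    by_rep: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_rep.setdefault(g.replicon_id, []).append((g.start, g.end))
    mask: dict[str, list[tuple[int, int]]] = {}
    for rep in replicons:
        intervals = sorted(by_rep.get(rep.id, []))
        out: list[tuple[int, int]] = []
        cursor = 1
        for start, end in intervals:
            if start > cursor:
                out.append((cursor, start - 1))
            cursor = max(cursor, end + 1)
        if cursor <= rep.length:
            out.append((cursor, rep.length))
        mask[rep.id] = out
    return mask


def build_tag_index(replicons: Iterable[Replicon], k: int = 17) -> TagIndex:
    """Index every genomic k-mer of both strands for exact tag lookup."""
    if k < 1:
        raise ValueError("k must be >= 1")
    index = TagIndex(k=k)
    loc = index.locations
    for rep in replicons:
        if rep.length < k:
            raise ValueError(
                f"replicon {rep.id!r} shorter than tag length {k}"
            )
        seq = rep.sequence
        for start0 in range(rep.length - k + 1):
            kmer = seq[start0 : start0 + k]
            if "N" in kmer:
                continue
            start1 = start0 + 1
            loc.setdefault(kmer, []).append((rep.id, start1, "+"))
            loc.setdefault(revcomp(kmer), []).append((rep.id, start1, "-"))
    return index
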