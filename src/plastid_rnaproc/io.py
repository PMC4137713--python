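"""Domain types and readers/writers for sequences, annotations and report tables.

Conventions used throughout the package:

* Internal sequence alphabet is DNA over ``{A, C, G, T, N}``; ``U`` is mapped
  to ``T`` on input and transcript-side bases are rendered back as ``U`` in
  emitted report tables.
* Internal coordinates are 0-based half-open on the forward strand of a
  contig; reverse-strand genes are handled by reverse-complementing the
  extracted window.  All emitted tables use 1-based inclusive coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_CLASSES = ("CDS", "rRNA", "tRNA", "ORF")
CATEGORIES = ("photosynthesis", "housekeeping", "ORF", "unknown")

ANNOTATION_TSV_COLUMNS = (
    "gene_id",
    "genome_id",
    "start",
    "end",
    "strand",
    "feature_class",
    "category",
    "pseudogene",
)


class SequenceFormatError(ValueError):
    """Raised for malformed sequence or annotation input."""


def reverse_complement(sequence: str) -> str:
    """Reverse-complement a DNA string over {A,C,G,T,N}."""
    return sequence.translate(_COMPLEMENT)[::-1]


def to_rna(sequence: str) -> str:
    """Render an internal DNA-alphabet string in RNA notation (T -> U)."""
    return sequence.replace("T", "U")


@dataclass
class GenomeRecord:
    """A contig: identifier plus its forward-strand sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceFormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        if bad:
            pos = next(
                i for i, b in enumerate(self.sequence) if b in bad
            )
            raise SequenceFormatError(
                f"alphabet violation in record {self.id!r} at position "
                f"{pos + 1}: {self.sequence[pos]!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """One gene on a contig, 0-based half-open forward-strand interval."""

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    feature_class: str = "CDS"
    category: str = "unknown"
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise SequenceFormatError(
                f"bad strand {self.strand!r} for gene {self.gene_id!r}"
            )
        if not (0 <= self.start < self.end):
            raise SequenceFormatError(
                f"gene {self.gene_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def coding_sequence(self, genome: GenomeRecord) -> str:
        """Extract the coding-strand (mRNA-sense) sequence of this gene."""
        if self.end > len(genome):
            raise SequenceFormatError(
                f"annotation {self.gene_id!r} outside contig {genome.id!r}"
            )
        window = genome.sequence[self.start : self.end]
        return window if self.strand == "+" else reverse_complement(window)


@dataclass
class TranscriptRecord:
    """A transcript in mRNA sense, stored in the DNA alphabet."""

    id: str
    sequence: str
    source_gene_ids: list[str] = field(default_factory=list)
    provenance: str = "observed"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        if bad:
            pos = next(i for i, b in enumerate(self.sequence) if b in bad)
            raise SequenceFormatError(
                f"alphabet violation in record {self.id!r} at position "
                f"{pos + 1}: {self.sequence[pos]!r}"
            )


@dataclass
class ProteinRecord:
    """An amino-acid sequence (ortholog proteins for conservation scoring)."""

    id: str
    sequence: str
    description: str = ""


def _normalize_nucleotide(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - NUCLEOTIDE_ALPHABET
    if bad:
        pos = next(i for i, b in enumerate(seq) if b in bad)
        raise SequenceFormatError(
            f"alphabet violation in record {record_id!r} at position "
            f"{pos + 1}: {seq[pos]!r}"
        )
    return seq


def read_sequences(path: str | Path, kind: str = "genome"):
    """Read a FASTA file into domain records.

    Parameters
    ----------
    path
        FASTA file path.
    kind
        ``"genome"`` -> GenomeRecord, ``"transcript"`` -> TranscriptRecord,
        ``"protein"`` -> ProteinRecord.  Nucleotide kinds are normalized
        (uppercase, U->T) and alphabet-checked.
    """
    if kind not in ("genome", "transcript", "protein"):
        raise ValueError(f"unknown sequence kind {kind!r}")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceFormatError(f"duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        desc = rec.description[len(rec.id) :].strip()
        if kind == "protein":
            records.append(ProteinRecord(rec.id, raw.upper(), desc))
        elif kind == "genome":
            records.append(
                GenomeRecord(rec.id, _normalize_nucleotide(raw, rec.id), desc)
            )
        else:
            records.append(
                TranscriptRecord(rec.id, _normalize_nucleotide(raw, rec.id))
            )
    if not records:
        raise SequenceFormatError(f"no records in {path}")
    return records


def write_sequences(records: Iterable, path: str | Path) -> None:
    """Write domain records to FASTA (internal DNA alphabet as stored)."""
    seqrecords = [
        SeqRecord(
            Seq(r.sequence),
            id=r.id,
            description=getattr(r, "description", "") or "",
        )
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def _parse_bool(token: str) -> bool:
    t = token.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise SequenceFormatError(f"bad boolean token {token!r}")


def read_annotations(
    path: str | Path,
    dialect: str = "tsv",
    genome: GenomeRecord | None = None,
) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or the package's TSV dialect.

    GFF3 coordinates (1-based inclusive) are converted to internal 0-based
    half-open; the TSV dialect stores internal coordinates directly and has
    the columns ``gene_id, genome_id, start, end, strand, feature_class,
    category, pseudogene``.  If *genome* is supplied every interval is
    checked against the contig length.
    """
    if dialect not in ("gff3", "tsv"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    annotations: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        header_skipped = False
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "gff3":
                if len(fields) < 9:
                    raise SequenceFormatError(
                        f"{path}:{line_no}: malformed GFF3 line"
                    )
                seqid, _src, ftype, start, end, _score, strand, _phase, attrs = (
                    fields[:9]
                )
                attr_map = {}
                for item in attrs.split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        attr_map[k.strip()] = v.strip()
                gene_id = attr_map.get("ID") or attr_map.get("Name")
                if gene_id is None:
                    raise SequenceFormatError(
                        f"{path}:{line_no}: GFF3 feature lacks ID attribute"
                    )
                ann = GeneAnnotation(
                    gene_id=gene_id,
                    genome_id=seqid,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    feature_class=ftype if ftype in FEATURE_CLASSES else "CDS",
                    category=attr_map.get("category", "unknown"),
                    pseudogene=_parse_bool(attr_map.get("pseudogene", "false")),
                )
            else:
                if not header_skipped and fields[0] == "gene_id":
                    header_skipped = True
                    continue
                if len(fields) != len(ANNOTATION_TSV_COLUMNS):
                    raise SequenceFormatError(
                        f"{path}:{line_no}: expected "
                        f"{len(ANNOTATION_TSV_COLUMNS)} columns"
                    )
                ann = GeneAnnotation(
                    gene_id=fields[0],
                    genome_id=fields[1],
                    start=int(fields[2]),
                    end=int(fields[3]),
                    strand=fields[4],
                    feature_class=fields[5],
                    category=fields[6],
                    pseudogene=_parse_bool(fields[7]),
                )
            if ann.gene_id in seen:
                raise SequenceFormatError(
                    f"duplicate gene identifier {ann.gene_id!r}"
                )
            seen.add(ann.gene_id)
            if genome is not None and ann.genome_id == genome.id:
                if ann.end > len(genome):
                    raise SequenceFormatError(
                        f"annotation {ann.gene_id!r} outside contig "
                        f"{genome.id!r}"
                    )
            annotations.append(ann)
    return annotations


def write_annotations(annotations: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write annotations in the package's TSV dialect (internal coordinates)."""
    df = pd.DataFrame([asdict(a) for a in annotations])
    df = df.reindex(columns=list(ANNOTATION_TSV_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open interval -> reported 1-based inclusive."""
    return start + 1, end


def from_one_based(start1: int, end1: int) -> tuple[int, int]:
    """Reported 1-based inclusive interval -> internal 0-based half-open."""
    return start1 - 1, end1


def write_report_table(
    rows: Sequence[dict],
    columns: Sequence[str],
    path: str | Path,
) -> pd.DataFrame:
    """Write one TSV report with a fixed column order.

    Emits a header-only file for an empty result set; re-running on
    identical inputs yields byte-identical output.
    """
    out_dir = os.path.dirname(str(path))
    if out_dir and not os.path.isdir(out_dir):
        os.makedirs(out_dir, exist_ok=True)
    df = pd.DataFrame(list(rows), columns=list(columns))
    df.to_csv(path, sep="\t", index=False)
    return df
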