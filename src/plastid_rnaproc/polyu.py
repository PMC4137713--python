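"""3' poly(U) tail detection, templating classification and site annotation.

A plastid transcript captured by oligo-d(A) RT-PCR ends in a run of U
residues.  The maximal terminal U run is provisionally stripped, the body is
aligned to the genomic locus, and the tail is the stripped run.  A tail that
is no longer than the genomic T-run starting immediately after the poly(U)
site could have been transcribed from the genome (``possibly_templated``);
a tail exceeding that run must be a post-transcriptional addition.  Any
terminal A run downstream of the U run is discarded first as an
oligo-d(A) primer remnant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .editing import PairwiseAlignment, align_transcript_to_genome
from .io import GeneAnnotation, GenomeRecord, TranscriptRecord

DEFAULT_MIN_TAIL = 5


@dataclass
class PolyUCall:
    """One transcript's 3' tail call and poly(U)-site annotation."""

    transcript_id: str
    gene_id: str
    tail_length: int = 0
    site_genome_pos: int | None = None  # forward-strand coord of last aligned base
    templated_run: int = 0
    status: str = "none"  # posttranscriptional | possibly_templated | none
    utr_length: int | None = None
    internal_site: bool = False
    overlaps_downstream_cds: bool = False
    cistron_gene_ids: list[str] = field(default_factory=list)
    cistron_class: str = ""
    body_span: tuple[int, int] | None = None  # forward-strand genomic span of body
    alignment: PairwiseAlignment | None = None


@dataclass
class CompositionStats:
    gc_fraction: float
    purine_fraction: float
    length: int


CISTRON_NAMES = {1: "monocistronic", 2: "dicistronic", 3: "tricistronic"}


def cistron_class_name(n: int) -> str:
    return CISTRON_NAMES.get(n, f"{n}-cistronic")


def split_terminal_tail(sequence: str, min_tail: int) -> tuple[str, int]:
    """Split off the terminal U(T) run, discarding a terminal A-run remnant.

    Returns ``(body, tail_length)``.  If the run (after A-remnant removal)
    is shorter than ``min_tail`` nothing is stripped and the full input is
    the body — detection is non-destructive for sub-threshold runs.
    """
    trimmed = sequence.rstrip("A")
    body = trimmed.rstrip("T")
    tail_length = len(trimmed) - len(body)
    if tail_length >= min_tail:
        return body, tail_length
    return sequence, 0


def genomic_t_run(
    genome: GenomeRecord,
    site_genome_pos: int,
    strand: str,
) -> int:
    """Length of the coding-strand T-run starting right after the site.

    For a forward-strand gene this counts T's at ``site+1, site+2, ...``;
    for a reverse-strand gene it counts A's (forward strand) walking left
    from ``site-1``, which are T's on the coding strand.
    """
    run = 0
    if strand == "+":
        pos = site_genome_pos + 1
        while pos < len(genome) and genome.sequence[pos] == "T":
            run += 1
            pos += 1
    else:
        pos = site_genome_pos - 1
        while pos >= 0 and genome.sequence[pos] == "A":
            run += 1
            pos -= 1
    return run


def detect_poly_u_tail(
    transcript: TranscriptRecord,
    gene: GeneAnnotation,
    genome: GenomeRecord,
    min_tail: int = DEFAULT_MIN_TAIL,
    flank: int = 400,
    span: tuple[int, int] | None = None,
) -> PolyUCall:
    """Detect and measure a transcript's 3' poly(U) tail.

    The body (tail-stripped transcript) is aligned with the editing-module
    aligner; ``site_genome_pos`` is the genomic coordinate matched by the
    final body base.  ``span`` extends the genomic window for polycistronic
    transcripts as in :func:`align_transcript_to_genome`.
    """
    if min_tail < 1:
        raise ValueError("min_tail must be >= 1")
    body_seq, tail_length = split_terminal_tail(transcript.sequence, min_tail)
    body = TranscriptRecord(
        id=transcript.id,
        sequence=body_seq,
        source_gene_ids=list(transcript.source_gene_ids),
        provenance=transcript.provenance,
    )
    alignment = align_transcript_to_genome(body, gene, genome, flank=flank, span=span)
    last_window_pos = None
    for col in reversed(alignment.columns):
        if col.transcript_pos is not None and col.window_pos is not None:
            last_window_pos = col.window_pos
            break
    site = alignment.genomic_position(last_window_pos) if last_window_pos is not None else None

    span = None
    aligned = [c.window_pos for c in alignment.columns if c.window_pos is not None
               and c.transcript_pos is not None]
    if aligned:
        g = sorted(alignment.genomic_position(p) for p in (aligned[0], aligned[-1]))
        span = (g[0], g[1] + 1)

    call = PolyUCall(
        transcript_id=transcript.id,
        gene_id=gene.gene_id,
        tail_length=tail_length,
        site_genome_pos=site,
        body_span=span,
        alignment=alignment,
    )
    if tail_length == 0 or site is None:
        call.status = "none"
        return call
    call.templated_run = genomic_t_run(genome, site, gene.strand)
    return classify_tail_templating(call)


def classify_tail_templating(call: PolyUCall) -> PolyUCall:
    """Decide whether an observed tail can be explained by the genome.

    Conservative rule: a tail is ``possibly_templated`` iff it is no longer
    than the genomic T-run at the site; any excess U proves
    post-transcriptional addition.
    """
    if call.tail_length <= 0:
        call.status = "none"
    elif call.tail_length > call.templated_run:
        call.status = "posttranscriptional"
    else:
        call.status = "possibly_templated"
    return call


def _coding_strand_offset(pos: int, reference: int, strand: str) -> int:
    """Signed coding-strand distance from *reference* to *pos*."""
    return pos - reference if strand == "+" else reference - pos


def annotate_poly_u_site(
    call: PolyUCall,
    gene: GeneAnnotation,
    annotations: list[GeneAnnotation],
) -> PolyUCall:
    """Fill UTR length, downstream-CDS overlap and cistron content.

    ``utr_length`` is the coding-strand distance from the last base of the
    source gene's stop codon to the poly(U) site: 0 for a site immediately
    after the stop, negative (with the ``internal_site`` flag) for a site
    inside the CDS.
    """
    if call.site_genome_pos is None:
        return call
    # forward-strand coordinate of the last CDS base in coding-strand sense
    last_cds_base = gene.end - 1 if gene.strand == "+" else gene.start
    call.utr_length = _coding_strand_offset(
        call.site_genome_pos, last_cds_base, gene.strand
    )
    call.internal_site = call.utr_length < 0

    same_contig = [
        a for a in annotations
        if a.genome_id == gene.genome_id and a.strand == gene.strand
    ]
    call.overlaps_downstream_cds = any(
        a.feature_class == "CDS"
        and a.gene_id != gene.gene_id
        and a.start <= call.site_genome_pos < a.end
        for a in same_contig
    )
    if call.body_span is not None:
        lo, hi = call.body_span
        members = [
            a for a in same_contig
            if a.feature_class == "CDS" and a.start < hi and a.end > lo
        ]
        members.sort(key=lambda a: a.start, reverse=(gene.strand == "-"))
        call.cistron_gene_ids = [a.gene_id for a in members]
        call.cistron_class = cistron_class_name(len(members))
    return call


def composition_stats(sequence: str) -> CompositionStats:
    """GC and purine fractions over the non-N bases of a sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper().replace("U", "T")
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("undefined composition: sequence is all N")
    return CompositionStats(
        gc_fraction=(counts["G"] + counts["C"]) / denom,
        purine_fraction=(counts["A"] + counts["G"]) / denom,
        length=len(seq),
    )
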