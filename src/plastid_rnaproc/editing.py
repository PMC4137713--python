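"""Substitutional RNA-editing detection, classification and census.

Transcripts are globally aligned against the coding-strand genomic window of
their source locus with affine gap penalties and free end gaps on the genomic
side (a transcript usually covers only part of the extracted window).  Every
mismatch column is an editing event; insertions and deletions are never
events — they are genomic features of the locus, reported separately as
alignment remarks.

Events are classified three ways, each a pure function of the bases involved:

* transition (purine<->purine or pyrimidine<->pyrimidine) vs transversion;
* GC effect: enriching (A/U -> G/C), depleting (G/C -> A/U), neutral;
* coding effect by in-silico translation of the genomic vs edited codon under
  the bacterial/plastid genetic code (translation table 11), with premature
  stop codons that editing removes flagged as ``stop_loss``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import Align
from Bio.Seq import Seq
from scipy import stats

from .io import GeneAnnotation, GenomeRecord, TranscriptRecord, reverse_complement

# the 12 substitution types in census order, RNA notation
TYPE_ORDER = (
    "A-C", "A-G", "A-U", "C-A", "C-G", "C-U",
    "G-A", "G-C", "G-U", "U-A", "U-C", "U-G",
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})  # translation table 11

DEFAULT_MATCH = 2.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP_OPEN = -8.0
DEFAULT_GAP_EXTEND = -2.0
DEFAULT_IDENTITY_FLOOR = 0.60
DEFAULT_FLANK = 400


class UnalignableTranscript(ValueError):
    """Transcript/locus identity below the floor: wrong locus assignment."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (79.615 at 1 decimal -> 79.6, 79.65 -> 79.7)."""
    scale = 10 ** ndigits
    scaled = x * scale
    if scaled >= 0:
        result = int(scaled + 0.5)
    else:
        result = -int(-scaled + 0.5)
    return result / scale


def _type_key(from_base: str, to_base: str) -> str:
    return f"{from_base}-{to_base}".replace("T", "U")


def classify_substitution_kind(from_base: str, to_base: str) -> str:
    """Transition iff both bases are purines or both pyrimidines."""
    pair = frozenset((from_base, to_base))
    return "transition" if pair in (frozenset("AG"), frozenset("CT")) else "transversion"


def classify_gc_effect(from_base: str, to_base: str) -> str:
    weak, strong = frozenset("AT"), frozenset("GC")
    if from_base in weak and to_base in strong:
        return "enrich"
    if from_base in strong and to_base in weak:
        return "deplete"
    return "neutral"


@dataclass
class AlignmentColumn:
    transcript_pos: int | None  # 0-based in transcript, None for a gap
    window_pos: int | None      # 0-based in the coding-strand genomic window
    state: str                  # match | mismatch | insertion | deletion


@dataclass
class PairwiseAlignment:
    """Transcript-vs-locus global alignment in coding-strand orientation.

    ``window_pos`` runs 5'->3' along the extracted coding-strand window;
    ``genomic_position`` converts it back to a forward-strand coordinate.
    """

    transcript_id: str
    gene_id: str
    columns: list[AlignmentColumn]
    score: float
    strand: str
    window_start: int   # forward-strand genomic start of the window
    window_end: int     # forward-strand genomic end (half-open)
    transcript_seq: str
    window_seq: str
    identity: float = 0.0
    _genomic_to_transcript: dict[int, int] | None = field(
        default=None, repr=False, compare=False
    )

    def genomic_position(self, window_pos: int) -> int:
        """Coding-strand window position -> forward-strand genomic coordinate."""
        if self.strand == "+":
            return self.window_start + window_pos
        return self.window_end - 1 - window_pos

    def transcript_pos_at_genomic(self, genome_pos: int) -> int | None:
        """Transcript position aligned to a forward-strand coordinate, or None."""
        if self._genomic_to_transcript is None:
            self._genomic_to_transcript = {
                self.genomic_position(c.window_pos): c.transcript_pos
                for c in self.columns
                if c.window_pos is not None and c.transcript_pos is not None
            }
        return self._genomic_to_transcript.get(genome_pos)

    @property
    def n_mismatches(self) -> int:
        return sum(1 for c in self.columns if c.state == "mismatch")

    @property
    def indel_remarks(self) -> list[tuple[str, int]]:
        """(kind, run length) for each internal indel run — genomic features
        of the locus (insertions/deletions), never editing events."""
        remarks = []
        run_state, run_len = None, 0
        for col in self.columns:
            if col.state in ("insertion", "deletion"):
                if col.state == run_state:
                    run_len += 1
                else:
                    if run_state is not None:
                        remarks.append((run_state, run_len))
                    run_state, run_len = col.state, 1
            else:
                if run_state is not None:
                    remarks.append((run_state, run_len))
                run_state, run_len = None, 0
        if run_state is not None:
            remarks.append((run_state, run_len))
        return remarks


@dataclass
class EditingEvent:
    """One substitutional editing event, mRNA sense."""

    gene_id: str
    genome_pos: int          # forward-strand genomic coordinate
    transcript_pos: int
    from_base: str           # genomic coding-strand base (DNA alphabet)
    to_base: str             # transcript base (DNA alphabet)
    kind: str = ""           # transition | transversion
    gc_effect: str = ""      # enrich | deplete | neutral
    coding_effect: str = ""  # synonymous | nonsynonymous | stop_loss | stop_gain
                             # | noncoding | indeterminate
    codon_index: int | None = None
    codon_pos: int | None = None

    def __post_init__(self) -> None:
        if self.from_base == self.to_base:
            raise ValueError("editing event with identical bases")
        if not self.kind:
            self.kind = classify_substitution_kind(self.from_base, self.to_base)
        if not self.gc_effect:
            self.gc_effect = classify_gc_effect(self.from_base, self.to_base)

    @property
    def type_key(self) -> str:
        return _type_key(self.from_base, self.to_base)

    @property
    def cds_pos(self) -> int | None:
        if self.codon_index is None:
            return None
        return 3 * self.codon_index + self.codon_pos


@dataclass
class EditingSummary:
    """Per-gene or genome-wide editing census (the published-table shape)."""

    counts: dict[str, int]
    total_events: int
    surveyed_length: int
    pct_bases_edited: float
    pct_transitions: float
    pct_transversions: float
    pct_gc_enrich: float
    pct_gc_deplete: float
    pct_gc_neutral: float
    pct_nonsynonymous: float
    pct_synonymous: float
    counts_total_mismatch: bool = False

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, int] | list[int],
        surveyed_length: int,
        total_events: int | None = None,
        n_nonsynonymous: int | None = None,
        n_synonymous: int | None = None,
    ) -> "EditingSummary":
        """Build a census from a 12-type count vector.

        ``total_events`` may be given explicitly for published tables whose
        printed total disagrees with their count rows; the discrepancy is
        flagged via ``counts_total_mismatch`` and the explicit total is used
        as the percentage denominator, which is the only reading under which
        such a table's percentage rows are internally consistent.
        """
        if surveyed_length <= 0:
            raise ValueError("surveyed_length must be positive")
        if not isinstance(counts, dict):
            if len(counts) != 12:
                raise ValueError("expected a 12-type count vector")
            counts = dict(zip(TYPE_ORDER, counts))
        counts = {k: int(counts.get(k, 0)) for k in TYPE_ORDER}
        count_sum = sum(counts.values())
        total = count_sum if total_events is None else int(total_events)

        transitions = sum(counts[k] for k in ("A-G", "C-U", "G-A", "U-C"))
        enrich = deplete = 0
        for key, n in counts.items():
            f, t = (b.replace("U", "T") for b in key.split("-"))
            effect = classify_gc_effect(f, t)
            if effect == "enrich":
                enrich += n
            elif effect == "deplete":
                deplete += n

        def pct(num, den):
            return 100.0 * num / den if den else 0.0

        syn_den = None
        if n_nonsynonymous is not None and n_synonymous is not None:
            syn_den = n_nonsynonymous + n_synonymous
        return cls(
            counts=counts,
            total_events=total,
            surveyed_length=surveyed_length,
            pct_bases_edited=pct(total, surveyed_length),
            pct_transitions=pct(transitions, total),
            pct_transversions=pct(total - transitions, total),
            pct_gc_enrich=pct(enrich, total),
            pct_gc_deplete=pct(deplete, total),
            pct_gc_neutral=pct(total - enrich - deplete, total),
            pct_nonsynonymous=pct(n_nonsynonymous, syn_den) if syn_den else 0.0,
            pct_synonymous=pct(n_synonymous, syn_den) if syn_den else 0.0,
            counts_total_mismatch=total != count_sum,
        )

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        """Percentage rows rounded half-away-from-zero at printed precision."""
        return {
            name: round_half_away(getattr(self, name), ndigits)
            for name in (
                "pct_bases_edited",
                "pct_transitions",
                "pct_transversions",
                "pct_gc_enrich",
                "pct_gc_deplete",
                "pct_gc_neutral",
                "pct_nonsynonymous",
                "pct_synonymous",
            )
        }


def _make_aligner(
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps for the genomic window's overhangs: the transcript may
    # cover only part of the extracted window (query gaps at the ends)
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def align_transcript_to_genome(
    transcript: TranscriptRecord,
    gene: GeneAnnotation,
    genome: GenomeRecord,
    flank: int = DEFAULT_FLANK,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    span: tuple[int, int] | None = None,
) -> PairwiseAlignment:
    """Globally align a (tail-stripped) transcript to its genomic locus.

    The genomic window is the locus span (the gene interval, or an explicit
    forward-strand ``span`` covering a polycistron) extended by ``flank`` nt
    on both sides to capture UTRs, extracted in coding-strand orientation.
    Mismatches are cheap relative to gaps (editing density can reach ~24% in
    the most divergent genes without fragmenting the alignment).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    s_start, s_end = span if span is not None else (gene.start, gene.end)
    w_start = max(0, s_start - flank)
    w_end = min(len(genome), s_end + flank)
    window = genome.sequence[w_start:w_end]
    if gene.strand == "-":
        window = reverse_complement(window)

    aligner = _make_aligner()
    alignment = aligner.align(window, transcript.sequence)[0]
    indices = alignment.indices  # 2 x ncols, -1 marks a gap

    columns: list[AlignmentColumn] = []
    matches = transcript_cols = 0
    for gi, ti in zip(indices[0], indices[1]):
        gi = int(gi) if gi >= 0 else None
        ti = int(ti) if ti >= 0 else None
        if ti is None:
            state = "deletion"
        elif gi is None:
            state = "insertion"
        else:
            state = "match" if window[gi] == transcript.sequence[ti] else "mismatch"
        columns.append(AlignmentColumn(ti, gi, state))
        if ti is not None:
            transcript_cols += 1
            if state == "match":
                matches += 1

    # trim the window's free end-gap overhangs: they are not aligned body
    first = next((i for i, c in enumerate(columns) if c.transcript_pos is not None), 0)
    last = next(
        (i for i in range(len(columns) - 1, -1, -1) if columns[i].transcript_pos is not None),
        len(columns) - 1,
    )
    identity = matches / transcript_cols if transcript_cols else 0.0
    result = PairwiseAlignment(
        transcript_id=transcript.id,
        gene_id=gene.gene_id,
        columns=columns[first : last + 1],
        score=float(alignment.score),
        strand=gene.strand,
        window_start=w_start,
        window_end=w_end,
        transcript_seq=transcript.sequence,
        window_seq=window,
        identity=identity,
    )
    if identity < identity_floor:
        raise UnalignableTranscript(
            f"unalignable transcript {transcript.id!r} vs {gene.gene_id!r}: "
            f"identity {identity:.2f} below floor {identity_floor:.2f}"
        )
    return result


def _cds_relative(gene: GeneAnnotation, genome_pos: int) -> int:
    """Coding-strand CDS position of a forward-strand coordinate."""
    if gene.strand == "+":
        return genome_pos - gene.start
    return gene.end - 1 - genome_pos


def call_editing_events(
    alignment: PairwiseAlignment,
    gene: GeneAnnotation | list[GeneAnnotation],
) -> tuple[list[EditingEvent], int]:
    """Call one editing event per mismatch column.

    ``gene`` is the transcript's source gene, or the ordered gene list of a
    polycistron (same contig/strand).  Returns ``(events, n_masked)`` where
    ``n_masked`` counts columns skipped because either base was N.  Indel
    columns are never events.  Events inside a member CDS get codon
    coordinates; events outside every CDS (UTR, intergenic, flank) are
    ``noncoding`` and assigned to the nearest member gene 5' of the site
    (or the first member).
    """
    genes = [gene] if isinstance(gene, GeneAnnotation) else list(gene)
    if not genes:
        raise ValueError("no source gene supplied")
    events: list[EditingEvent] = []
    masked = 0
    for col in alignment.columns:
        if col.state != "mismatch":
            continue
        g_base = alignment.window_seq[col.window_pos]
        t_base = alignment.transcript_seq[col.transcript_pos]
        if g_base == "N" or t_base == "N":
            masked += 1
            continue
        gpos = alignment.genomic_position(col.window_pos)
        owner = None
        for g in genes:
            if g.feature_class == "CDS" and g.start <= gpos < g.end:
                owner = g
                break
        if owner is not None:
            cds_pos = _cds_relative(owner, gpos)
            events.append(
                EditingEvent(
                    gene_id=owner.gene_id,
                    genome_pos=gpos,
                    transcript_pos=col.transcript_pos,
                    from_base=g_base,
                    to_base=t_base,
                    codon_index=cds_pos // 3,
                    codon_pos=cds_pos % 3,
                )
            )
        else:
            # noncoding: attribute to the nearest member whose CDS lies 5'
            upstream = [g for g in genes if _cds_relative(g, gpos) >= g.length]
            owner = upstream[-1] if upstream else genes[0]
            events.append(
                EditingEvent(
                    gene_id=owner.gene_id,
                    genome_pos=gpos,
                    transcript_pos=col.transcript_pos,
                    from_base=g_base,
                    to_base=t_base,
                    coding_effect="noncoding",
                )
            )
    return events, masked


def _translate_codon(codon: str) -> str | None:
    if "N" in codon:
        return None
    return str(Seq(codon).translate(table=11))


def classify_editing_event(
    event: EditingEvent,
    genomic_codon: str,
    edited_codon: str,
) -> EditingEvent:
    """Fill the coding-effect classification of one event.

    ``edited_codon`` is the genomic codon with *all* edits at that codon
    applied, so two edits jointly converting a stop codon to a sense codon
    are each classified as ``stop_loss``.
    """
    if event.coding_effect == "noncoding":
        return event
    if "N" in genomic_codon or "N" in edited_codon:
        event.coding_effect = "indeterminate"
        return event
    g_is_stop = genomic_codon in STOP_CODONS
    e_is_stop = edited_codon in STOP_CODONS
    if g_is_stop and not e_is_stop:
        event.coding_effect = "stop_loss"
    elif e_is_stop and not g_is_stop:
        event.coding_effect = "stop_gain"
    elif _translate_codon(genomic_codon) == _translate_codon(edited_codon):
        event.coding_effect = "synonymous"
    else:
        event.coding_effect = "nonsynonymous"
    return event


def annotate_coding_effects(
    events: list[EditingEvent],
    gene: GeneAnnotation,
    genome: GenomeRecord,
) -> list[EditingEvent]:
    """Classify the coding effect of every CDS event of one gene.

    Edits sharing a codon are applied jointly before translation.
    """
    cds = gene.coding_sequence(genome)
    by_codon: dict[int, list[EditingEvent]] = {}
    for ev in events:
        if ev.gene_id == gene.gene_id and ev.codon_index is not None:
            by_codon.setdefault(ev.codon_index, []).append(ev)
    for codon_index, group in by_codon.items():
        start = 3 * codon_index
        genomic_codon = cds[start : start + 3]
        if len(genomic_codon) < 3:
            for ev in group:
                ev.coding_effect = "indeterminate"
            continue
        edited = list(genomic_codon)
        for ev in group:
            edited[ev.codon_pos] = ev.to_base
        edited_codon = "".join(edited)
        for ev in group:
            classify_editing_event(ev, genomic_codon, edited_codon)
    return events


def summarize_editing(
    events: list[EditingEvent],
    surveyed_length: int,
) -> EditingSummary:
    """Census a set of events into the 12-type table with percentage rows.

    Syn/nonsyn percentages are computed over CDS events only (noncoding and
    indeterminate events are excluded from that denominator); stop-codon
    gains and losses count as nonsynonymous.
    """
    if surveyed_length <= 0:
        raise ValueError("surveyed_length must be positive")
    counts = {k: 0 for k in TYPE_ORDER}
    n_nonsyn = n_syn = 0
    for ev in events:
        counts[ev.type_key] += 1
        if ev.coding_effect in ("nonsynonymous", "stop_loss", "stop_gain"):
            n_nonsyn += 1
        elif ev.coding_effect == "synonymous":
            n_syn += 1
    return EditingSummary.from_counts(
        counts,
        surveyed_length,
        n_nonsynonymous=n_nonsyn,
        n_synonymous=n_syn,
    )


def detect_premature_stops(
    gene: GeneAnnotation,
    genome: GenomeRecord,
) -> list[tuple[int, str]]:
    """List every in-frame stop codon strictly before the final codon.

    A CDS whose length is not a multiple of 3 is scanned in the annotated
    frame over its complete codons.
    """
    cds = gene.coding_sequence(genome)
    n_codons = len(cds) // 3
    return [
        (i, cds[3 * i : 3 * i + 3])
        for i in range(n_codons - 1)
        if cds[3 * i : 3 * i + 3] in STOP_CODONS
    ]


def verify_stop_correction(
    gene: GeneAnnotation,
    genome: GenomeRecord,
    alignment: PairwiseAlignment,
) -> list[tuple[int, str, str]]:
    """Check whether each premature genomic stop is removed in the transcript.

    Returns ``(codon_index, genomic_stop, status)`` with status ``corrected``
    (transcript codon is no longer a stop), ``uncorrected``, or ``uncovered``
    (the transcript does not span all three codon positions).
    """
    results = []
    for codon_index, stop_codon in detect_premature_stops(gene, genome):
        bases = []
        covered = True
        for off in range(3):
            cds_pos = 3 * codon_index + off
            gpos = (
                gene.start + cds_pos
                if gene.strand == "+"
                else gene.end - 1 - cds_pos
            )
            t_pos = alignment.transcript_pos_at_genomic(gpos)
            if t_pos is None:
                covered = False
                break
            bases.append(alignment.transcript_seq[t_pos])
        if not covered:
            status = "uncovered"
        else:
            status = "uncorrected" if "".join(bases) in STOP_CODONS else "corrected"
        results.append((codon_index, stop_codon, status))
    return results


def paralog_discrimination_test(
    k_obs: int,
    len_a: int,
    k_ref: int,
    len_b: int,
) -> float:
    """One-sided binomial test that paralog A is edited less than paralog B.

    The null editing rate is the reference paralog's observed rate
    ``k_ref/len_b``; the p-value is the exact lower tail
    ``P(X <= k_obs), X ~ Binomial(len_a, k_ref/len_b)``.
    """
    if len_a <= 0 or len_b <= 0:
        raise ValueError("region lengths must be positive")
    if k_ref < 0 or k_obs < 0:
        raise ValueError("event counts must be non-negative")
    p0 = k_ref / len_b
    if p0 == 0.0:
        if k_obs > 0:
            warnings.warn(
                "reference paralog has zero events; lower-tail p-value is 0",
                stacklevel=2,
            )
            return 0.0
        return 1.0
    return float(stats.binom.cdf(k_obs, len_a, p0))
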