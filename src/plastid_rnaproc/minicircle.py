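"""Episomal minicircle detection via terminal redundancy, plus circular
restriction mapping.

An assembled contig that represents a circular element carries an exact
copy of its own 5' end at its 3' end (terminal redundancy).  Removing the
redundant suffix yields the circle; a deterministic canonical rotation (an
annotated anchor gene's 5' end, else the lexicographically smallest
rotation) makes circles comparable across assemblies.  Restriction motifs
are searched on both strands of the doubled sequence so sites straddling
the circular junction are found.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .io import GeneAnnotation, GenomeRecord, reverse_complement

DEFAULT_MIN_OVERLAP = 20
ECORI_MOTIF = "GAATTC"


@dataclass
class MinicircleCall:
    contig_id: str
    is_circular: bool
    terminal_overlap: int
    circle_length: int
    circle_sequence: str = ""       # circle on the input strand, input rotation
    canonical_sequence: str = ""
    rotation_anchor: str = ""       # "gene:<id>" or "lexicographic"


@dataclass
class RestrictionSite:
    motif: str
    position: int  # 0-based on the canonical circle
    strand: str


def _longest_terminal_overlap(sequence: str, min_overlap: int) -> int:
    """Longest k < len(seq) with seq[:k] == seq[-k:], or 0 if < min_overlap."""
    n = len(sequence)
    for k in range(n - 1, min_overlap - 1, -1):
        if sequence[:k] == sequence[-k:]:
            return k
    return 0


def detect_terminal_redundancy(
    contig: GenomeRecord,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> MinicircleCall:
    """Call a contig circular if its ends share an exact overlap.

    The circle is the contig with the redundant suffix removed.  An overlap
    spanning the whole contig (perfect repeat) leaves no circle and is an
    error.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    overlap = _longest_terminal_overlap(contig.sequence, min_overlap)
    if overlap and overlap == len(contig) - 1 and len(set(contig.sequence)) == 1:
        raise ValueError(f"degenerate repeat in contig {contig.id!r}")
    if overlap >= min_overlap:
        circle = contig.sequence[: len(contig) - overlap]
        if not circle:
            raise ValueError(f"degenerate repeat in contig {contig.id!r}")
        return MinicircleCall(
            contig_id=contig.id,
            is_circular=True,
            terminal_overlap=overlap,
            circle_length=len(circle),
            circle_sequence=circle,
        )
    return MinicircleCall(
        contig_id=contig.id,
        is_circular=False,
        terminal_overlap=0,
        circle_length=0,
    )


def _smallest_rotation_index(s: str) -> int:
    """Index of the lexicographically smallest rotation (Booth's algorithm)."""
    doubled = s + s
    n = len(s)
    f = [-1] * len(doubled)
    k = 0
    for j in range(1, len(doubled)):
        sj = doubled[j]
        i = f[j - k - 1]
        while i != -1 and sj != doubled[k + i + 1]:
            if sj < doubled[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != doubled[k + i + 1]:
            if sj < doubled[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonicalize_circle(
    call: MinicircleCall,
    annotations: list[GeneAnnotation] | None = None,
) -> MinicircleCall:
    """Rotate the circle to a deterministic start.

    If an annotation on the circle is supplied the rotation starts at the
    first annotated gene's 5' end (anchor ``gene:<id>``); otherwise — or if
    no annotation lies on the circle — at the lexicographically smallest
    rotation of the input strand.
    """
    if not call.is_circular:
        raise ValueError(f"contig {call.contig_id!r} is not circular")
    circle = call.circle_sequence
    anchor_ann = None
    if annotations:
        on_circle = [
            a for a in annotations
            if a.genome_id == call.contig_id and a.start < call.circle_length
        ]
        if on_circle:
            anchor_ann = min(on_circle, key=lambda a: a.start)
        else:
            warnings.warn(
                "no annotation lies on the circle; falling back to "
                "lexicographic rotation",
                stacklevel=2,
            )
    if anchor_ann is not None:
        start = anchor_ann.start if anchor_ann.strand == "+" else anchor_ann.end - 1
        call.rotation_anchor = f"gene:{anchor_ann.gene_id}"
    else:
        start = _smallest_rotation_index(circle)
        call.rotation_anchor = "lexicographic"
    call.canonical_sequence = circle[start:] + circle[:start]
    return call


def find_restriction_sites(
    call: MinicircleCall,
    motif: str = ECORI_MOTIF,
) -> list[RestrictionSite]:
    """Find all occurrences of a restriction motif on a circle, both strands.

    Scans the doubled sequence so motifs straddling the junction are found;
    palindromic motifs (e.g. EcoRI's GAATTC) are reported once per position,
    on the forward strand.
    """
    if not call.is_circular:
        raise ValueError(f"contig {call.contig_id!r} is not circular")
    motif = motif.upper().replace("U", "T")
    circle = call.canonical_sequence or call.circle_sequence
    n = len(circle)
    if len(motif) > n:
        raise ValueError("motif longer than circle")
    doubled = circle + circle[: len(motif) - 1]
    palindromic = motif == reverse_complement(motif)
    sites: list[RestrictionSite] = []
    for pos in range(n):
        if doubled[pos : pos + len(motif)] == motif:
            sites.append(RestrictionSite(motif, pos, "+"))
    if not palindromic:
        rc = reverse_complement(motif)
        for pos in range(n):
            if doubled[pos : pos + len(motif)] == rc:
                sites.append(RestrictionSite(motif, pos, "-"))
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def digest_fragments(call: MinicircleCall, motif: str = ECORI_MOTIF) -> list[int]:
    """Fragment lengths from a complete circular digest with one enzyme.

    A single site on an L-nt circle linearizes it into one L-nt fragment.
    """
    sites = find_restriction_sites(call, motif)
    if not sites:
        return []
    n = len(call.canonical_sequence or call.circle_sequence)
    cuts = sorted({s.position for s in sites})
    if len(cuts) == 1:
        return [n]
    return [
        (cuts[(i + 1) % len(cuts)] - cuts[i]) % n or n
        for i in range(len(cuts))
    ]
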