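"""Synthetic plastid genome/transcriptome generator with a ground-truth manifest.

Emulates the statistical structure of a highly divergent, heavily processed
plastid transcriptome: a multi-gene genome with genes on both strands;
per-site substitutional editing at ~4.3% with a transition-dominated type
spectrum; editing hotspots in short (~84 bp) divergent regions at a
multiplied rate; premature in-frame stop codons (default 11 across the
genome) that editing always corrects; short 3'-UTRs (geometric, mean 30 nt)
ending at a poly(U) site; non-templated poly(U) tails of 5-19 nt, a small
fraction of sites sitting on genomic T-runs long enough to explain the tail;
pseudogene paralogs (frameshifted copies) with no editing and no tail;
dicistronic transcripts for some untailed genes read through into a tailed
neighbour; ortholog proteins whose divergence is coupled to the editing
hotspots; and one minicircle contig assembled with terminal redundancy and a
single EcoRI site.

Everything is reproducible from the seed, and the truth manifest suffices to
reconstruct every emitted transcript byte-for-byte from the genome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Seq import Seq

from .io import GeneAnnotation, GenomeRecord, TranscriptRecord, reverse_complement

# Sense codons under translation table 11 (all 64 minus TAA/TAG/TGA)
_BASES = "ACGT"
SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
]
STOP_CHOICES = ("TAA", "TAG", "TGA")

# Default editing-type weights: the census of an extended plastid
# transcriptome survey — four transitions dominate, seven low-level
# transversions (order matches editing.TYPE_ORDER).
DEFAULT_TYPE_WEIGHTS = (15, 789, 16, 8, 4, 49, 99, 8, 1, 11, 540, 11)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    seed: int = 0
    n_genes: int = 30
    gene_length_range: tuple[int, int] = (300, 1500)   # nt, multiples of 3
    intergenic_range: tuple[int, int] = (50, 300)      # nt
    editing_prob: float = 0.043                        # per CDS site
    utr_editing_prob: float = 0.016                    # per UTR site
    type_weights: tuple = DEFAULT_TYPE_WEIGHTS
    hotspot_fraction: float = 0.3
    hotspot_length: int = 84                           # nt
    hotspot_multiplier: float = 4.0
    premature_stop_count: int = 11
    polyu_fraction: float = 0.7
    tail_length_range: tuple[int, int] = (5, 19)
    templated_fraction: float = 0.07
    templated_run_range: tuple[int, int] = (6, 12)
    utr_mean: float = 30.0                             # geometric mean, nt
    pseudogene_count: int = 2
    polycistron_prob: float = 0.5
    ortholog_sub_rate: float = 0.05                    # per residue
    hotspot_extra_sub: float = 0.5                     # extra, hotspot codons
    minicircle_length: int = 2323
    minicircle_redundancy: int = 150
    minicircle_gene_length: int = 1800

    def __post_init__(self) -> None:
        for p in (
            self.editing_prob,
            self.utr_editing_prob,
            self.hotspot_fraction,
            self.polyu_fraction,
            self.templated_fraction,
            self.polycistron_prob,
            self.ortholog_sub_rate,
            self.hotspot_extra_sub,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.minicircle_redundancy >= self.minicircle_length:
            raise ValueError("terminal redundancy must be shorter than the circle")


@dataclass
class PlannedTail:
    """Per-gene 3'-end plan fixed at genome-build time."""

    gene_id: str
    tailed: bool
    tail_length: int = 0
    utr_length: int = 0
    templated_run: int = 0
    site_genome_pos: int = -1   # forward-strand coord of the last body base


@dataclass
class SyntheticTruth:
    """Ground-truth manifest; with the genome it reconstructs every transcript."""

    # per gene: list of (cds_pos, from_base, to_base, genome_pos), mRNA sense
    events: dict[str, list[tuple[int, str, str, int]]] = field(default_factory=dict)
    # per gene: list of (utr_offset, from_base, to_base, genome_pos)
    utr_events: dict[str, list[tuple[int, str, str, int]]] = field(default_factory=dict)
    tails: dict[str, PlannedTail] = field(default_factory=dict)
    premature_stops: dict[str, list[int]] = field(default_factory=dict)
    pseudogene_ids: list[str] = field(default_factory=list)
    pseudogene_source: dict[str, str] = field(default_factory=dict)
    hotspots: dict[str, tuple[int, int]] = field(default_factory=dict)  # CDS nt interval
    # transcript_id -> ordered source gene ids (transcription order)
    transcripts: dict[str, list[str]] = field(default_factory=dict)
    ortholog_subs: dict[str, list[int]] = field(default_factory=dict)   # residue indices
    minicircle: dict = field(default_factory=dict)

    def all_cds_events(self) -> set[tuple[str, int, str, str]]:
        """Planted CDS events as (gene_id, genome_pos, from, to) tuples."""
        return {
            (gid, gpos, f, t)
            for gid, evs in self.events.items()
            for (_pos, f, t, gpos) in evs
        }

    def to_json(self, path) -> None:
        payload = {
            "events": self.events,
            "utr_events": self.utr_events,
            "tails": {k: asdict(v) for k, v in self.tails.items()},
            "premature_stops": self.premature_stops,
            "pseudogene_ids": self.pseudogene_ids,
            "pseudogene_source": self.pseudogene_source,
            "hotspots": self.hotspots,
            "transcripts": self.transcripts,
            "ortholog_subs": self.ortholog_subs,
            "minicircle": self.minicircle,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + one stop codon."""
    internal = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    stop = STOP_CHOICES[rng.integers(len(STOP_CHOICES))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in internal) + stop


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(4, size=length))


def generate_genome_and_annotations(
    config: SyntheticConfig,
) -> tuple[GenomeRecord, list[GeneAnnotation], SyntheticTruth]:
    """Build the genome, annotations, and the genome-time half of the truth.

    Genes alternate between strands with ATG starts and terminal stops.
    Premature stops, hotspots, pseudogene paralogs (frameshifted copies) and
    the per-gene 3'-end plan (UTR length, tail, templated T-run — the T-run
    must be written into the genomic sequence, hence planned here) are all
    fixed at this stage and recorded in the truth manifest.
    """
    rng = np.random.default_rng([config.seed, 1])
    truth = SyntheticTruth()
    genome_id = f"synth_plastome_s{config.seed}"

    lo_c = config.gene_length_range[0] // 3
    hi_c = config.gene_length_range[1] // 3
    n = config.n_genes
    cds_list = [_random_cds(rng, int(rng.integers(lo_c, hi_c + 1))) for _ in range(n)]
    gene_ids = [f"gene{i + 1:02d}" for i in range(n)]
    strands = ["+" if i % 2 == 0 else "-" for i in range(n)]
    categories = [
        "photosynthesis" if rng.random() < 0.5 else "housekeeping" for _ in range(n)
    ]

    # premature stops: one per chosen gene, in-frame, away from the ends
    n_stops = min(config.premature_stop_count, n)
    stop_genes = sorted(rng.choice(n, size=n_stops, replace=False))
    for gi in stop_genes:
        n_codons = len(cds_list[gi]) // 3
        codon_index = int(rng.integers(5, n_codons - 5))
        stop = STOP_CHOICES[rng.integers(len(STOP_CHOICES))]
        cds = cds_list[gi]
        cds_list[gi] = cds[: 3 * codon_index] + stop + cds[3 * codon_index + 3 :]
        truth.premature_stops.setdefault(gene_ids[gi], []).append(codon_index)

    # hotspots: one codon-aligned window per chosen gene, interior to the CDS
    n_hot = int(round(config.hotspot_fraction * n))
    hot_genes = sorted(rng.choice(n, size=n_hot, replace=False))
    for gi in hot_genes:
        n_codons = len(cds_list[gi]) // 3
        span_codons = config.hotspot_length // 3
        start_codon = int(rng.integers(1, n_codons - span_codons - 1))
        truth.hotspots[gene_ids[gi]] = (
            3 * start_codon,
            3 * start_codon + config.hotspot_length,
        )

    # 3'-end plan: tail presence, UTR length, templated run
    plans: list[PlannedTail] = []
    for gi in range(n):
        tailed = rng.random() < config.polyu_fraction
        plan = PlannedTail(gene_id=gene_ids[gi], tailed=tailed)
        if tailed:
            plan.utr_length = int(rng.geometric(1.0 / config.utr_mean))
            if rng.random() < config.templated_fraction:
                run = int(rng.integers(*config.templated_run_range, endpoint=True))
                plan.templated_run = run
                plan.tail_length = int(
                    rng.integers(config.tail_length_range[0], run, endpoint=True)
                )
            else:
                plan.tail_length = int(
                    rng.integers(*config.tail_length_range, endpoint=True)
                )
        plans.append(plan)

    # assemble: [spacer gene]... with each gene's 3' region written into the
    # adjacent spacer (following spacer for + genes, preceding for - genes)
    parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    cursor = 0
    for gi in range(n):
        plan = plans[gi]
        strand = strands[gi]
        spacer_len = int(rng.integers(*config.intergenic_range, endpoint=True))
        spacer_len = max(spacer_len, plan.utr_length + plan.templated_run + 2)
        spacer = list(_random_seq(rng, spacer_len))
        if strand == "-":
            # coding-strand downstream of a minus gene runs leftward from its
            # forward-strand start: UTR then T-run, reverse-complemented
            utr = list(_random_seq(rng, plan.utr_length))
            if plan.tailed:
                if plan.utr_length:
                    while utr[-1] == "T":
                        utr[-1] = _BASES[rng.integers(4)]
                tail_region = "T" * plan.templated_run
                block = reverse_complement("".join(utr) + tail_region)
                spacer[spacer_len - len(block) :] = list(block)
                guard = spacer_len - len(block) - 1
                while spacer[guard] == "A":  # would extend the templated run
                    spacer[guard] = _BASES[rng.integers(4)]
        parts.append("".join(spacer))
        cursor += spacer_len

        start = cursor
        seq = cds_list[gi] if strand == "+" else reverse_complement(cds_list[gi])
        parts.append(seq)
        cursor += len(seq)
        annotations.append(
            GeneAnnotation(
                gene_id=gene_ids[gi],
                genome_id=genome_id,
                start=start,
                end=cursor,
                strand=strand,
                feature_class="CDS",
                category=categories[gi],
                pseudogene=False,
            )
        )
        if strand == "+" and plans[gi].tailed:
            # write UTR + templated run into the start of the next spacer;
            # done by appending a dedicated block before the next spacer
            utr = list(_random_seq(rng, plan.utr_length))
            if plan.utr_length:
                while utr[-1] == "T":
                    utr[-1] = _BASES[rng.integers(4)]
            block = "".join(utr) + "T" * plan.templated_run
            guard = list(_random_seq(rng, 1))
            while guard[0] == "T":
                guard[0] = _BASES[rng.integers(4)]
            parts.append(block + guard[0])
            cursor += len(block) + 1

    # trailing spacer so the last gene's flank exists
    tail_spacer = int(rng.integers(*config.intergenic_range, endpoint=True))
    parts.append(_random_seq(rng, tail_spacer))
    cursor += tail_spacer

    # pseudogene paralogs: frameshifted copies of functional genes, no 3' plan
    n_pseudo = min(config.pseudogene_count, n)
    # prefer longer sources so the paralog comparison has power
    order = sorted(range(n), key=lambda i: -len(cds_list[i]))
    for k in range(n_pseudo):
        src = order[k]
        src_id = gene_ids[src]
        ps_id = f"{src_id}-ps"
        cds = cds_list[src]
        del_pos = int(rng.integers(30, len(cds) - 30))
        ps_seq = cds[:del_pos] + cds[del_pos + 1 :]  # 1-nt frameshift deletion
        spacer_len = int(rng.integers(*config.intergenic_range, endpoint=True))
        parts.append(_random_seq(rng, spacer_len))
        cursor += spacer_len
        start = cursor
        parts.append(ps_seq)
        cursor += len(ps_seq)
        annotations.append(
            GeneAnnotation(
                gene_id=ps_id,
                genome_id=genome_id,
                start=start,
                end=cursor,
                strand="+",
                feature_class="CDS",
                category=categories[src],
                pseudogene=True,
            )
        )
        truth.pseudogene_ids.append(ps_id)
        truth.pseudogene_source[ps_id] = src_id
    parts.append(_random_seq(rng, 60))

    genome = GenomeRecord(
        id=genome_id,
        sequence="".join(parts),
        description="synthetic plastid genome",
    )

    # resolve forward-strand site coordinates now that layout is fixed
    by_id = {a.gene_id: a for a in annotations}
    for plan in plans:
        ann = by_id[plan.gene_id]
        if plan.tailed:
            if ann.strand == "+":
                plan.site_genome_pos = ann.end - 1 + plan.utr_length
            else:
                plan.site_genome_pos = ann.start - plan.utr_length
        truth.tails[plan.gene_id] = plan

    return genome, annotations, truth


def _draw_edit_target(
    rng: np.random.Generator, from_base: str, weights
) -> str:
    """Draw the edited base for a site, conditioned on its genomic base."""
    from .editing import TYPE_ORDER

    opts, w = [], []
    for key, weight in zip(TYPE_ORDER, weights):
        f, t = (b.replace("U", "T") for b in key.split("-"))
        if f == from_base:
            opts.append(t)
            w.append(weight)
    w = np.asarray(w, dtype=float)
    if w.sum() == 0:
        w = np.ones_like(w)
    return opts[rng.choice(len(opts), p=w / w.sum())]


def _per_base_edit_probs(
    config: SyntheticConfig, base_composition: dict[str, float]
) -> dict[str, float]:
    """Per-site editing probability for each genomic base.

    Editing must realize the configured 12-type weights *marginally* (the
    published censuses are marginal type spectra), so a site with base X is
    edited with probability ``p * w_X / f_X`` where ``w_X`` is the summed
    weight of the three types leaving X and ``f_X`` the genomic frequency of
    X.  The expected genome-wide fraction is then exactly the configured
    per-site probability, and the expected type spectrum is exactly the
    weight vector.
    """
    from .editing import TYPE_ORDER

    w = {b: 0.0 for b in _BASES}
    total = float(sum(config.type_weights))
    for key, weight in zip(TYPE_ORDER, config.type_weights):
        f = key.split("-")[0].replace("U", "T")
        w[f] += weight / total
    return {
        b: (
            min(1.0, config.editing_prob * w[b] / base_composition[b])
            if base_composition.get(b, 0.0) > 0
            else 0.0
        )
        for b in _BASES
    }


def _plan_gene_editing(
    rng: np.random.Generator,
    gene_id: str,
    cds: str,
    config: SyntheticConfig,
    hotspot: tuple[int, int] | None,
    premature_stops: list[int],
    annotation: GeneAnnotation,
    base_probs: dict[str, float],
) -> list[tuple[int, str, str, int]]:
    """Per-site Bernoulli editing plan for one CDS, mRNA sense.

    Hotspot sites are edited at a multiplied rate; every premature stop is
    forcibly corrected by a U->C edit at its first codon position (TAA->CAA,
    TAG->CAG, TGA->CGA, all sense codons), overriding any random edit in
    that codon.
    """
    stop_positions = {3 * ci + off for ci in premature_stops for off in range(3)}
    events: list[tuple[int, str, str, int]] = []
    probs = np.array([base_probs[b] for b in cds])
    if hotspot is not None:
        probs[hotspot[0] : hotspot[1]] = np.minimum(
            1.0, probs[hotspot[0] : hotspot[1]] * config.hotspot_multiplier
        )
    draws = rng.random(len(cds))
    for pos in range(len(cds)):
        if pos in stop_positions:
            continue
        if draws[pos] < probs[pos]:
            from_base = cds[pos]
            to_base = _draw_edit_target(rng, from_base, config.type_weights)
            gpos = (
                annotation.start + pos
                if annotation.strand == "+"
                else annotation.end - 1 - pos
            )
            events.append((pos, from_base, to_base, gpos))
    for ci in premature_stops:
        pos = 3 * ci
        gpos = (
            annotation.start + pos
            if annotation.strand == "+"
            else annotation.end - 1 - pos
        )
        events.append((pos, "T", "C", gpos))
    events.sort(key=lambda e: e[0])
    return events


def _apply_events(sequence: str, events) -> str:
    seq = list(sequence)
    for pos, from_base, to_base, _gpos in events:
        assert seq[pos] == from_base, "truth manifest inconsistent with genome"
        seq[pos] = to_base
    return "".join(seq)


def _coding_span(genome: GenomeRecord, start: int, end: int, strand: str) -> str:
    window = genome.sequence[start:end]
    return window if strand == "+" else reverse_complement(window)


def build_transcript_sequence(
    genome: GenomeRecord,
    annotations: list[GeneAnnotation],
    truth: SyntheticTruth,
    gene_ids: list[str],
) -> str:
    """Deterministically rebuild a transcript from genome + truth manifest.

    The body is the coding-strand genomic span from the first gene's start
    to the last gene's poly(U) site (or CDS end), with all planted CDS and
    UTR events applied; the tail is appended verbatim.  Used both by the
    generator and by the reconstruction invariant.
    """
    by_id = {a.gene_id: a for a in annotations}
    genes = [by_id[g] for g in gene_ids]
    strand = genes[0].strand
    last = genes[-1]
    plan = truth.tails[last.gene_id]
    if strand == "+":
        span_start = genes[0].start
        span_end = (plan.site_genome_pos + 1) if plan.tailed else last.end
    else:
        span_end = genes[0].end
        span_start = plan.site_genome_pos if plan.tailed else last.start
    body = _coding_span(genome, span_start, span_end, strand)

    def span_offset(gpos: int) -> int:
        return gpos - span_start if strand == "+" else span_end - 1 - gpos

    span_events = []
    for g in genes:
        for (_pos, f, t, gpos) in truth.events.get(g.gene_id, []):
            span_events.append((span_offset(gpos), f, t, gpos))
        for (_off, f, t, gpos) in truth.utr_events.get(g.gene_id, []):
            span_events.append((span_offset(gpos), f, t, gpos))
    body = _apply_events(body, span_events)
    return body + "T" * plan.tail_length


def generate_transcripts(
    genome: GenomeRecord,
    annotations: list[GeneAnnotation],
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> tuple[list[TranscriptRecord], SyntheticTruth]:
    """Emit one transcript per functional gene (or dicistron) plus pseudogenes.

    Editing is planted per site (Bernoulli, hotspot-multiplied), premature
    stops are forcibly corrected, UTRs carry low-rate editing, and tails
    follow the genome-time plan.  Where an untailed gene sits directly
    upstream of a tailed same-strand neighbour, a dicistronic transcript
    replaces the upstream gene's own transcript with probability
    ``polycistron_prob``.  Pseudogene transcripts are unedited and untailed.
    """
    rng = np.random.default_rng([config.seed, 2])
    by_id = {a.gene_id: a for a in annotations}
    functional = [a for a in annotations if not a.pseudogene]

    # base composition of the editable (functional CDS) sites, used to turn
    # the marginal type weights into per-base editing probabilities
    counts = {b: 0 for b in "ACGTN"}
    n_sites = 0
    for ann in functional:
        for b in ann.coding_sequence(genome):
            counts[b] += 1
            n_sites += 1
    composition = {b: counts[b] / n_sites for b in _BASES}
    base_probs = _per_base_edit_probs(config, composition)

    # plant CDS editing for every functional gene
    for ann in functional:
        cds = ann.coding_sequence(genome)
        truth.events[ann.gene_id] = _plan_gene_editing(
            rng,
            ann.gene_id,
            cds,
            config,
            truth.hotspots.get(ann.gene_id),
            truth.premature_stops.get(ann.gene_id, []),
            ann,
            base_probs,
        )

    # plant UTR editing (low rate) for tailed genes
    for ann in functional:
        plan = truth.tails[ann.gene_id]
        if not plan.tailed or plan.utr_length == 0:
            continue
        utr_events = []
        for off in range(plan.utr_length):
            if off == plan.utr_length - 1:
                # never edit the final UTR base: a substitution to U there
                # would merge with the tail and shift the poly(U) site
                continue
            if rng.random() < config.utr_editing_prob:
                gpos = (
                    ann.end + off if ann.strand == "+" else ann.start - 1 - off
                )
                from_base = (
                    genome.sequence[gpos]
                    if ann.strand == "+"
                    else reverse_complement(genome.sequence[gpos])
                )
                to_base = _draw_edit_target(rng, from_base, config.type_weights)
                utr_events.append((off, from_base, to_base, gpos))
        if utr_events:
            truth.utr_events[ann.gene_id] = utr_events

    # choose dicistrons: untailed gene directly upstream of a tailed
    # same-strand neighbour (genomic adjacency, transcription order)
    consumed: set[str] = set()
    pairs: list[tuple[str, str]] = []
    ordered = sorted(functional, key=lambda a: a.start)
    for i in range(len(ordered) - 1):
        a, b = ordered[i], ordered[i + 1]
        if a.strand != b.strand:
            continue
        up, down = (a, b) if a.strand == "+" else (b, a)
        if (
            not truth.tails[up.gene_id].tailed
            and truth.tails[down.gene_id].tailed
            and up.gene_id not in consumed
            and down.gene_id not in consumed
            and rng.random() < config.polycistron_prob
        ):
            pairs.append((up.gene_id, down.gene_id))
            consumed.add(up.gene_id)

    transcripts: list[TranscriptRecord] = []
    for up_id, down_id in pairs:
        tid = f"t_{up_id}_{down_id}"
        truth.transcripts[tid] = [up_id, down_id]
    for ann in functional:
        if ann.gene_id in consumed:
            continue
        tid = f"t_{ann.gene_id}"
        truth.transcripts[tid] = [ann.gene_id]

    for tid in sorted(truth.transcripts):
        gene_ids = truth.transcripts[tid]
        seq = build_transcript_sequence(genome, annotations, truth, gene_ids)
        transcripts.append(
            TranscriptRecord(
                id=tid,
                sequence=seq,
                source_gene_ids=list(gene_ids),
                provenance="synthetic",
            )
        )

    # pseudogene transcripts: genomic sequence, unedited, untailed
    for ps_id in truth.pseudogene_ids:
        ann = by_id[ps_id]
        tid = f"t_{ps_id}"
        truth.transcripts[tid] = [ps_id]
        transcripts.append(
            TranscriptRecord(
                id=tid,
                sequence=ann.coding_sequence(genome),
                source_gene_ids=[ps_id],
                provenance="synthetic",
            )
        )
    return transcripts, truth


def generate_ortholog_proteins(
    genome: GenomeRecord,
    annotations: list[GeneAnnotation],
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> list:
    """Ortholog proteins with hotspot-coupled divergence.

    Each functional gene is translated from its unedited genomic CDS with
    premature stops corrected (the forced U->C edits applied); the ortholog
    then receives residue substitutions at the base rate everywhere and at
    an elevated rate inside hotspot-overlapping codons, coupling low
    conservation to high editing density.
    """
    from .io import ProteinRecord

    rng = np.random.default_rng([config.seed, 3])
    proteins = []
    for ann in annotations:
        if ann.pseudogene:
            continue
        cds = ann.coding_sequence(genome)
        fixed = list(cds)
        for ci in truth.premature_stops.get(ann.gene_id, []):
            fixed[3 * ci] = "C"  # the forced stop-correcting edit
        aa = str(Seq("".join(fixed)).translate(table=11)).rstrip("*")
        hotspot = truth.hotspots.get(ann.gene_id)
        hot_codons = (
            range(hotspot[0] // 3, hotspot[1] // 3) if hotspot is not None else ()
        )
        residues = list(aa)
        subs = []
        for i in range(len(residues)):
            rate = config.ortholog_sub_rate
            if i in hot_codons:
                rate = min(1.0, rate + config.hotspot_extra_sub)
            if rng.random() < rate:
                choices = [a for a in AMINO_ACIDS if a != residues[i]]
                residues[i] = choices[rng.integers(len(choices))]
                subs.append(i)
        truth.ortholog_subs[ann.gene_id] = subs
        proteins.append(
            ProteinRecord(
                id=f"ortholog_{ann.gene_id}",
                sequence="".join(residues),
                description="synthetic haptophyte ortholog",
            )
        )
    return proteins


def generate_minicircle_contig(
    config: SyntheticConfig,
) -> tuple[GenomeRecord, GeneAnnotation, dict]:
    """A linear contig assembled from a circle with terminal redundancy.

    The circle carries one annotated gene and exactly one EcoRI site
    (GAATTC), junction wrap-around included; the emitted contig is the
    circle plus its first ``minicircle_redundancy`` nt.
    """
    rng = np.random.default_rng([config.seed, 4])
    L = config.minicircle_length
    motif = "GAATTC"
    circle = list(_random_seq(rng, L))

    def occurrences(seq: str) -> list[int]:
        doubled = seq + seq[: len(motif) - 1]
        return [i for i in range(len(seq)) if doubled[i : i + len(motif)] == motif]

    # scrub accidental sites, plant exactly one, re-check until unique
    site_pos = int(rng.integers(config.minicircle_gene_length + 100, L - len(motif)))
    circle_seq = ""
    for _ in range(1000):
        occ = occurrences("".join(circle))
        stray = [p for p in occ if p != site_pos]
        if not stray and occ == [site_pos]:
            circle_seq = "".join(circle)
            break
        for pos in stray:
            j = (pos + int(rng.integers(len(motif)))) % L
            circle[j] = _BASES[rng.integers(4)]
        circle[site_pos : site_pos + len(motif)] = list(motif)
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not place a unique restriction site")

    contig_id = f"synth_minicircle_s{config.seed}"
    contig = GenomeRecord(
        id=contig_id,
        sequence=circle_seq + circle_seq[: config.minicircle_redundancy],
        description="synthetic minicircle contig (terminally redundant)",
    )
    annotation = GeneAnnotation(
        gene_id="dnaK-1",
        genome_id=contig_id,
        start=50,
        end=50 + config.minicircle_gene_length,
        strand="+",
        feature_class="CDS",
        category="housekeeping",
        pseudogene=False,
    )
    truth = {
        "circle_length": L,
        "terminal_redundancy": config.minicircle_redundancy,
        "ecorisite_pos": site_pos,
        "gene_start": annotation.start,
        "gene_end": annotation.end,
    }
    return contig, annotation, truth


def generate_all(config: SyntheticConfig):
    """Run the full generator: genome, transcripts, orthologs, minicircle.

    Returns ``(genome, annotations, transcripts, proteins, contig,
    circle_annotation, truth)``; the minicircle truth is stored under
    ``truth.minicircle``.
    """
    genome, annotations, truth = generate_genome_and_annotations(config)
    transcripts, truth = generate_transcripts(genome, annotations, truth, config)
    proteins = generate_ortholog_proteins(genome, annotations, truth, config)
    contig, circle_ann, circle_truth = generate_minicircle_contig(config)
    truth.minicircle = circle_truth
    return genome, annotations, transcripts, proteins, contig, circle_ann, truth
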