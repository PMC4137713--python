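"""One-command orchestration: poly(U) calling -> editing -> windows -> minicircle.

Tails are stripped before editing analysis so a poly(U) tail is never
miscalled as a 3' editing cluster; the tail-stripped body alignment from the
poly(U) stage is reused for event calling.  All stages write TSV reports
(1-based inclusive coordinates, transcript-side bases in RNA notation) plus
a machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

from Bio.Seq import Seq

from . import __version__
from .io import (
    GeneAnnotation,
    GenomeRecord,
    TranscriptRecord,
    read_annotations,
    read_sequences,
    to_rna,
    write_annotations,
    write_report_table,
    write_sequences,
)
from .editing import (
    EditingEvent,
    UnalignableTranscript,
    annotate_coding_effects,
    call_editing_events,
    paralog_discrimination_test,
    summarize_editing,
    verify_stop_correction,
)
from .polyu import annotate_poly_u_site, detect_poly_u_tail
from .windows import (
    category_association_test,
    correlate_tracks,
    region_enrichment_test,
    window_conservation_track,
    window_editing_track,
)
from .minicircle import (
    canonicalize_circle,
    detect_terminal_redundancy,
    find_restriction_sites,
)
from .synthetic import SyntheticConfig, generate_all

logger = logging.getLogger("plastid_rnaproc")

PSEUDOGENE_SUFFIX = "-ps"


@dataclass
class RunConfig:
    """All pipeline inputs and parameters (YAML-mappable)."""

    out_dir: str = "results"
    # real-mode inputs
    genome: str | None = None
    annotations: str | None = None
    annotations_dialect: str = "tsv"
    transcripts: str | None = None
    orthologs: str | None = None
    contigs: str | None = None
    # synthetic mode
    synthetic: bool = False
    seed: int = 0
    # stage toggles
    run_polyu: bool = True
    run_editing: bool = True
    run_windows: bool = True
    run_minicircle: bool = True
    # parameters
    min_tail: int = 5
    flank: int = 400
    window: int = 60
    step: int = 3
    matrix: str = "BLOSUM62"
    min_overlap: int = 20
    motif: str = "GAATTC"
    background: str = "exclusive"


def _source_genes(
    transcript: TranscriptRecord,
    by_id: dict[str, GeneAnnotation],
) -> list[GeneAnnotation]:
    """Resolve a transcript's source genes.

    Uses explicit ``source_gene_ids`` when present; otherwise the id
    convention ``t_<gene>[_<gene>...]`` (gene ids without underscores).
    """
    ids = list(transcript.source_gene_ids)
    if not ids:
        raw = transcript.id
        if raw.startswith("t_"):
            raw = raw[2:]
        ids = [tok for tok in raw.split("_") if tok in by_id]
    genes = [by_id[i] for i in ids if i in by_id]
    if genes and len({(g.genome_id, g.strand) for g in genes}) != 1:
        raise ValueError(
            f"transcript {transcript.id!r}: source genes span contigs/strands"
        )
    return genes


def _edited_cds(gene: GeneAnnotation, genome: GenomeRecord, events) -> str:
    cds = list(gene.coding_sequence(genome))
    for ev in events:
        pos = ev.cds_pos
        if pos is not None and 0 <= pos < len(cds):
            cds[pos] = ev.to_base
    return "".join(cds)


def run_analysis(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write the report bundle.

    Returns the in-memory bundle: inputs, per-stage results, and (in
    synthetic mode) the ground-truth manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": asdict(config)}

    # ---- inputs -----------------------------------------------------------
    truth = None
    contigs: list[GenomeRecord] = []
    proteins = []
    if config.synthetic:
        syn = SyntheticConfig(seed=config.seed)
        genome, annotations, transcripts, proteins, contig, circle_ann, truth = (
            generate_all(syn)
        )
        contigs = [contig]
        annotations_all = annotations + [circle_ann]
        write_sequences([genome], out / "genome.fasta")
        write_sequences(transcripts, out / "transcripts.fasta")
        write_sequences(proteins, out / "orthologs.fasta")
        write_sequences([contig], out / "contigs.fasta")
        write_annotations(annotations_all, out / "annotations.tsv")
        truth.to_json(out / "truth.json")
        bundle["truth"] = truth
    else:
        genome = read_sequences(config.genome, "genome")[0] if config.genome else None
        annotations_all = (
            read_annotations(config.annotations, config.annotations_dialect, genome)
            if config.annotations
            else []
        )
        annotations = [a for a in annotations_all if genome and a.genome_id == genome.id]
        transcripts = (
            read_sequences(config.transcripts, "transcript")
            if config.transcripts
            else []
        )
        proteins = (
            read_sequences(config.orthologs, "protein") if config.orthologs else []
        )
        contigs = (
            read_sequences(config.contigs, "genome") if config.contigs else []
        )
    by_id = {a.gene_id: a for a in annotations}
    ortholog_by_gene = {
        p.id.removeprefix("ortholog_"): p for p in proteins
    }
    bundle.update(
        genome=genome, annotations=annotations, transcripts=transcripts
    )

    # ---- poly(U) + editing over each transcript ---------------------------
    polyu_rows, event_rows, stop_rows = [], [], []
    polyu_calls = {}
    events_by_gene: dict[str, list[EditingEvent]] = {}
    covered_positions: set[tuple[str, int]] = set()
    tailed_genes: set[str] = set()
    failures: list[str] = []

    for transcript in transcripts:
        genes = _source_genes(transcript, by_id)
        if not genes or genome is None:
            logger.warning("transcript %s: no source gene; skipped", transcript.id)
            continue
        span = (min(g.start for g in genes), max(g.end for g in genes))
        try:
            call = detect_poly_u_tail(
                transcript,
                genes[0],
                genome,
                min_tail=config.min_tail,
                flank=config.flank,
                span=span,
            )
        except UnalignableTranscript as exc:
            logger.error("%s", exc)
            failures.append(transcript.id)
            continue
        call = annotate_poly_u_site(call, genes[-1], annotations)
        polyu_calls[transcript.id] = call
        if call.status != "none":
            tailed_genes.update(g.gene_id for g in genes)
        if config.run_polyu:
            polyu_rows.append(
                {
                    "transcript_id": transcript.id,
                    "gene_id": genes[-1].gene_id,
                    "tail_length": call.tail_length,
                    "site_pos_1based": (call.site_genome_pos + 1)
                    if call.site_genome_pos is not None
                    else "",
                    "templated_run": call.templated_run,
                    "status": call.status,
                    "utr_length": call.utr_length,
                    "internal_site": call.internal_site,
                    "overlaps_downstream_cds": call.overlaps_downstream_cds,
                    "cistron_class": call.cistron_class,
                    "cistron_gene_ids": ",".join(call.cistron_gene_ids),
                }
            )

        if not config.run_editing:
            continue
        alignment = call.alignment
        events, masked = call_editing_events(alignment, genes)
        for g in genes:
            annotate_coding_effects(events, g, genome)
            gene_events = [e for e in events if e.gene_id == g.gene_id]
            seen = {
                (e.genome_pos, e.from_base, e.to_base)
                for e in events_by_gene.get(g.gene_id, [])
            }
            events_by_gene.setdefault(g.gene_id, []).extend(
                e
                for e in gene_events
                if (e.genome_pos, e.from_base, e.to_base) not in seen
            )
        for col in alignment.columns:
            if col.transcript_pos is not None and col.window_pos is not None:
                covered_positions.add(
                    (genome.id, alignment.genomic_position(col.window_pos))
                )
        for ev in events:
            event_rows.append(
                {
                    "transcript_id": transcript.id,
                    "gene_id": ev.gene_id,
                    "genome_pos_1based": ev.genome_pos + 1,
                    "transcript_pos_1based": ev.transcript_pos + 1,
                    "from_base": to_rna(ev.from_base),
                    "to_base": to_rna(ev.to_base),
                    "kind": ev.kind,
                    "gc_effect": ev.gc_effect,
                    "coding_effect": ev.coding_effect,
                    "codon_index": ev.codon_index if ev.codon_index is not None else "",
                    "codon_pos": ev.codon_pos if ev.codon_pos is not None else "",
                }
            )
        for g in genes:
            for codon_index, stop_codon, status in verify_stop_correction(
                g, genome, alignment
            ):
                stop_rows.append(
                    {
                        "gene_id": g.gene_id,
                        "transcript_id": transcript.id,
                        "codon_index": codon_index,
                        "genomic_stop": to_rna(stop_codon),
                        "status": status,
                    }
                )

    if config.run_polyu:
        write_report_table(
            polyu_rows,
            [
                "transcript_id", "gene_id", "tail_length", "site_pos_1based",
                "templated_run", "status", "utr_length", "internal_site",
                "overlaps_downstream_cds", "cistron_class", "cistron_gene_ids",
            ],
            out / "polyu_calls.tsv",
        )
        bundle["polyu_calls"] = polyu_calls

    summary = None
    if config.run_editing:
        write_report_table(
            event_rows,
            [
                "transcript_id", "gene_id", "genome_pos_1based",
                "transcript_pos_1based", "from_base", "to_base", "kind",
                "gc_effect", "coding_effect", "codon_index", "codon_pos",
            ],
            out / "editing_events.tsv",
        )
        write_report_table(
            stop_rows,
            ["gene_id", "transcript_id", "codon_index", "genomic_stop", "status"],
            out / "stop_correction.tsv",
        )
        all_events = [e for evs in events_by_gene.values() for e in evs]
        summary_rows = []
        for gene_id in sorted(events_by_gene):
            gene = by_id[gene_id]
            gene_summary = summarize_editing(
                [e for e in events_by_gene[gene_id]], max(gene.length, 1)
            )
            summary_rows.append(
                {"gene_id": gene_id, "surveyed_length": gene.length,
                 "total_events": gene_summary.total_events,
                 **{k: f"{v:.2f}" for k, v in gene_summary.rounded(2).items()}}
            )
        surveyed = len(covered_positions)
        if all_events and surveyed:
            summary = summarize_editing(all_events, surveyed)
            summary_rows.append(
                {"gene_id": "GENOME", "surveyed_length": surveyed,
                 "total_events": summary.total_events,
                 **{k: f"{v:.2f}" for k, v in summary.rounded(2).items()}}
            )
        write_report_table(
            summary_rows,
            ["gene_id", "surveyed_length", "total_events", "pct_bases_edited",
             "pct_transitions", "pct_transversions", "pct_gc_enrich",
             "pct_gc_deplete", "pct_gc_neutral", "pct_nonsynonymous",
             "pct_synonymous"],
            out / "editing_summary.tsv",
        )
        bundle["events_by_gene"] = events_by_gene
        bundle["summary"] = summary
        bundle["stop_reports"] = stop_rows

        # paralog discrimination: pseudogene vs its functional source
        paralog_rows = []
        for ann in annotations:
            if not ann.pseudogene:
                continue
            src_id = ann.gene_id.removesuffix(PSEUDOGENE_SUFFIX)
            src = by_id.get(src_id)
            if src is None:
                continue
            k_obs = len(events_by_gene.get(ann.gene_id, []))
            k_ref = len(events_by_gene.get(src_id, []))
            p = paralog_discrimination_test(k_obs, ann.length, k_ref, src.length)
            paralog_rows.append(
                {"pseudogene": ann.gene_id, "reference": src_id,
                 "k_obs": k_obs, "len_obs": ann.length,
                 "k_ref": k_ref, "len_ref": src.length,
                 "binomial_p": f"{p:.3e}"}
            )
        write_report_table(
            paralog_rows,
            ["pseudogene", "reference", "k_obs", "len_obs", "k_ref", "len_ref",
             "binomial_p"],
            out / "paralog_tests.tsv",
        )
        bundle["paralog_reports"] = paralog_rows

    # ---- sliding windows: editing vs conservation -------------------------
    if config.run_windows and config.run_editing:
        track_rows, corr_rows, enrich_rows = [], [], []
        correlations = {}
        for gene_id in sorted(events_by_gene):
            gene = by_id[gene_id]
            ortholog = ortholog_by_gene.get(gene_id)
            if (
                gene.pseudogene
                or ortholog is None
                or gene.length < config.window
                or genome is None
            ):
                continue
            gene_events = events_by_gene[gene_id]
            cds_events = [e for e in gene_events if e.cds_pos is not None]
            editing_track = window_editing_track(
                cds_events, gene.length, config.window, config.step, gene_id
            )
            edited = _edited_cds(gene, genome, cds_events)
            query = str(Seq(edited).translate(table=11)).rstrip("*").replace("*", "X")
            if not query:
                continue
            cons_track = window_conservation_track(
                query, ortholog.sequence, config.window, config.step,
                config.matrix, gene_id,
            )
            n = min(len(editing_track.starts), len(cons_track.starts))
            editing_track.starts, editing_track.values = (
                editing_track.starts[:n], editing_track.values[:n])
            cons_track.starts, cons_track.values = (
                cons_track.starts[:n], cons_track.values[:n])
            for s, e_val, c_val in zip(
                editing_track.starts, editing_track.values, cons_track.values
            ):
                track_rows.append(
                    {"gene_id": gene_id, "start_1based": s + 1,
                     "editing_fraction": f"{e_val:.4f}",
                     "conservation_score": f"{c_val:.4f}"}
                )
            try:
                corr = correlate_tracks(editing_track, cons_track)
            except ValueError as exc:
                logger.info("correlation skipped for %s: %s", gene_id, exc)
                continue
            correlations[gene_id] = corr
            corr_rows.append(
                {"gene_id": gene_id, "r": f"{corr.r:.4f}", "n": corr.n,
                 "p_value": f"{corr.p_value:.3e}"}
            )
            # most-edited candidate region (hotspot-length window, step 3)
            if cds_events and gene.length >= 84:
                counts = {}
                positions = sorted({e.cds_pos for e in cds_events})
                for s in range(0, gene.length - 84 + 1, 3):
                    counts[s] = sum(1 for p in positions if s <= p < s + 84)
                best = max(counts, key=lambda s: (counts[s], -s))
                k = counts[best]
                total_k = len(positions)
                enr = region_enrichment_test(
                    k, 84, total_k, gene.length, config.background
                )
                enrich_rows.append(
                    {"gene_id": gene_id, "region_start_1based": best + 1,
                     "region_len": 84, "k": k, "total_k": total_k,
                     "background_rate": f"{enr.background_rate:.4f}",
                     "binomial_p": f"{enr.binomial_p:.3e}",
                     "chisq_p": f"{enr.chisq_p:.3e}"}
                )
        write_report_table(
            track_rows,
            ["gene_id", "start_1based", "editing_fraction", "conservation_score"],
            out / "window_tracks.tsv",
        )
        write_report_table(
            corr_rows, ["gene_id", "r", "n", "p_value"], out / "correlations.tsv"
        )
        write_report_table(
            enrich_rows,
            ["gene_id", "region_start_1based", "region_len", "k", "total_k",
             "background_rate", "binomial_p", "chisq_p"],
            out / "enrichment.tsv",
        )
        bundle["correlations"] = correlations

        # poly(U) presence vs functional category
        photo_t = sum(
            1 for a in annotations
            if not a.pseudogene and a.category == "photosynthesis"
            and a.gene_id in tailed_genes
        )
        photo_u = sum(
            1 for a in annotations
            if not a.pseudogene and a.category == "photosynthesis"
            and a.gene_id not in tailed_genes
        )
        house_t = sum(
            1 for a in annotations
            if not a.pseudogene and a.category == "housekeeping"
            and a.gene_id in tailed_genes
        )
        house_u = sum(
            1 for a in annotations
            if not a.pseudogene and a.category == "housekeeping"
            and a.gene_id not in tailed_genes
        )
        table = [[photo_t, photo_u], [house_t, house_u]]
        assoc_rows = []
        try:
            stat, p, low = category_association_test(table)
            assoc_rows.append(
                {"photosynthesis_tailed": photo_t,
                 "photosynthesis_untailed": photo_u,
                 "housekeeping_tailed": house_t,
                 "housekeeping_untailed": house_u,
                 "chisq_stat": f"{stat:.4f}", "p_value": f"{p:.4f}",
                 "low_expected_flag": low}
            )
        except ValueError as exc:
            logger.info("category association skipped: %s", exc)
        write_report_table(
            assoc_rows,
            ["photosynthesis_tailed", "photosynthesis_untailed",
             "housekeeping_tailed", "housekeeping_untailed", "chisq_stat",
             "p_value", "low_expected_flag"],
            out / "category_association.tsv",
        )

    # ---- minicircles ------------------------------------------------------
    if config.run_minicircle:
        circle_rows = []
        circle_calls = {}
        canonical = []
        for contig in contigs:
            call = detect_terminal_redundancy(contig, config.min_overlap)
            sites = []
            if call.is_circular:
                call = canonicalize_circle(
                    call,
                    [a for a in annotations_all if a.genome_id == contig.id],
                )
                sites = find_restriction_sites(call, config.motif)
                canonical.append(
                    GenomeRecord(
                        id=f"{contig.id}_circle",
                        sequence=call.canonical_sequence,
                        description=f"canonical circle, anchor {call.rotation_anchor}",
                    )
                )
            circle_calls[contig.id] = (call, sites)
            circle_rows.append(
                {"contig_id": contig.id, "is_circular": call.is_circular,
                 "terminal_overlap": call.terminal_overlap,
                 "circle_length": call.circle_length,
                 "rotation_anchor": call.rotation_anchor,
                 "motif": config.motif, "n_sites": len(sites),
                 "site_positions_1based": ",".join(
                     str(s.position + 1) for s in sites)}
            )
        write_report_table(
            circle_rows,
            ["contig_id", "is_circular", "terminal_overlap", "circle_length",
             "rotation_anchor", "motif", "n_sites", "site_positions_1based"],
            out / "minicircles.tsv",
        )
        if canonical:
            write_sequences(canonical, out / "canonical_circles.fasta")
        bundle["minicircles"] = circle_calls

    # ---- manifest ---------------------------------------------------------
    stages = [
        name
        for name, on in (
            ("polyu", config.run_polyu),
            ("editing", config.run_editing),
            ("windows", config.run_windows and config.run_editing),
            ("minicircle", config.run_minicircle),
        )
        if on
    ]
    manifest = {
        "version": __version__,
        "stages": stages,
        "seed": config.seed if config.synthetic else None,
        "parameters": asdict(config),
        "n_transcripts": len(transcripts),
        "n_unalignable": len(failures),
        "unalignable": failures,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    bundle["manifest"] = manifest
    return bundle


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
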