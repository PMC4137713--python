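"""Editing detection and classification against independent oracles."""

import math
import random
from functools import lru_cache

import pytest
from hypothesis import given, strategies as st

from plastid_rnaproc.editing import (
    EditingEvent,
    EditingSummary,
    UnalignableTranscript,
    align_transcript_to_genome,
    annotate_coding_effects,
    call_editing_events,
    classify_editing_event,
    classify_gc_effect,
    classify_substitution_kind,
    detect_premature_stops,
    paralog_discrimination_test,
    round_half_away,
    summarize_editing,
    verify_stop_correction,
)
from plastid_rnaproc.io import GeneAnnotation, GenomeRecord, TranscriptRecord, reverse_complement

MATCH, MISMATCH, OPEN, EXTEND = 2.0, -1.0, -8.0, -2.0


def alignment_score_oracle(target: str, query: str) -> float:
    """Independent affine-gap global aligner with free query-gap end runs.

    Exhaustive dynamic programme over (target index, query index, previous
    operation); a deletion (query gap) is free while no query base has been
    consumed yet or after the last one — the same scoring contract as the
    production aligner, implemented from the recurrence directly.
    """

    n, m = len(target), len(query)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == n and j == m:
            return 0.0
        options = []
        if i < n and j < m:
            s = MATCH if target[i] == query[j] else MISMATCH
            options.append(s + best(i + 1, j + 1, "M"))
        if i < n:  # query gap (deletion of target base)
            if j == 0 or j == m:
                cost = 0.0  # free end gap on the genomic window
            else:
                cost = EXTEND if prev == "D" else OPEN
            options.append(cost + best(i + 1, j, "D"))
        if j < m:  # target gap (transcript insertion)
            cost = EXTEND if prev == "I" else OPEN
            options.append(cost + best(i, j + 1, "I"))
        return max(options)

    return best(0, 0, "start")


def _locus(sequence: str, strand: str = "+") -> tuple[GenomeRecord, GeneAnnotation]:
    genome = GenomeRecord("c", sequence)
    gene = GeneAnnotation("g1", "c", 0, len(sequence), strand)
    return genome, gene


class TestAlignment:
    def test_identical_sequences_all_match(self):
        genome, gene = _locus("ATGGCCAAATTTGGGTAA")
        t = TranscriptRecord("t", genome.sequence)
        aln = align_transcript_to_genome(t, gene, genome, flank=0)
        assert {c.state for c in aln.columns} == {"match"}
        assert aln.identity == 1.0

    def test_single_substitution_single_mismatch_column(self):
        seq = "ATGGCCAAATTTGGGTAA"
        genome, gene = _locus(seq)
        k = 7
        t = TranscriptRecord("t", seq[:k] + "G" + seq[k + 1 :])
        aln = align_transcript_to_genome(t, gene, genome, flank=0)
        mism = [c for c in aln.columns if c.state == "mismatch"]
        assert len(mism) == 1 and mism[0].window_pos == k

    @pytest.mark.parametrize(
        "target,query",
        [
            ("ATGGCCAAATTTGGG", "ATGGCCTTTGGG"),       # 3-nt deletion
            ("ATGGCCAAATTT", "ATGGACAAATTT"),          # one substitution
            ("ATGCATGCATGCAT", "ATGCATATGCAT"),        # 2-nt deletion in repeat
            ("ACGTACGTACGT", "ACGTACGTACGTAAA"),       # 3-nt insertion at end
        ],
    )
    def test_score_matches_exhaustive_dp_oracle(self, target, query):
        genome, gene = _locus(target)
        aln = align_transcript_to_genome(
            TranscriptRecord("t", query), gene, genome, flank=0
        )
        assert aln.score == alignment_score_oracle(target, query)

    def test_indels_reported_as_remarks_not_events(self):
        genome, gene = _locus("ATGGCCAAATTTGGG")
        aln = align_transcript_to_genome(
            TranscriptRecord("t", "ATGGCCTTTGGG"), gene, genome, flank=0
        )
        events, _ = call_editing_events(aln, gene)
        assert events == []
        assert ("deletion", 3) in aln.indel_remarks

    def test_low_identity_raises_unalignable(self):
        genome, gene = _locus("ATGGCCAAATTTGGGACT")
        with pytest.raises(UnalignableTranscript):
            align_transcript_to_genome(
                TranscriptRecord("t", "CCTTAGGACTGACTGAGT"), gene, genome, flank=0
            )


class TestEventCalling:
    def test_no_mismatches_no_events(self):
        genome, gene = _locus("ATGAAACCCGGGTAA")
        aln = align_transcript_to_genome(
            TranscriptRecord("t", genome.sequence), gene, genome, flank=0
        )
        assert call_editing_events(aln, gene) == ([], 0)

    def test_codon_arithmetic(self):
        # substitution at CDS position 30 sits in codon 10 (0-based), pos 0
        seq = "ATG" + "AAA" * 12
        genome, gene = _locus(seq)
        t = TranscriptRecord("t", seq[:30] + "G" + seq[31:])
        aln = align_transcript_to_genome(t, gene, genome, flank=0)
        (ev,), _ = call_editing_events(aln, gene)
        assert (ev.from_base, ev.to_base) == ("A", "G")
        assert (ev.codon_index, ev.codon_pos) == (10, 0)

    def test_n_columns_masked_not_called(self):
        seq = "ATGAANCCCGGGTAA"
        genome, gene = _locus(seq)
        t = TranscriptRecord("t", "ATGAATCCCGGGTAA")
        aln = align_transcript_to_genome(t, gene, genome, flank=0)
        events, masked = call_editing_events(aln, gene)
        assert events == [] and masked == 1

    def test_reverse_strand_events_reported_in_mrna_sense(self):
        # coding-strand A->G edit on a reverse gene must surface as A->G
        cds = "ATGAAACCCGGGTAA"
        genome_seq = "TTTT" + reverse_complement(cds) + "GGGG"
        genome = GenomeRecord("c", genome_seq)
        gene = GeneAnnotation("g1", "c", 4, 4 + len(cds), "-")
        edited = cds[:4] + "G" + cds[5:]  # A->G at CDS position 4
        aln = align_transcript_to_genome(
            TranscriptRecord("t", edited), gene, genome, flank=2
        )
        (ev,), _ = call_editing_events(aln, gene)
        assert (ev.from_base, ev.to_base) == ("A", "G")
        assert (ev.codon_index, ev.codon_pos) == (1, 1)

    def test_planted_events_recovered_exactly(self, default_run, default_truth):
        called = {
            (e.gene_id, e.genome_pos, e.from_base, e.to_base)
            for evs in default_run["events_by_gene"].values()
            for e in evs
            if e.codon_index is not None
        }
        planted = default_truth.all_cds_events()
        assert called == planted  # precision = recall = 1


class TestClassification:
    @pytest.mark.parametrize(
        "f,t,kind,gc",
        [
            ("A", "G", "transition", "enrich"),
            ("G", "C", "transversion", "neutral"),
            ("T", "C", "transition", "enrich"),
            ("C", "A", "transversion", "deplete"),
            ("A", "T", "transversion", "neutral"),
            ("G", "T", "transversion", "deplete"),
        ],
    )
    def test_kind_and_gc_effect(self, f, t, kind, gc):
        assert classify_substitution_kind(f, t) == kind
        assert classify_gc_effect(f, t) == gc

    def test_stop_codon_jointly_edited_to_glutamine(self):
        # genomic TGA edited at two positions to CAA: both events are
        # stop losses and the edited codon translates to glutamine
        ev1 = EditingEvent("g", 0, 0, "T", "C", codon_index=0, codon_pos=0)
        ev2 = EditingEvent("g", 1, 1, "G", "A", codon_index=0, codon_pos=1)
        for ev in (ev1, ev2):
            classify_editing_event(ev, "TGA", "CAA")
            assert ev.coding_effect == "stop_loss"
        from Bio.Seq import Seq

        assert str(Seq("CAA").translate(table=11)) == "Q"

    def test_joint_codon_application_via_annotate(self):
        seq = "ATGTGAAAATAA"
        genome, gene = _locus(seq)
        t = TranscriptRecord("t", "ATGCAAAAATAA")
        aln = align_transcript_to_genome(t, gene, genome, flank=0)
        events, _ = call_editing_events(aln, gene)
        annotate_coding_effects(events, gene, genome)
        assert [e.coding_effect for e in events] == ["stop_loss", "stop_loss"]

    def test_synonymous_vs_nonsynonymous(self):
        ev = EditingEvent("g", 2, 2, "A", "G", codon_index=0, codon_pos=2)
        classify_editing_event(ev, "CCA", "CCG")  # Pro -> Pro
        assert ev.coding_effect == "synonymous"
        ev2 = EditingEvent("g", 0, 0, "A", "G", codon_index=0, codon_pos=0)
        classify_editing_event(ev2, "AAA", "GAA")  # Lys -> Glu
        assert ev2.coding_effect == "nonsynonymous"


KARENIA_COUNTS = [26, 59, 0, 1, 0, 17, 15, 24, 0, 0, 116, 2]


class TestSummary:
    def test_empty_events(self):
        s = summarize_editing([], 1000)
        assert s.total_events == 0 and s.pct_bases_edited == 0.0

    def test_published_census_reproduced(self):
        s = EditingSummary.from_counts(KARENIA_COUNTS, 5473)
        assert round_half_away(s.pct_bases_edited, 2) == 4.75
        r = s.rounded(1)
        assert r["pct_transitions"] == 79.6
        assert r["pct_transversions"] == 20.4
        assert r["pct_gc_enrich"] == 78.1
        assert r["pct_gc_deplete"] == 12.7
        assert r["pct_gc_neutral"] == 9.2

    def test_tally_conservation_and_permutation_invariance(self, default_run):
        events = [
            e for evs in default_run["events_by_gene"].values() for e in evs
        ]
        s = summarize_editing(events, 10_000)
        assert sum(s.counts.values()) == len(events) == s.total_events
        shuffled = list(events)
        random.Random(7).shuffle(shuffled)
        assert summarize_editing(shuffled, 10_000) == s

    def test_generator_truth_tally_matches(self, default_run, default_truth):
        from collections import Counter

        planted = Counter(
            f"{f}-{t}".replace("T", "U")
            for evs in default_truth.events.values()
            for (_p, f, t, _g) in evs
        )
        called_cds = [
            e
            for evs in default_run["events_by_gene"].values()
            for e in evs
            if e.codon_index is not None
        ]
        s = summarize_editing(called_cds, 10_000)
        assert {k: v for k, v in s.counts.items() if v} == dict(planted)

    def test_surveyed_length_must_be_positive(self):
        with pytest.raises(ValueError):
            summarize_editing([], 0)


class TestPrematureStops:
    def test_terminal_stop_is_not_premature(self):
        genome, gene = _locus("ATGAAATAG")
        assert detect_premature_stops(gene, genome) == []

    def test_planted_stop_found_by_direct_scan(self):
        codons = ["ATG"] + ["AAA"] * 18 + ["TAA"]
        codons[5] = "TGA"
        genome, gene = _locus("".join(codons))
        assert detect_premature_stops(gene, genome) == [(5, "TGA")]

    def test_all_planted_stops_recovered(self, default_run, default_truth, annotations_by_id):
        detected = {
            (gid, ci)
            for gid, a in annotations_by_id.items()
            if not a.pseudogene
            for ci, _codon in detect_premature_stops(a, default_run["genome"])
        }
        planted = {
            (gid, ci)
            for gid, idxs in default_truth.premature_stops.items()
            for ci in idxs
        }
        assert detected == planted
        assert len(planted) == 11

    def test_stop_correction_statuses(self):
        codons = ["ATG", "TGA", "AAA", "CCC", "TAA"]
        genome, gene = _locus("".join(codons))
        corrected = TranscriptRecord("t", "ATGCAAAAACCCTAA")
        aln = align_transcript_to_genome(corrected, gene, genome, flank=0)
        assert verify_stop_correction(gene, genome, aln) == [(1, "TGA", "corrected")]
        uncorrected = TranscriptRecord("t", genome.sequence)
        aln = align_transcript_to_genome(uncorrected, gene, genome, flank=0)
        assert verify_stop_correction(gene, genome, aln) == [(1, "TGA", "uncorrected")]
        downstream = TranscriptRecord("t", "AAACCCTAA")  # starts after the stop
        aln = align_transcript_to_genome(downstream, gene, genome, flank=0)
        assert verify_stop_correction(gene, genome, aln) == [(1, "TGA", "uncovered")]


def binomial_cdf_oracle(k: int, n: int, p: float) -> float:
    """Exact lower tail by direct enumeration (n small)."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1)
    )


class TestParalogDiscrimination:
    def test_matches_exact_enumeration(self):
        for n, p0_counts in [(10, (1, 20)), (20, (3, 60)), (15, (5, 100))]:
            k_ref, len_b = p0_counts
            for k in range(0, 6):
                expected = binomial_cdf_oracle(k, n, k_ref / len_b)
                assert paralog_discrimination_test(k, n, k_ref, len_b) == pytest.approx(
                    expected, abs=1e-12
                )

    def test_zero_events_closed_form(self):
        # P(X = 0) with n = 10, p0 = 0.05 is 0.95^10
        p = paralog_discrimination_test(0, 10, 5, 100)
        assert p == pytest.approx(0.95**10, abs=1e-12)

    def test_depleted_paralog_is_significant(self):
        # one event vs fifteen over equal-length regions
        assert paralog_discrimination_test(1, 400, 15, 400) < 1e-5

    def test_expected_count_not_significant(self):
        # observing exactly the expected count sits near the distribution median
        p = paralog_discrimination_test(20, 400, 20, 400)
        assert 0.5 < p < 0.65

    def test_zero_reference_rate_warns(self):
        with pytest.warns(UserWarning):
            assert paralog_discrimination_test(1, 100, 0, 100) == 0.0


@given(st.sampled_from("ACGT"), st.sampled_from("ACGT"))
def test_classification_pure_and_total(f, t):
    if f == t:
        return
    kind = classify_substitution_kind(f, t)
    gc = classify_gc_effect(f, t)
    assert kind in ("transition", "transversion")
    assert gc in ("enrich", "deplete", "neutral")
    # symmetry: reversing the substitution keeps the kind, flips the GC effect
    assert classify_substitution_kind(t, f) == kind
    flipped = classify_gc_effect(t, f)
    assert {gc, flipped} in ({"enrich", "deplete"}, {"neutral"})
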