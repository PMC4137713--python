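# Methods

`plastid-rnaproc` analyses transcript processing in highly divergent plastid
genomes of the kind found in fucoxanthin dinoflagellates: substitutional RNA
editing, 3′ poly(U) tail addition, their relationship to sequence
conservation, and episomal minicircles. This note records the models and
procedures implemented, the parameters that matter, what the synthetic data
generator does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Coordinate and alphabet conventions

All sequences are stored in the DNA alphabet (`U` → `T` on input); all
comparisons between transcript and genome happen in one alphabet, and
transcript-side bases are rendered back as `U` only in emitted reports.
Internal coordinates are 0-based half-open on the forward strand;
reverse-strand genes are handled by reverse-complementing the extracted
window, and every emitted table uses 1-based inclusive coordinates. `N`
bases are carried through but never participate in editing or tail calls
(columns touching an `N` are counted as masked).

## Transcript–genome alignment

Each transcript is aligned globally against the coding-strand genomic window
of its source locus (the gene interval, or the full span of a polycistron),
extended by a flank (default 400 nt) to capture UTRs. Scoring: match +2,
mismatch −1, gap open −8, gap extend −2, with free end gaps on the genomic
side only. Mismatches are deliberately cheap relative to gaps: editing
density can reach ~24% of positions in the most divergent genes, and an
aligner with conventional mismatch penalties would fragment exactly the
alignments that matter most. Transcripts whose aligned identity falls below
a configurable floor (default 60%) are rejected as unalignable — a wrong
locus assignment — and logged rather than silently scored.

Every mismatch column is one editing event. Indels between transcript and
genome are *never* events: editing in this system is substitutional, and
insertion/deletion differences (e.g. a frameshift in a pseudogene copy) are
genomic features, reported as alignment remarks.

## Event classification and census

Each event is classified by three pure functions of the bases involved:

* **kind** — transition iff {from, to} is {A,G} or {C,U}; else transversion;
* **GC effect** — enriching for A/U → G/C, depleting for G/C → A/U, neutral
  for A↔U and G↔C;
* **coding effect** — by in-silico translation of the genomic versus edited
  codon under the bacterial/plastid genetic code (translation table 11).
  All edits sharing a codon are applied jointly before translation, so two
  edits that together convert a TGA stop into a CAA glutamine codon are each
  a `stop_loss`. UTR events are `noncoding`; codons containing `N` are
  `indeterminate` and excluded from the synonymous/nonsynonymous
  denominator. Stop gains and losses count as nonsynonymous.

The census tallies events into the 12-type vector
(A-C, A-G, A-U, C-A, C-G, C-U, G-A, G-C, G-U, U-A, U-C, U-G) with percentage
rows for bases edited, transitions/transversions, the three GC effects, and
synonymous/nonsynonymous (over CDS events only, so the pair sums to 100%).
Percentages are rounded half-away-from-zero at the printed precision; this
convention reproduces published census tables exactly from their count rows.
`EditingSummary.from_counts` accepts an explicit event total for published
tables whose printed total disagrees with their own count rows; the
discrepancy is flagged (`counts_total_mismatch`) and the explicit total used
as the percentage denominator — the only reading under which such a table's
percentage rows are internally consistent.

## Premature stop codons

Premature stops are every in-frame TAA/TAG/TGA strictly before the final
codon of an annotated CDS (a CDS whose length is not a multiple of 3 is
scanned over its complete codons in the annotated frame). Against a
transcript alignment, each stop is `corrected` if the transcript codon at
that index is no longer a stop, `uncorrected` if it is, and `uncovered` if
the transcript does not span all three positions.

## Pseudogene discrimination

Whether a paralog is edited less than its functional counterpart is tested
with an exact one-sided binomial test: with `k_ref` events over `len_b` nt in
the reference paralog, the null rate is `p0 = k_ref/len_b` and the p-value is
the lower tail `P(X ≤ k_obs)` for `X ~ Binomial(len_a, p0)`. One-sided in
the direction of depletion because the scientific claim is "significantly
fewer events". A zero reference rate with observed events yields p = 0 with
a warning.

## Poly(U) tail calling

The maximal terminal U run is provisionally stripped (any trailing A run is
discarded first, as an oligo-d(A) primer remnant of the RT protocol this
assay emulates); the body is aligned as above; the tail length is the
stripped run and the poly(U) site is the genomic coordinate matched by the
final body base. Runs shorter than `min_tail` (default 5 nt) are restored
untouched and the call is `none` — detection is non-destructive. The
default of 5 suppresses single-base noise while passing every tail length
the system is known to produce (5–19 nt); it is configurable.

**Templating rule.** The genomic coding-strand T-run starting immediately
after the site is measured; a tail is `possibly_templated` iff
`tail_length ≤ templated_run` and `posttranscriptional` otherwise. This is
deliberately conservative: a tail fully explainable by a genomic T-tract may
be a primer-misannealing artifact, while any excess U (e.g. a 19-nt tail on
a T12 tract) proves post-transcriptional addition. The terminal run is
strict (no non-U bases tolerated); the slack is configurable but defaults
to 0 because mixed tails have not been described.

**Site annotation.** `utr_length` is the coding-strand distance from the
last base of the source gene's stop codon to the site — 0 for a site
immediately after the stop, negative (flagged `internal site`) for a site
inside the CDS, which is a reportable observation, not an error. The site
is checked for overlap with any same-strand downstream CDS, and the cistron
content (mono-/di-/tricistronic) is the ordered list of same-strand CDSs the
aligned body intersects.

## Sliding windows, correlation, enrichment

Editing frequency and protein-level conservation are each scored over a
60-bp window sliding along the CDS with a default step of 3 nt. The step is
codon-aligned so every window covers whole codons and its translation is
well defined; window length must be divisible by 3.

Conservation comes from **one** global protein alignment (BLOSUM62, gap open
−11, extend −1, free end gaps) of the edited-transcript translation against
the ortholog, then per-window summation — not per-window local searches,
which would be unstable and underdetermined. Per query residue: 1 for an
identity, 0.5 for a positive (aligned pair with positive matrix score that
is not an identity), 0 otherwise, including residues aligned to gaps; a
window's score averages its window/3 codons.

The two tracks are compared with a sample Pearson correlation; the p-value
comes from the t-distribution with n−2 degrees of freedom, two-sided.
Constant tracks are a hard error (zero variance), not an NaN.

Locally elevated editing is tested two ways: an exact binomial upper tail
`P(X ≥ k)` for the region's `k` events over `n` nt against the background
rate, and a 1-df Pearson chi-squared test on the 2×2 region-versus-rest
table, without continuity correction (switchable; the choice is documented
because it is not determined by the underlying analysis being reproduced).
The background **excludes** the tested region by default
(`background=exclusive`): including the region's own events inflates the
null rate and biases the test toward non-significance; an `inclusive` mode
is provided as a deviation knob. Gene-category association (e.g. poly(U)
presence × photosynthesis/housekeeping) uses the same chi-squared machinery
and flags expected counts below 5. No multiple-testing correction is
applied: statistics are reported per gene.

## Minicircle detection

A contig assembled from a circular element carries an exact copy of its 5′
end at its 3′ end. The longest exact suffix–prefix overlap of at least
`min_overlap` nt (default 20 — long enough that chance terminal identity at
these contig sizes is negligible) makes the contig circular; the circle is
the contig minus the redundant suffix, so
`circle_length + terminal_overlap = contig length` always. Only exact
overlaps are accepted, matching the end-identity signature being detected.

The canonical rotation starts at an annotated anchor gene's 5′ end when one
lies on the circle, else at the lexicographically smallest rotation (Booth's
algorithm); either way the result is rotation-independent. Restriction
motifs are scanned over the doubled sequence so sites straddling the
junction are found, on both strands, with palindromic motifs (EcoRI GAATTC)
reported once per position. A single site on an L-nt circle digests to one
L-nt linear fragment.

## Synthetic data generator

The generator emulates the statistical structure this analysis assumes, with
a truth manifest sufficient to rebuild every transcript byte-for-byte.
Defaults are the emulated study conditions:

| parameter | default | role |
|---|---|---|
| `n_genes` | 30 | functional genes, strands alternating |
| `gene_length_range` | 300–1,500 nt | uniform over codon counts |
| `intergenic_range` | 50–300 nt | spacers (extended if a 3′ plan needs room) |
| `editing_prob` | 0.043 | expected per-site CDS editing fraction |
| `type_weights` | extended-census counts | marginal 12-type spectrum |
| `hotspot_fraction` / length / multiplier | 0.3 / 84 nt / 4× | divergent-region hotspots |
| `premature_stop_count` | 11 | in-frame stops planted genome-wide |
| `polyu_fraction` | 0.7 | genes whose transcripts receive a tail |
| `tail_length_range` | 5–19 nt | poly(U) tail lengths |
| `templated_fraction` / run range | 0.07 / 6–12 nt | sites sitting on genomic T-runs |
| `utr_mean` | 30 nt | geometric 3′-UTR length |
| `utr_editing_prob` | 0.016 | per-site UTR editing |
| `pseudogene_count` | 2 | frameshifted paralog copies |
| `polycistron_prob` | 0.5 | untailed gene read through into a tailed neighbour |
| `ortholog_sub_rate` / `hotspot_extra_sub` | 0.05 / 0.5 | ortholog divergence, hotspot-coupled |
| minicircle length / redundancy | 2,323 / 150 nt | one EcoRI site planted |

Editing is planted independently per site (Bernoulli), with no positional
autocorrelation beyond the hotspot intervals — the simplest structure
consistent with hotspots being the observed clustering. Because the
published censuses are *marginal* type spectra, a site with genomic base X
is edited with probability `p·w_X/f_X` (w_X: summed weight of types leaving
X; f_X: genomic frequency of X), and the target base follows the
conditional weights. This makes the expected genome-wide fraction exactly
`editing_prob` and the expected type spectrum exactly the weight vector;
with uniform per-site probabilities instead, the realized spectrum would be
flattened toward the genome's base composition.

Every planted premature stop is forcibly corrected by a U→C edit at its
first codon position (TAA→CAA, TAG→CAG, TGA→CGA, all sense codons) rather
than left to chance, so the universal-correction property is reproducible by
construction. UTRs are genomic sequence (so bodies align contiguously); the
final UTR base is never edited to U, and the genomic base after a
non-templated site is never T, so the planted tail/site/run triple is
exactly recoverable. Dicistrons replace the upstream gene's own transcript
(chosen among untailed genes directly upstream of a tailed same-strand
neighbour), so each planted event is emitted exactly once per gene context.
Ortholog proteins are translations of the stop-corrected genomic CDS with
residue substitutions at the base rate, plus extra substitutions in
hotspot-overlapping codons — the coupling that makes editing and
conservation anticorrelate.

**What the generator does not emulate:** sequencing error, RT-PCR chimeras,
transcript abundance, mixed-base tails, editing autocorrelation beyond
hotspots, genuine phylogenetic divergence (ortholog substitutions are
uniform over amino acids rather than matrix-biased), or base-composition
skew. Passing truth-recovery tests therefore demonstrates correctness of
the calling logic under clean alignments, not robustness to noisy real
products; the identity floor and masking behaviour are exercised
separately with constructed inputs.

## Numerical and degenerate-input choices

* Rounding in census reports: half away from zero at printed precision.
* Percentage denominators are zero-guarded (0 events → 0%, not NaN).
* Alignment ties: the aligner's first optimal alignment is taken;
  deterministic for fixed inputs and parameters.
* A homopolymer or full-length-repeat contig is a "degenerate repeat" error
  in circle detection rather than a 0- or 1-nt circle.
* Binomial tests are exact (no normal approximation) at all sizes used.
* The per-base editing probability is clipped at 1 (relevant only for
  extreme weight/composition combinations).
* Sub-seeds for the generator's stages are derived from the user seed via
  `numpy` seed sequences, so stages are independently reproducible.

## Problem sizes

The default synthetic data set (30 genes, ~33 kb genome, ~1,200 planted
events) runs through the complete pipeline in a few seconds; the
seed-robustness check of the editing–conservation correlation evaluates 100
generator seeds on the longest hotspot gene each, about ten seconds in
total. These sizes give every statistic comfortable power (binomial and
correlation p-values far below their thresholds) while keeping the whole
suite fast.
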