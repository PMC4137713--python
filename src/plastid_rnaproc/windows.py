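"""Sliding-window editing and conservation tracks, correlation and enrichment.

Editing frequency and protein-level conservation are each scored over a
60-bp sliding window along a CDS (codon-aligned step, default 3 nt).
Conservation of a window is ``(identities + 0.5 * positives) / n_codons``
from one global protein alignment of the query translation against a
haptophyte ortholog, a "positive" being an aligned pair with a positive
BLOSUM62 score that is not an identity.  The two tracks are compared with a
Pearson correlation (t-distribution p-value, n-2 df); locally elevated
editing is tested against the rest of the gene with an exact binomial test
and a 1-df chi-squared test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

DEFAULT_WINDOW = 60
DEFAULT_STEP = 3
DEFAULT_MATRIX = "BLOSUM62"


@dataclass
class WindowTrack:
    gene_id: str
    window_length: int
    step: int
    starts: list[int]
    values: list[float]

    def __post_init__(self) -> None:
        if len(self.starts) != len(self.values):
            raise ValueError("starts and values must have equal length")


@dataclass
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    p_value: float


@dataclass
class EnrichmentResult:
    region: tuple[int, int]
    k: int
    n: int
    background_rate: float
    binomial_p: float
    chisq_p: float
    chisq_stat: float


def window_starts(cds_length: int, window: int, step: int) -> list[int]:
    if cds_length < window:
        raise ValueError(
            f"gene too short for windowing: CDS {cds_length} nt < window {window} nt"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    return list(range(0, cds_length - window + 1, step))


def window_editing_track(
    events,
    cds_length: int,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    gene_id: str = "",
) -> WindowTrack:
    """Per-window fraction of edited positions along a CDS.

    ``events`` may be EditingEvent objects (their CDS position is
    ``3*codon_index + codon_pos``) or bare integer CDS positions.
    """
    positions = set()
    for ev in events:
        if isinstance(ev, int):
            pos = ev
        else:
            if ev.codon_index is None:
                continue
            pos = 3 * ev.codon_index + ev.codon_pos
        if 0 <= pos < cds_length:
            positions.add(pos)
    edited = np.zeros(cds_length, dtype=np.int32)
    edited[list(positions)] = 1
    cumulative = np.concatenate([[0], np.cumsum(edited)])
    starts = window_starts(cds_length, window, step)
    values = [
        float(cumulative[s + window] - cumulative[s]) / window for s in starts
    ]
    return WindowTrack(gene_id, window, step, starts, values)


def _protein_aligner(matrix_name: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # free end gaps on both sides (semi-global): terminal extensions in
    # either protein should not drag down interior conservation
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    return aligner


def residue_conservation_scores(
    query_protein: str,
    ortholog_protein: str,
    matrix_name: str = DEFAULT_MATRIX,
) -> np.ndarray:
    """Per-query-residue conservation: 1 identity, 0.5 positive, 0 otherwise.

    One global alignment with free end gaps; query residues aligned to gaps
    score 0.
    """
    if not ortholog_protein:
        raise ValueError("empty ortholog protein")
    if not query_protein:
        raise ValueError("empty query protein")
    aligner = _protein_aligner(matrix_name)
    matrix = aligner.substitution_matrix
    alignment = aligner.align(query_protein, ortholog_protein)[0]
    indices = alignment.indices
    scores = np.zeros(len(query_protein))
    for qi, oi in zip(indices[0], indices[1]):
        if qi < 0 or oi < 0:
            continue
        q, o = query_protein[int(qi)], ortholog_protein[int(oi)]
        if q == o:
            scores[int(qi)] = 1.0
        else:
            try:
                pair_score = matrix[q, o]
            except (KeyError, IndexError):
                pair_score = -1.0
            if pair_score > 0:
                scores[int(qi)] = 0.5
    return scores


def window_conservation_track(
    query_protein: str,
    ortholog_protein: str,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    matrix_name: str = DEFAULT_MATRIX,
    gene_id: str = "",
) -> WindowTrack:
    """Per-nucleotide-window conservation of the query translation.

    Window starts are codon-aligned (``window`` divisible by 3); each
    window's score averages the conservation of its ``window/3`` codons.
    """
    if window % 3 != 0:
        raise ValueError("window must be divisible by 3")
    scores = residue_conservation_scores(query_protein, ortholog_protein, matrix_name)
    cds_length = 3 * len(query_protein)
    starts = window_starts(cds_length, window, step)
    n_codons = window // 3
    cumulative = np.concatenate([[0.0], np.cumsum(scores)])
    values = []
    for s in starts:
        # first codon touched by [s, s+window); for codon-aligned starts
        # (default step 3) this covers exactly window/3 codons
        first = s // 3
        values.append(float(cumulative[first + n_codons] - cumulative[first]) / n_codons)
    return WindowTrack(gene_id, window, step, starts, values)


def correlate_tracks(a: WindowTrack, b: WindowTrack) -> CorrelationResult:
    """Pearson correlation between two aligned window tracks."""
    if a.starts != b.starts:
        raise ValueError("tracks have different window starts")
    n = len(a.values)
    if n < 3:
        raise ValueError("need at least 3 windows")
    x = np.asarray(a.values, dtype=float)
    y = np.asarray(b.values, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: constant track")
    result = stats.pearsonr(x, y)
    r = float(result.statistic)
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
    return CorrelationResult(r=r, n=n, t_stat=float(t), p_value=float(result.pvalue))


def region_enrichment_test(
    k: int,
    n: int,
    total_k: int,
    total_n: int,
    background: str = "exclusive",
) -> EnrichmentResult:
    """Test a region for elevated editing against the rest of the gene.

    ``binomial_p`` is the exact upper tail P(X >= k) under the background
    rate; ``chisq_p`` comes from the 2x2 region-vs-rest table (1 df, no
    continuity correction).  The default background excludes the tested
    region; ``background="inclusive"`` uses the whole-gene rate.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n and n >= 1")
    if not (k <= total_k and n <= total_n):
        raise ValueError("region must be contained in the gene")
    rest_k = total_k - k
    rest_n = total_n - n
    if background == "exclusive":
        if rest_n == 0:
            raise ValueError("exclusive background undefined: region is whole gene")
        rate = rest_k / rest_n
    elif background == "inclusive":
        rate = total_k / total_n
    else:
        raise ValueError(f"unknown background mode {background!r}")

    if rate == 0.0:
        if k > 0:
            warnings.warn("zero background rate; upper-tail p-value is 0", stacklevel=2)
            binomial_p = 0.0
        else:
            binomial_p = 1.0
    else:
        binomial_p = float(stats.binom.sf(k - 1, n, rate))

    table = np.array([[k, n - k], [rest_k, rest_n - rest_k]], dtype=float)
    if table[0].sum() == 0 or table[1].sum() == 0 or table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        chisq_stat, chisq_p = 0.0, 1.0
    else:
        chisq_stat, chisq_p, _, _ = stats.chi2_contingency(table, correction=False)
    return EnrichmentResult(
        region=(0, n),
        k=k,
        n=n,
        background_rate=rate,
        binomial_p=binomial_p,
        chisq_p=float(chisq_p),
        chisq_stat=float(chisq_stat),
    )


def category_association_test(table) -> tuple[float, float, bool]:
    """Pearson chi-squared test of a 2x2 association table.

    Returns ``(statistic, p_value, low_expected)``; 1 df, no continuity
    correction; ``low_expected`` flags any expected count below 5.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any():
        raise ValueError("negative cell count")
    if arr.sum() == 0:
        raise ValueError("empty table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal")
    statistic, p, _, expected = stats.chi2_contingency(arr, correction=False)
    return float(statistic), float(p), bool((expected < 5).any())
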