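"""From peak files to interaction matrices and confidence metrics.

An interaction between a primary transcript and a protein is called when at
least one cross-link peak of that protein overlaps the gene's transcript
span.  Confidence is quantified by full-transcript peak density and top peak
score, percentile ranks of an RBP's own mRNA among its targets, the
interaction support index across method/peak-caller combinations, Jaccard
peak overlap between datasets, and percentile-based stringency filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core_io import (
    EXONIC_CONTEXTS,
    GenomicInterval,
    InteractionMatrix,
    Peak,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

DENSITY_CONTEXTS = EXONIC_CONTEXTS + ("intron", "full")


@dataclass(frozen=True)
class RegionDensity:
    """Peak density of one RBP in one region of one gene: nt_peak/nt_total."""

    gene_id: str
    rbp_id: str
    context: str
    nt_peak: int
    nt_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.nt_peak <= self.nt_total:
            raise ValueError(f"nt_peak {self.nt_peak} outside [0, {self.nt_total}]")

    @property
    def density(self) -> float:
        return self.nt_peak / self.nt_total


@dataclass(frozen=True)
class RankResult:
    rbp_id: str
    metric: str
    own_mrna_value: float
    percentile_rank: float
    n_targets: int


@dataclass(frozen=True)
class SupportIndex:
    """Number of method/peak-caller combinations supporting an interaction."""

    gene_id: str
    rbp_id: str
    n_methods_studied: int
    isi: int

    def __post_init__(self) -> None:
        if not 0 <= self.isi <= self.n_methods_studied:
            raise ValueError("ISI outside [0, n_methods_studied]")


# ---------------------------------------------------------------------------
# Interval coverage helpers
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def _clip_to_spans(
    peaks: Iterable[Peak], spans: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """Peak pieces clipped to a set of spans (same chromosome assumed per span)."""
    pieces = []
    for peak in peaks:
        iv = peak.interval
        for span in spans:
            if span.chrom != iv.chrom:
                continue
            s, e = max(iv.start, span.start), min(iv.end, span.end)
            if s < e:
                pieces.append((s, e))
    return pieces


# ---------------------------------------------------------------------------
# Interaction calling
# ---------------------------------------------------------------------------

def call_interactions(
    peaks: Iterable[Peak],
    models: Mapping[str, TranscriptModel],
    rbp_ids: Sequence[str] | None = None,
    rbp_gene: Mapping[str, str] | None = None,
) -> InteractionMatrix:
    """Binary incidence from one dataset's peaks.

    A cell (gene, RBP) is 1 when at least one peak of the RBP overlaps the
    gene's primary-transcript envelope; the per-pair weights are the
    full-transcript peak density (union of peak nucleotides over the span
    length) and the maximum peak score.  Peaks overlapping no annotated gene
    are counted and logged, then excluded.
    """
    gene_ids = list(models)
    rbp_list = sorted({p.rbp_id for p in peaks}) if rbp_ids is None else list(rbp_ids)
    gi = {g: i for i, g in enumerate(gene_ids)}
    ri = {r: j for j, r in enumerate(rbp_list)}

    trees: dict[str, IntervalTree] = {}
    spans = {}
    for gene, model in models.items():
        span = model.span
        spans[gene] = span
        trees.setdefault(span.chrom, IntervalTree()).addi(span.start, span.end, gene)

    pair_pieces: dict[tuple[int, int], list[tuple[int, int]]] = {}
    pair_score: dict[tuple[int, int], float] = {}
    unassigned = 0
    for peak in peaks:
        if peak.rbp_id not in ri:
            continue
        iv = peak.interval
        tree = trees.get(iv.chrom)
        hits = tree.overlap(iv.start, iv.end) if tree is not None else ()
        if not hits:
            unassigned += 1
            continue
        j = ri[peak.rbp_id]
        for hit in hits:
            key = (gi[hit.data], j)
            s, e = max(iv.start, hit.begin), min(iv.end, hit.end)
            pair_pieces.setdefault(key, []).append((s, e))
            pair_score[key] = max(pair_score.get(key, -np.inf), peak.score)
    if unassigned:
        logger.warning("%d peaks overlapped no annotated gene; excluded", unassigned)

    inc = np.zeros((len(gene_ids), len(rbp_list)), dtype=bool)
    density = np.full(inc.shape, np.nan)
    score = np.full(inc.shape, np.nan)
    for (i, j), pieces in pair_pieces.items():
        inc[i, j] = True
        span = spans[gene_ids[i]]
        density[i, j] = union_length(pieces) / span.length
        score[i, j] = pair_score[(i, j)]
    return InteractionMatrix(gene_ids, rbp_list, inc, density, score, rbp_gene)


# ---------------------------------------------------------------------------
# Densities and ranks
# ---------------------------------------------------------------------------

def region_density(
    peaks: Iterable[Peak],
    model: TranscriptModel,
    context: str,
    rbp_id: str | None = None,
) -> RegionDensity:
    """Peak density within one genomic context of one transcript.

    ``nt_peak`` is the size of the union of peak-covered nucleotides within
    the context (overlapping peaks are not double counted); peaks spanning a
    context boundary contribute only their within-context part.
    """
    if context not in DENSITY_CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    spans = model.spans("full") if context == "full" else model.spans(context)
    nt_total = sum(iv.length for iv in spans)
    if nt_total == 0:
        raise ValueError(f"{model.gene_id}: context {context} absent or empty")
    peaks = list(peaks)
    if rbp_id is not None:
        peaks = [p for p in peaks if p.rbp_id == rbp_id]
    nt_peak = union_length(_clip_to_spans(peaks, spans))
    name = rbp_id if rbp_id is not None else (peaks[0].rbp_id if peaks else "")
    return RegionDensity(model.gene_id, name, context, nt_peak, nt_total)


def percentile_rank(values: Sequence[float], query_index: int) -> float:
    """Midrank percentile of one value among the others.

    %R = 100 * (strictly below + 0.5 * ties among the others) / (n - 1); the
    unique maximum of n distinct values scores 100, the unique minimum 0.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values")
    q = values[query_index]
    others = np.delete(values, query_index)
    below = np.sum(others < q)
    ties = np.sum(others == q)
    if ties == n - 1:
        logger.info("all values equal; percentile rank defaults to 50")
    return 100.0 * (below + 0.5 * ties) / (n - 1)


def own_mrna_rank(
    matrix: InteractionMatrix, rbp_id: str, metric: str = "density"
) -> RankResult:
    """Percentile rank of an RBP's own mRNA among its detected targets."""
    j = matrix.rbp_ids.index(rbp_id)
    own_gene = matrix.rbp_gene.get(rbp_id, rbp_id)
    i = matrix.gene_index(own_gene)
    if not matrix.incidence[i, j]:
        raise ValueError(f"{rbp_id} does not bind its own mRNA in this dataset")
    weights = matrix.weights(metric)
    targets = np.nonzero(matrix.incidence[:, j])[0]
    values = weights[targets, j]
    query = int(np.nonzero(targets == i)[0][0])
    return RankResult(
        rbp_id, metric, float(values[query]),
        percentile_rank(values, query), len(targets),
    )


def support_index(
    gene_id: str,
    rbp_id: str,
    dataset_matrices: Mapping[str, InteractionMatrix],
) -> SupportIndex:
    """Count datasets (method/peak-caller combinations) supporting a pair.

    Only datasets in which the RBP was assayed enter the denominator; an RBP
    assayed nowhere is an error.
    """
    studied = supported = 0
    for matrix in dataset_matrices.values():
        if rbp_id not in matrix.rbp_ids:
            continue
        studied += 1
        j = matrix.rbp_ids.index(rbp_id)
        try:
            i = matrix.gene_index(gene_id)
        except KeyError:
            continue
        supported += bool(matrix.incidence[i, j])
    if studied == 0:
        raise ValueError(f"{rbp_id} assayed in no dataset")
    return SupportIndex(gene_id, rbp_id, studied, supported)


# ---------------------------------------------------------------------------
# Jaccard overlap between peak sets
# ---------------------------------------------------------------------------

def jaccard_overlap(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    universe_length: int,
) -> tuple[float, float, float]:
    """Nucleotide-level Jaccard index of two peak sets vs. random expectation.

    For coverage fractions a and b placed independently over a universe of
    ``universe_length`` nucleotides, the expected Jaccard index is
    a*b / (a + b - a*b); the returned ratio J / expected_J measures
    concordance beyond chance.
    """
    if universe_length <= 0:
        raise ValueError("universe_length must be positive")
    if not peaks_a or not peaks_b:
        raise ValueError("both peak sets must be non-empty")

    def _nts(peaks: Sequence[Peak]) -> dict[str, list[tuple[int, int]]]:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in peaks:
            by_chrom.setdefault(p.interval.chrom, []).append(
                (p.interval.start, p.interval.end)
            )
        return {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}

    cov_a, cov_b = _nts(peaks_a), _nts(peaks_b)
    inter = 0
    for chrom in set(cov_a) & set(cov_b):
        ivs = cov_a[chrom] + cov_b[chrom]
        merged_len = union_length(ivs)
        len_a = sum(e - s for s, e in cov_a[chrom])
        len_b = sum(e - s for s, e in cov_b[chrom])
        inter += len_a + len_b - merged_len
    total_a = sum(e - s for ivs in cov_a.values() for s, e in ivs)
    total_b = sum(e - s for ivs in cov_b.values() for s, e in ivs)
    union = total_a + total_b - inter
    j = inter / union if union else 0.0
    a, b = total_a / universe_length, total_b / universe_length
    expected = a * b / (a + b - a * b) if a + b else 0.0
    ratio = j / expected if expected > 0 else np.inf
    return j, expected, ratio


# ---------------------------------------------------------------------------
# Stringency filtering
# ---------------------------------------------------------------------------

def stringency_filter(
    matrix: InteractionMatrix, weight: str = "density", q: float = 0.0
) -> InteractionMatrix:
    """Keep only 1-cells whose weight reaches the q-th percentile.

    The threshold is the linear-interpolation percentile of all 1-cell
    weights in the dataset; cells tied with the threshold are kept.  Margins
    of the returned matrix are implied by the surviving incidence.
    """
    if not 0 <= q < 100:
        raise ValueError("q must be in [0, 100)")
    out = matrix.copy()
    if q == 0:
        return out
    w = out.weights(weight)
    ones = out.incidence
    threshold = np.percentile(w[ones], q)
    drop = ones & ~(np.nan_to_num(w, nan=-np.inf) >= threshold)
    out.incidence = ones & ~drop
    if out.density is not None:
        out.density = np.where(out.incidence, out.density, np.nan)
    if out.score is not None:
        out.score = np.where(out.incidence, out.score, np.nan)
    return out
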