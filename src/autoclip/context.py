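"""Genomic-context preference of autogenous binding and its confound controls.

Length-normalized context profiles (5'UTR / CDS / 3'UTR) quantify where on a
transcript an RBP binds; paired tests compare the CDS component of
autogenous interactions against the same mRNA's other binders.  Confound
controls: translation-inhibition condition comparisons, intron-density
z-scores against UTR-matched references, IUPAC motif coverage, peak-density
comparison between domain-mapped and remaining CDS, and the randomized-group
proportion test used for functional-category incidence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import EXONIC_CONTEXTS, GenomicInterval, Peak, TranscriptModel
from .interactions import (
    RegionDensity,
    merge_intervals,
    region_density,
    percentile_rank,
    union_length,
    _clip_to_spans,
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "[AG]", "Y": "[CU]", "S": "[CG]", "W": "[AU]",
    "K": "[GU]", "M": "[AC]", "B": "[CGU]", "D": "[AGU]",
    "H": "[ACU]", "V": "[ACG]", "N": "[ACGU]",
}


@dataclass(frozen=True)
class ContextProfile:
    """Length-normalized probability of peaks in the three exonic contexts."""

    gene_id: str
    rbp_id: str
    utr5: float
    cds: float
    utr3: float

    def __post_init__(self) -> None:
        total = self.utr5 + self.cds + self.utr3
        if any(v < 0 for v in (self.utr5, self.cds, self.utr3)):
            raise ValueError("negative context probability")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"context probabilities sum to {total}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.utr5, self.cds, self.utr3])


@dataclass(frozen=True)
class IntronZ:
    rbp_id: str
    own_intron_density: float
    reference_densities: tuple[float, ...]
    z: float
    flagged: bool  # reference too small or degenerate


def context_profile(
    peaks: Iterable[Peak], model: TranscriptModel, rbp_id: str | None = None
) -> ContextProfile:
    """Per-context densities normalized to sum to one.

    Undefined (ValueError) when all three exonic densities are zero or a
    context is missing from the model.
    """
    densities = []
    for ctx in EXONIC_CONTEXTS:
        if model.length(ctx) == 0:
            raise ValueError(f"{model.gene_id}: missing context {ctx}")
        densities.append(region_density(peaks, model, ctx, rbp_id).density)
    total = sum(densities)
    if total == 0:
        raise ValueError(f"{model.gene_id}: no exonic peaks; profile undefined")
    u5, cds, u3 = (d / total for d in densities)
    name = rbp_id if rbp_id is not None else ""
    return ContextProfile(model.gene_id, name, u5, cds, u3)


def cds_preference_test(
    autogenous_cds: Sequence[float],
    reference_cds: Sequence[float],
    min_pairs: int = 10,
) -> dict[str, float]:
    """Paired one-sided test for higher CDS preference in autogenous binding.

    ``autogenous_cds`` holds the CDS component of each autogenous context
    profile and ``reference_cds`` the matched mean CDS component of the same
    mRNA's non-autogenous binders.  The Wilcoxon signed-rank test is primary;
    a paired t-test is reported alongside.  Fewer than ``min_pairs`` pairs is
    refused, mirroring the inclusion rule for method/peak-caller combinations.
    """
    a = np.asarray(autogenous_cds, dtype=float)
    b = np.asarray(reference_cds, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples differ in length")
    if len(a) < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} autogenous pairs, got {len(a)}"
        )
    if np.allclose(a, b):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(
            stats.wilcoxon(a, b, alternative="greater", zero_method="wilcox").pvalue
        )
    t_p = float(stats.ttest_rel(a, b, alternative="greater").pvalue)
    return {"wilcoxon_p": wilcoxon_p, "paired_t_p": t_p, "n_pairs": len(a)}


def intron_zscore(
    own_intron_density: float,
    own_utr_density: float,
    target_intron_densities: Sequence[float],
    target_utr_densities: Sequence[float],
    mode: str = "utr_window",
    rbp_id: str = "",
    window: float = 0.10,
    k_nearest: int = 20,
    min_reference: int = 5,
) -> IntronZ:
    """Z-score of the own-mRNA intron density against UTR-matched targets.

    The reference set holds targets whose (joint) UTR peak density lies
    within a relative +/-``window`` of the own mRNA's, or the ``k_nearest``
    targets by absolute UTR-density difference.  A reference smaller than
    ``min_reference`` or with zero spread is flagged.
    """
    ti = np.asarray(target_intron_densities, dtype=float)
    tu = np.asarray(target_utr_densities, dtype=float)
    if ti.shape != tu.shape:
        raise ValueError("target density vectors differ in length")
    if mode == "utr_window":
        lo, hi = own_utr_density * (1 - window), own_utr_density * (1 + window)
        ref = ti[(tu >= lo) & (tu <= hi)]
    elif mode == "knn20":
        order = np.argsort(np.abs(tu - own_utr_density), kind="stable")
        ref = ti[order[:k_nearest]]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    flagged = len(ref) < min_reference
    sd = ref.std(ddof=1) if len(ref) > 1 else 0.0
    if sd == 0:
        return IntronZ(rbp_id, own_intron_density, tuple(ref), np.nan, True)
    z = (own_intron_density - ref.mean()) / sd
    return IntronZ(rbp_id, own_intron_density, tuple(ref), float(z), flagged)


def motif_coverage(sequence: str, motifs: Sequence[str]) -> float:
    """Fraction of sequence positions covered by any exact IUPAC motif match.

    Overlapping matches are unioned; an invalid IUPAC code raises.
    """
    if not motifs:
        raise ValueError("empty motif set")
    seq = sequence.upper().replace("T", "U")
    covered: list[tuple[int, int]] = []
    for motif in motifs:
        motif = motif.upper().replace("T", "U")
        try:
            pattern = "".join(IUPAC[c] for c in motif)
        except KeyError as err:
            raise ValueError(f"invalid IUPAC code {err.args[0]!r} in {motif}") from err
        for m in re.finditer(f"(?=({pattern}))", seq):
            covered.append((m.start(), m.start() + len(motif)))
    return union_length(covered) / len(seq) if seq else 0.0


def condition_compare(
    datasets: Mapping[str, Sequence[Peak]],
    models: Mapping[str, TranscriptModel],
    rbp_id: str,
    own_gene: str,
) -> list[dict[str, object]]:
    """Own-mRNA density and percentile rank per condition-labelled dataset.

    Reuses region densities and percentile ranks - no new statistic.  Each
    dataset maps a condition label (e.g. control / arsenite) to the RBP's
    peaks over all its targets; the rank compares the own mRNA's
    full-transcript density against the other target transcripts with at
    least one peak in the same dataset.  Both the absolute density and the
    relative rank are invariant diagnostics: a global monotone rescaling of
    binding leaves the rank unchanged.
    """
    if len(datasets) < 2:
        raise ValueError("need >= 2 condition-labelled datasets")
    if own_gene not in models:
        raise ValueError(f"own gene {own_gene} not annotated")
    rows: list[dict[str, object]] = []
    for condition, peaks in datasets.items():
        densities = []
        own_value = 0.0
        own_index = None
        for gene, model in models.items():
            span = model.span
            gene_peaks = [
                p for p in peaks
                if p.rbp_id == rbp_id and p.interval.overlaps(span)
            ]
            if gene == own_gene:
                own_value = region_density(gene_peaks or [], model, "full", rbp_id).density if gene_peaks else 0.0
                own_index = len(densities)
                densities.append(own_value)
            elif gene_peaks:
                densities.append(
                    region_density(gene_peaks, model, "full", rbp_id).density
                )
        row: dict[str, object] = {"condition": condition, "own_density": own_value}
        if len(densities) >= 2:
            row["own_percentile_rank"] = percentile_rank(densities, own_index)
        else:
            row["own_percentile_rank"] = float("nan")
        rows.append(row)
    return rows


def domain_region_density_compare(
    per_rbp_peaks: Mapping[str, Sequence[Peak]],
    models: Mapping[str, TranscriptModel],
    domain_spans: Mapping[str, Sequence[GenomicInterval]],
) -> dict[str, object]:
    """Peak density in domain-mapped CDS vs the remaining CDS, per RBP.

    ``domain_spans`` maps gene_id to CDS sub-intervals covered by structured
    domains; spans must lie within the CDS and both partitions must be
    non-empty.  Returns paired densities and a two-sided Wilcoxon p-value
    across RBPs.
    """
    inside, outside = [], []
    for rbp, peaks in per_rbp_peaks.items():
        model = models[rbp]
        spans = domain_spans.get(rbp, ())
        if not spans:
            raise ValueError(f"{rbp}: empty domain span set")
        cds = model.spans("cds")
        cds_cov = merge_intervals([(iv.start, iv.end) for iv in cds])
        dom_cov = merge_intervals([(iv.start, iv.end) for iv in spans])
        for s, e in dom_cov:
            if not any(cs <= s and e <= ce for cs, ce in cds_cov):
                raise ValueError(f"{rbp}: domain span [{s},{e}) outside CDS")
        dom_len = sum(e - s for s, e in dom_cov)
        cds_len = sum(e - s for s, e in cds_cov)
        rest_len = cds_len - dom_len
        if rest_len <= 0:
            raise ValueError(f"{rbp}: no CDS remains outside domains")
        dom_spans = [
            GenomicInterval(cds[0].chrom, s, e, model.strand) for s, e in dom_cov
        ]
        peak_in_cds = _clip_to_spans(peaks, cds)
        nt_dom = union_length(_clip_to_spans(peaks, dom_spans))
        nt_cds = union_length(peak_in_cds)
        inside.append(nt_dom / dom_len)
        outside.append((nt_cds - nt_dom) / rest_len)
    inside_arr, outside_arr = np.asarray(inside), np.asarray(outside)
    if np.allclose(inside_arr, outside_arr):
        p = 1.0
    else:
        p = float(stats.wilcoxon(inside_arr, outside_arr).pvalue)
    return {
        "domain_density": inside,
        "non_domain_density": outside,
        "wilcoxon_p": p,
    }


def group_randomization_test(
    outcomes: Sequence[bool],
    group_mask: Sequence[bool],
    trials: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-sided randomization p for a group's deviation from the base rate.

    Draws random same-sized groups without replacement and counts how often
    their outcome proportion deviates from the global proportion at least as
    much (in absolute value) as the observed group's.  For binary outcomes a
    random group's positive count is hypergeometric, which is how the trials
    are drawn.
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    outcomes = np.asarray(outcomes, dtype=bool)
    mask = np.asarray(group_mask, dtype=bool)
    if outcomes.shape != mask.shape:
        raise ValueError("outcomes and mask differ in length")
    g = int(mask.sum())
    if g < 1:
        raise ValueError("group must be non-empty")
    n = len(outcomes)
    if g == n:
        return 1.0
    total_pos = int(outcomes.sum())
    p_global = total_pos / n
    observed_dev = abs(outcomes[mask].mean() - p_global)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.hypergeometric(total_pos, n - total_pos, g, size=trials)
    devs = np.abs(draws / g - p_global)
    return float((devs >= observed_dev - 1e-12).mean())
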