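"""Synthetic inputs with the statistical structure the analysis assumes.

Every input class the pipeline consumes can be generated here at toy scale:
binary interaction matrices with prescribed column margins and a planted
autogenous excess, per-context peak sets, coding mRNA-protein pairs under the
standard codon table, saturating TPM/binding-probability curves and
planted-signal nucleobase-amino-acid affinity scales.  All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .core_io import (
    AMINO_ACIDS,
    BASES,
    AffinityScale,
    GenomicInterval,
    InteractionMatrix,
    Peak,
    TranscriptModel,
    as_rna,
    write_affinity_scale,
    write_matrix,
    write_peaks,
    write_residue_scale,
    write_sequences,
    write_transcript_models,
)

_STANDARD_TABLE = CodonTable.unambiguous_rna_by_id[1]

#: codons per amino acid under the standard genetic code (RNA alphabet)
CODONS: dict[str, list[str]] = {}
for codon, aa in _STANDARD_TABLE.forward_table.items():
    CODONS.setdefault(aa, []).append(codon)
for aa in CODONS:
    CODONS[aa].sort()

#: one fixed representative codon per amino acid (alphabetically first);
#: the planted affinity scale defines its signal relative to these.
CANONICAL_CODON = {aa: codons[0] for aa, codons in CODONS.items()}

STOP_CODON = "UAA"
PYRIMIDINES = set("CU")


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def translate_rna(cds: str) -> str:
    """In-silico translation of an RNA CDS (no stop codon expected inside)."""
    cds = as_rna(cds)
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    table = _STANDARD_TABLE.forward_table
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon not in table:
            raise ValueError(f"stop or invalid codon {codon} at {i}")
        out.append(table[codon])
    return "".join(out)


# ---------------------------------------------------------------------------
# Simulation spec
# ---------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """Study conditions for one simulated CLIP compendium.

    The target-count range mirrors the span of mRNA targets per RBP seen in
    real method/peak-caller combinations (tens to thousands, drawn
    log-uniformly); ``autogenous_factor`` is a planted multiplicative excess
    of autogenous 1-cells over the margin-implied base rate and
    ``autogenous_weight_shift`` an upshift (in SD units of the log-weight) of
    the autogenous confidence weights.  The TPM/binding-probability curve is
    hyperbolic with asymptote ``p_max`` and half-saturation ``tpm_k``.
    """

    n_genes: int = 20_000
    n_rbps: int = 25
    target_count_range: tuple[int, int] = (50, 9000)
    autogenous_factor: float = 1.0
    autogenous_weight_shift: float = 0.0
    context_densities: dict = field(
        default_factory=lambda: {"utr5": 0.03, "cds": 0.05, "utr3": 0.03, "intron": 0.01}
    )
    mean_peak_length: int = 30
    p_max: float = 0.9
    tpm_k: float = 10.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.autogenous_factor < 1:
            raise ValueError("autogenous_factor must be >= 1")
        if self.n_rbps > self.n_genes:
            raise ValueError("n_rbps must not exceed n_genes")
        for ctx, d in self.context_densities.items():
            if not 0 <= d <= 1:
                raise ValueError(f"density for {ctx} outside [0, 1]")


# ---------------------------------------------------------------------------
# Interaction matrices
# ---------------------------------------------------------------------------

def simulate_interaction_matrix(
    spec: SimulationSpec,
    seed: int | np.random.Generator | None = None,
) -> InteractionMatrix:
    """Binary genes x RBPs matrix with drawn margins and a planted diagonal.

    Each RBP's target count is drawn log-uniformly from
    ``spec.target_count_range`` and its targets are placed uniformly at
    random among the genes; the column margins therefore match the drawn
    counts up to the diagonal planting.  The autogenous cell of RBP ``j``
    (its own gene is gene ``j``) is then set to 1 with probability
    ``min(1, f * c_j / n_genes)`` where ``f`` is the planted enrichment
    factor and ``c_j / n_genes`` the margin-implied base rate.  Weights for
    1-cells are log-normal; autogenous weights may be upshifted.
    """
    rng = _rng(seed if seed is not None else spec.rng_seed)
    n, m = spec.n_genes, spec.n_rbps
    lo, hi = spec.target_count_range
    if hi > n:
        raise ValueError("infeasible margins: target count exceeds gene number")
    counts = np.rint(np.exp(rng.uniform(np.log(lo), np.log(hi), size=m))).astype(int)
    counts = np.clip(counts, 1, n)

    inc = np.zeros((n, m), dtype=bool)
    for j in range(m):
        inc[rng.choice(n, size=counts[j], replace=False), j] = True

    # planting acts on the diagonal after margin-conditioned generation
    p0 = counts / n
    p_auto = np.minimum(1.0, spec.autogenous_factor * p0)
    inc[np.arange(m), np.arange(m)] = rng.random(m) < p_auto

    gene_ids = [f"G{i:05d}" for i in range(n)]
    rbp_ids = gene_ids[:m]

    density = np.full((n, m), np.nan)
    score = np.full((n, m), np.nan)
    ones = np.nonzero(inc)
    k = len(ones[0])
    log_d = rng.normal(-3.5, 1.0, size=k)
    log_s = rng.normal(2.0, 1.0, size=k)
    if spec.autogenous_weight_shift:
        auto = ones[0] == ones[1]  # diagonal cells among the 1-cells
        log_d[auto] += spec.autogenous_weight_shift
        log_s[auto] += spec.autogenous_weight_shift
    density[ones] = np.exp(log_d)
    score[ones] = np.exp(log_s)
    return InteractionMatrix(gene_ids, rbp_ids, inc, density, score)


# ---------------------------------------------------------------------------
# Peaks and transcript models
# ---------------------------------------------------------------------------

def simulate_peaks(
    model: TranscriptModel,
    densities: Mapping[str, float],
    mean_peak_length: int = 30,
    seed: int | np.random.Generator | None = None,
    rbp_id: str = "RBP",
    dataset_id: str = "sim",
) -> list[Peak]:
    """Peaks with a requested per-context nucleotide density.

    Each context span is cut into ``mean_peak_length`` blocks and every block
    becomes a peak independently with the requested density, so the realized
    peak-nucleotide fraction fluctuates within binomial sampling error around
    the request.  Peaks never cross context boundaries.
    """
    rng = _rng(seed)
    for ctx, d in densities.items():
        if not 0 <= d <= 1:
            raise ValueError(f"density for {ctx} outside [0, 1]")
        if d > 0 and model.length(ctx) and mean_peak_length > model.length(ctx):
            raise ValueError(
                f"mean peak length {mean_peak_length} exceeds {ctx} length "
                f"{model.length(ctx)}"
            )
    peaks: list[Peak] = []
    for ctx, d in densities.items():
        if d == 0:
            continue
        for span in model.spans(ctx):
            for start in range(span.start, span.end, mean_peak_length):
                if rng.random() < d:
                    end = min(start + mean_peak_length, span.end)
                    peaks.append(
                        Peak(
                            GenomicInterval(span.chrom, start, end, span.strand),
                            rbp_id,
                            dataset_id,
                            float(np.exp(rng.normal(2.0, 1.0))),
                        )
                    )
    return peaks


def make_transcript_models(
    n_genes: int,
    seed: int | np.random.Generator | None = None,
    utr5_range: tuple[int, int] = (40, 80),
    cds_codon_range: tuple[int, int] = (100, 200),
    utr3_range: tuple[int, int] = (60, 120),
    intron_range: tuple[int, int] = (100, 300),
    chrom: str = "chr1",
    gap: int = 500,
) -> dict[str, TranscriptModel]:
    """Gene models laid end to end on one chromosome.

    Each gene is utr5 / cds / intron (splitting the CDS) / cds / utr3; exonic
    lengths match the transcript sequences produced by
    :func:`simulate_coding_pair` for the same draw.
    """
    rng = _rng(seed)
    models = {}
    pos = 0
    for i in range(n_genes):
        gene = f"G{i:05d}"
        u5 = int(rng.integers(*utr5_range))
        n_codons = int(rng.integers(*cds_codon_range))
        u3 = int(rng.integers(*utr3_range))
        intron = int(rng.integers(*intron_range))
        cds_len = 3 * n_codons
        half = 3 * (n_codons // 2)
        s = pos
        spans = {
            "utr5": [GenomicInterval(chrom, s, s + u5)],
            "cds": [
                GenomicInterval(chrom, s + u5, s + u5 + half),
                GenomicInterval(
                    chrom, s + u5 + half + intron, s + u5 + cds_len + intron
                ),
            ],
            "introns": [
                GenomicInterval(chrom, s + u5 + half, s + u5 + half + intron)
            ],
            "utr3": [
                GenomicInterval(
                    chrom, s + u5 + cds_len + intron, s + u5 + cds_len + intron + u3
                )
            ],
        }
        models[gene] = TranscriptModel(gene, f"{gene}.1", "+", **spans)
        pos = s + u5 + cds_len + intron + u3 + gap
    return models


# ---------------------------------------------------------------------------
# Coding pairs and affinity scales
# ---------------------------------------------------------------------------

def simulate_coding_pair(
    length_aa: int,
    utr_lengths: tuple[int, int] = (50, 150),
    seed: int | np.random.Generator | None = None,
    codon_usage: str = "uniform",
    include_stop: bool = False,
    gene_id: str = "G00000",
) -> tuple[str, str, TranscriptModel]:
    """A random protein, its mRNA and a transcript-local model.

    The CDS translates exactly back to the protein.  ``codon_usage`` is
    either ``uniform`` (random synonymous codon per residue) or ``canonical``
    (the fixed representative codon per amino acid that the planted affinity
    scale is defined against).  Returns (protein, mrna, model) with the model
    in transcript-local coordinates (chrom = gene_id).
    """
    if length_aa < 1:
        raise ValueError("protein length must be >= 1")
    if codon_usage not in ("uniform", "canonical"):
        raise ValueError(f"unknown codon usage {codon_usage!r}")
    rng = _rng(seed)
    protein = "".join(rng.choice(list(AMINO_ACIDS), size=length_aa))
    if codon_usage == "canonical":
        codons = [CANONICAL_CODON[aa] for aa in protein]
    else:
        codons = [CODONS[aa][rng.integers(len(CODONS[aa]))] for aa in protein]
    cds = "".join(codons) + (STOP_CODON if include_stop else "")
    u5, u3 = utr_lengths
    bases = list(BASES)
    mrna = (
        "".join(rng.choice(bases, size=u5))
        + cds
        + "".join(rng.choice(bases, size=u3))
    )
    model = TranscriptModel(
        gene_id,
        f"{gene_id}.1",
        "+",
        utr5=[GenomicInterval(gene_id, 0, u5)] if u5 else [],
        cds=[GenomicInterval(gene_id, u5, u5 + len(cds))],
        utr3=[GenomicInterval(gene_id, u5 + len(cds), u5 + len(cds) + u3)]
        if u3
        else [],
    )
    return protein, mrna, model


def pyrimidine_fraction(codon: str) -> float:
    return sum(b in PYRIMIDINES for b in codon) / len(codon)


def planted_affinity_scale(
    strength: float,
    seed: int | np.random.Generator | None = None,
    noise_sd: float = 1.0,
) -> AffinityScale:
    """Affinity scale with a planted coding signal of known size.

    For every amino acid, the mean pair energy over the distinct bases of its
    canonical codon is exactly ``strength`` lower (more favorable) than the
    mean over the remaining bases, on top of Gaussian noise.  The attached
    residue scalar anti-correlates with canonical-codon pyrimidine content
    with the same strength, so pyrimidine-density profiles of coding mRNA
    match their protein's affinity profile with negative Pearson R.  With
    ``strength = 0`` the scale is pure noise.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    rng = _rng(seed)
    e = rng.normal(0.0, noise_sd, size=(20, 4))
    for i, aa in enumerate(AMINO_ACIDS):
        codon_bases = sorted({b for b in CANONICAL_CODON[aa]})
        idx = [BASES.index(b) for b in codon_bases]
        other = [k for k in range(4) if k not in idx]
        gap = e[i, idx].mean() - e[i, other].mean()
        e[i, idx] -= gap + strength
    pyr = np.array([pyrimidine_fraction(CANONICAL_CODON[aa]) for aa in AMINO_ACIDS])
    scalar_values = rng.normal(0.0, noise_sd, size=20) - strength * (pyr - pyr.mean())
    residue_scalar = dict(zip(AMINO_ACIDS, scalar_values.tolist()))
    return AffinityScale(e, residue_scalar)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def binding_probability(tpm: np.ndarray | float, p_max: float, k: float):
    """Hyperbolic saturating binding-probability curve p = p_max*TPM/(K+TPM)."""
    tpm = np.asarray(tpm, dtype=float)
    out = p_max * tpm / (k + tpm)
    return float(out) if out.ndim == 0 else out


def simulate_expression(
    n_genes: int,
    p_max: float = 0.9,
    k: float = 10.0,
    seed: int | np.random.Generator | None = None,
    log_mean: float = 1.0,
    log_sd: float = 1.5,
) -> pd.DataFrame:
    """Log-normal per-gene TPM plus the true saturating binding probability."""
    rng = _rng(seed)
    tpm = np.exp(rng.normal(log_mean, log_sd, size=n_genes))
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n_genes)],
            "tpm": tpm,
            "p_true": binding_probability(tpm, p_max, k),
        }
    )


# ---------------------------------------------------------------------------
# Full input bundles
# ---------------------------------------------------------------------------

def simulate_dataset_peaks(
    matrix: InteractionMatrix,
    models: Mapping[str, TranscriptModel],
    dataset_id: str,
    seed: int | np.random.Generator | None = None,
    peak_length: int = 30,
    dropout: float = 0.0,
) -> list[Peak]:
    """Peak set realizing a given interaction matrix.

    Every 1-cell surviving dropout yields at least one peak on the target
    gene's transcript (so interaction calling recovers the cell), with the
    number of peaks scaled by the cell's density weight and the top peak
    carrying the cell's score weight.
    """
    rng = _rng(seed)
    peaks: list[Peak] = []
    rows, cols = np.nonzero(matrix.incidence)
    for i, j in zip(rows, cols):
        if dropout and rng.random() < dropout:
            continue
        gene = matrix.gene_ids[i]
        rbp = matrix.rbp_ids[j]
        model = models[gene]
        spans = model.spans("full") + model.spans("intron")
        lengths = np.array([s.length for s in spans], dtype=float)
        d = 0.02 if matrix.density is None else float(matrix.density[i, j])
        total = int(sum(lengths))
        n_peaks = max(1, int(rng.poisson(d * total / peak_length)))
        top_score = 1.0 if matrix.score is None else float(matrix.score[i, j])
        for p in range(n_peaks):
            span = spans[rng.choice(len(spans), p=lengths / lengths.sum())]
            width = min(peak_length, span.length)
            start = span.start + int(rng.integers(span.length - width + 1))
            score = top_score if p == 0 else top_score * float(rng.random())
            peaks.append(
                Peak(
                    GenomicInterval(span.chrom, start, start + width, span.strand),
                    rbp,
                    dataset_id,
                    score,
                )
            )
    return peaks


def write_bundle(
    outdir: str | Path,
    spec: SimulationSpec | None = None,
    seed: int | None = 0,
    n_datasets: int = 2,
    dropout: float = 0.1,
    scale_strength: float = 5.0,
) -> dict:
    """Write a complete toy input bundle and return the planted truth.

    Produces peaks_<dataset>.bed, models.tsv, matrix.tsv, mrna.fasta,
    protein.fasta, scale.tsv, residue_scale.tsv, tpm.tsv, curation.tsv and
    truth.json under ``outdir``.
    """
    spec = spec or SimulationSpec(n_genes=300, n_rbps=20, target_count_range=(10, 150))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    r_models, r_matrix, r_seq, r_peaks, r_scale, r_expr = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    models = make_transcript_models(spec.n_genes, r_models)
    matrix = simulate_interaction_matrix(spec, r_matrix)

    proteins, mrnas = {}, {}
    for gene, model in models.items():
        n_codons = model.length("cds") // 3
        u5, u3 = model.length("utr5"), model.length("utr3")
        protein, mrna, _ = simulate_coding_pair(
            n_codons, (u5, u3), r_seq, gene_id=gene
        )
        proteins[gene] = protein
        mrnas[gene] = mrna

    dataset_ids = [f"sim_method{d}" for d in range(n_datasets)]
    for d, dataset in enumerate(dataset_ids):
        peaks = simulate_dataset_peaks(
            matrix, models, dataset, r_peaks, dropout=0.0 if d == 0 else dropout
        )
        write_peaks(peaks, outdir / f"peaks_{dataset}.bed")

    scale = planted_affinity_scale(scale_strength, r_scale)
    expression = simulate_expression(spec.n_genes, spec.p_max, spec.tpm_k, r_expr)

    write_transcript_models(models, outdir / "models.tsv")
    write_matrix(matrix, outdir / "matrix.tsv")
    write_sequences(mrnas, outdir / "mrna.fasta")
    write_sequences(proteins, outdir / "protein.fasta")
    write_affinity_scale(scale, outdir / "scale.tsv")
    write_residue_scale(scale.residue_scalar, outdir / "residue_scale.tsv")
    expression[["gene_id", "tpm"]].to_csv(outdir / "tpm.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"dataset_id": dataset_ids, "overexpressed": [0] * n_datasets}
    ).to_csv(outdir / "curation.tsv", sep="\t", index=False)

    truth = {
        "seed": seed,
        "spec": {k: v for k, v in asdict(spec).items()},
        "observed_autogenous": matrix.observed_autogenous(),
        "n_datasets": n_datasets,
        "dataset_ids": dataset_ids,
        "scale_strength": scale_strength,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
    return truth
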