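"""Domain types shared by all analysis stages, plus readers/writers for the
plain-text formats the pipeline touches (BED6 peaks, TSV transcript models,
nucleobase-amino-acid affinity scales, TPM tables, curation flags, FASTA).

Coordinate convention: 0-based, half-open (BED) everywhere.  DNA input is
normalized to the RNA alphabet (T -> U) at read time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Fixed amino-acid order used for every energy table in the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Fixed nucleobase order (RNA alphabet).
BASES = "ACGU"
#: Exonic genomic contexts of a spliced transcript, 5' to 3'.
EXONIC_CONTEXTS = ("utr5", "cds", "utr3")
#: All genomic contexts a transcript model may carry.
CONTEXTS = EXONIC_CONTEXTS + ("intron",)

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def as_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert the DNA alphabet to RNA."""
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty interval: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """One cross-link peak: the atomic CLIP observation.

    ``rbp_id`` names the assayed protein (gene symbol), ``dataset_id`` the
    CLIP-method/peak-caller/cell-line combination that produced the peak and
    ``score`` the caller's own confidence value, treated as opaque and only
    ever compared within a single dataset.
    """

    interval: GenomicInterval
    rbp_id: str
    dataset_id: str
    score: float = 0.0
    overexpressed: bool = False

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise ValueError("empty dataset_id")
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score for {self.rbp_id}")


def _check_disjoint_sorted(spans: Sequence[GenomicInterval], label: str) -> None:
    for a, b in zip(spans, spans[1:]):
        if b.start < a.end and a.chrom == b.chrom:
            raise ValueError(f"overlapping {label} spans at {a} / {b}")


@dataclass
class TranscriptModel:
    """Region spans of one selected (MANE-like) transcript of a gene.

    All density work uses this single transcript per gene so that peak
    densities in different regions are comparable.  Spans within a context
    are kept sorted and disjoint; different contexts must not overlap.
    """

    gene_id: str
    transcript_id: str
    strand: str = "+"
    utr5: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ctx in CONTEXTS:
            spans = sorted(self.spans(ctx), key=lambda iv: (iv.chrom, iv.start))
            setattr(self, "introns" if ctx == "intron" else ctx, spans)
            _check_disjoint_sorted(spans, ctx)
        all_spans = [
            (iv, ctx) for ctx in CONTEXTS for iv in self.spans(ctx)
        ]
        all_spans.sort(key=lambda t: (t[0].chrom, t[0].start))
        for (a, ca), (b, cb) in zip(all_spans, all_spans[1:]):
            if a.overlaps(b):
                raise ValueError(
                    f"{self.gene_id}: contexts {ca} and {cb} overlap ({a}, {b})"
                )

    def spans(self, context: str) -> list[GenomicInterval]:
        if context == "intron":
            return self.introns
        if context == "full":
            return [iv for ctx in CONTEXTS for iv in self.spans(ctx)]
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        return getattr(self, context)

    def length(self, context: str) -> int:
        return sum(iv.length for iv in self.spans(context))

    @property
    def exonic_length(self) -> int:
        return sum(self.length(c) for c in EXONIC_CONTEXTS)

    @property
    def span(self) -> GenomicInterval:
        """Primary-transcript envelope: first to last annotated nucleotide."""
        spans = self.spans("full")
        if not spans:
            raise ValueError(f"{self.gene_id}: no spans")
        return GenomicInterval(
            spans[0].chrom,
            min(iv.start for iv in spans),
            max(iv.end for iv in spans),
            self.strand,
        )


class InteractionMatrix:
    """Binary genes x RBPs incidence with optional per-pair weights.

    Rows are mRNAs (genes), columns are assayed RBPs.  ``density`` holds the
    full-transcript peak density and ``score`` the top peak score of each
    detected pair; weights are defined (non-NaN) exactly where incidence is 1.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        rbp_ids: Sequence[str],
        incidence: np.ndarray,
        density: np.ndarray | None = None,
        score: np.ndarray | None = None,
        rbp_gene: Mapping[str, str] | None = None,
    ) -> None:
        incidence = np.asarray(incidence, dtype=bool)
        if incidence.shape != (len(gene_ids), len(rbp_ids)):
            raise ValueError("incidence shape does not match id lists")
        self.gene_ids = list(gene_ids)
        self.rbp_ids = list(rbp_ids)
        self.incidence = incidence
        #: maps each RBP column to the gene identity of its own mRNA; by
        #: default an RBP and its mRNA share one identifier.
        self.rbp_gene = dict(rbp_gene) if rbp_gene else {r: r for r in rbp_ids}
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        for name, w in (("density", density), ("score", score)):
            if w is not None:
                w = np.asarray(w, dtype=float)
                if w.shape != incidence.shape:
                    raise ValueError(f"{name} shape mismatch")
                if np.any(np.nan_to_num(w[incidence], nan=0.0) < 0):
                    raise ValueError(f"negative {name} weight")
        self.density = density
        self.score = score

    # -- margins ----------------------------------------------------------
    @property
    def row_margins(self) -> np.ndarray:
        """Number of RBP partners per mRNA."""
        return self.incidence.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        """Number of mRNA targets per RBP."""
        return self.incidence.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.incidence.shape

    # -- autogenous diagonal ---------------------------------------------
    def autogenous_cells(self) -> list[tuple[int, int]]:
        """(row, column) index of each RBP whose own gene is annotated."""
        cells = []
        for j, rbp in enumerate(self.rbp_ids):
            gene = self.rbp_gene.get(rbp, rbp)
            i = self._gene_index.get(gene)
            if i is not None:
                cells.append((i, j))
        return cells

    def observed_autogenous(self) -> int:
        return int(sum(self.incidence[i, j] for i, j in self.autogenous_cells()))

    def gene_index(self, gene_id: str) -> int:
        return self._gene_index[gene_id]

    def weights(self, kind: str) -> np.ndarray:
        w = {"density": self.density, "score": self.score}.get(kind)
        if w is None:
            raise ValueError(f"no {kind!r} weights attached")
        return w

    def copy(self) -> "InteractionMatrix":
        return InteractionMatrix(
            self.gene_ids,
            self.rbp_ids,
            self.incidence.copy(),
            None if self.density is None else self.density.copy(),
            None if self.score is None else self.score.copy(),
            self.rbp_gene,
        )

    # -- round trip through TSV ------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format table of 1-cells with weights."""
        rows, cols = np.nonzero(self.incidence)
        return pd.DataFrame(
            {
                "gene_id": [self.gene_ids[i] for i in rows],
                "rbp_id": [self.rbp_ids[j] for j in cols],
                "density": (
                    self.density[rows, cols] if self.density is not None else np.nan
                ),
                "score": (
                    self.score[rows, cols] if self.score is not None else np.nan
                ),
            }
        )


@dataclass
class AffinityScale:
    """Knowledge-based nucleobase-amino-acid pair energies.

    ``pair_energy`` is a 20 x 4 array in the fixed :data:`AMINO_ACIDS` /
    :data:`BASES` order; lower values mean more favorable contact.  The
    optional ``residue_scalar`` (e.g. a polar-requirement-like value per
    residue) feeds profile matching.
    """

    pair_energy: np.ndarray
    residue_scalar: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.pair_energy = np.asarray(self.pair_energy, dtype=float)
        if self.pair_energy.shape != (20, 4):
            raise ValueError("pair_energy must be 20 x 4")
        if not np.all(np.isfinite(self.pair_energy)):
            raise ValueError("non-finite pair energy")
        if self.residue_scalar is not None:
            missing = set(AMINO_ACIDS) - set(self.residue_scalar)
            if missing:
                raise ValueError(f"residue_scalar missing {sorted(missing)}")

    def energy(self, aa: str, base: str) -> float:
        base = as_rna(base)
        return float(self.pair_energy[AA_INDEX[aa], BASE_INDEX[base]])

    @property
    def triplet_energy(self) -> np.ndarray:
        """20 x 64 table: energy of a residue against a trinucleotide, i.e.
        the sum of its three single-base energies.  Triplet index is
        base-4 big-endian in :data:`BASES` order."""
        e = self.pair_energy
        t = (
            e[:, :, None, None] + e[:, None, :, None] + e[:, None, None, :]
        )  # (20,4,4,4), first axis of the triple = first base
        return t.reshape(20, 64)

    def scalar_array(self) -> np.ndarray:
        if self.residue_scalar is None:
            raise ValueError("no residue_scalar attached")
        return np.array([self.residue_scalar[aa] for aa in AMINO_ACIDS])


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError(f"negative TPM for {self.gene_id}")


@dataclass
class NullConfig:
    """Parameters of the two null frameworks.

    ``total_genes`` approximates the size of the cellular mRNA pool for the
    protein-centric background; ``n_matrices`` fixed-margin randomizations
    estimate per-pair probabilities; the pooled autogenous-count distribution
    is exact (dynamic programming) up to ``exact_threshold`` pairs and Monte
    Carlo with ``mc_trials`` draws beyond it.
    """

    total_genes: int = 20_000
    n_matrices: int = 1000
    mc_trials: int = 1_000_000
    exact_threshold: int = 20
    n_trades: int | None = None  # default: 5 x traded dimension
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("total_genes", "n_matrices", "mc_trials", "exact_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_peaks(
    path: str | Path,
    dataset_id: str,
    overexpressed: bool = False,
) -> list[Peak]:
    """Read a 6+-column BED file of cross-link peaks.

    Column 4 (name) carries the assayed RBP's gene symbol, column 5 the
    caller score.  Malformed lines are rejected with their line number.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}, line {lineno}: expected >=6 BED columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, name, score, strand = fields[:6]
            try:
                interval = GenomicInterval(chrom, int(start), int(end), strand)
                peak = Peak(interval, name, dataset_id, float(score), overexpressed)
            except ValueError as err:
                raise ValueError(f"{path}, line {lineno}: {err}") from err
            peaks.append(peak)
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.rbp_id}\t"
                f"{p.score:g}\t{iv.strand}\n"
            )


_MODEL_COLUMNS = ["gene_id", "transcript_id", "strand", "context", "chrom", "start", "end"]


def read_transcript_models(path: str | Path) -> dict[str, TranscriptModel]:
    """Read the flat TSV transcript-model dialect (one span per row).

    Columns: gene_id, transcript_id, strand, context (utr5/cds/utr3/intron),
    chrom, start, end.  Each gene must map to a single transcript; contexts
    within a gene must not overlap.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "transcript_id": str})
    missing = set(_MODEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["context"]) - set(CONTEXTS)
    if bad:
        raise ValueError(f"{path}: unknown context labels {sorted(bad)}")
    models: dict[str, TranscriptModel] = {}
    for gene_id, grp in df.groupby("gene_id", sort=False):
        tx = grp["transcript_id"].unique()
        if len(tx) > 1:
            raise ValueError(
                f"{path}: gene {gene_id} has conflicting transcripts {list(tx)}"
            )
        strand = grp["strand"].iloc[0]
        kwargs: dict[str, list[GenomicInterval]] = {
            "utr5": [], "cds": [], "utr3": [], "introns": []
        }
        for row in grp.itertuples():
            iv = GenomicInterval(row.chrom, int(row.start), int(row.end), strand)
            key = "introns" if row.context == "intron" else row.context
            kwargs[key].append(iv)
        models[str(gene_id)] = TranscriptModel(
            gene_id=str(gene_id), transcript_id=str(tx[0]), strand=strand, **kwargs
        )
    return models


def write_transcript_models(
    models: Mapping[str, TranscriptModel], path: str | Path
) -> None:
    rows = []
    for model in models.values():
        for ctx in CONTEXTS:
            for iv in model.spans(ctx):
                rows.append(
                    (model.gene_id, model.transcript_id, model.strand,
                     ctx, iv.chrom, iv.start, iv.end)
                )
    pd.DataFrame(rows, columns=_MODEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_affinity_scale(path: str | Path) -> AffinityScale:
    """Read a 20 x 4 pair-energy table (rows = amino acids, header = bases).

    A ``T`` column header is accepted as an alias for ``U``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [as_rna(str(c)) for c in df.columns]
    df.index = [str(i).upper() for i in df.index]
    missing_aa = set(AMINO_ACIDS) - set(df.index)
    if missing_aa:
        raise ValueError(f"{path}: missing amino acid {sorted(missing_aa)}")
    missing_base = set(BASES) - set(df.columns)
    if missing_base:
        raise ValueError(f"{path}: missing base column {sorted(missing_base)}")
    table = df.loc[list(AMINO_ACIDS), list(BASES)]
    if table.isna().any().any():
        aa = table.index[table.isna().any(axis=1)][0]
        base = table.columns[table.isna().any(axis=0)][0]
        raise ValueError(f"{path}: missing cell ({aa}, {base})")
    return AffinityScale(table.to_numpy(dtype=float))


def write_affinity_scale(scale: AffinityScale, path: str | Path) -> None:
    pd.DataFrame(
        scale.pair_energy, index=list(AMINO_ACIDS), columns=list(BASES)
    ).to_csv(path, sep="\t")


def read_residue_scale(path: str | Path) -> dict[str, float]:
    """Two-column TSV (amino acid, scalar) for profile matching."""
    df = pd.read_csv(path, sep="\t", header=None, names=["aa", "value"], comment="#")
    scale = {str(r.aa).upper(): float(r.value) for r in df.itertuples()}
    missing = set(AMINO_ACIDS) - set(scale)
    if missing:
        raise ValueError(f"{path}: missing residues {sorted(missing)}")
    return scale


def write_residue_scale(scale: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for aa in AMINO_ACIDS:
            fh.write(f"{aa}\t{scale[aa]:g}\n")


def read_expression(path: str | Path) -> dict[str, float]:
    """TSV with columns gene_id, tpm."""
    df = pd.read_csv(path, sep="\t")
    records = [ExpressionRecord(str(r.gene_id), float(r.tpm)) for r in df.itertuples()]
    return {r.gene_id: r.tpm for r in records}


def read_curation(path: str | Path) -> dict[str, bool]:
    """TSV with columns dataset_id, overexpressed (0/1 or true/false)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    truthy = {"1", "true", "yes"}
    return {
        str(r.dataset_id): str(r.overexpressed).strip().lower() in truthy
        for r in df.itertuples()
    }


def read_sequences(path: str | Path, rna: bool = True) -> dict[str, str]:
    """FASTA reader; nucleotide records are normalized to RNA when ``rna``."""
    out = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        out[record.id] = as_rna(seq) if rna else seq
    return out


def write_sequences(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_matrix(matrix: InteractionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_matrix(
    path: str | Path,
    gene_ids: Sequence[str] | None = None,
    rbp_ids: Sequence[str] | None = None,
) -> InteractionMatrix:
    """Rebuild an :class:`InteractionMatrix` from its long-format TSV.

    ``gene_ids``/``rbp_ids`` fix the full row/column universe; by default the
    universe is the set of identifiers present in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "rbp_id": str})
    genes = list(gene_ids) if gene_ids is not None else sorted(df["gene_id"].unique())
    rbps = list(rbp_ids) if rbp_ids is not None else sorted(df["rbp_id"].unique())
    gi = {g: i for i, g in enumerate(genes)}
    ri = {r: j for j, r in enumerate(rbps)}
    inc = np.zeros((len(genes), len(rbps)), dtype=bool)
    dens = np.full_like(inc, np.nan, dtype=float)
    score = np.full_like(inc, np.nan, dtype=float)
    for row in df.itertuples():
        i, j = gi[row.gene_id], ri[row.rbp_id]
        inc[i, j] = True
        dens[i, j] = row.density
        score[i, j] = row.score
    return InteractionMatrix(genes, rbps, inc, dens, score)
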