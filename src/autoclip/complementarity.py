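"""mRNA-protein complementarity scoring.

Two complementary views of co-aligned binding between an mRNA and the
protein it encodes:

* profile matching - windowed nucleobase-density profiles of the mRNA
  against windowed per-residue affinity profiles of the protein, compared by
  Pearson R at every 1-nt alignment offset (favorable matching shows up as
  negative R, because lower affinity values mean stronger binding);
* additive energies - E_stat, the sum over all aligned (amino acid,
  trinucleotide) pairs of knowledge-based nucleobase-amino-acid pair
  energies, scanned over every offset and judged against backgrounds of
  randomized sequences drawn from trinucleotide frequencies.

Both scans place the protein N-to-C along the mRNA 5'-to-3' by default and
shift one nucleotide at a time over the full mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import AA_INDEX, BASE_INDEX, AffinityScale, as_rna


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def encode_rna(seq: str) -> np.ndarray:
    seq = as_rna(seq)
    try:
        return np.array([BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as err:
        raise ValueError(f"invalid base {err.args[0]!r}") from err


def encode_protein(seq: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[a] for a in seq.upper()], dtype=np.int64)
    except KeyError as err:
        raise ValueError(f"unknown residue {err.args[0]!r}") from err


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class Profile:
    """Moving-average track along a sequence (valid windows only).

    ``values[i]`` averages the underlying per-nucleotide track over
    ``[i, i + window)``; the track length is sequence length - window + 1.
    """

    values: np.ndarray
    window: int
    kind: str

    def __len__(self) -> int:
        return len(self.values)


def _moving_average(track: np.ndarray, window: int) -> np.ndarray:
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(track):
        raise ValueError(f"window {window} exceeds track length {len(track)}")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(track, kernel, mode="valid")


def density_profile(
    rna_seq: str, base_class: Sequence[str] = ("C", "U"), window: int = 63
) -> Profile:
    """Windowed fraction of nucleotides belonging to ``base_class``."""
    idx = encode_rna(rna_seq)
    members = {BASE_INDEX[as_rna(b)] for b in base_class}
    track = np.isin(idx, list(members)).astype(float)
    return Profile(_moving_average(track, window), window, "nucleobase_density")


def affinity_profile(
    protein_seq: str,
    residue_scalar: Mapping[str, float],
    window_nt: int = 63,
) -> Profile:
    """Windowed per-residue affinity expanded to nucleotide resolution.

    Each residue contributes its scalar at the three positions of its codon
    (step replication), after which the same nt window as for the mRNA
    profile is applied, so both profiles share a coordinate frame.
    """
    missing = set(protein_seq.upper()) - set(residue_scalar)
    if missing:
        raise ValueError(f"unknown residue(s) {sorted(missing)}")
    per_residue = np.array([residue_scalar[a] for a in protein_seq.upper()])
    track = np.repeat(per_residue, 3)
    return Profile(_moving_average(track, window_nt), window_nt, "residue_affinity")


# ---------------------------------------------------------------------------
# Alignment scans
# ---------------------------------------------------------------------------

@dataclass
class AlignmentScan:
    """Metric per 1-nt alignment offset plus the in-frame coding offset.

    ``cds_rank`` ranks the coding offset by matching strength: most negative
    metric first (rank 1), ties broken by offset order, 1-based.  Offsets
    within 2 nt of the coding offset are flagged near-CDS.
    """

    offsets: np.ndarray
    metric: np.ndarray
    cds_offset: int
    kind: str
    orientation: str = "forward"
    shuffled: str = "none"

    def __post_init__(self) -> None:
        if self.cds_offset not in self.offsets:
            raise ValueError("cds_offset not among scanned offsets")

    @property
    def cds_value(self) -> float:
        return float(self.metric[self.offsets == self.cds_offset][0])

    @property
    def near_cds(self) -> np.ndarray:
        return np.abs(self.offsets - self.cds_offset) <= 2

    @property
    def cds_rank(self) -> int:
        """1-based rank of the coding offset by ascending metric."""
        valid = np.isfinite(self.metric)
        order = np.lexsort((self.offsets[valid], self.metric[valid]))
        ranked_offsets = self.offsets[valid][order]
        return int(np.nonzero(ranked_offsets == self.cds_offset)[0][0]) + 1


def profile_scan(
    mrna_profile: Profile, protein_profile: Profile, cds_offset: int
) -> AlignmentScan:
    """Pearson R between the protein profile and every mRNA profile window.

    Offsets cover every position where the protein track fits fully inside
    the mRNA track.  Zero-variance windows yield an undefined (NaN) R and
    are excluded from ranking.
    """
    x = np.asarray(mrna_profile.values, dtype=float)
    y = np.asarray(protein_profile.values, dtype=float)
    m, n = len(y), len(x)
    if m >= n:
        raise ValueError("protein profile must be shorter than mRNA profile")
    yc = y - y.mean()
    sy = np.sqrt(np.sum(yc**2))
    ones = np.ones(m)
    sx = np.convolve(x, ones, "valid")
    sxx = np.convolve(x**2, ones, "valid")
    sxy = np.correlate(x, yc, "valid")  # sum x[o+i] * yc[i]
    var_x = sxx - sx**2 / m
    var_x = np.where(var_x < 1e-12, 0.0, var_x)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / (np.sqrt(var_x) * sy)
    r[(var_x == 0) | (sy == 0)] = np.nan
    offsets = np.arange(n - m + 1)
    return AlignmentScan(offsets, r, cds_offset, "pearson_r")


# ---------------------------------------------------------------------------
# E_stat
# ---------------------------------------------------------------------------

def estat(protein_seq: str, rna_window: str, scale: AffinityScale) -> float:
    """Additive interaction energy of a protein against a 3L-nt RNA stretch.

    Sum over residues of the binding energies between the residue and the
    three nucleobases of its aligned trinucleotide.
    """
    aa = encode_protein(protein_seq)
    nt = encode_rna(rna_window)
    if len(nt) != 3 * len(aa):
        raise ValueError(
            f"RNA window of {len(nt)} nt does not match {len(aa)} residues"
        )
    return float(scale.pair_energy[np.repeat(aa, 3), nt].sum())


def _offset_energies(
    aa: np.ndarray, nt: np.ndarray, scale: AffinityScale
) -> np.ndarray:
    """E_stat at every alignment offset 0 .. len(nt) - 3L."""
    L = len(aa)
    n = len(nt)
    if 3 * L > n:
        raise ValueError("protein longer than mRNA allows")
    onehot = np.eye(4)[nt]
    trip = onehot[:-2] + onehot[1:-1] + onehot[2:]  # (n-2, 4)
    per_pos = trip @ scale.pair_energy[aa].T  # (n-2, L)
    offsets = np.arange(n - 3 * L + 1)
    idx = offsets[:, None] + 3 * np.arange(L)[None, :]
    return per_pos[idx, np.arange(L)[None, :]].sum(axis=1)


def estat_scan(
    protein_seq: str,
    mrna_seq: str,
    cds_offset: int,
    scale: AffinityScale,
    orientation: str = "forward",
    shuffle: str = "none",
    seed: int | np.random.Generator | None = None,
) -> AlignmentScan:
    """E_stat at every 1-nt offset of the protein along the mRNA.

    ``reverse`` orientation reads the mRNA 3' to 5' (the coding offset is
    mapped to its mirrored position); ``shuffle`` permutes the named
    sequence once per scan before scanning.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if shuffle not in ("none", "protein", "rna"):
        raise ValueError(f"unknown shuffle {shuffle!r}")
    rng = _rng(seed)
    aa = encode_protein(protein_seq)
    nt = encode_rna(mrna_seq)
    if shuffle == "protein":
        aa = aa[rng.permutation(len(aa))]
    elif shuffle == "rna":
        nt = nt[rng.permutation(len(nt))]
    used_offset = cds_offset
    if orientation == "reverse":
        nt = nt[::-1]
        used_offset = len(nt) - 3 * len(aa) - cds_offset
    energies = _offset_energies(aa, nt, scale)
    offsets = np.arange(len(energies))
    return AlignmentScan(offsets, energies, used_offset, "estat", orientation, shuffle)


# ---------------------------------------------------------------------------
# Randomized backgrounds
# ---------------------------------------------------------------------------

@dataclass
class BackgroundZ:
    """A query value standardized against a randomized background."""

    value: float
    background_mean: float
    background_sd: float
    z: float
    n_background: int
    flagged: bool = False


def uniform_trinucleotide_freqs() -> np.ndarray:
    return np.full(64, 1 / 64)


def _background_energies(
    aa: np.ndarray,
    trinucleotide_freqs: np.ndarray,
    n: int,
    scale: AffinityScale,
    rng: np.random.Generator,
) -> np.ndarray:
    """Energies of the protein against random iid-trinucleotide sequences."""
    freqs = np.asarray(trinucleotide_freqs, dtype=float)
    if freqs.shape != (64,) or abs(freqs.sum() - 1) > 1e-8:
        raise ValueError("trinucleotide_freqs must be 64 values summing to 1")
    draws = rng.choice(64, size=(n, len(aa)), p=freqs)
    t64 = scale.triplet_energy
    return t64[aa[None, :], draws].sum(axis=1)


def randomized_background(
    protein_seq: str,
    query_value: float,
    trinucleotide_freqs: np.ndarray | None = None,
    n: int = 1000,
    scale: AffinityScale | None = None,
    seed: int | np.random.Generator | None = None,
) -> BackgroundZ:
    """Z-score of a query E_stat against random-sequence alignments.

    The background aligns the protein against ``n`` random 3L-nt sequences
    drawn iid from the given trinucleotide frequencies (uniform by default).
    A degenerate background (zero spread) is flagged and yields NaN z.
    """
    if scale is None:
        raise ValueError("an affinity scale is required")
    rng = _rng(seed)
    aa = encode_protein(protein_seq)
    freqs = (
        uniform_trinucleotide_freqs() if trinucleotide_freqs is None else trinucleotide_freqs
    )
    energies = _background_energies(aa, freqs, n, scale, rng)
    mean, sd = float(energies.mean()), float(energies.std(ddof=1))
    if sd == 0:
        return BackgroundZ(query_value, mean, 0.0, np.nan, n, True)
    return BackgroundZ(query_value, mean, sd, (query_value - mean) / sd, n)


def fragment_analysis(
    protein_seq: str,
    mrna_seq: str,
    cds_offset: int,
    scale: AffinityScale,
    fragment_lengths: Sequence[int],
    trinucleotide_freqs: np.ndarray | None = None,
    n_background: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> dict[int, BackgroundZ]:
    """Mean in-frame co-aligned fragment energy, z-scored per length.

    For each fragment length the observed statistic is the mean E_stat over
    all in-frame co-aligned fragments of the protein with its CDS; the
    background is the energy of single random fragments (random start,
    random trinucleotides at the given frequencies) of equal length.
    """
    rng = _rng(seed)
    aa = encode_protein(protein_seq)
    L = len(aa)
    nt = encode_rna(mrna_seq)
    cds = nt[cds_offset : cds_offset + 3 * L]
    if len(cds) != 3 * L:
        raise ValueError("CDS window exceeds mRNA bounds")
    t64 = scale.triplet_energy
    codons = 16 * cds[0::3] + 4 * cds[1::3] + cds[2::3]
    per_residue = t64[aa, codons]
    prefix = np.concatenate([[0.0], np.cumsum(per_residue)])
    freqs = (
        uniform_trinucleotide_freqs() if trinucleotide_freqs is None else trinucleotide_freqs
    )
    out: dict[int, BackgroundZ] = {}
    for lf in fragment_lengths:
        if not 1 <= lf <= L:
            raise ValueError(f"fragment length {lf} outside [1, {L}]")
        frag_sums = prefix[lf:] - prefix[:-lf]  # all in-frame fragments
        observed = float(frag_sums.mean())
        starts = rng.integers(0, L - lf + 1, size=n_background)
        draws = rng.choice(64, size=(n_background, lf), p=freqs)
        frag_aa = aa[starts[:, None] + np.arange(lf)[None, :]]
        bg = t64[frag_aa, draws].sum(axis=1)
        mean, sd = float(bg.mean()), float(bg.std(ddof=1))
        if sd == 0:
            out[lf] = BackgroundZ(observed, mean, 0.0, np.nan, n_background, True)
        else:
            out[lf] = BackgroundZ(observed, mean, sd, (observed - mean) / sd, n_background)
    return out


def disordered_subset_scan(
    protein_seq: str,
    disorder_mask: Sequence[bool],
    mrna_seq: str,
    cds_offset: int,
    scale: AffinityScale,
    trinucleotide_freqs: np.ndarray | None = None,
    n_background: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> BackgroundZ:
    """E_stat restricted to disordered residues and their in-frame codons.

    The query sums pair energies over mask-selected residues only; the
    background draws random trinucleotides for the same reduced residue set.
    """
    mask = np.asarray(disorder_mask, dtype=bool)
    aa = encode_protein(protein_seq)
    if mask.shape != aa.shape:
        raise ValueError("mask length must equal protein length")
    if not mask.any():
        raise ValueError("empty disorder mask")
    rng = _rng(seed)
    nt = encode_rna(mrna_seq)
    cds = nt[cds_offset : cds_offset + 3 * len(aa)]
    if len(cds) != 3 * len(aa):
        raise ValueError("CDS window exceeds mRNA bounds")
    codons = 16 * cds[0::3] + 4 * cds[1::3] + cds[2::3]
    t64 = scale.triplet_energy
    sel = np.nonzero(mask)[0]
    query = float(t64[aa[sel], codons[sel]].sum())
    freqs = (
        uniform_trinucleotide_freqs() if trinucleotide_freqs is None else trinucleotide_freqs
    )
    bg = _background_energies(aa[sel], freqs, n_background, scale, rng)
    mean, sd = float(bg.mean()), float(bg.std(ddof=1))
    if sd == 0:
        return BackgroundZ(query, mean, 0.0, np.nan, n_background, True)
    return BackgroundZ(query, mean, sd, (query - mean) / sd, n_background)


# ---------------------------------------------------------------------------
# Bound vs unbound comparison
# ---------------------------------------------------------------------------

def bound_vs_unbound(
    bound_pairs: Sequence[tuple[str, str]],
    unbound_cds: Sequence[str],
    scale: AffinityScale,
    n_samples: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> dict[str, object]:
    """Autogenous CDS energies of bound RBPs against unbound-mRNA alignments.

    ``bound_pairs`` holds (protein, own CDS) of RBPs detected to bind their
    own mRNA; for each, ``n_samples`` random alignment positions in the
    unbound CDS pool give the background, yielding one z per bound RBP and a
    pooled background z sample.  A two-sided Mann-Whitney U test compares
    the two z samples.
    """
    if not unbound_cds:
        raise ValueError("no unbound mRNAs")
    rng = _rng(seed)
    unbound_nt = [encode_rna(c) for c in unbound_cds]
    bound_z: list[float] = []
    null_z: list[float] = []
    for protein, own_cds in bound_pairs:
        aa = encode_protein(protein)
        L3 = 3 * len(aa)
        own = estat(protein, own_cds[:L3], scale)
        eligible = [c for c in unbound_nt if len(c) >= L3]
        if not eligible:
            raise ValueError("no unbound mRNA long enough for background")
        energies = np.empty(n_samples)
        which = rng.integers(0, len(eligible), size=n_samples)
        for s in range(n_samples):
            c = eligible[which[s]]
            start = int(rng.integers(0, len(c) - L3 + 1))
            window = c[start : start + L3]
            energies[s] = float(
                scale.pair_energy[np.repeat(aa, 3), window].sum()
            )
        mean, sd = energies.mean(), energies.std(ddof=1)
        if sd == 0:
            continue
        bound_z.append(float((own - mean) / sd))
        null_z.extend(((energies - mean) / sd).tolist())
    if len(bound_z) < 2:
        raise ValueError("too few bound RBPs with usable backgrounds")
    p = float(stats.mannwhitneyu(bound_z, null_z, alternative="two-sided").pvalue)
    return {
        "bound_z": bound_z,
        "background_z": null_z,
        "mannwhitney_p": p,
        "n_bound": len(bound_z),
    }


def species_bound_vs_unbound(
    records: Sequence[tuple[str, str, bool]],
    proteins: Mapping[str, str],
    cds: Mapping[str, str],
    scale: AffinityScale,
    n_samples: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> list[dict[str, object]]:
    """Per-species bound-vs-unbound comparison.

    ``records`` holds (rbp_id, species, bound_flag); sequences are looked up
    by rbp_id.  Returns one result row per species (single species input
    yields a single row).
    """
    rng = _rng(seed)
    species_list = sorted({sp for _, sp, _ in records})
    out = []
    for sp in species_list:
        bound = [
            (proteins[r], cds[r]) for r, s, flag in records if s == sp and flag
        ]
        unbound = [cds[r] for r, s, flag in records if s == sp and not flag]
        if len(bound) < 5:
            raise ValueError(f"{sp}: need >= 5 bound RBPs with sequences")
        result = bound_vs_unbound(bound, unbound, scale, n_samples, rng)
        result["species"] = sp
        out.append(result)
    return out
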