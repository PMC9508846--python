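"""Null backgrounds for autogenous-interaction enrichment.

Two frameworks are implemented.  The protein-centric framework assigns each
RBP a background probability equal to its number of mRNA targets divided by
the size of the cellular mRNA pool (20 000 genes by default), assuming all
mRNAs are equally likely targets.  The symmetric framework conditions on the
partner counts of both molecules by sampling fixed-margin randomizations of
the binary interaction matrix with the Curveball Markov chain and reading
off per-pair occupancy frequencies.  Either way, the N per-pair
probabilities are pooled into a distribution over the possible number k of
autogenous binders via the Poisson binomial distribution - exactly (dynamic
programming over the convolution, identical to the 2^N sum) for small N,
by Monte Carlo for large N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import beta

from .core_io import InteractionMatrix, NullConfig
from .interactions import stringency_filter

logger = logging.getLogger(__name__)

TRADES_PER_ROW = 5  # mixing guidance of the original Curveball description


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Clopper-Pearson exact binomial interval
# ---------------------------------------------------------------------------

def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided confidence interval for k/n."""
    if not 0 <= k <= n:
        raise ValueError("k outside [0, n]")
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


# ---------------------------------------------------------------------------
# Protein-centric background
# ---------------------------------------------------------------------------

def protein_centric_probs(
    matrix: InteractionMatrix, total_genes: int = 20_000
) -> np.ndarray:
    """Background probability per autogenous-eligible RBP: targets / G.

    Only RBPs whose own gene is among the matrix rows contribute (others are
    excluded with a warning, mirroring how unannotated RBP genes are dropped).
    """
    margins = matrix.col_margins
    if np.any(margins > total_genes):
        raise ValueError("column margin exceeds total_genes")
    cells = matrix.autogenous_cells()
    excluded = len(matrix.rbp_ids) - len(cells)
    if excluded:
        logger.warning("%d RBPs lack an annotated own gene; excluded", excluded)
    return np.array([margins[j] / total_genes for _, j in cells], dtype=float)


# ---------------------------------------------------------------------------
# Curveball fixed-margin randomization
# ---------------------------------------------------------------------------

def _curveball_rows(
    inc: np.ndarray, n_trades: int, rng: np.random.Generator
) -> np.ndarray:
    """Curveball chain on the rows of a boolean matrix.

    One trade picks two random rows, pools the columns unique to each and
    redistributes the pool uniformly at random while preserving each row's
    count.  Row and column sums are invariant by construction.
    """
    inc = inc.copy()
    n_rows = inc.shape[0]
    pairs = rng.integers(0, n_rows, size=(n_trades, 2))
    for i, j in pairs:
        if i == j:
            continue
        a, b = inc[i], inc[j]
        diff = a ^ b
        pool = np.flatnonzero(diff)
        if pool.size == 0:
            continue
        ka = int(a[pool].sum())
        sel = rng.permutation(pool)
        inc[i, pool] = False
        inc[i, sel[:ka]] = True
        inc[j, pool] = False
        inc[j, sel[ka:]] = True
    return inc


def default_trades(shape: tuple[int, int]) -> int:
    """Default trade count: 5 x the traded (smaller) dimension."""
    return TRADES_PER_ROW * min(shape)


def curveball_shuffle(
    matrix: InteractionMatrix | np.ndarray,
    n_trades: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> InteractionMatrix | np.ndarray:
    """One fixed-margin randomization of a binary interaction matrix.

    The chain trades along the smaller dimension (trading rows or columns
    leaves both margin vectors fixed and targets the same uniform
    distribution); margin conservation is asserted on every sample.
    """
    rng = _rng(seed)
    inc = matrix.incidence if isinstance(matrix, InteractionMatrix) else np.asarray(matrix, dtype=bool)
    if inc.shape[0] < 2 and inc.shape[1] < 2:
        raise ValueError("matrix must have at least 2 rows or 2 columns")
    trades = default_trades(inc.shape) if n_trades is None else n_trades
    transpose = inc.shape[1] < inc.shape[0]
    work = inc.T.copy() if transpose else inc
    out = _curveball_rows(np.ascontiguousarray(work), trades, rng)
    out = out.T if transpose else out
    assert (out.sum(axis=0) == inc.sum(axis=0)).all()
    assert (out.sum(axis=1) == inc.sum(axis=1)).all()
    if isinstance(matrix, InteractionMatrix):
        return InteractionMatrix(
            matrix.gene_ids, matrix.rbp_ids, out, rbp_gene=matrix.rbp_gene
        )
    return out


def sample_states(
    inc: np.ndarray,
    n_samples: int,
    n_trades: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> dict[tuple[int, ...], int]:
    """Frequencies of visited matrix states over independent Curveball chains.

    Intended for small matrices (<= 64 columns); each state is keyed by its
    rows encoded as bit masks.  Used to check sampling uniformity against
    full enumeration of a fixed-margin family.
    """
    from itertools import combinations
    from math import comb

    inc = np.asarray(inc, dtype=bool)
    n_rows, n_cols = inc.shape
    if n_cols > 8:
        raise ValueError("bitmask state sampling supports up to 8 columns")
    trades = default_trades(inc.shape) if n_trades is None else n_trades
    rng = _rng(seed)

    # all size-k subsets of every possible symmetric-difference bit pattern
    n_states = 1 << n_cols
    max_subsets = comb(n_cols, n_cols // 2)
    subsets = np.zeros((n_states, n_cols + 1, max_subsets), dtype=np.int64)
    n_subsets = np.ones((n_states, n_cols + 1), dtype=np.int64)
    for d in range(n_states):
        bits = [b for b in range(n_cols) if d >> b & 1]
        for k in range(len(bits) + 1):
            combos = [sum(1 << b for b in c) for c in combinations(bits, k)]
            n_subsets[d, k] = len(combos)
            subsets[d, k, : len(combos)] = combos
    popcount = np.array([bin(x).count("1") for x in range(n_states)])

    weights = 1 << np.arange(n_cols, dtype=np.int64)
    start = (inc @ weights).astype(np.int64)
    state = np.tile(start, (n_samples, 1))
    ar = np.arange(n_samples)
    # all chains advance in lock step; each picks its own row pair per trade
    for _ in range(trades):
        i = rng.integers(0, n_rows, n_samples)
        j = rng.integers(0, n_rows, n_samples)
        a = state[ar, i]
        b = state[ar, j]
        diff = a ^ b
        ka = popcount[a & diff]
        r = rng.integers(0, n_subsets[diff, ka])
        sub = subsets[diff, ka, r]
        state[ar, j] = (b & ~diff) | (diff & ~sub)
        state[ar, i] = (a & ~diff) | sub
    uniq, freq = np.unique(state, axis=0, return_counts=True)
    return {tuple(int(x) for x in row): int(c) for row, c in zip(uniq, freq)}


@dataclass
class PairProbabilityMatrix:
    """Per-pair occupancy frequencies across fixed-margin randomizations."""

    gene_ids: list[str]
    rbp_ids: list[str]
    p: np.ndarray
    n_samples: int

    def ci(self, i: int, j: int, alpha: float = 0.05) -> tuple[float, float]:
        """Clopper-Pearson interval for one cell's probability."""
        k = int(round(self.p[i, j] * self.n_samples))
        return clopper_pearson(k, self.n_samples, alpha)


def pair_probabilities(
    matrix: InteractionMatrix,
    n_matrices: int = 1000,
    n_trades: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> PairProbabilityMatrix:
    """Cell-occupancy probabilities over ``n_matrices`` Curveball samples.

    Each sample is an independent chain started at the observed matrix and
    advanced ``n_trades`` trades (default 5 x the traded dimension).
    """
    if n_matrices < 1:
        raise ValueError("n_matrices must be >= 1")
    rng = _rng(seed)
    inc = matrix.incidence
    trades = default_trades(inc.shape) if n_trades is None else n_trades
    transpose = inc.shape[1] < inc.shape[0]
    work = np.ascontiguousarray(inc.T if transpose else inc)
    row_sums = work.sum(axis=1)
    col_sums = work.sum(axis=0)
    counts = np.zeros(work.shape, dtype=np.int64)
    for _ in range(n_matrices):
        sample = _curveball_rows(work, trades, rng)
        assert (sample.sum(axis=1) == row_sums).all()
        assert (sample.sum(axis=0) == col_sums).all()
        counts += sample
    p = counts / n_matrices
    if transpose:
        p = p.T
    return PairProbabilityMatrix(matrix.gene_ids, matrix.rbp_ids, p, n_matrices)


# ---------------------------------------------------------------------------
# Poisson binomial pooling
# ---------------------------------------------------------------------------

def poisson_binomial(
    probs: Sequence[float],
    mode: str = "auto",
    trials: int = 1_000_000,
    seed: int | np.random.Generator | None = None,
    exact_threshold: int = 20,
) -> np.ndarray:
    """Distribution of the number of successes among independent Bernoullis.

    ``exact`` evaluates the distribution by dynamic-programming convolution,
    mathematically identical to the sum over all 2^N outcome combinations;
    ``mc`` draws ``trials`` Bernoulli vectors; ``auto`` switches from exact
    to Monte Carlo above ``exact_threshold`` probabilities.  Returns the pmf
    over k = 0..N.
    """
    p = np.asarray(probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities outside [0, 1]")
    n = len(p)
    if mode == "auto":
        mode = "exact" if n <= exact_threshold else "mc"
    if mode == "exact":
        pmf = np.zeros(n + 1)
        pmf[0] = 1.0
        for pi in p:
            pmf[1:] = pmf[1:] * (1 - pi) + pmf[:-1] * pi
            pmf[0] *= 1 - pi
        return pmf
    if mode == "mc":
        if trials <= 0:
            raise ValueError("trials must be positive")
        rng = _rng(seed)
        counts = np.zeros(n + 1, dtype=np.int64)
        chunk = max(1, min(trials, 200_000))
        remaining = trials
        while remaining > 0:
            m = min(chunk, remaining)
            k = (rng.random((m, n)) < p).sum(axis=1)
            counts += np.bincount(k, minlength=n + 1)
            remaining -= m
        return counts / trials
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class NullSummary:
    """Pooled null for the autogenous count and the observed value's rank."""

    probs: np.ndarray  # pmf over k = 0..N
    observed_k: int
    expected_k: float
    sd: float
    percentile_rank: float
    p_value: float  # upper tail P(K >= observed)
    framework: str
    n_pairs: int

    @property
    def ratio(self) -> float:
        """Observed over expected number of autogenous binders."""
        return self.observed_k / self.expected_k if self.expected_k > 0 else np.inf

    def central_interval(self, level: float = 0.95) -> tuple[int, int]:
        """Smallest conservative central interval [k_lo, k_hi] of the null."""
        tail = (1 - level) / 2
        cdf = np.cumsum(self.probs)
        k_lo = int(np.searchsorted(cdf, tail, side="right"))
        upper = np.concatenate([[1.0], 1 - cdf])  # upper[k] = P(K >= k)
        k_hi = int(np.max(np.nonzero(upper > tail)[0]))
        return k_lo, k_hi


def summarize_null(
    pmf: np.ndarray, observed_k: int, framework: str
) -> NullSummary:
    pmf = np.asarray(pmf, dtype=float)
    n = len(pmf) - 1
    if not 0 <= observed_k <= n:
        raise ValueError("observed_k outside [0, N]")
    ks = np.arange(n + 1)
    expected = float(np.sum(ks * pmf))
    sd = float(np.sqrt(np.sum((ks - expected) ** 2 * pmf)))
    below = float(pmf[:observed_k].sum())
    at = float(pmf[observed_k])
    rank = 100.0 * (below + 0.5 * at)
    p_upper = float(pmf[observed_k:].sum())
    return NullSummary(pmf, observed_k, expected, sd, rank, p_upper, framework, n)


# ---------------------------------------------------------------------------
# Autogenous enrichment
# ---------------------------------------------------------------------------

def autogenous_enrichment(
    matrix: InteractionMatrix,
    framework: str = "protein_centric",
    config: NullConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> NullSummary:
    """Observed autogenous count against the pooled null of one framework.

    The per-pair probabilities come either from column margins over the total
    gene count (protein-centric) or from the autogenous diagonal of the
    Curveball pair-probability matrix (symmetric); pooling uses the Poisson
    binomial distribution, exact up to ``config.exact_threshold`` pairs.
    """
    config = config or NullConfig()
    rng = _rng(seed if seed is not None else config.rng_seed)
    cells = matrix.autogenous_cells()
    if not cells:
        raise ValueError("matrix has no autogenous diagonal")
    observed = matrix.observed_autogenous()
    if framework == "protein_centric":
        probs = protein_centric_probs(matrix, config.total_genes)
    elif framework == "symmetric":
        pp = pair_probabilities(matrix, config.n_matrices, config.n_trades, rng)
        probs = np.array([pp.p[i, j] for i, j in cells])
    else:
        raise ValueError(f"unknown framework {framework!r}")
    pmf = poisson_binomial(
        probs,
        mode="auto",
        trials=config.mc_trials,
        seed=rng,
        exact_threshold=config.exact_threshold,
    )
    return summarize_null(pmf, observed, framework)


@dataclass(frozen=True)
class StringencyPoint:
    q: float
    observed_k: int
    expected_k: float
    ratio: float
    percentile_rank: float


def enrichment_vs_stringency(
    matrix: InteractionMatrix,
    weight: str = "density",
    framework: str = "protein_centric",
    q_grid: Sequence[float] = tuple(range(0, 100, 10)),
    config: NullConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[StringencyPoint]:
    """Observed/expected autogenous enrichment at increasing stringency.

    At each percentile cut-off q the matrix is restricted to the top 1-cells
    by weight and the enrichment recomputed; in the symmetric framework the
    background is recomputed on the filtered matrix.
    """
    config = config or NullConfig()
    rng = _rng(seed if seed is not None else config.rng_seed)
    points = []
    for q in q_grid:
        filtered = stringency_filter(matrix, weight, q)
        if not filtered.incidence.any():
            points.append(StringencyPoint(q, 0, np.nan, np.nan, np.nan))
            continue
        summary = autogenous_enrichment(filtered, framework, config, rng)
        points.append(
            StringencyPoint(
                q,
                summary.observed_k,
                summary.expected_k,
                summary.ratio,
                summary.percentile_rank,
            )
        )
    return points


# ---------------------------------------------------------------------------
# Overexpression correction
# ---------------------------------------------------------------------------

@dataclass
class OverexpressionResult:
    summary: NullSummary
    #: row index -> margin targeted after saturation scaling
    target_margins: dict[int, int]
    #: autogenous-cell occupancy frequencies across the corrected ensemble
    probs: np.ndarray


def overexpression_correction(
    matrix: InteractionMatrix,
    tpm: Mapping[str, float],
    p_max: float,
    tpm_k: float,
    corrected_genes: Sequence[str],
    config: NullConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> OverexpressionResult:
    """Symmetric-framework null with margins scaled to saturation.

    For each corrected mRNA row the endogenous partner count is scaled by
    p_asym / p(TPM_endog) under the saturating binding curve (factors below 1
    are clamped to 1 with a warning); randomly chosen 0-cells of the row are
    flipped to 1 until the scaled margin is met.  Matrix modification and
    Curveball shuffling are repeated ``config.n_matrices`` times and the
    diagonal occupancy frequencies pooled as usual.
    """
    config = config or NullConfig()
    rng = _rng(seed if seed is not None else config.rng_seed)
    cells = matrix.autogenous_cells()
    observed = matrix.observed_autogenous()
    inc0 = matrix.incidence
    n_cols = inc0.shape[1]

    targets: dict[int, int] = {}
    for gene in corrected_genes:
        i = matrix.gene_index(gene)
        if gene not in tpm:
            raise ValueError(f"no TPM for corrected gene {gene}")
        p_endog = p_max * tpm[gene] / (tpm_k + tpm[gene])
        factor = p_max / p_endog if p_endog > 0 else np.inf
        if factor < 1:
            logger.warning("scaling factor %.3f < 1 for %s; clamped", factor, gene)
            factor = 1.0
        margin = int(inc0[i].sum())
        targets[i] = min(n_cols, int(round(margin * factor)))

    counts = np.zeros(len(cells), dtype=np.int64)
    trades = (
        default_trades(inc0.shape) if config.n_trades is None else config.n_trades
    )
    for _ in range(config.n_matrices):
        inc = inc0.copy()
        for i, target in targets.items():
            zeros = np.flatnonzero(~inc[i])
            need = target - int(inc[i].sum())
            if need > 0:
                flip = rng.choice(zeros, size=min(need, zeros.size), replace=False)
                inc[i, flip] = True
        shuffled = curveball_shuffle(inc, trades, rng)
        counts += np.array([shuffled[i, j] for i, j in cells])
    probs = counts / config.n_matrices
    pmf = poisson_binomial(
        probs, "auto", config.mc_trials, rng, config.exact_threshold
    )
    summary = summarize_null(pmf, observed, "symmetric_overexpression_corrected")
    return OverexpressionResult(summary, targets, probs)
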