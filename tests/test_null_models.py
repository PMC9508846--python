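"""Null frameworks: Curveball, Poisson binomial, enrichment, corrections."""

import numpy as np
import pytest
from scipy import stats as sstats
from statsmodels.stats.proportion import proportion_confint

from autoclip.core_io import InteractionMatrix, NullConfig
from autoclip.null_models import (
    clopper_pearson,
    curveball_shuffle,
    enrichment_vs_stringency,
    autogenous_enrichment,
    overexpression_correction,
    pair_probabilities,
    poisson_binomial,
    protein_centric_probs,
    sample_states,
    summarize_null,
)
from autoclip.synthetic_data import SimulationSpec, simulate_interaction_matrix


from oracles import brute_force_poisson_binomial, enumerate_fixed_margin  # noqa: E402


def square_matrix(inc):
    inc = np.asarray(inc, dtype=bool)
    ids = [f"G{i}" for i in range(inc.shape[0])]
    return InteractionMatrix(ids, ids[: inc.shape[1]], inc)


class TestClopperPearson:
    @pytest.mark.parametrize("k,n", [(0, 10), (3, 10), (500, 1000), (999, 1000)])
    def test_matches_statsmodels_beta_interval(self, k, n):
        lo, hi = clopper_pearson(k, n)
        slo, shi = proportion_confint(k, n, method="beta")
        assert lo == pytest.approx(slo, abs=1e-12)
        assert hi == pytest.approx(shi, abs=1e-12)


class TestProteinCentric:
    def test_margin_arithmetic(self):
        inc = np.zeros((3, 2), dtype=bool)
        m = square_matrix(np.zeros((2, 2)))
        m.incidence = np.array([[1, 1], [1, 1]], dtype=bool)
        probs = protein_centric_probs(m, 4)
        assert np.allclose(probs, [0.5, 0.5])

    def test_example_expected_k(self):
        ids = [f"G{i}" for i in range(2)]
        inc = np.zeros((2, 2), dtype=bool)
        m = InteractionMatrix(ids, ids, inc)
        m.incidence = np.zeros((2, 2), dtype=bool)
        # margins 2000 and 4000 out of G=20000 -> p = (0.1, 0.2)
        big = np.zeros((20000, 2), dtype=bool)
        big[:2000, 0] = True
        big[:4000, 1] = True
        genes = [f"G{i}" for i in range(20000)]
        m = InteractionMatrix(genes, genes[:2], big)
        probs = protein_centric_probs(m, 20000)
        assert np.allclose(probs, [0.1, 0.2])
        assert probs.sum() == pytest.approx(0.3)

    def test_margin_exceeding_universe_rejected(self):
        m = square_matrix(np.ones((5, 2)))
        with pytest.raises(ValueError):
            protein_centric_probs(m, 3)

    def test_expected_linear_in_margins(self, rng):
        spec = SimulationSpec(n_genes=200, n_rbps=6, target_count_range=(5, 80))
        m = simulate_interaction_matrix(spec, 9)
        probs = protein_centric_probs(m, 200)
        assert np.allclose(probs, m.col_margins / 200)


class TestCurveball:
    def test_margins_preserved_exactly(self, rng):
        for rep in range(5):
            inc = rng.random((30, 12)) < 0.3
            out = curveball_shuffle(inc, seed=rep)
            assert (out.sum(axis=0) == inc.sum(axis=0)).all()
            assert (out.sum(axis=1) == inc.sum(axis=1)).all()

    def test_identical_rows_unchanged(self):
        inc = np.tile(np.array([1, 0, 1, 0], dtype=bool), (4, 1))
        out = curveball_shuffle(inc, seed=0)
        assert np.array_equal(out, inc)

    def test_two_state_family_balanced(self):
        """2x2 identity has two fixed-margin states, each sampled ~50%."""
        counts = sample_states(np.eye(2, dtype=bool), 10_000, seed=3)
        assert set(counts) == {(1, 2), (2, 1)}
        freq = counts[(1, 2)] / 10_000
        assert abs(freq - 0.5) < 0.015

    def test_sampled_states_lie_in_enumerated_family(self):
        inc = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
        family = enumerate_fixed_margin(inc.sum(axis=1), inc.sum(axis=0))
        weights = 1 << np.arange(3, dtype=np.int64)
        keys = {tuple(int(x) for x in (s @ weights)) for s in family}
        counts = sample_states(inc, 3000, seed=1)
        assert set(counts) <= keys

    def test_uniformity_small_family(self):
        """Sampling frequencies match uniform over an enumerated family."""
        inc = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
        family = enumerate_fixed_margin(inc.sum(axis=1), inc.sum(axis=0))
        n = 20_000
        counts = sample_states(inc, n, n_trades=200, seed=5)
        observed = np.array(list(counts.values()))
        assert observed.sum() == n
        chi = sstats.chisquare(observed, f_exp=np.full(len(family), n / len(family)))
        assert len(counts) == len(family)
        assert chi.pvalue > 0.01


class TestPairProbabilities:
    def test_all_ones_matrix_is_fixed(self):
        m = square_matrix(np.ones((3, 3)))
        pp = pair_probabilities(m, 50, seed=0)
        assert np.allclose(pp.p, 1.0)

    def test_identity_diagonal_half_within_cp_band(self):
        m = square_matrix(np.eye(2))
        pp = pair_probabilities(m, 1000, seed=1)
        lo, hi = clopper_pearson(500, 1000)
        half = hi - 0.5  # ~0.0315 band around 0.5
        assert abs(pp.p[0, 0] - 0.5) < 2 * half

    def test_ensemble_conserves_total_ones(self, rng):
        inc = rng.random((40, 8)) < 0.25
        ids = [f"G{i}" for i in range(40)]
        m = InteractionMatrix(ids, ids[:8], inc)
        pp = pair_probabilities(m, 200, seed=2)
        assert pp.p.sum() == pytest.approx(inc.sum())
        # row/column means of p match normalized observed margins
        assert np.allclose(pp.p.sum(axis=1), inc.sum(axis=1))
        assert np.allclose(pp.p.sum(axis=0), inc.sum(axis=0))

    def test_cell_ci_is_clopper_pearson(self):
        m = square_matrix(np.eye(2))
        pp = pair_probabilities(m, 100, seed=4)
        k = int(round(pp.p[0, 0] * 100))
        assert pp.ci(0, 0) == clopper_pearson(k, 100)


class TestPoissonBinomial:
    def test_symmetric_pair(self):
        pmf = poisson_binomial([0.5, 0.5], "exact")
        assert pmf[1] == pytest.approx(0.5)

    def test_three_prob_enumeration(self):
        pmf = poisson_binomial([0.1, 0.2, 0.3], "exact")
        assert pmf[0] == pytest.approx(0.504)

    def test_dp_equals_brute_force(self, rng):
        for n in (1, 4, 8, 10):
            probs = rng.random(n)
            dp = poisson_binomial(probs, "exact")
            brute = brute_force_poisson_binomial(probs)
            assert np.allclose(dp, brute, atol=1e-12)

    def test_dp_matches_scipy(self, rng):
        probs = rng.random(15)
        dp = poisson_binomial(probs, "exact")
        ref = sstats.poisson_binom.pmf(np.arange(16), probs)
        assert np.allclose(dp, ref, atol=1e-12)

    def test_mc_close_to_exact(self, rng):
        probs = rng.random(10)
        exact = poisson_binomial(probs, "exact")
        mc = poisson_binomial(probs, "mc", trials=200_000, seed=7)
        assert np.max(np.abs(mc - exact)) < 0.005

    def test_auto_mode_switches(self):
        pmf = poisson_binomial([0.5] * 25, "auto", trials=10_000, seed=1,
                               exact_threshold=20)
        assert pmf.sum() == pytest.approx(1.0)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            poisson_binomial([0.5, 1.2], "exact")


class TestNullSummary:
    def test_moments_and_rank(self):
        pmf = poisson_binomial([0.2, 0.4, 0.6], "exact")
        s = summarize_null(pmf, 3, "protein_centric")
        assert s.expected_k == pytest.approx(1.2)
        assert s.p_value == pytest.approx(0.2 * 0.4 * 0.6)
        assert s.percentile_rank > 95

    def test_zero_diagonal_rank_at_most_50(self):
        pmf = poisson_binomial([0.3, 0.3], "exact")
        s = summarize_null(pmf, 0, "protein_centric")
        assert s.observed_k == 0
        assert s.percentile_rank <= 50

    def test_central_interval_covers_95(self):
        pmf = poisson_binomial([0.5] * 12, "exact")
        lo, hi = summarize_null(pmf, 6, "x").central_interval()
        assert pmf[lo : hi + 1].sum() >= 0.95


class TestEnrichment:
    def test_excluded_rbp_without_annotation(self, caplog):
        ids = ["G0", "G1"]
        inc = np.ones((2, 3), dtype=bool)
        m = InteractionMatrix(ids, ["G0", "G1", "G9"], inc)
        with caplog.at_level("WARNING"):
            probs = protein_centric_probs(m, 100)
        assert len(probs) == 2
        assert "excluded" in caplog.text

    def test_q0_point_equals_plain_enrichment(self):
        spec = SimulationSpec(n_genes=300, n_rbps=10, target_count_range=(10, 100),
                              autogenous_factor=2.0)
        m = simulate_interaction_matrix(spec, 21)
        config = NullConfig(total_genes=300, rng_seed=0)
        plain = autogenous_enrichment(m, "protein_centric", config)
        curve = enrichment_vs_stringency(
            m, "density", "protein_centric", [0], config
        )
        assert curve[0].observed_k == plain.observed_k
        assert curve[0].expected_k == pytest.approx(plain.expected_k)

    def test_upshifted_weights_increase_with_stringency(self):
        spec = SimulationSpec(
            n_genes=2000, n_rbps=60, target_count_range=(20, 900),
            autogenous_factor=4.0, autogenous_weight_shift=2.0,
        )
        m = simulate_interaction_matrix(spec, 5)
        config = NullConfig(total_genes=2000, rng_seed=0)
        curve = enrichment_vs_stringency(
            m, "density", "protein_centric", [0, 40, 80], config
        )
        ratios = [p.ratio for p in curve]
        assert ratios[2] > ratios[0]

    def test_symmetric_framework_runs_and_centers(self):
        spec = SimulationSpec(n_genes=400, n_rbps=12, target_count_range=(10, 150))
        m = simulate_interaction_matrix(spec, 8)
        config = NullConfig(n_matrices=200, mc_trials=50_000, rng_seed=0)
        s = autogenous_enrichment(m, "symmetric", config)
        assert s.n_pairs == 12
        assert 0 <= s.percentile_rank <= 100
        assert s.probs.sum() == pytest.approx(1.0, abs=1e-9)


class TestOverexpressionCorrection:
    def _matrix(self):
        rng = np.random.default_rng(0)
        inc = rng.random((30, 6)) < 0.2
        inc[np.arange(6), np.arange(6)] = True
        ids = [f"G{i}" for i in range(30)]
        return InteractionMatrix(ids, ids[:6], inc)

    def test_saturated_tpm_no_modification(self):
        m = self._matrix()
        tpm = {"G3": 1e9}  # p(TPM) ~ p_max -> factor 1
        res = overexpression_correction(
            m, tpm, 0.9, 10.0, ["G3"], NullConfig(n_matrices=20, rng_seed=1)
        )
        assert res.target_margins[3] == int(m.incidence[3].sum())

    def test_factor_two_doubles_margin(self):
        m = self._matrix()
        # p(K) = p_max/2 -> factor exactly 2
        tpm = {"G2": 10.0}
        res = overexpression_correction(
            m, tpm, 0.9, 10.0, ["G2"], NullConfig(n_matrices=20, rng_seed=1)
        )
        assert res.target_margins[2] == 2 * int(m.incidence[2].sum())

    def test_twin_simulation_recovers_saturated_null(self, rng):
        """Correcting a margin-halved twin approximates the fixed-margin
        null of the fully expressed matrix for the corrected rows."""
        inc_full = rng.random((200, 10)) < 0.25
        ids = [f"G{i}" for i in range(200)]
        corrected = [f"G{i}" for i in range(5)]
        for i in range(5):  # even margin so halving inverts doubling exactly
            inc_full[i] = False
            inc_full[i, rng.choice(10, size=4, replace=False)] = True
        full = InteractionMatrix(ids, ids[:10], inc_full)
        inc_twin = inc_full.copy()
        for g in corrected:
            i = full.gene_index(g)
            ones = np.flatnonzero(inc_twin[i])
            drop = rng.choice(ones, size=len(ones) // 2, replace=False)
            inc_twin[i, drop] = False
        twin = InteractionMatrix(ids, ids[:10], inc_twin)
        # TPM at the half-saturation constant -> scaling factor exactly 2
        tpm = {g: 10.0 for g in corrected}
        res = overexpression_correction(
            twin, tpm, 0.9, 10.0, corrected,
            NullConfig(n_matrices=300, mc_trials=20_000, rng_seed=3),
        )
        pp_full = pair_probabilities(full, 300, seed=4)
        cells = full.autogenous_cells()
        for idx, (i, j) in enumerate(cells[:5]):
            assert res.probs[idx] == pytest.approx(pp_full.p[i, j], abs=0.12)

    def test_probs_are_frequencies(self):
        m = self._matrix()
        res = overexpression_correction(
            m, {"G1": 10.0}, 0.9, 10.0, ["G1"],
            NullConfig(n_matrices=50, mc_trials=10_000, rng_seed=2),
        )
        assert np.all((res.probs >= 0) & (res.probs <= 1))
        assert res.summary.framework == "symmetric_overexpression_corrected"
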