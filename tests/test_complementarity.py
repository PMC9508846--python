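"""Profiles, E_stat scans, randomized backgrounds and planted-signal checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from autoclip.core_io import AMINO_ACIDS, AffinityScale
from autoclip.complementarity import (
    AlignmentScan,
    affinity_profile,
    bound_vs_unbound,
    density_profile,
    disordered_subset_scan,
    estat,
    estat_scan,
    fragment_analysis,
    profile_scan,
    randomized_background,
    species_bound_vs_unbound,
)
from autoclip.synthetic_data import planted_affinity_scale, simulate_coding_pair


def zero_scale():
    return AffinityScale(np.zeros((20, 4)))


class TestDensityProfile:
    def test_all_pyrimidine_constant_one(self):
        prof = density_profile("CU" * 40, ("C", "U"), window=9)
        assert np.allclose(prof.values, 1.0)

    def test_alternating_phase_counts(self):
        prof = density_profile("AC" * 100, ("C", "U"), window=63)
        assert set(np.round(prof.values * 63).astype(int)) <= {31, 32}

    def test_full_base_class_constant_one(self):
        prof = density_profile("ACGU" * 30, ("A", "C", "G", "U"), window=13)
        assert np.allclose(prof.values, 1.0)

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            density_profile("ACGU", ("C",), window=63)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            density_profile("ACGU" * 30, ("C",), window=10)

    def test_length_contract(self):
        prof = density_profile("A" * 100, ("A",), window=63)
        assert len(prof) == 100 - 63 + 1


class TestAffinityProfile:
    def test_homopolymer_constant(self):
        scale = {aa: 0.0 for aa in AMINO_ACIDS}
        scale["K"] = 2.5
        prof = affinity_profile("K" * 30, scale, window_nt=9)
        assert np.allclose(prof.values, 2.5)

    def test_expansion_length_contract(self):
        scale = {aa: 1.0 for aa in AMINO_ACIDS}
        prof = affinity_profile("ACDEFGHIKL" * 4, scale, window_nt=63)
        assert len(prof) == 3 * 40 - 63 + 1

    def test_two_block_profile_matches_convolution(self):
        scale = {aa: 0.0 for aa in AMINO_ACIDS}
        scale["A"] = 1.0
        protein = "A" * 20 + "G" * 20
        prof = affinity_profile(protein, scale, window_nt=15)
        track = np.repeat([scale[a] for a in protein], 3)
        expected = np.convolve(track, np.full(15, 1 / 15), mode="valid")
        assert np.allclose(prof.values, expected)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="residue"):
            affinity_profile("AXZ", {aa: 0.0 for aa in AMINO_ACIDS})


class TestProfileScan:
    def test_self_match_r_plus_one(self, rng):
        x = rng.normal(size=200)
        mp = type("P", (), {"values": x})()
        pp = type("P", (), {"values": x[40:100]})()
        scan = profile_scan(mp, pp, 40)
        assert scan.metric[40] == pytest.approx(1.0)

    def test_negated_match_r_minus_one(self, rng):
        x = rng.normal(size=200)
        mp = type("P", (), {"values": x})()
        pp = type("P", (), {"values": -x[40:100] + 5})()
        scan = profile_scan(mp, pp, 40)
        assert scan.metric[40] == pytest.approx(-1.0)

    def test_zero_variance_window_excluded(self, rng):
        x = np.concatenate([np.full(50, 2.0), rng.normal(size=100)])
        pp = type("P", (), {"values": rng.normal(size=20)})()
        mp = type("P", (), {"values": x})()
        scan = profile_scan(mp, pp, 60)
        assert np.isnan(scan.metric[0])

    def test_planted_scale_ranks_cds_top(self, rng):
        """Planted anti-correlation puts the coding offset at the top ranks."""
        scale = planted_affinity_scale(5.0, rng)
        hits = 0
        n = 100
        for _ in range(n):
            protein, mrna, model = simulate_coding_pair(
                120, (60, 60), rng, codon_usage="canonical"
            )
            mp = density_profile(mrna, ("C", "U"), 63)
            pp = affinity_profile(protein, scale.residue_scalar, 63)
            scan = profile_scan(mp, pp, model.length("utr5"))
            hits += scan.cds_rank <= 2
        assert hits >= 90


class TestEstat:
    def test_zero_scale_zero_energy(self):
        assert estat("ACD", "AUGGCAGAU", zero_scale()) == 0.0

    def test_single_residue_sum(self):
        scale = AffinityScale(np.full((20, 4), -1.0))
        assert estat("M", "ACG", scale) == -3.0

    def test_nested_loop_oracle(self, rng):
        scale = AffinityScale(rng.normal(size=(20, 4)))
        protein, rna = "MKV", "AUGAAAGUU"
        from autoclip.core_io import AA_INDEX, BASE_INDEX

        expected = sum(
            scale.pair_energy[AA_INDEX[aa], BASE_INDEX[b]]
            for i, aa in enumerate(protein)
            for b in rna[3 * i : 3 * i + 3]
        )
        assert estat(protein, rna, scale) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estat("MK", "AUG", zero_scale())

    @given(split=st.integers(min_value=1, max_value=9))
    @settings(max_examples=10, derandomize=True)
    def test_additivity(self, split):
        rng = np.random.default_rng(0)
        scale = AffinityScale(rng.normal(size=(20, 4)))
        protein, mrna, _ = simulate_coding_pair(10, (0, 0), 3)
        total = estat(protein, mrna, scale)
        left = estat(protein[:split], mrna[: 3 * split], scale)
        right = estat(protein[split:], mrna[3 * split :], scale)
        assert total == pytest.approx(left + right)


class TestEstatScan:
    def test_offset_count_contract(self, rng):
        scale = AffinityScale(rng.normal(size=(20, 4)))
        protein, mrna, model = simulate_coding_pair(20, (15, 25), rng)
        scan = estat_scan(protein, mrna, model.length("utr5"), scale)
        assert len(scan.offsets) == len(mrna) - 3 * 20 + 1

    def test_cds_offset_value_equals_estat(self, rng):
        scale = AffinityScale(rng.normal(size=(20, 4)))
        protein, mrna, model = simulate_coding_pair(20, (15, 25), rng)
        off = model.length("utr5")
        scan = estat_scan(protein, mrna, off, scale)
        cds = mrna[off : off + 60]
        assert scan.cds_value == pytest.approx(estat(protein, cds, scale))

    def test_translation_covariance(self, rng):
        scale = AffinityScale(rng.normal(size=(20, 4)))
        protein, mrna, model = simulate_coding_pair(15, (10, 10), rng)
        off = model.length("utr5")
        prefix = "ACGUA"
        scan = estat_scan(protein, mrna, off, scale)
        shifted = estat_scan(protein, prefix + mrna, off + len(prefix), scale)
        assert np.allclose(shifted.metric[len(prefix) :], scan.metric)
        assert shifted.cds_value == pytest.approx(scan.cds_value)

    def test_reverse_scan_of_palindrome_equals_forward(self, rng):
        scale = AffinityScale(rng.normal(size=(20, 4)))
        half = "".join(rng.choice(list("ACGU"), size=40))
        mrna = half + half[::-1]
        protein, _, _ = simulate_coding_pair(8, (0, 0), rng)
        fwd = estat_scan(protein, mrna, 0, scale, "forward")
        rev = estat_scan(protein, mrna, 0, scale, "reverse")
        assert np.allclose(fwd.metric, rev.metric)

    def test_planted_minimum_at_cds(self, rng):
        scale = planted_affinity_scale(5.0, rng)
        protein, mrna, model = simulate_coding_pair(
            100, (30, 30), rng, codon_usage="canonical"
        )
        scan = estat_scan(protein, mrna, model.length("utr5"), scale)
        assert scan.cds_rank == 1

    def test_protein_shuffle_destroys_minimum(self, rng):
        """Shuffled-protein coding offsets rank uniformly, not at the top."""
        scale = planted_affinity_scale(5.0, 99)
        ranks = []
        for rep in range(60):
            protein, mrna, model = simulate_coding_pair(
                60, (30, 30), rng, codon_usage="canonical"
            )
            scan = estat_scan(
                protein, mrna, model.length("utr5"), scale,
                shuffle="protein", seed=rep,
            )
            ranks.append(scan.cds_rank / len(scan.offsets))
        assert 0.3 < np.mean(ranks) < 0.7

    def test_tie_breaking_by_offset_order(self):
        scan = AlignmentScan(
            np.arange(5), np.array([1.0, 0.0, 0.0, 2.0, 0.0]), 2, "estat"
        )
        # offsets 1, 2, 4 tie at the minimum; offset order breaks the tie
        assert scan.cds_rank == 2


class TestBackground:
    def test_degenerate_zero_scale_flagged(self):
        res = randomized_background("MKV", 0.0, None, 100, zero_scale(), 0)
        assert res.flagged and np.isnan(res.z)

    def test_query_from_background_near_standard_normal(self, rng):
        scale = AffinityScale(rng.normal(size=(20, 4)))
        protein = "".join(rng.choice(list(AMINO_ACIDS), size=40))
        from autoclip.complementarity import _background_energies, encode_protein

        aa = encode_protein(protein)
        zs = []
        for rep in range(200):
            q = float(_background_energies(aa, np.full(64, 1 / 64), 1, scale, rng)[0])
            zs.append(randomized_background(protein, q, None, 400, scale, rep).z)
        assert abs(np.mean(zs)) < 0.2

    def test_planted_pairs_separate_from_noncoding(self, rng):
        """Coding pairs give much lower z than random proteins vs random RNA."""
        scale = planted_affinity_scale(5.0, 7)
        coding_z, random_z = [], []
        for rep in range(25):
            protein, mrna, model = simulate_coding_pair(
                60, (0, 0), rng, codon_usage="canonical"
            )
            q = estat(protein, mrna, scale)
            coding_z.append(randomized_background(protein, q, None, 300, scale, rep).z)
            other = "".join(rng.choice(list("ACGU"), size=180))
            q2 = estat(protein, other, scale)
            random_z.append(randomized_background(protein, q2, None, 300, scale, rep).z)
        from scipy.stats import mannwhitneyu

        p = mannwhitneyu(coding_z, random_z, alternative="less").pvalue
        assert p < 0.001


class TestFragments:
    def test_full_length_matches_whole_protein_background(self, rng):
        scale = planted_affinity_scale(3.0, 5)
        protein, mrna, model = simulate_coding_pair(40, (0, 0), rng, "canonical")
        res = fragment_analysis(protein, mrna, 0, scale, [40], None, 3000, 1)
        whole_q = estat(protein, mrna, scale)
        assert res[40].value == pytest.approx(whole_q)
        ref = randomized_background(protein, whole_q, None, 3000, scale, 2)
        assert res[40].z == pytest.approx(ref.z, abs=0.6)

    def test_zero_scale_degenerate_flagged(self, rng):
        protein, mrna, _ = simulate_coding_pair(20, (0, 0), rng)
        res = fragment_analysis(protein, mrna, 0, zero_scale(), [5], None, 100, 0)
        assert res[5].flagged

    def test_planted_z_magnitude_grows_with_length(self, rng):
        scale = planted_affinity_scale(5.0, 6)
        protein, mrna, _ = simulate_coding_pair(120, (0, 0), rng, "canonical")
        res = fragment_analysis(
            protein, mrna, 0, scale, [4, 20, 80], None, 2000, 3
        )
        zs = [res[k].z for k in (4, 20, 80)]
        assert all(z < 0 for z in zs)
        assert zs[0] > zs[1] > zs[2]  # magnitude increases with length


class TestDisorderedSubset:
    def test_all_true_mask_equals_whole_query(self, rng):
        scale = planted_affinity_scale(2.0, 4)
        protein, mrna, _ = simulate_coding_pair(30, (0, 0), rng, "canonical")
        res = disordered_subset_scan(
            protein, np.ones(30, bool), mrna, 0, scale, None, 500, 0
        )
        assert res.value == pytest.approx(estat(protein, mrna, scale))

    def test_single_residue_mask_is_triplet_energy(self, rng):
        scale = AffinityScale(rng.normal(size=(20, 4)))
        protein, mrna, _ = simulate_coding_pair(10, (0, 0), rng)
        mask = np.zeros(10, bool)
        mask[4] = True
        res = disordered_subset_scan(protein, mask, mrna, 0, scale, None, 50, 0)
        assert res.value == pytest.approx(
            estat(protein[4], mrna[12:15], scale)
        )

    def test_empty_mask_rejected(self, rng):
        protein, mrna, _ = simulate_coding_pair(10, (0, 0), rng)
        with pytest.raises(ValueError, match="empty"):
            disordered_subset_scan(
                protein, np.zeros(10, bool), mrna, 0, zero_scale()
            )

    def test_partial_masks_keep_negative_mean_z(self, rng):
        scale = planted_affinity_scale(5.0, 8)
        zs = []
        for rep in range(20):
            protein, mrna, _ = simulate_coding_pair(60, (0, 0), rng, "canonical")
            mask = rng.random(60) < 0.4
            if not mask.any():
                continue
            zs.append(
                disordered_subset_scan(
                    protein, mask, mrna, 0, scale, None, 300, rep
                ).z
            )
        assert np.mean(zs) < -2


class TestBoundVsUnbound:
    def _pairs(self, rng, scale_strength, n, L=50):
        scale = planted_affinity_scale(scale_strength, 13)
        pairs = []
        for _ in range(n):
            protein, mrna, _ = simulate_coding_pair(L, (0, 0), rng, "canonical")
            pairs.append((protein, mrna))
        return scale, pairs

    def test_planted_signal_detected(self, rng):
        scale, bound = self._pairs(rng, 5.0, 20)
        unbound = [
            "".join(rng.choice(list("ACGU"), size=300)) for _ in range(30)
        ]
        res = bound_vs_unbound(bound, unbound, scale, n_samples=200, seed=0)
        assert res["mannwhitney_p"] < 0.01
        assert np.mean(res["bound_z"]) < -2

    def test_no_unbound_rejected(self, rng):
        scale, bound = self._pairs(rng, 1.0, 6)
        with pytest.raises(ValueError, match="unbound"):
            bound_vs_unbound(bound, [], scale)

    def test_single_species_single_row(self, rng):
        scale = planted_affinity_scale(2.0, 3)
        proteins, cds = {}, {}
        records = []
        for i in range(8):
            p, m, _ = simulate_coding_pair(30, (0, 0), rng, "canonical")
            name = f"R{i}"
            proteins[name], cds[name] = p, m
            records.append((name, "yeast", i < 5))
        out = species_bound_vs_unbound(
            records, proteins, cds, scale, n_samples=100, seed=0
        )
        assert len(out) == 1 and out[0]["species"] == "yeast"
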