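import numpy as np
import pytest

import dicodex as dx
from oracles import naive_counts, naive_class_normalize, random_toy_set


class TestCountTokens:
    def test_single_cds_codon_counts(self):
        seq = dx.CodingSequence("g", ("ATG", "GCT", "GCT", "GCC", "TAA"), 4)
        table = dx.count_tokens([seq], 1)
        assert table.counts["GCT"] == 2
        assert table.counts["GCC"] == 1
        assert sum(table.counts.values()) == 3
        assert len(table.counts) == 61  # zeros present

    def test_single_cds_dicodon_counts(self):
        seq = dx.CodingSequence("g", ("ATG", "GCT", "GCT", "GCC", "TAA"), 4)
        table = dx.count_tokens([seq], 2)
        assert table.counts["GCTGCT"] == 1
        assert table.counts["GCTGCC"] == 1
        assert sum(table.counts.values()) == 2
        assert len(table.counts) == 3721

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            dx.count_tokens([], 1)

    @pytest.mark.parametrize("arity", [1, 2])
    def test_counts_sum_over_sequences(self, arity, toy_seqs):
        whole = dx.count_tokens(toy_seqs, arity)
        summed = {}
        for seq in toy_seqs:
            for tok, c in dx.count_tokens([seq], arity).counts.items():
                summed[tok] = summed.get(tok, 0) + c
        assert whole.counts == summed

    @pytest.mark.parametrize("arity", [1, 2])
    def test_matches_naive_recount_on_random_sets(self, arity):
        rng = np.random.default_rng(42)
        for _ in range(25):
            seqs = random_toy_set(rng)
            got = dx.count_tokens(seqs, arity).counts
            want = naive_counts(seqs, arity)
            assert {t: c for t, c in got.items() if c} == want


class TestWeightedCounts:
    def test_hand_computed_weighted_count(self):
        # o(t)=2 with w=10 and o(t)=1 with w=0: b = (2*10 + 1*0) / 10 = 2
        s1 = dx.CodingSequence("a", ("ATG", "AAA", "AAA"), 3)
        s2 = dx.CodingSequence("b", ("ATG", "AAA"), 2)
        table = dx.weighted_count_tokens([s1, s2], {"a": 10.0, "b": 0.0}, 1)
        assert table.counts["AAA"] == pytest.approx(2.0)
        assert table.total_weight == pytest.approx(10.0)

    def test_equal_weights_proportional_to_plain(self, toy_seqs):
        plain = dx.count_tokens(toy_seqs, 2)
        weighted = dx.weighted_count_tokens(
            toy_seqs, {s.gene_id: 3.0 for s in toy_seqs}, 2
        )
        for tok, c in plain.counts.items():
            assert weighted.counts[tok] * len(toy_seqs) == pytest.approx(c)

    def test_missing_weights_skipped(self, toy_seqs):
        table = dx.weighted_count_tokens(toy_seqs, {"g1": 1.0}, 1)
        only_g1 = dx.count_tokens(toy_seqs[:1], 1)
        assert table.counts == pytest.approx(only_g1.counts)

    def test_all_zero_weights_rejected(self, toy_seqs):
        with pytest.raises(ValueError):
            dx.weighted_count_tokens(toy_seqs, {s.gene_id: 0.0 for s in toy_seqs}, 1)

    def test_negative_weight_rejected(self, toy_seqs):
        with pytest.raises(ValueError):
            dx.weighted_count_tokens(toy_seqs, {"g1": -1.0, "g2": 1.0, "g3": 1.0}, 1)

    def test_matches_naive_weighted_recount(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            seqs = random_toy_set(rng)
            weights = {s.gene_id: float(rng.uniform(0.1, 5.0)) for s in seqs}
            got = dx.weighted_count_tokens(seqs, weights, 2)
            want = naive_counts(seqs, 2, weights)
            total = sum(weights.values())
            for tok, b in want.items():
                assert got.counts[tok] == pytest.approx(b / total)


class TestRelativeAdaptiveness:
    def test_direct_ratios_with_pseudocount(self):
        # class counts {GCT:10, GCC:5, GCA:0, GCG:0}, pseudo-count 0.5
        seqs = [
            dx.CodingSequence(
                "g", ("ATG",) + ("GCT",) * 10 + ("GCC",) * 5, 16
            )
        ]
        table = dx.relative_adaptiveness(dx.count_tokens(seqs, 1))
        assert table.values["GCT"] == pytest.approx(1.0)
        assert table.values["GCC"] == pytest.approx(0.5)
        assert table.values["GCA"] == pytest.approx(0.05)
        assert table.values["GCG"] == pytest.approx(0.05)

    def test_equal_counts_give_all_ones(self):
        seqs = [dx.CodingSequence("g", ("ATG", "GCT", "GCC", "GCA", "GCG"), 5)]
        table = dx.relative_adaptiveness(dx.count_tokens(seqs, 1))
        for codon in ("GCT", "GCC", "GCA", "GCG"):
            assert table.values[codon] == pytest.approx(1.0)

    def test_unobserved_class_floored_at_epsilon(self):
        seqs = [dx.CodingSequence("g", ("ATG", "GCT", "GCT"), 3)]
        table = dx.relative_adaptiveness(dx.count_tokens(seqs, 1))
        assert table.values["AAA"] == table.epsilon  # lysine never observed

    def test_per_class_max_is_one_everywhere_observed(self, small_sim, code):
        for arity in (1, 2):
            table = dx.relative_adaptiveness(dx.count_tokens(small_sim["seqs"], arity))
            for members in code.classes(arity).values():
                vmax = max(table.values[t] for t in members)
                assert vmax == pytest.approx(1.0) or vmax == table.epsilon

    def test_matches_naive_oracle_over_dicodon_classes(self, code):
        rng = np.random.default_rng(3)
        seqs = random_toy_set(rng, n_seqs=10)
        table = dx.relative_adaptiveness(
            dx.count_tokens(seqs, 2), pseudocount=0.0
        )
        naive = naive_class_normalize(naive_counts(seqs, 2), code.classes(2))
        for tok, v in naive.items():
            if v > 0:
                assert table.values[tok] == pytest.approx(v)

    def test_weighted_path_uses_no_pseudocount(self):
        seqs = [
            dx.CodingSequence("g", ("ATG",) + ("GCT",) * 10 + ("GCC",) * 5, 16)
        ]
        table = dx.relative_adaptiveness(
            dx.weighted_count_tokens(seqs, {"g": 2.0}, 1)
        )
        assert table.kind == "f"
        assert table.values["GCA"] == table.epsilon

    def test_constant_weight_equivalence(self, toy_seqs):
        """Equal weights reduce f exactly to a (pseudo-count disabled)."""
        for arity in (1, 2):
            a = dx.relative_adaptiveness(
                dx.count_tokens(toy_seqs, arity), pseudocount=0.0
            )
            f = dx.relative_adaptiveness(
                dx.weighted_count_tokens(
                    toy_seqs, {s.gene_id: 2.5 for s in toy_seqs}, arity
                )
            )
            assert a.values == f.values

    def test_weight_rescaling_invariance(self, small_sim):
        seqs = small_sim["seqs"][:50]
        weights = {s.gene_id: small_sim["weights"][s.gene_id] for s in seqs}
        scaled = {g: 137.0 * w for g, w in weights.items()}
        f1 = dx.relative_adaptiveness(dx.weighted_count_tokens(seqs, weights, 2))
        f2 = dx.relative_adaptiveness(dx.weighted_count_tokens(seqs, scaled, 2))
        for tok in f1.values:
            assert f1.values[tok] == pytest.approx(f2.values[tok], rel=1e-12)


class TestPowerTransform:
    def test_identity_and_square(self, toy_seqs):
        table = dx.relative_adaptiveness(dx.count_tokens(toy_seqs, 1))
        same = dx.power_transform(table, 1)
        assert same.values == table.values
        squared = dx.power_transform(table, 2)
        for tok, v in table.values.items():
            assert squared.values[tok] == pytest.approx(v * v)
        assert squared.power == 2.0

    def test_square_shifts_mass_to_extremes(self, small_sim):
        table = dx.relative_adaptiveness(dx.count_tokens(small_sim["seqs"], 2))
        squared = dx.power_transform(table, 2)
        vals = np.array(list(table.values.values()))
        sq = np.array(list(squared.values.values()))
        assert (sq <= vals).all()
        assert (sq[vals < 1] < vals[vals < 1]).all()

    def test_invalid_power(self, toy_seqs):
        table = dx.relative_adaptiveness(dx.count_tokens(toy_seqs, 1))
        with pytest.raises(ValueError):
            dx.power_transform(table, 0)


class TestExpectedProduct:
    def test_products_match_double_loop(self, small_sim, code):
        table = dx.relative_adaptiveness(dx.count_tokens(small_sim["seqs"], 1))
        expected = dx.expected_product_table(table)
        assert len(expected.values) == 3721
        for a in code.sense_codons[::7]:
            for b in code.sense_codons[::11]:
                want = max(table.values[a] * table.values[b], table.epsilon)
                assert expected.values[a + b] == pytest.approx(want)

    def test_optimal_pair_has_product_one(self, small_sim):
        table = dx.relative_adaptiveness(dx.count_tokens(small_sim["seqs"], 1))
        ones = [t for t, v in table.values.items() if v == 1.0]
        expected = dx.expected_product_table(table)
        assert expected.values[ones[0] + ones[1]] == pytest.approx(1.0)

    def test_requires_codon_table(self, small_sim):
        dicodon = dx.relative_adaptiveness(dx.count_tokens(small_sim["seqs"], 2))
        with pytest.raises(ValueError):
            dx.expected_product_table(dicodon)


class TestSerialization:
    def test_tsv_roundtrip_bit_stable(self, tmp_path, small_sim):
        table = dx.relative_adaptiveness(
            dx.weighted_count_tokens(
                small_sim["seqs"], small_sim["weights"], 2
            )
        )
        path = tmp_path / "contrib.tsv"
        table.to_tsv(path)
        back = dx.ContributionTable.from_tsv(path)
        assert back.arity == 2 and back.kind == "f"
        assert back.values == table.values  # full double precision

    def test_from_tsv_validates_columns(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("token\tvalue\nGCT\t0.5\n")
        with pytest.raises(ValueError, match="missing columns"):
            dx.ContributionTable.from_tsv(path)
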