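import dataclasses

import numpy as np
import pytest

from conftest import brute_force_pair_counts, make_record, make_set, random_snv_set
from ffpeqc.concordance import (
    classify_concordance,
    common_positions,
    commonality_fraction,
    concordance_rate,
    is_concordant,
    kit_difference_stats,
    pair_summary,
    round_half_up,
)
from ffpeqc.simulate import SimulationConfig, simulate_pair
from ffpeqc.variant_io import SNV, apply_quality_filter


class TestCommonPositions:
    def test_identical_sets_pair_every_record(self, rng):
        a = random_snv_set(rng, 40)
        b = make_set(list(a), sample_id="B", condition="FFPE")
        assert len(common_positions(a, b)) == 40

    def test_disjoint_sets_share_nothing(self):
        a = make_set([make_record(pos=i) for i in range(1, 11)])
        b = make_set([make_record(pos=i) for i in range(100, 110)], condition="FFPE")
        assert common_positions(a, b) == []

    def test_constructed_overlap_matches_brute_force(self, rng):
        for _ in range(10):
            a = random_snv_set(rng, int(rng.integers(5, 80)))
            b = random_snv_set(rng, int(rng.integers(5, 80)), condition="FFPE")
            n_pos, _, _ = brute_force_pair_counts(list(a), list(b))
            assert len(common_positions(a, b)) == n_pos

    def test_mixed_vclass_rejected(self):
        mixed = make_set([make_record(pos=1), make_record(pos=2, ref="CT", alt="C")])
        snvs = make_set([make_record(pos=1)], condition="FFPE")
        with pytest.raises(ValueError, match="mixed"):
            common_positions(mixed, snvs)

    def test_ref_mismatch_at_same_coordinate_is_not_shared(self):
        a = make_set([make_record(pos=5, ref="C", alt="T")])
        b = make_set([make_record(pos=5, ref="G", alt="T")], condition="FFPE")
        assert common_positions(a, b) == []


class TestClassification:
    def test_same_call_concordant(self):
        a, b = make_record(), make_record()
        assert is_concordant(a, b)

    def test_different_alt_discordant(self):
        assert not is_concordant(make_record(alt="T"), make_record(alt="G"))

    def test_genotype_mode_rejects_zygosity_change(self):
        het, hom = make_record(gt=(0, 1)), make_record(gt=(1, 1))
        assert not is_concordant(het, hom, mode="genotype")
        assert is_concordant(het, hom, mode="allele")

    def test_hand_classified_ten_pair_fixture(self):
        # hand truth: genotype mode -> 6 concordant, allele mode -> 8
        ff, ffpe, genotype_truth, allele_truth = [], [], 0, 0
        cases = [
            ("T", (0, 1), "T", (0, 1), True, True),
            ("G", (1, 1), "G", (1, 1), True, True),
            ("T", (0, 1), "G", (0, 1), False, False),
            ("T", (0, 1), "T", (1, 1), False, True),
            ("A", (1, 1), "A", (1, 1), True, True),
            ("T", (1, 0), "T", (0, 1), True, True),   # unordered genotype
            ("G", (0, 1), "T", (1, 1), False, False),
            ("T", (0, 1), "T", (0, 1), True, True),
            ("A", (1, 1), "A", (0, 1), False, True),
            ("T", (0, 1), "T", (0, 1), True, True),
        ]
        for i, (alt_a, gt_a, alt_b, gt_b, geno_ok, allele_ok) in enumerate(cases):
            ref = "C" if "C" not in (alt_a, alt_b) else "G"
            ff.append(make_record(pos=i + 1, ref=ref, alt=alt_a, gt=gt_a))
            ffpe.append(make_record(pos=i + 1, ref=ref, alt=alt_b, gt=gt_b))
            genotype_truth += geno_ok
            allele_truth += allele_ok
        pairs = list(zip(ff, ffpe))
        assert classify_concordance(pairs, "genotype") == (genotype_truth, 10 - genotype_truth)
        assert classify_concordance(pairs, "allele") == (allele_truth, 10 - allele_truth)


class TestRates:
    @pytest.mark.parametrize(
        "n_co,n_pos,expected",
        [(39772, 39778, 99.98), (3216, 3267, 98.44), (500, 500, 100.00),
         (37572, 37577, 99.99)],
    )
    def test_concordance_rate_reference_rows(self, n_co, n_pos, expected):
        assert concordance_rate(n_co, n_pos) == expected

    def test_rate_undefined_without_common_positions(self):
        with pytest.raises(ValueError, match="undefined"):
            concordance_rate(0, 0)

    @pytest.mark.parametrize(
        "n_ff,n_ffpe,n_pos,expected_rounded",
        [(41189, 36215, 35751, 86), (3732, 2736, 2593, 67), (7, 7, 7, 100)],
    )
    def test_commonality_union_denominator(self, n_ff, n_ffpe, n_pos, expected_rounded):
        assert round(commonality_fraction(n_ff, n_ffpe, n_pos)) == expected_rounded

    def test_commonality_exact_values(self):
        assert round(commonality_fraction(41189, 36215, 35751), 2) == 85.83
        assert round(commonality_fraction(3732, 2736, 2593), 2) == 66.92

    def test_round_half_up_at_ties(self):
        assert round_half_up(99.985, 2) == 99.99
        assert round_half_up(98.445, 2) == 98.45
        assert round(99.985, 2) == 99.98  # why banker's rounding is not used


class TestPairSummary:
    def test_identical_pair_is_fully_concordant(self, rng):
        ff = random_snv_set(rng, 30)
        ffpe = make_set(list(ff), sample_id="E", condition="FFPE")
        pc = pair_summary(ff, ffpe, SNV)
        assert (pc.n_di, pc.p, pc.common_frac) == (0, 100.00, 100.0)

    def test_twenty_variant_hand_fixture(self):
        # FF: 12 shared + 4 private; FFPE: 12 shared + 3 private.
        # Of the shared: 8 identical, 3 alt swaps, 1 zygosity flip.
        ff, ffpe = [], []
        for i in range(8):
            ff.append(make_record(pos=i + 1))
            ffpe.append(make_record(pos=i + 1))
        for i in range(8, 11):
            ff.append(make_record(pos=i + 1, alt="T"))
            ffpe.append(make_record(pos=i + 1, alt="G"))
        ff.append(make_record(pos=12, gt=(0, 1)))
        ffpe.append(make_record(pos=12, gt=(1, 1)))
        ff += [make_record(pos=p) for p in (20, 21, 22, 23)]
        ffpe += [make_record(pos=p) for p in (30, 31, 32)]
        pc = pair_summary(make_set(ff), make_set(ffpe, condition="FFPE"), SNV)
        assert (pc.n_ff, pc.n_ffpe, pc.n_pos, pc.n_co, pc.n_di) == (16, 15, 12, 8, 4)
        assert pc.p == round_half_up(100 * 8 / 12, 2)
        assert pc.common_frac == 100 * 12 / (16 + 15 - 12)
        allele = pair_summary(make_set(ff), make_set(ffpe, condition="FFPE"),
                              SNV, mode="allele")
        assert (allele.n_co, allele.n_di) == (9, 3)

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(15):
            ff = random_snv_set(rng, int(rng.integers(10, 200)), pos_space=400)
            ffpe = random_snv_set(rng, int(rng.integers(10, 200)),
                                  condition="FFPE", pos_space=400)
            n_pos, n_co, n_di = brute_force_pair_counts(list(ff), list(ffpe))
            pc = pair_summary(ff, ffpe, SNV)
            assert (pc.n_pos, pc.n_co, pc.n_di) == (n_pos, n_co, n_di)

    def test_swap_symmetry_of_npos_and_commonality(self, rng):
        ff = random_snv_set(rng, 60)
        ffpe = random_snv_set(rng, 80, condition="FFPE")
        a = pair_summary(ff, ffpe, SNV)
        b = pair_summary(
            make_set(list(ffpe), sample_id="x"),
            make_set(list(ff), sample_id="y", condition="FFPE"), SNV)
        assert (a.n_pos, a.common_frac) == (b.n_pos, b.common_frac)

    def test_simulator_injected_discordance_is_recovered_exactly(self):
        cfg = SimulationConfig(n_germline=4000, discordance_prob=0.01, seed=9)
        ff, ffpe, ledger = simulate_pair(cfg)
        pc_snv = pair_summary(apply_quality_filter(ff), apply_quality_filter(ffpe), "SNV")
        pc_ind = pair_summary(apply_quality_filter(ff), apply_quality_filter(ffpe), "INDEL")
        assert pc_snv.n_di + pc_ind.n_di == ledger.n_discordant
        assert pc_snv.n_pos + pc_ind.n_pos == ledger.n_shared


class TestKitStats:
    def test_even_group_median_averages_middle_two(self):
        summaries = [
            dataclasses.replace(_pc(str(i), 1000 + d, 1000), pair_id=str(i))
            for i, d in enumerate([10, 30, 20, 40])
        ]
        out = kit_difference_stats(summaries, {s.pair_id: "GeneRead" for s in summaries})
        assert out[0].median_diff == 25.0

    def test_identical_counts_give_zero_median(self):
        summaries = [_pc(str(i), 500, 500) for i in range(3)]
        out = kit_difference_stats(summaries, {str(i): "QIAamp" for i in range(3)})
        assert out[0].median_diff == 0

    def test_unmapped_pair_rejected(self):
        with pytest.raises(ValueError, match="kit"):
            kit_difference_stats([_pc("1", 10, 10)], {})


def _pc(pair_id, n_ff, n_ffpe):
    from ffpeqc.concordance import PairComparison
    return PairComparison(pair_id=pair_id, vclass=SNV, n_ff=n_ff, n_ffpe=n_ffpe,
                          n_pos=0, n_co=0, n_di=0, p=float("nan"),
                          common_frac=float("nan"))
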