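"""Trinucleotide-adjusted SNV burden, Fisher enrichment, terminator partition."""

import math

import numpy as np
import pytest

from irtopo.genome_io import GenomeSequence, SnvSite
from irtopo.ir_detection import InvertedRepeat
from irtopo.snv_burden import (
    CANONICAL_TRINUCS,
    burden_tables,
    classify_positions,
    expected_burden_trinuc,
    fisher_ir_enrichment,
    genome_snv_density,
    partition_by_terminator,
    regression_deviation_ratio,
    segment_class_counts,
    terminator_partition_density,
    trinucleotide_profile,
)

from conftest import random_seq


def snv(seq_id, pos, ref="A", alt="G"):
    return SnvSite(seq_id, pos, ref, alt, 60.0, 100.0)


def make_ir(seq, start, arm, spacer, seq_id="g"):
    end = start + 2 * arm + spacer
    return InvertedRepeat(
        seq_id, start, end, arm, spacer,
        seq[start : start + arm], seq[start + arm : start + arm + spacer], seq[end - arm : end],
    )


class TestCanonicalClasses:
    def test_exactly_32(self):
        assert len(CANONICAL_TRINUCS) == 32
        assert len(set(CANONICAL_TRINUCS)) == 32

    def test_revcomp_canonicalization(self):
        from irtopo.ir_detection import reverse_complement

        for t in CANONICAL_TRINUCS:
            assert t <= reverse_complement(t)
        # TTT is represented by AAA
        assert "AAA" in CANONICAL_TRINUCS and "TTT" not in CANONICAL_TRINUCS

    def test_classify_homopolymer(self):
        cls = classify_positions("AAAA")
        aaa = CANONICAL_TRINUCS.index("AAA")
        assert list(cls) == [-1, aaa, aaa, -1]
        assert list(classify_positions("TTTT"))[1:3] == [aaa, aaa]

    def test_n_context_unclassified(self):
        cls = classify_positions("AANAA")
        assert cls[1] == -1 and cls[2] == -1 and cls[3] == -1


class TestProfile:
    def test_simple_rate(self):
        g = GenomeSequence("g", "AAAA")
        prof = trinucleotide_profile(g, [snv("g", 1)])
        j = CANONICAL_TRINUCS.index("AAA")
        assert prof.genome_occurrences[j] == 2
        assert prof.p[j] == pytest.approx(0.5)

    def test_duplicate_positions_counted_once(self):
        g = GenomeSequence("g", "AAAAA")
        prof = trinucleotide_profile(g, [snv("g", 2, alt="G"), snv("g", 2, alt="C")])
        j = CANONICAL_TRINUCS.index("AAA")
        assert prof.snv_site_occurrences[j] == 1

    def test_genome_snv_density(self):
        g = GenomeSequence("g", "A" * 10_000)
        sites = [snv("g", p) for p in range(10)] + [snv("g", 3, alt="C")]
        assert genome_snv_density(sites, g) == pytest.approx(1e-3)
        assert genome_snv_density([], g) == 0.0


class TestExpectedBurden:
    def test_matches_per_position_oracle(self, rng):
        seq = random_seq(rng, 5000)
        g = GenomeSequence("g", seq)
        sites = [snv("g", int(p), seq[int(p)]) for p in rng.choice(5000, 60, replace=False)]
        prof = trinucleotide_profile(g, sites)
        segments = {"g": [(100, 400), (1200, 1500), (4800, 5000)]}
        expected = expected_burden_trinuc(segments, g, prof)
        cls = classify_positions(seq)
        oracle = sum(
            prof.p[cls[pos]]
            for s, e in segments["g"]
            for pos in range(s, e)
            if cls[pos] >= 0
        )
        assert expected == pytest.approx(oracle, abs=1e-9)

    def test_zero_rates_zero_expectation(self, rng):
        seq = random_seq(rng, 500)
        g = GenomeSequence("g", seq)
        prof = trinucleotide_profile(g, [])
        assert expected_burden_trinuc({"g": [(0, 500)]}, g, prof) == 0.0

    def test_class_partition_is_exhaustive(self, rng):
        seq = random_seq(rng, 2000)
        g = GenomeSequence("g", seq)
        inside = {"g": [(100, 600)]}
        outside = {"g": [(0, 100), (600, 2000)]}
        total = segment_class_counts({"g": [(0, 2000)]}, g)
        assert (segment_class_counts(inside, g) + segment_class_counts(outside, g) == total).all()
        assert total.sum() == 1998  # every interior position of an N-free genome

    def test_uniform_rates_converge_to_length_null(self, rng):
        # equal p_j for all classes ~ L·r on an N-free genome (up to edge effects)
        seq = random_seq(rng, 8000)
        g = GenomeSequence("g", seq)
        sites = [snv("g", int(p), seq[int(p)]) for p in rng.choice(8000, 400, replace=False)]
        prof = trinucleotide_profile(g, sites)
        prof.p[:] = 5e-2
        seg = {"g": [(1000, 3000)]}
        e_tri = expected_burden_trinuc(seg, g, prof)
        assert e_tri == pytest.approx(2000 * 5e-2, rel=1e-9)


class TestBurdenTables:
    def test_spacer_only_snv(self, rng):
        seq = random_seq(rng, 300)
        ir = make_ir(seq, 50, 10, 4)
        g = GenomeSequence("g", seq)
        spacer_pos = 50 + 10 + 1
        tabs = burden_tables([ir], [snv("g", spacer_pos, seq[spacer_pos])], g)
        assert tabs["spacers"].observed == 1
        assert tabs["arms"].observed == 0
        assert tabs["arms"].L == 20 and tabs["spacers"].L == 4

    def test_no_snvs(self, rng):
        seq = random_seq(rng, 200)
        tabs = burden_tables([make_ir(seq, 20, 10, 2)], [], GenomeSequence("g", seq))
        assert tabs["arms"].observed == 0 and tabs["spacers"].observed == 0

    def test_length_expectation_arithmetic(self, rng):
        # L = 100 arm bp at r = 0.01 -> E = 1.0
        seq = random_seq(rng, 10_000)
        irs = [make_ir(seq, 100 + 200 * k, 10, 0) for k in range(5)]
        g = GenomeSequence("g", seq)
        sites = [snv("g", int(p), seq[int(p)]) for p in rng.choice(10_000, 100, replace=False)]
        tabs = burden_tables(irs, sites, g)
        assert tabs["arms"].L == 100
        assert tabs["arms"].r == pytest.approx(0.01)
        assert tabs["arms"].expected_length == pytest.approx(1.0)

    def test_arm_precedence_on_overlap(self, rng):
        seq = random_seq(rng, 300)
        a = make_ir(seq, 50, 10, 4)  # spacer [60, 64)
        b = make_ir(seq, 55, 10, 0)  # arms [55,65) + [65,75): covers a's spacer
        tabs = burden_tables([a, b], [], GenomeSequence("g", seq))
        assert tabs["spacers"].L == 0  # fully reassigned to arms
        assert tabs["arms"].L == 25  # merged arm union [50, 75)


class TestFisher:
    def test_hand_computed_odds_ratio(self):
        odds, p = fisher_ir_enrichment(10, 5.0, 100)
        assert odds == pytest.approx((10 * 95) / (90 * 5), rel=1e-9)
        assert 0 < p <= 1

    def test_equal_proportions_or_one(self):
        odds, _ = fisher_ir_enrichment(10, 10.0, 100)
        assert odds == pytest.approx(1.0)

    def test_direction(self):
        odds, _ = fisher_ir_enrichment(50, 20.0, 100)
        assert odds > 1

    def test_zero_margin_flagged(self):
        odds, p = fisher_ir_enrichment(0, 0.0, 100)
        assert math.isnan(odds) and math.isnan(p)

    def test_rounding_half_away_from_zero(self):
        # expected 4.5 rounds to 5
        odds, _ = fisher_ir_enrichment(10, 4.5, 100)
        assert odds == pytest.approx((10 * 95) / (90 * 5), rel=1e-9)


class TestTerminatorPartition:
    def test_no_terminators_all_far(self, rng):
        seq = random_seq(rng, 500)
        irs = [make_ir(seq, 50, 10, 4), make_ir(seq, 200, 10, 0)]
        near, far = partition_by_terminator(irs, {}, distance=50)
        assert near == [] and far == irs

    def test_boundary_inclusive_at_50(self, rng):
        seq = random_seq(rng, 1000)
        ir = make_ir(seq, 100, 10, 4)  # span [100, 124)
        exactly_50 = {"g": [(174, 190)]}  # gap = 174 - 124 = 50
        near, far = partition_by_terminator([ir], exactly_50, distance=50)
        assert near == [ir]
        too_far = {"g": [(175, 190)]}  # gap 51
        near, far = partition_by_terminator([ir], too_far, distance=50)
        assert far == [ir]

    def test_density_table_structure(self, rng):
        seq = random_seq(rng, 2000)
        irs = [make_ir(seq, 100, 10, 4), make_ir(seq, 800, 12, 2)]
        sites = [snv("g", 111, seq[111])]  # inside first IR's spacer
        df = terminator_partition_density(irs, sites, {"g": [(130, 150)]})
        near_spacer = df[(df.segment == "spacers") & (df.group == "near") & (df.spacer == "all")]
        assert near_spacer["observed"].item() == 1
        assert near_spacer["density"].item() == pytest.approx(1 / 4)


class TestRegressionDeviation:
    def test_slope_one_numerator_zero(self):
        exp = np.array([1.0, 2.0, 3.0])
        r = regression_deviation_ratio(exp, exp * 2, exp, exp)  # arm slope 2, spacer slope 1
        assert r == 0.0

    def test_equal_deviations_ratio_one(self):
        # slopes tan(60°) and tan(30°) deviate equally from 45°
        exp = np.array([1.0, 2.0, 4.0])
        obs_spacer = exp * math.tan(math.pi / 3)
        obs_arm = exp * math.tan(math.pi / 6)
        r = regression_deviation_ratio(obs_arm, exp, obs_spacer, exp)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_denominator_slope_one_flagged(self):
        exp = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ZeroDivisionError):
            regression_deviation_ratio(exp, exp, exp * 3, exp)

    def test_orientation_switch_inverts(self):
        exp = np.array([1.0, 3.0, 5.0])
        r1 = regression_deviation_ratio(exp * 1.2, exp, exp * 2.0, exp)
        r2 = regression_deviation_ratio(
            exp * 1.2, exp, exp * 2.0, exp, orientation="arm_over_spacer"
        )
        assert r1 == pytest.approx(1 / r2)
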