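"""Per-gene codon-usage indices against hand values and brute-force oracles."""

import math

import numpy as np
import pytest

from codonuse.genetic_code import SENSE_CODONS, STOP_CODONS
from codonuse.metrics import (
    CodonCountTable,
    compute_cai,
    compute_cbi,
    compute_enc,
    compute_fop,
    compute_rscu,
    count_codons,
    enc_from_class_means,
    expected_enc,
    fk_homozygosity,
    optimal_codons,
    pooled_counts,
    positional_composition,
    pr2_coordinates,
    relative_adaptiveness,
    stop_codon_partition,
)
from codonuse.simulate import KNOWN_OPTIMAL_SET

import oracles


def _counts(seq):
    return CodonCountTable.from_string(seq)


class TestCounting:
    def test_simple_counts(self):
        t = _counts("ATGGCCTAA")
        assert t.counts["ATG"] == t.counts["GCC"] == t.counts["TAA"] == 1
        assert t.total() == 3 and t.nt_total == 9
        t2 = _counts("ATGATG")
        assert t2.counts["ATG"] == 2 and t2.total() == 2

    def test_length_not_multiple_of_three_raises(self):
        with pytest.raises(ValueError):
            _counts("ATGG")

    def test_count_conservation_random(self):
        rng = np.random.default_rng(0)
        codons = rng.choice(list(SENSE_CODONS), size=100)
        t = _counts("".join(codons))
        assert t.total() == 100


class TestRSCU:
    def test_two_fold_family(self):
        # Lys family AAA/AAG with counts (3, 1)
        r = compute_rscu(_counts("AAA" * 3 + "AAG"))
        assert r.rscu["AAA"] == pytest.approx(1.5)
        assert r.rscu["AAG"] == pytest.approx(0.5)

    def test_uniform_usage_gives_ones(self, fixtures):
        r = compute_rscu(count_codons(fixtures["rscu_uniform"]))
        assert all(r.rscu[c] == pytest.approx(1.0) for c in SENSE_CODONS)

    def test_absent_family_is_nan_not_zero(self):
        r = compute_rscu(_counts("AAA" * 4))
        assert math.isnan(r.rscu["GGG"])

    def test_family_sums_equal_family_size(self, random_genes):
        from codonuse.genetic_code import FAMILIES
        for gene in random_genes[:20]:
            r = compute_rscu(count_codons(gene))
            for fam in FAMILIES.values():
                vals = [r.rscu[c] for c in fam]
                if any(math.isnan(v) for v in vals):
                    continue
                assert sum(vals) == pytest.approx(len(fam), abs=1e-9)

    def test_stop_family_partition(self):
        # stop usage (2, 1, 1) -> RSCU (1.5, 0.75, 0.75) summing to 3
        seq = "TAA" * 2 + "TAG" + "TGA"
        r = compute_rscu(_counts(seq))
        assert sum(r.rscu[c] for c in STOP_CODONS) == pytest.approx(3.0)
        part = stop_codon_partition({c: r.rscu[c] for c in STOP_CODONS})
        assert part["TAA"] == pytest.approx(0.5)


class TestFk:
    @pytest.mark.parametrize(
        "counts,expected",
        [((3, 1), 0.5), ((5, 0), 1.0), ((2, 2), 1 / 3)],
    )
    def test_hand_values(self, counts, expected):
        assert fk_homozygosity(counts) == pytest.approx(expected)

    def test_undefined_below_two(self):
        assert math.isnan(fk_homozygosity((1, 0)))
        assert math.isnan(fk_homozygosity((0, 0)))


class TestENC:
    def test_enc20_fixture(self, fixtures):
        assert compute_enc(count_codons(fixtures["enc20"])) == pytest.approx(20.0)

    def test_uniform_limit_is_61(self):
        assert enc_from_class_means(0.5, 1 / 3, 0.25, 1 / 6) == pytest.approx(61.0)

    def test_enc_at_least_20(self, random_genes):
        for gene in random_genes[:50]:
            enc = compute_enc(count_codons(gene))
            assert math.isnan(enc) or enc >= 20.0 - 1e-12

    def test_not_capped_at_61(self):
        # every two-codon family used (1,1): fk = 0 -> infinite ENC is legal
        seq = "".join(("AAA" + "AAG") for _ in range(1)) + "ATT" * 3 + "GCT" * 2 + "TTA" * 2
        enc = compute_enc(_counts(seq))
        assert enc > 61 or math.isinf(enc)

    def test_matches_oracle(self, random_genes):
        for gene in random_genes[:50]:
            mine = compute_enc(count_codons(gene))
            ref = oracles.oracle_enc(gene.seq)
            if math.isnan(ref):
                assert math.isnan(mine)
            else:
                assert mine == pytest.approx(ref, abs=1e-9)


class TestExpectedENC:
    @pytest.mark.parametrize("s,expected", [(0.5, 60.5), (1.0, 32.0), (0.0, 31.0)])
    def test_closed_form(self, s, expected):
        assert expected_enc(s) == pytest.approx(expected)

    def test_domain(self):
        with pytest.raises(ValueError):
            expected_enc(1.2)

    def test_symmetry_up_to_linear_term(self):
        for s in np.linspace(0, 0.5, 11):
            assert expected_enc(s) - s == pytest.approx(expected_enc(1 - s) - (1 - s))


class TestCAI:
    def test_w_ratio_to_family_max(self):
        r = compute_rscu(_counts("AAA" * 3 + "AAG"))
        w = relative_adaptiveness(r)
        assert w["AAA"] == pytest.approx(1.0)
        assert w["AAG"] == pytest.approx(1 / 3)
        assert "ATG" not in w and "TGG" not in w and "TAA" not in w

    def test_all_uniform_reference_gives_w_one(self, fixtures):
        r = compute_rscu(count_codons(fixtures["rscu_uniform"]))
        w = relative_adaptiveness(r)
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_cai_one_on_family_maximal_gene(self, fixtures):
        gene = fixtures["cai_one"]
        counts = count_codons(gene)
        w = relative_adaptiveness(compute_rscu(counts, pseudocount=0.5))
        assert compute_cai(counts, w) == pytest.approx(1.0)

    def test_single_codon_gene(self):
        assert compute_cai(_counts("AAG"), {"AAG": 0.4}) == pytest.approx(0.4)

    def test_bounds_and_oracle(self, random_genes):
        pooled = pooled_counts(random_genes)
        w = relative_adaptiveness(compute_rscu(pooled, pseudocount=0.5))
        for gene in random_genes[:50]:
            cai = compute_cai(count_codons(gene), w)
            assert 0.0 <= cai <= 1.0
            assert cai == pytest.approx(oracles.oracle_cai(gene.seq, w), abs=1e-9)


class TestOptimalCodons:
    def test_strict_threshold(self):
        # counts (161, 39) -> RSCU (1.61, 0.39): first codon optimal
        r = compute_rscu(_counts("AAA" * 161 + "AAG" * 39))
        assert optimal_codons(r) == {"AAA"}
        # counts (160, 40) -> RSCU exactly (1.6, 0.4): boundary excluded
        r = compute_rscu(_counts("AAA" * 160 + "AAG" * 40))
        assert optimal_codons(r) == frozenset()

    def test_uniform_genome_has_no_optimal_codons(self, fixtures):
        r = compute_rscu(count_codons(fixtures["rscu_uniform"]))
        assert optimal_codons(r) == frozenset()


class TestCBIandFOP:
    def test_all_optimal_gene(self, fixtures):
        counts = count_codons(fixtures["cbi_all_optimal"])
        assert compute_cbi(counts, KNOWN_OPTIMAL_SET) == pytest.approx(1.0)
        assert compute_fop(counts, KNOWN_OPTIMAL_SET) == pytest.approx(1.0)

    def test_at_random_gene(self, fixtures):
        counts = count_codons(fixtures["cbi_at_random"])
        assert compute_cbi(counts, KNOWN_OPTIMAL_SET) == pytest.approx(0.0)

    def test_empty_optimal_set_undefined(self, fixtures):
        counts = count_codons(fixtures["clean"])
        assert math.isnan(compute_cbi(counts, frozenset()))
        assert math.isnan(compute_fop(counts, frozenset()))

    def test_cbi_can_be_negative(self):
        # gene avoids the optimal codon entirely
        counts = _counts("AAG" * 10)
        assert compute_cbi(counts, {"AAA"}) == pytest.approx(-1.0)

    def test_matches_oracle(self, random_genes):
        pooled = pooled_counts(random_genes)
        optimal = optimal_codons(compute_rscu(pooled))
        assert optimal  # biased genes must yield some superior codons
        for gene in random_genes[:50]:
            counts = count_codons(gene)
            assert compute_cbi(counts, optimal) == pytest.approx(
                oracles.oracle_cbi(gene.seq, set(optimal)), abs=1e-9
            )
            assert compute_fop(counts, optimal) == pytest.approx(
                oracles.oracle_fop(gene.seq, set(optimal)), abs=1e-9
            )

    def test_fop_rscu_weighted_degenerate_mean(self):
        # reference where AAA carries the whole Lys family -> RSCU 2.0;
        # a gene using only AAA then has weighted-mean RSCU exactly 2.0
        ref = compute_rscu(_counts("AAA" * 2))
        assert ref.rscu["AAA"] == pytest.approx(2.0)
        counts = _counts("AAA" * 5)
        assert compute_fop(counts, {"AAA"}, mode="rscu_weighted", rscu=ref) == pytest.approx(2.0)


class TestComposition:
    def test_all_gtg_gene(self):
        comp = positional_composition(_counts("GTG" * 10))
        assert comp.gc3 == pytest.approx(1.0)
        assert comp.gc12 == pytest.approx(0.5)  # G at 1, T at 2

    def test_hand_count_atg_tac(self):
        comp = positional_composition(_counts("ATG" * 2 + "TAC" * 2))
        assert comp.g3 == pytest.approx(0.5)
        assert comp.c3 == pytest.approx(0.5)
        assert comp.a3 == comp.t3 == 0.0
        assert comp.gc12 == pytest.approx(0.0)  # positions 1-2 are all A/T

    def test_third_position_fractions_sum_to_one(self, random_genes):
        for gene in random_genes[:30]:
            comp = positional_composition(count_codons(gene))
            assert comp.a3 + comp.t3 + comp.g3 + comp.c3 == pytest.approx(1.0)

    def test_gc_identities_and_oracle(self, random_genes):
        for gene in random_genes[:30]:
            comp = positional_composition(count_codons(gene))
            assert comp.gc12 == pytest.approx((comp.gc1 + comp.gc2) / 2)
            assert comp.gc == pytest.approx((comp.gc1 + comp.gc2 + comp.gc3) / 3)
            gc, gc12, gc3 = oracles.oracle_composition(gene.seq)
            assert comp.gc == pytest.approx(gc, abs=1e-9)
            assert comp.gc12 == pytest.approx(gc12, abs=1e-9)
            assert comp.gc3 == pytest.approx(gc3, abs=1e-9)

    def test_stop_codons_excluded_by_default(self):
        with_stop = positional_composition(_counts("GCG" * 5 + "TAA"))
        assert with_stop.gc3 == pytest.approx(1.0)
        assert with_stop.n_codons == 5


class TestPR2:
    def test_center(self, fixtures):
        x, y = pr2_coordinates(count_codons(fixtures["pr2_center"]))
        assert (x, y) == (pytest.approx(0.5), pytest.approx(0.5))

    def test_all_g_third_positions(self):
        x, y = pr2_coordinates(_counts("GCG" * 6))
        assert x == pytest.approx(1.0)
        assert math.isnan(y)  # no A or T at third positions

    def test_matches_oracle(self, random_genes):
        for gene in random_genes[:30]:
            x, y = pr2_coordinates(count_codons(gene))
            ox, oy = oracles.oracle_pr2(gene.seq)
            assert x == pytest.approx(ox, abs=1e-9)
            assert y == pytest.approx(oy, abs=1e-9)


def test_printed_stop_rscu_partition():
    part = stop_codon_partition({"UGA": 1.645, "UAA": 0.45, "UAG": 0.905})
    assert part["TGA"] == pytest.approx(1.645 / 3)
    assert sum(part.values()) == pytest.approx(1.0)
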