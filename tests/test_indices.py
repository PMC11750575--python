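"""Composition and CUB indices against hand computations and brute-force oracles."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubkit.genetic_code import bacterial_code
from cubkit.indices import (
    aromo,
    build_reference_weights,
    cai,
    cbi,
    composition,
    enc,
    fop,
    gravy,
    rscu,
    weights_from_counts,
)
from cubkit.seq_ingest import CodingSequence, CodonCountTable

CODE = bacterial_code()


def table(d):
    return CodonCountTable(Counter(d))


def wright_enc_oracle(counts):
    """Independent direct ENC: family homozygosities from codon proportions,
    class means, 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, clamped to [20, 61]."""
    by_class = {2: [], 3: [], 4: [], 6: []}
    for fam in CODE.families.values():
        k = len(fam)
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in fam)
        if n < 2:
            continue
        f = (n * sum((counts.get(c, 0) / n) ** 2 for c in fam) - 1) / (n - 1)
        if f > 0:
            by_class[k].append(f)
    means = {k: sum(v) / len(v) if v else None for k, v in by_class.items()}
    if means[3] is None and means[2] is not None and means[4] is not None:
        means[3] = (means[2] + means[4]) / 2
    sizes = {2: 9, 3: 1, 4: 5, 6: 3}
    present = [k for k in (2, 3, 4, 6) if means[k] is not None]
    if not present:
        return float("nan")
    val = 2 + sum(sizes[k] / means[k] for k in present) * 18 / sum(
        sizes[k] for k in present
    )
    return min(61.0, max(20.0, val))


class TestComposition:
    def test_hand_enumeration_gc_positions(self):
        # codons GCG + GCA: position1 G,G; position2 C,C; position3 G,A
        rec = composition(table({"GCG": 1, "GCA": 1}), CODE)
        assert rec.gc1 == 1.0 and rec.gc2 == 1.0
        assert rec.gc3 == 0.5 and rec.gc12 == 1.0

    def test_gc12_is_mean_of_gc1_gc2(self):
        rec = composition(table({"GCG": 2, "ATT": 1, "AAA": 3}), CODE)
        assert rec.gc12 == pytest.approx((rec.gc1 + rec.gc2) / 2)

    def test_gc3s_excludes_met_trp(self):
        # Met, Trp, Ala-GCT: only GCT is synonymous; its third base is T
        rec = composition(table({"ATG": 1, "TGG": 1, "GCT": 1}), CODE)
        assert rec.gc3s == 0.0

    def test_third_base_counts_partition_sense_codons(self):
        t = table({"GCA": 2, "GCT": 3, "AAG": 1, "TTC": 4})
        rec = composition(t, CODE)
        assert rec.a3 + rec.t3 + rec.g3 + rec.c3 == t.total

    def test_zero_sense_codons_errors(self):
        with pytest.raises(ValueError):
            composition(table({"TAA": 3}), CODE)


class TestRscu:
    def test_hand_computation_ala(self):
        r = rscu(table({"GCT": 2, "GCC": 1, "GCA": 1, "GCG": 0}), CODE)
        assert r["GCT"] == pytest.approx(2.0)
        assert r["GCC"] == pytest.approx(1.0)
        assert r["GCG"] == pytest.approx(0.0)

    def test_uniform_usage_gives_one(self):
        t = table({c: 5 for fam in CODE.families.values() for c in fam})
        r = rscu(t, CODE)
        assert np.allclose(r.to_numpy(), 1.0)

    def test_single_codon_twofold_family(self):
        r = rscu(table({"AAA": 7}), CODE)  # Lys AAA/AAG
        assert r["AAA"] == pytest.approx(2.0) and r["AAG"] == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_family_sums_equal_family_sizes(self, seed):
        rng = np.random.default_rng(seed)
        counts = {c: int(rng.integers(0, 20)) for c in CODE.synonymous_codons}
        r = rscu(table(counts), CODE)
        for fam in CODE.families.values():
            if len(fam) == 1:
                continue
            total = sum(counts.get(c, 0) for c in fam)
            fam_sum = sum(r[c] for c in fam)
            expected = len(fam) if total > 0 else 0.0
            assert fam_sum == pytest.approx(expected)


class TestReferenceWeightsAndCai:
    def test_single_codon_reference_pseudo_weights(self):
        w = weights_from_counts(table({"GCT": 10}), CODE)
        assert w["GCT"] == 1.0
        assert w["GCC"] == w["GCA"] == w["GCG"] == 0.01

    def test_uniform_reference_all_ones(self):
        t = table({c: 3 for c in CODE.synonymous_codons})
        w = weights_from_counts(t, CODE)
        assert np.allclose(w.w.to_numpy(), 1.0)

    def test_cai_one_on_all_optimal_gene(self):
        w = weights_from_counts(table({"GCT": 10, "AAA": 10}), CODE)
        assert cai(table({"GCT": 5, "AAA": 2}), w, CODE) == pytest.approx(1.0)

    def test_cai_geometric_mean(self):
        # two codons with w = 1 and w = 0.25 -> sqrt(0.25) = 0.5
        w = weights_from_counts(table({"AAA": 8, "AAG": 2}), CODE)
        assert w["AAG"] == pytest.approx(0.25)
        assert cai(table({"AAA": 1, "AAG": 1}), w, CODE) == pytest.approx(0.5)

    def test_cai_excludes_met_trp(self):
        w = weights_from_counts(table({"AAA": 8, "AAG": 2}), CODE)
        with_met = cai(table({"AAA": 1, "AAG": 1, "ATG": 50, "TGG": 50}), w, CODE)
        assert with_met == pytest.approx(0.5)

    def test_empty_reference_errors(self):
        seqs = [CodingSequence("g1", "ATGGCTTAA", description="g1 hypothetical")]
        with pytest.raises(ValueError, match="id list"):
            build_reference_weights(seqs, selector="annotation-pattern")

    def test_annotation_pattern_selects_ribosomal(self):
        seqs = [
            CodingSequence("g1", "ATGGCTGCTTAA", description="g1 30S ribosomal protein S4"),
            CodingSequence("g2", "ATGGCCGCCTAA", description="g2 hypothetical protein"),
        ]
        w = build_reference_weights(seqs, selector="annotation-pattern")
        assert w.reference_ids == ("g1",)
        assert w["GCT"] == 1.0 and w["GCC"] == 0.01


class TestEnc:
    def test_single_codon_per_family_is_20(self):
        t = table({fam[0]: 10 for fam in CODE.families.values()})
        assert enc(t, CODE) == pytest.approx(20.0)

    def test_uniform_usage_caps_at_61(self):
        t = table({c: 10 for fam in CODE.families.values() for c in fam})
        assert enc(t, CODE) == pytest.approx(61.0)

    def test_no_informative_family_is_nan(self):
        assert math.isnan(enc(table({"AAA": 1}), CODE))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = {c: int(rng.integers(0, 30)) for c in CODE.synonymous_codons}
        got = enc(table(counts), CODE)
        want = wright_enc_oracle(counts)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-9)


class TestCbiFop:
    optimal = {"GCT", "AAA"}

    def test_all_optimal_gene(self):
        t = table({"GCT": 10, "AAA": 4})
        assert cbi(t, self.optimal, CODE) == pytest.approx(1.0)
        assert fop(t, self.optimal, CODE) == pytest.approx(1.0)

    def test_uniform_usage_cbi_zero(self):
        t = table({"GCT": 3, "GCC": 3, "GCA": 3, "GCG": 3, "AAA": 6, "AAG": 6})
        assert cbi(t, self.optimal, CODE) == pytest.approx(0.0)

    def test_avoiding_optimal_in_twofold_family_is_minus_one(self):
        # Lys 2-fold family only; gene uses AAG exclusively
        t = table({"AAG": 12})
        assert cbi(t, {"AAA"}, CODE) == pytest.approx(-1.0)

    def test_fop_uniform_fourfold(self):
        t = table({"GCT": 5, "GCC": 5, "GCA": 5, "GCG": 5})
        assert fop(t, {"GCT"}, CODE) == pytest.approx(0.25)

    def test_families_without_optimal_excluded(self):
        # Pro codons present but no Pro codon in the optimal set
        t = table({"GCT": 10, "CCC": 100})
        assert fop(t, {"GCT"}, CODE) == pytest.approx(1.0)

    def test_degenerate_cbi_is_nan(self):
        assert math.isnan(cbi(table({"GGG": 5}), {"AAA"}, CODE))


class TestGravyAromo:
    def test_all_ala_kyte_doolittle(self):
        assert gravy(table({"GCT": 7}), CODE) == pytest.approx(1.8)

    def test_all_arg_kyte_doolittle(self):
        assert gravy(table({"CGT": 3}), CODE) == pytest.approx(-4.5)

    def test_aromatic_fraction(self):
        # Met, Phe, Tyr -> 2 aromatic of 3
        t = table({"ATG": 1, "TTC": 1, "TAC": 1})
        assert aromo(t, CODE) == pytest.approx(2 / 3)

    def test_no_aromatics_zero_all_trp_one(self):
        assert aromo(table({"GCT": 5}), CODE) == 0.0
        assert aromo(table({"TGG": 5}), CODE) == 1.0


class TestScaleAndOrderInvariance:
    def test_indices_invariant_under_count_doubling(self):
        rng = np.random.default_rng(5)
        counts = {c: int(rng.integers(1, 20)) for c in CODE.synonymous_codons}
        t1, t2 = table(counts), table({c: 2 * n for c, n in counts.items()})
        w = weights_from_counts(table({"GCT": 8, "GCC": 2, "AAA": 9, "AAG": 1}), CODE)
        opt = {"GCT", "AAA"}
        assert cai(t1, w, CODE) == pytest.approx(cai(t2, w, CODE))
        assert cbi(t1, opt, CODE) == pytest.approx(cbi(t2, opt, CODE), abs=1e-12)
        assert fop(t1, opt, CODE) == pytest.approx(fop(t2, opt, CODE))
        assert gravy(t1, CODE) == pytest.approx(gravy(t2, CODE))
        assert aromo(t1, CODE) == pytest.approx(aromo(t2, CODE))
        c1, c2 = composition(t1, CODE), composition(t2, CODE)
        assert c1.gc3 == pytest.approx(c2.gc3)
        assert c1.gc3s == pytest.approx(c2.gc3s)
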