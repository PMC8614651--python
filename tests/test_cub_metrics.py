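import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cubscan.cub_metrics import (
    CodonCountTable,
    classify_rscu,
    count_codons,
    enc_expected,
    enc_observed,
    enc_ratio,
    pool_counts,
    rscu,
)
from cubscan.genetic_code import AA_TO_CODONS, FAMILY_SIZE, SENSE_CODONS

from conftest import make_cds, random_count_table


# --------------------------------------------------------------------------
# independent step-by-step oracle for Wright's ENC (plain loops, no numpy)

def wright_enc_oracle(counts: dict) -> float:
    class_f = {2: [], 3: [], 4: [], 6: []}
    usable = False
    for aa, fam in AA_TO_CODONS.items():
        k = len(fam)
        if k == 1:
            continue
        ns = [counts.get(c, 0) for c in fam]
        n = sum(ns)
        if n < 2:
            continue
        usable = True
        sum_p2 = sum((x / n) ** 2 for x in ns)
        f_hat = (n * sum_p2 - 1) / (n - 1)
        if f_hat <= 0:
            continue
        if f_hat < 1 / k:
            f_hat = 1 / k
        class_f[k].append(f_hat)
    if not usable:
        raise ValueError("no usable family")
    fbar = {k: (sum(v) / len(v) if v else None) for k, v in class_f.items()}
    if fbar[3] is None and fbar[2] is not None and fbar[4] is not None:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    if any(fbar[k] is None for k in (2, 3, 4, 6)):
        return float("nan")
    enc = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(enc, 61.0)


def one_codon_per_aa_table(count=100, pick_first=True, rng=None):
    counts = {}
    for aa, fam in AA_TO_CODONS.items():
        codon = fam[0] if pick_first else fam[rng.integers(len(fam))]
        counts[codon] = count
    return CodonCountTable.from_counts(counts)


class TestCountCodons:
    def test_basic(self):
        t = count_codons(make_cds(["ATG", "AAA", "AAA", "TAA"]))
        assert t.counts == {"ATG": 1, "AAA": 2}
        assert t.total == 3

    def test_pooling_additive(self):
        a = count_codons(make_cds(["ATG", "AAA", "TAA"]))
        b = count_codons(make_cds(["ATG", "AAA", "CCC", "TAA"]))
        pooled = pool_counts([a, b])
        assert pooled.counts == {"ATG": 2, "AAA": 2, "CCC": 1}
        assert pooled.total == a.total + b.total


class TestEncObserved:
    def test_maximal_bias_is_exactly_20(self):
        assert enc_observed(one_codon_per_aa_table()) == 20.0

    def test_equal_usage_is_exactly_61(self):
        t = CodonCountTable.from_counts({c: 1000 for c in SENSE_CODONS})
        assert enc_observed(t) == 61.0

    def test_two_fold_family_homozygosity_hand_value(self):
        # Phe {TTT:3, TTC:1}: F = (4*(0.5625+0.0625)-1)/3 = 0.5 -> 2 codons.
        # Fill the other classes with single-codon families (F = 1) so the
        # class means are 0.5, 1, 1, 1 and ENC = 2 + 9/0.5 + 1 + 5 + 3 = 29.
        counts = {"TTT": 3, "TTC": 1}
        for aa, fam in AA_TO_CODONS.items():
            if aa not in ("F", "M", "W"):
                counts[fam[0]] = 10
        got = enc_observed(CodonCountTable.from_counts(counts))
        f2_mean = (0.5 + 8 * 1.0) / 9
        assert got == pytest.approx(2 + 9 / f2_mean + 1 + 5 + 3)

    def test_undefined_when_whole_class_unused(self):
        # only two-fold families observed -> F4/F6 missing -> NaN + warning
        counts = {fam[0]: 10 for aa, fam in AA_TO_CODONS.items()
                  if FAMILY_SIZE[aa] == 2}
        with pytest.warns(UserWarning, match="ENC undefined"):
            assert math.isnan(enc_observed(CodonCountTable.from_counts(counts)))

    def test_error_when_all_families_singleton(self):
        with pytest.raises(ValueError):
            enc_observed(CodonCountTable.from_counts({"AAA": 1}))

    def test_oracle_equivalence_on_random_tables(self, rng):
        checked = 0
        for _ in range(200):
            table = random_count_table(rng)
            try:
                expected = wright_enc_oracle(table.counts)
            except ValueError:
                continue
            got = enc_observed(table)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9)
            checked += 1
        assert checked >= 150

    def test_skewing_a_family_never_increases_enc(self):
        # move counts of the Ala family from uniform toward one codon
        base = {c: 60 for c in SENSE_CODONS}
        fam = AA_TO_CODONS["A"]
        prev = None
        for shift in range(0, 60, 10):
            counts = dict(base)
            counts[fam[0]] += 3 * shift
            for c in fam[1:]:
                counts[c] -= shift
            enc = enc_observed(CodonCountTable.from_counts(counts))
            if prev is not None:
                assert enc <= prev + 1e-12
            prev = enc

    def test_pooling_identical_sequences_scale_invariant(self, rng):
        table = random_count_table(rng, max_count=60)
        big = CodonCountTable.from_counts(
            {c: 50 * n for c, n in table.counts.items()})
        if big.total < 1000:
            big = CodonCountTable.from_counts(
                {c: 20 * n for c, n in big.counts.items()})
        assert enc_observed(big) == pytest.approx(
            enc_observed(CodonCountTable.from_counts(
                {c: 2 * n for c, n in big.counts.items()})), abs=0.05)


class TestEncExpected:
    @pytest.mark.parametrize("s, expected", [
        (0.5, 60.5),          # 2 + 0.5 + 29/0.5
        (1.0, 32.0),          # 2 + 1 + 29/1
        (0.0, 31.0),
    ])
    def test_values(self, s, expected):
        assert enc_expected(s) == pytest.approx(expected)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_symmetry_about_half(self, s):
        assert enc_expected(s) - s == pytest.approx(
            enc_expected(1 - s) - (1 - s))

    @pytest.mark.parametrize("s", [-0.1, 1.1])
    def test_out_of_range(self, s):
        with pytest.raises(ValueError):
            enc_expected(s)


class TestEncRatio:
    def test_values(self):
        assert enc_ratio(60.0, 60.0) == 0.0
        assert enc_ratio(50.0, 60.0) == pytest.approx(1 / 6)
        assert enc_ratio(61.0, 60.5) == pytest.approx(-0.00826, abs=1e-5)

    def test_zero_expected_is_error(self):
        with pytest.raises(ValueError):
            enc_ratio(50.0, 0.0)


class TestRscu:
    def test_phe_family(self):
        t = CodonCountTable.from_counts({"TTT": 3, "TTC": 1})
        r = rscu(t)
        assert r.rscu["TTT"] == pytest.approx(1.5)
        assert r.rscu["TTC"] == pytest.approx(0.5)

    def test_uniform_usage_all_one(self):
        r = rscu(CodonCountTable.from_counts({c: 7 for c in SENSE_CODONS}))
        assert all(v == pytest.approx(1.0) for v in r.rscu.values())
        assert set(r.rscu_class.values()) == {"unbiased"}

    def test_single_codon_family_over_represented(self):
        r = rscu(CodonCountTable.from_counts({"GCA": 8}))
        assert r.rscu["GCA"] == pytest.approx(4.0)
        assert r.rscu_class["GCA"] == "over_represented"
        assert r.rscu["GCT"] == 0.0 and r.rscu_class["GCT"] == "rare"

    def test_unobserved_family_all_zero(self):
        r = rscu(CodonCountTable.from_counts({"TTT": 5}))
        assert all(r.rscu[c] == 0.0 for c in AA_TO_CODONS["A"])

    def test_classification_boundaries(self):
        assert classify_rscu(1.6) == "preferred"       # "greater than 1.6"
        assert classify_rscu(1.6000001) == "over_represented"
        assert classify_rscu(1.0) == "unbiased"
        assert classify_rscu(0.999) == "rare"

    def test_family_sums_on_random_tables(self, rng):
        for _ in range(1000):
            table = random_count_table(rng, max_count=8)
            r = rscu(table)
            for aa, fam in AA_TO_CODONS.items():
                k = len(fam)
                if k == 1:
                    continue
                observed = sum(table.counts.get(c, 0) for c in fam) > 0
                total = sum(r.rscu[c] for c in fam)
                if observed:
                    assert total == pytest.approx(k, abs=1e-9)
                else:
                    assert total == 0.0

    def test_universe_is_59_codons(self):
        r = rscu(CodonCountTable.from_counts({c: 2 for c in SENSE_CODONS}))
        assert len(r.rscu) == 59
        assert "ATG" not in r.rscu and "TGG" not in r.rscu
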