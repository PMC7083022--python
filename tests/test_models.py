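"""Inheritance-model encodings and Hardy-Weinberg tests."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from genassoc.models import (
    GenotypeCounts,
    InheritanceModel,
    cochran_armitage_trend,
    encode_model,
    hwe_chi2,
    hwe_exact_p,
)
from genassoc.stats import woolf_or_ci

CASES_677 = GenotypeCounts(53, 60, 22)
CONTROLS_677 = GenotypeCounts(31, 62, 19)


class TestEncodeModel:
    def test_dominant_published_contrast(self):
        [mt] = encode_model(CASES_677, CONTROLS_677, "dominant")
        assert mt.table.cells == (82, 53, 81, 31)
        assert round(woolf_or_ci(mt.table).or_point, 2) == 0.59

    def test_recessive_published_contrast(self):
        cases, controls = GenotypeCounts(87, 46, 2), GenotypeCounts(70, 35, 7)
        [mt] = encode_model(cases, controls, "recessive")
        assert mt.table.cells == (2, 133, 7, 105)
        assert round(woolf_or_ci(mt.table).or_point, 2) == 0.23

    def test_overdominant_published_contrast(self):
        [mt] = encode_model(CASES_677, CONTROLS_677, "overdominant")
        assert mt.table.cells == (60, 75, 62, 50)
        assert round(woolf_or_ci(mt.table).or_point, 2) == 0.65

    def test_allelic_published_contrast(self):
        [mt] = encode_model(CASES_677, CONTROLS_677, "allelic")
        assert mt.table.cells == (104, 166, 100, 124)
        assert round(woolf_or_ci(mt.table).or_point, 2) == 0.78

    def test_codominant_gives_per_contrast_tables(self):
        tables = encode_model(CASES_677, CONTROLS_677, "codominant")
        assert [mt.table.cells for mt in tables] == [(60, 53, 62, 31), (22, 53, 19, 31)]

    def test_codominant_drops_class_absent_in_both_groups(self):
        tables = encode_model(GenotypeCounts(128, 7, 0), GenotypeCounts(102, 10, 0),
                              "codominant")
        assert len(tables) == 1
        assert tables[0].dropped_classes != ()

    @given(st.tuples(*[st.integers(0, 50)] * 6))
    def test_cells_sum_to_analysed_subjects(self, counts):
        cases = GenotypeCounts(*counts[:3])
        controls = GenotypeCounts(*counts[3:])
        if cases.n == 0 or controls.n == 0:
            return
        n = cases.n + controls.n
        for model in InheritanceModel:
            for mt in encode_model(cases, controls, model):
                total = sum(mt.table.cells)
                if model is InheritanceModel.ALLELIC:
                    assert total == 2 * n
                elif model is InheritanceModel.CODOMINANT:
                    # each codominant contrast analyses only its two classes
                    a, b, c, d = mt.table.cells
                    assert b == cases.n_ref_hom and d == controls.n_ref_hom
                    assert a + c in (cases.n_het + controls.n_het,
                                     cases.n_alt_hom + controls.n_alt_hom)
                else:
                    assert total == n

    @given(st.tuples(*[st.integers(0, 50)] * 6))
    def test_dominant_recessive_swap_under_allele_relabelling(self, counts):
        cases = GenotypeCounts(*counts[:3])
        controls = GenotypeCounts(*counts[3:])
        if cases.n == 0 or controls.n == 0:
            return
        # recessive on the relabelled marker tests the same subject split as
        # dominant on the original, with the exposure columns exchanged
        [dom] = encode_model(cases, controls, "dominant")
        [rec_flipped] = encode_model(cases.flipped(), controls.flipped(), "recessive")
        a, b, c, d = dom.table.cells
        assert rec_flipped.table.cells == (b, a, d, c)


class TestHWEChi2:
    def test_published_case_group(self):
        r = hwe_chi2(CASES_677)
        assert round(r.p_chi2, 2) == 0.47

    def test_exact_hwe_proportions(self):
        r = hwe_chi2(GenotypeCounts(25, 50, 25))
        assert math.isclose(r.chi2, 0.0, abs_tol=1e-12)
        assert r.p_chi2 == 1.0

    def test_hand_computed_statistic(self):
        # controls (31, 62, 19): p_ref = 124/224, expected (34.3036, 55.3929, 22.3036)
        r = hwe_chi2(CONTROLS_677)
        n, p = 112, 124 / 224
        e = (n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2)
        chi2 = sum((o - ei) ** 2 / ei for o, ei in zip((31, 62, 19), e))
        assert math.isclose(r.chi2, chi2, rel_tol=1e-12)
        assert round(r.p_chi2, 2) == 0.20

    def test_expected_counts_sum_to_group_size(self):
        r = hwe_chi2(GenotypeCounts(10, 7, 3))
        assert math.isclose(sum(r.expected_counts), 20, rel_tol=1e-12)

    def test_monomorphic_warns_not_errors(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            r = hwe_chi2(GenotypeCounts(50, 0, 0))
        assert r.p_chi2 == 1.0 and r.monomorphic

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            hwe_chi2(GenotypeCounts(0, 0, 0))

    def test_null_rejection_rate_is_nominal(self, rng):
        # genotypes simulated under HWE: the 1-df chi-square should reject
        # at the 5% level about 5% of the time
        n, maf, reps = 500, 0.3, 1000
        rejections = 0
        probs = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2]
        draws = rng.multinomial(n, probs, size=reps)
        for row in draws:
            if hwe_chi2(GenotypeCounts(*row)).p_chi2 < 0.05:
                rejections += 1
        assert 0.04 <= rejections / reps <= 0.07


def exact_hwe_oracle(g: GenotypeCounts) -> float:
    """Brute-force oracle: exact conditional probabilities of every
    heterozygote count, in rational arithmetic."""
    n, na, nb = g.n, g.n_ref_alleles, g.n_alt_alleles
    rare = min(na, nb)

    def weight(nab):
        nrr = (rare - nab) // 2
        ncc = n - nab - nrr
        return Fraction(math.factorial(n) * 2**nab,
                        math.factorial(nrr) * math.factorial(nab) * math.factorial(ncc))
    weights = {h: weight(h) for h in range(rare % 2, rare + 1, 2)}
    total = sum(weights.values())
    obs = weights[g.n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


class TestHWEExact:
    def test_published_rare_allele_group(self):
        # 7 heterozygotes among 135, no alt-homozygote: exact p ~ 1.00
        assert hwe_exact_p(GenotypeCounts(128, 7, 0)) > 0.99

    def test_most_probable_configuration_included(self):
        assert hwe_exact_p(GenotypeCounts(25, 50, 25)) == pytest.approx(1.0)

    @given(st.tuples(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)))
    def test_matches_rational_enumeration_oracle(self, counts):
        g = GenotypeCounts(*counts)
        if g.n == 0 or min(g.n_ref_alleles, g.n_alt_alleles) == 0:
            return
        assert math.isclose(hwe_exact_p(g), exact_hwe_oracle(g), rel_tol=1e-9)

    def test_exact_and_chi2_agree_asymptotically(self, rng):
        # the conditional exact test and the 1-df chi-square converge as the
        # lattice of attainable heterozygote counts becomes fine; the <0.02
        # agreement needs n in the tens of thousands (discreteness decays
        # like 1/sqrt(n)), which is why both tests are reported at study n
        probs = [0.49, 0.42, 0.09]  # HWE at MAF 0.3
        agree = 0
        reps = 200
        for row in rng.multinomial(20_000, probs, size=reps):
            r = hwe_chi2(GenotypeCounts(*row))
            agree += abs(r.p_chi2 - r.p_exact) < 0.02
        assert agree / reps >= 0.95


class TestCochranArmitage:
    def test_identical_distributions_give_p_one(self):
        r = cochran_armitage_trend(GenotypeCounts(10, 20, 10), GenotypeCounts(10, 20, 10))
        assert r.p == 1.0

    def test_strong_trend_is_significant(self):
        r = cochran_armitage_trend(GenotypeCounts(10, 30, 60), GenotypeCounts(60, 30, 10))
        assert r.p < 1e-6
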