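"""Two-locus EM, linkage disequilibrium, haplotype association."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genassoc.datasets import study_haplotypes
from genassoc.haplotypes import (
    HAPLOTYPE_ORDER,
    HaplotypeTable,
    em_two_snp,
    haplotype_case_control,
    joint_genotype_counts,
    ld_from_haps,
)
from genassoc.simulate import simulate_two_locus


def brute_force_ml_freqs(joint, coarse=0.02, fine=0.001):
    """Independent maximizer: coarse grid over the 3-simplex, then a local
    fine grid around the best point."""
    joint = np.asarray(joint, dtype=float)

    def loglik(f):
        ll = 0.0
        for da in range(3):
            for db in range(3):
                n = joint[da, db]
                if n == 0:
                    continue
                p = 0.0
                for h1 in HAPLOTYPE_ORDER:
                    for h2 in HAPLOTYPE_ORDER:
                        if h1[0] + h2[0] == da and h1[1] + h2[1] == db:
                            p += f[HAPLOTYPE_ORDER.index(h1)] * f[HAPLOTYPE_ORDER.index(h2)]
                ll += n * math.log(p) if p > 0 else -math.inf
        return ll

    def grid(lo, hi, step):
        ticks = np.arange(lo, hi + step / 2, step)
        best, best_ll = None, -math.inf
        for f0, f1, f2 in itertools.product(ticks, ticks, ticks):
            f3 = 1.0 - f0 - f1 - f2
            if f3 < -1e-12:
                continue
            f = (f0, f1, f2, max(f3, 0.0))
            ll = loglik(f)
            if ll > best_ll:
                best, best_ll = f, ll
        return np.array(best)

    best = grid(0.0, 1.0, coarse)
    lo = np.maximum(best[:3] - 2 * coarse, 0.0)
    hi = np.minimum(best[:3] + 2 * coarse, 1.0)
    ticks = [np.arange(l, h + fine / 2, fine) for l, h in zip(lo, hi)]
    best2, best_ll = None, -math.inf
    for f0 in ticks[0]:
        for f1 in ticks[1]:
            for f2 in ticks[2]:
                f3 = 1.0 - f0 - f1 - f2
                if f3 < -1e-12:
                    continue
                f = (f0, f1, f2, max(f3, 0.0))
                ll = loglik(f)
                if ll > best_ll:
                    best2, best_ll = f, ll
    return np.array(best2)


class TestEM:
    def test_no_double_heterozygote_equals_gamete_counting(self):
        joint = np.array([[5, 2, 1], [3, 0, 2], [1, 4, 6]])
        res = em_two_snp(joint)
        # with no phase ambiguity each subject's two gametes are resolvable,
        # so EM must equal the direct gamete count
        counts = np.zeros(4)
        for (da, db), n in np.ndenumerate(joint):
            if n == 0:
                continue
            if da == 1:
                pairs = [((0, db // 2), (1, db // 2))]
            elif db == 1:
                pairs = [((da // 2, 0), (da // 2, 1))]
            else:
                pairs = [((da // 2, db // 2), (da // 2, db // 2))]
            for h1, h2 in pairs:
                counts[HAPLOTYPE_ORDER.index(h1)] += n
                counts[HAPLOTYPE_ORDER.index(h2)] += n
        np.testing.assert_allclose(res.freqs, counts / counts.sum(), atol=1e-9)
        assert res.converged

    def test_all_double_heterozygotes_uniform_is_stationary(self):
        # one hand-computed E/M step from the uniform point: the cis fraction
        # is 1/2, so each haplotype receives n/2 of the 2n gametes and the
        # frequencies stay at (1/4, 1/4, 1/4, 1/4)
        joint = np.zeros((3, 3), dtype=int)
        joint[1, 1] = 20
        res = em_two_snp(joint, init=(0.25, 0.25, 0.25, 0.25))
        np.testing.assert_allclose(res.freqs, [0.25] * 4, atol=1e-12)

    def test_recovers_generating_frequencies(self, rng):
        truth = np.array([0.4, 0.3, 0.2, 0.1])
        joint, _ = simulate_two_locus(truth, n=10_000, rng=rng)
        res = em_two_snp(joint)
        assert np.max(np.abs(res.freqs - truth)) < 0.01

    def test_log_likelihood_is_non_decreasing(self):
        joint = np.array([[10, 5, 2], [6, 12, 3], [1, 4, 7]])
        lls = [em_two_snp(joint, max_iter=k, tol=0.0).log_likelihood
               for k in range(1, 15)]
        for prev, cur in zip(lls, lls[1:]):
            assert cur >= prev - 1e-9

    @pytest.mark.parametrize("joint", [
        [[4, 1, 0], [2, 6, 1], [0, 2, 3]],
        [[0, 0, 5], [0, 8, 0], [5, 0, 0]],
        [[10, 2, 0], [3, 5, 1], [0, 1, 0]],
    ])
    def test_matches_brute_force_maximizer(self, joint):
        em = em_two_snp(joint).freqs
        grid = brute_force_ml_freqs(joint)
        assert np.max(np.abs(em - grid)) < 0.005


class TestLD:
    def test_perfect_ld(self):
        r = ld_from_haps([0.5, 0.0, 0.0, 0.5])
        assert math.isclose(r.d, 0.25, rel_tol=1e-12)
        assert r.d_prime == 1.0 and math.isclose(r.r2, 1.0, rel_tol=1e-12)

    def test_equilibrium(self):
        pa, pb = 0.7, 0.4
        f = [pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)]
        r = ld_from_haps(f)
        assert abs(r.d) < 1e-12 and r.r2 < 1e-20 and r.d_prime == 0.0

    def test_hand_computed_example(self):
        r = ld_from_haps([0.4, 0.3, 0.2, 0.1])
        assert math.isclose(r.d, -0.02, abs_tol=1e-12)
        assert round(r.d_prime, 4) == 0.1667
        assert math.isclose(r.r2, 0.0004 / (0.7 * 0.3 * 0.6 * 0.4), rel_tol=1e-12)
        assert r.d_sign == -1

    def test_monomorphic_locus_undefined(self):
        r = ld_from_haps([0.6, 0.4, 0.0, 0.0])
        assert r.d_prime is None and r.r2 is None

    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    @settings(max_examples=100)
    def test_zero_haplotype_implies_full_dprime(self, raw):
        f = np.array(raw)
        f[np.argmin(f)] = 0.0
        if f.sum() == 0:
            return
        f = f / f.sum()
        pa, pb = f[0] + f[1], f[0] + f[2]
        if pa in (0.0, 1.0) or pb in (0.0, 1.0):
            return
        r = ld_from_haps(f)
        assert math.isclose(r.d_prime, 1.0, rel_tol=1e-9)


class TestHaplotypeAssociation:
    def test_published_mthfr_pair(self):
        res = haplotype_case_control(study_haplotypes()["MTHFR"])
        by_label = {r.haplotype: r for r in res}
        assert all(r.reference == "TA" for r in res)
        assert round(by_label["CC"].or_result.or_point, 2) == 1.27
        assert round(by_label["CA"].or_result.or_point, 2) == 1.30
        assert by_label["TC"].absent and by_label["TC"].or_result is None

    def test_published_xrcc1_pair(self):
        res = haplotype_case_control(study_haplotypes()["XRCC1"])
        by_label = {r.haplotype: r for r in res}
        assert all(r.reference == "CG" for r in res)
        assert round(by_label["TG"].or_result.or_point, 2) == 0.52
        assert round(by_label["CA"].or_result.or_point, 2) == 0.93
        assert by_label["TA"].absent

    def test_identical_distributions_give_unit_ors(self):
        h = HaplotypeTable(("AA", "AB", "BA"), (50, 30, 20), (50, 30, 20))
        for r in haplotype_case_control(h):
            assert math.isclose(r.or_result.or_point, 1.0, rel_tol=1e-12)

    def test_reference_tie_breaks_lexicographically(self):
        h = HaplotypeTable(("ZZ", "AA", "MM"), (40, 40, 20), (40, 40, 20))
        res = haplotype_case_control(h)
        assert all(r.reference == "AA" for r in res)

    def test_reference_never_contrasted_with_itself(self):
        res = haplotype_case_control(study_haplotypes()["MTHFR"])
        assert "TA" not in {r.haplotype for r in res}

    def test_zero_count_in_one_group_uses_gart(self):
        h = HaplotypeTable(("AA", "AB"), (90, 0), (80, 10))
        [r] = haplotype_case_control(h)
        assert r.or_result.method == "gart"

    def test_joint_counts_drop_missing(self):
        j = joint_genotype_counts([0, 1, None, 2], [1, 1, 1, float("nan")])
        assert j.sum() == 2
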