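"""Two-locus haplotype frequencies, linkage disequilibrium, association.

For two biallelic SNPs there are four haplotypes.  From unphased genotypes
only the double heterozygote is phase-ambiguous, so the classical EM
algorithm (:func:`em_two_snp`) converges quickly: every other cell of the
3x3 joint-dosage table resolves deterministically into gametes, and each
E-step splits the double-heterozygote cell between the cis (A1B1/A2B2) and
trans (A1B2/A2B1) phase in proportion to the current haplotype-frequency
products.

LD statistics follow the usual definitions: D is the haplotype-frequency
covariance ``p_AB - p_A p_B``, D' is D scaled by its attainable bound given
the allele frequencies (reported as a magnitude, with the sign of D carried
separately), and r^2 is the squared allelic correlation.

Haplotype case-control association contrasts every haplotype against the
most common haplotype in the pooled sample (ties broken lexicographically
on the label), via Woolf odds-ratio intervals with the Gart zero-cell
fallback and a Pearson chi-square per contrast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .stats import Table2x2, ORResult, TestResult, odds_ratio_ci, pearson_chi2

__all__ = [
    "HAPLOTYPE_ORDER",
    "EMResult",
    "LDStats",
    "HaplotypeTable",
    "HaplotypeAssociation",
    "joint_genotype_counts",
    "em_two_snp",
    "ld_from_haps",
    "haplotype_case_control",
]

#: Haplotype order used for every 4-vector: (A1B1, A1B2, A2B1, A2B2),
#: allele 1 = reference allele at each locus.
HAPLOTYPE_ORDER = ((0, 0), (0, 1), (1, 0), (1, 1))


def joint_genotype_counts(dosages_a: Sequence, dosages_b: Sequence) -> np.ndarray:
    """3x3 joint dosage table from per-subject dosages at two loci.

    Subjects with a MISSING dosage at either locus are dropped.
    """
    counts = np.zeros((3, 3), dtype=int)
    for da, db in zip(dosages_a, dosages_b):
        if da is None or db is None:
            continue
        da, db = float(da), float(db)
        if math.isnan(da) or math.isnan(db):
            continue
        counts[int(da), int(db)] += 1
    return counts


def _validate_joint(joint) -> np.ndarray:
    j = np.asarray(joint, dtype=float)
    if j.shape != (3, 3):
        raise ValueError("joint genotype counts must be a 3x3 matrix")
    if np.any(j < 0):
        raise ValueError("counts must be non-negative")
    if j.sum() == 0:
        raise ValueError("no subjects")
    return j


@dataclass(frozen=True)
class EMResult:
    """EM haplotype-frequency estimate for two biallelic loci."""

    freqs: np.ndarray  # 4-vector in HAPLOTYPE_ORDER
    n_iter: int
    converged: bool
    log_likelihood: float


def _hap_counts_given_phase(j: np.ndarray, cis_fraction: float) -> np.ndarray:
    """Expected haplotype counts (order HAPLOTYPE_ORDER) given the fraction
    of double heterozygotes in cis phase."""
    h = np.zeros(4)
    # deterministic cells: subject (da, db) carries haplotypes resolvable
    # whenever at most one locus is heterozygous
    for da in range(3):
        for db in range(3):
            n = j[da, db]
            if n == 0 or (da == 1 and db == 1):
                continue
            # alleles at A: da alt copies; at B: db alt copies
            if da == 1:
                pairs = [((0, db // 2), (1, db // 2))]
            elif db == 1:
                pairs = [((da // 2, 0), (da // 2, 1))]
            else:
                pairs = [((da // 2, db // 2), (da // 2, db // 2))]
            for h1, h2 in pairs:
                h[HAPLOTYPE_ORDER.index(h1)] += n
                h[HAPLOTYPE_ORDER.index(h2)] += n
    n_dh = j[1, 1]
    h[0] += n_dh * cis_fraction       # A1B1
    h[3] += n_dh * cis_fraction       # A2B2
    h[1] += n_dh * (1 - cis_fraction)  # A1B2
    h[2] += n_dh * (1 - cis_fraction)  # A2B1
    return h


def _log_likelihood(j: np.ndarray, f: np.ndarray) -> float:
    ll = 0.0
    for da in range(3):
        for db in range(3):
            n = j[da, db]
            if n == 0:
                continue
            p = 0.0
            for i1, (a1, b1) in enumerate(HAPLOTYPE_ORDER):
                for i2, (a2, b2) in enumerate(HAPLOTYPE_ORDER):
                    if a1 + a2 == da and b1 + b2 == db:
                        p += f[i1] * f[i2]
            ll += n * math.log(p) if p > 0 else -math.inf
    return ll


def em_two_snp(
    joint,
    tol: float = 1e-10,
    max_iter: int = 1000,
    init: Optional[Sequence] = None,
) -> EMResult:
    """Maximum-likelihood haplotype frequencies for two SNPs by EM.

    Parameters
    ----------
    joint : 3x3 array-like
        Subject counts indexed by (dosage at locus A, dosage at locus B).
    tol : float
        Converged when the largest absolute frequency change of an
        iteration falls below this.
    max_iter : int
        Iteration cap; non-convergence returns the best estimate with a
        warning and ``converged=False``.
    init : 4-vector, optional
        Starting frequencies; the default is linkage equilibrium (products
        of the observed allele frequencies).

    Returns frequencies in :data:`HAPLOTYPE_ORDER`.
    """
    j = _validate_joint(joint)
    n_hap = 2.0 * j.sum()
    p_alt_a = (j * np.arange(3)[:, None]).sum() / n_hap
    p_alt_b = (j * np.arange(3)[None, :]).sum() / n_hap

    if init is not None:
        f = np.asarray(init, dtype=float)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1) > 1e-6:
            raise ValueError("init must be a non-negative 4-vector summing to 1")
        f = f / f.sum()
    else:
        pa = np.array([1 - p_alt_a, p_alt_a])
        pb = np.array([1 - p_alt_b, p_alt_b])
        f = np.array([pa[a] * pb[b] for a, b in HAPLOTYPE_ORDER])

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        cis_fraction = 0.5 if cis + trans == 0 else cis / (cis + trans)
        new = _hap_counts_given_phase(j, cis_fraction) / n_hap
        delta = np.max(np.abs(new - f))
        f = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"two-SNP EM did not converge in {max_iter} iterations", stacklevel=2
        )
    return EMResult(freqs=f, n_iter=it, converged=converged,
                    log_likelihood=_log_likelihood(j, f))


@dataclass(frozen=True)
class LDStats:
    """Pairwise linkage disequilibrium between two biallelic loci.

    ``d_prime`` is |D'|; the sign of D is in ``d_sign``.  A monomorphic
    locus leaves D' and r^2 undefined (None).
    """

    d: float
    d_prime: Optional[float]
    d_sign: int
    r2: Optional[float]


def ld_from_haps(freqs: Sequence) -> LDStats:
    """D, |D'| and r^2 from a 4-vector of haplotype frequencies.

    ``freqs`` follows :data:`HAPLOTYPE_ORDER`; allele "1" is the reference
    allele at each locus.  ``D = p_A1B1 - p_A1 p_B1``; ``D`` is normalised
    by ``min(p_A1 (1-p_B1), (1-p_A1) p_B1)`` when positive and by
    ``min(p_A1 p_B1, (1-p_A1)(1-p_B1))`` when negative.
    """
    f = np.asarray(freqs, dtype=float)
    if f.shape != (4,) or np.any(f < 0):
        raise ValueError("freqs must be a non-negative 4-vector")
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("haplotype frequencies must sum to 1")
    p_a = f[0] + f[1]  # allele 1 at locus A
    p_b = f[0] + f[2]  # allele 1 at locus B
    d = f[0] - p_a * p_b
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LDStats(d=d, d_prime=None, d_sign=0, r2=None)
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d == 0 else abs(d) / d_max
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    sign = 0 if d == 0 else (1 if d > 0 else -1)
    return LDStats(d=float(d), d_prime=float(d_prime), d_sign=sign, r2=float(r2))


@dataclass(frozen=True)
class HaplotypeTable:
    """Per-group counts of the haplotypes at a locus pair.

    Labels name the constituent alleles (e.g. ``"TA"`` for
    rs1801133-T / rs1801131-A); counts are chromosomes, not subjects.
    """

    labels: Tuple[str, ...]
    case_counts: Tuple[float, ...]
    control_counts: Tuple[float, ...]

    def __post_init__(self):
        if not (len(self.labels) == len(self.case_counts) == len(self.control_counts)):
            raise ValueError("labels and count vectors must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate haplotype labels")
        if any(x < 0 for x in self.case_counts + self.control_counts):
            raise ValueError("counts must be non-negative")

    def case_freqs(self) -> np.ndarray:
        c = np.asarray(self.case_counts, dtype=float)
        return c / c.sum()

    def control_freqs(self) -> np.ndarray:
        c = np.asarray(self.control_counts, dtype=float)
        return c / c.sum()


@dataclass(frozen=True)
class HaplotypeAssociation:
    """Case-control association of one haplotype against the reference."""

    haplotype: str
    reference: str
    case_count: float
    control_count: float
    or_result: Optional[ORResult]  # None for the reference row / absent haplotypes
    test_result: Optional[TestResult]
    absent: bool = False


def haplotype_case_control(h: HaplotypeTable) -> List[HaplotypeAssociation]:
    """Association of each haplotype vs the most common one.

    The reference is the most frequent haplotype in the pooled sample
    (ties broken by the lexicographically smallest label).  Each other
    haplotype forms a cases/controls x haplotype/reference 2x2 analysed by
    Woolf OR (Gart on zero cells) and Pearson chi-square.  Haplotypes with
    zero count in both groups are reported as absent with no OR.
    """
    pooled = [ca + co for ca, co in zip(h.case_counts, h.control_counts)]
    if sum(c > 0 for c in pooled) < 2:
        raise ValueError("need at least two haplotypes with non-zero pooled count")
    ref_idx = min(range(len(pooled)), key=lambda i: (-pooled[i], h.labels[i]))
    ref = h.labels[ref_idx]
    ref_cases = int(round(h.case_counts[ref_idx]))
    ref_controls = int(round(h.control_counts[ref_idx]))

    out = []
    for i, lab in enumerate(h.labels):
        if i == ref_idx:
            continue
        ca = int(round(h.case_counts[i]))
        co = int(round(h.control_counts[i]))
        if ca == 0 and co == 0:
            out.append(HaplotypeAssociation(lab, ref, 0, 0, None, None, absent=True))
            continue
        t = Table2x2(ca, ref_cases, co, ref_controls)
        orr = odds_ratio_ci(t)
        try:
            test = pearson_chi2(t.as_array())
        except ValueError:  # degenerate margin (e.g. haplotype absent in one group)
            test = None
        out.append(HaplotypeAssociation(lab, ref, ca, co, orr, test))
    return out
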