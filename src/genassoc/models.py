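"""Inheritance-model encodings and Hardy-Weinberg equilibrium tests.

Three genotype classes (ref-homozygote, heterozygote, alt-homozygote) are
collapsed into 2x2 case-control contrasts under the five standard
inheritance models:

codominant
    each non-reference genotype vs the reference homozygote (up to two
    tables, one per contrast, each tested on its own);
dominant
    carriers of the alt allele (het + alt-hom) vs ref-hom;
recessive
    alt-hom vs the rest (ref-hom + het);
overdominant
    het vs both homozygotes;
allelic
    alleles rather than subjects: each person contributes two alleles to a
    2x2 of allele counts (the additive/allele-count rendering).

A Cochran-Armitage trend test is available as an extra, model-free option.

HWE is tested by the classical 1-df chi-square on genotype counts and by
the exact conditional test on the heterozygote count given the allele
counts; both are reported because they can disagree at rare alleles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .stats import Table2x2, TestResult

__all__ = [
    "GenotypeCounts",
    "InheritanceModel",
    "ModelTable",
    "encode_model",
    "hwe_chi2",
    "hwe_exact",
    "hwe_test",
    "HWEResult",
    "cochran_armitage_trend",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Subject counts per genotype class for one group (cases or controls)."""

    n_ref_hom: int
    n_het: int
    n_alt_hom: int

    def __post_init__(self):
        for x in self.counts:
            if x != int(x) or x < 0:
                raise ValueError(f"genotype counts must be non-negative integers: {self.counts}")

    @property
    def counts(self) -> tuple:
        return (self.n_ref_hom, self.n_het, self.n_alt_hom)

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def n_ref_alleles(self) -> int:
        return 2 * self.n_ref_hom + self.n_het

    @property
    def n_alt_alleles(self) -> int:
        return 2 * self.n_alt_hom + self.n_het

    @property
    def ref_allele_freq(self) -> float:
        return self.n_ref_alleles / (2 * self.n)

    @classmethod
    def from_dosages(cls, dosages: Sequence) -> "GenotypeCounts":
        """Tally dosages 0/1/2, ignoring MISSING (None/NaN) entries."""
        tally = [0, 0, 0]
        for d in dosages:
            if d is None:
                continue
            d = float(d)
            if math.isnan(d):
                continue
            tally[int(d)] += 1
        return cls(*tally)

    def flipped(self) -> "GenotypeCounts":
        return GenotypeCounts(self.n_alt_hom, self.n_het, self.n_ref_hom)


class InheritanceModel(str, Enum):
    CODOMINANT = "codominant"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    OVERDOMINANT = "overdominant"
    ALLELIC = "allelic"


@dataclass(frozen=True)
class ModelTable:
    """One 2x2 contrast produced by an inheritance-model encoding."""

    model: InheritanceModel
    contrast: str  # e.g. "C/T vs C/C"
    table: Table2x2
    dropped_classes: tuple = ()  # codominant classes absent from both groups


def _labels(marker=None):
    if marker is None:
        return ("ref-hom", "het", "alt-hom", "ref", "alt")
    return (
        marker.label(0),
        marker.label(1),
        marker.label(2),
        marker.ref_allele,
        marker.alt_allele,
    )


def encode_model(
    cases: GenotypeCounts,
    controls: GenotypeCounts,
    model: InheritanceModel,
    marker=None,
) -> List[ModelTable]:
    """Collapse case/control genotype counts into 2x2 tables under a model.

    Tables are oriented with cases as group 1 and the tested category as
    "exposed"; the reference category is the ref-homozygote class (or the
    pooled complement, depending on the model).  Codominant contrasts whose
    genotype class is absent from both groups are dropped and flagged.
    """
    model = InheritanceModel(model)
    if cases.n == 0 or controls.n == 0:
        raise ValueError("both groups must be non-empty")
    l0, l1, l2, ref_al, alt_al = _labels(marker)
    ca, co = cases.counts, controls.counts

    if model is InheritanceModel.CODOMINANT:
        out, dropped = [], []
        for idx, lab in ((1, l1), (2, l2)):
            if ca[idx] == 0 and co[idx] == 0:
                dropped.append(lab)
        for idx, lab in ((1, l1), (2, l2)):
            if ca[idx] == 0 and co[idx] == 0:
                continue
            out.append(
                ModelTable(
                    model,
                    f"{lab} vs {l0}",
                    Table2x2(ca[idx], ca[0], co[idx], co[0]),
                    dropped_classes=tuple(dropped),
                )
            )
        return out
    if model is InheritanceModel.DOMINANT:
        t = Table2x2(ca[1] + ca[2], ca[0], co[1] + co[2], co[0])
        return [ModelTable(model, f"{l1}-{l2} vs {l0}", t)]
    if model is InheritanceModel.RECESSIVE:
        t = Table2x2(ca[2], ca[0] + ca[1], co[2], co[0] + co[1])
        return [ModelTable(model, f"{l2} vs {l0}-{l1}", t)]
    if model is InheritanceModel.OVERDOMINANT:
        t = Table2x2(ca[1], ca[0] + ca[2], co[1], co[0] + co[2])
        return [ModelTable(model, f"{l1} vs {l0}-{l2}", t)]
    if model is InheritanceModel.ALLELIC:
        t = Table2x2(
            cases.n_alt_alleles, cases.n_ref_alleles,
            controls.n_alt_alleles, controls.n_ref_alleles,
        )
        return [ModelTable(model, f"{alt_al} vs {ref_al}", t)]
    raise ValueError(f"unknown inheritance model {model!r}")  # pragma: no cover


@dataclass(frozen=True)
class HWEResult:
    """Hardy-Weinberg test for one group: chi-square and exact p-values."""

    chi2: float
    p_chi2: float
    p_exact: float
    allele_freq: float  # ref-allele frequency
    expected_counts: tuple
    monomorphic: bool = False


def _hwe_expected(g: GenotypeCounts) -> tuple:
    n = g.n
    p = g.ref_allele_freq
    q = 1.0 - p
    return (n * p * p, 2 * n * p * q, n * q * q)


def hwe_chi2(g: GenotypeCounts, yates: bool = False) -> HWEResult:
    """1-df chi-square test of Hardy-Weinberg proportions.

    Expected counts (n p^2, 2 n p q, n q^2) from the observed allele
    frequency; no continuity correction unless ``yates=True``.  Monomorphic
    input returns p = 1 with a warning rather than erroring.
    """
    if g.n == 0:
        raise ValueError("no subjects")
    if g.n_ref_alleles == 0 or g.n_alt_alleles == 0:
        warnings.warn("monomorphic marker: HWE trivially satisfied", stacklevel=2)
        return HWEResult(0.0, 1.0, 1.0, g.ref_allele_freq, _hwe_expected(g), monomorphic=True)
    expected = _hwe_expected(g)
    chi2 = 0.0
    for o, e in zip(g.counts, expected):
        diff = abs(o - e)
        if yates:
            diff = max(diff - 0.5, 0.0)
        chi2 += diff * diff / e
    p = float(sps.chi2.sf(chi2, 1))
    return HWEResult(chi2, p, hwe_exact_p(g), g.ref_allele_freq, expected)


def hwe_exact_p(g: GenotypeCounts) -> float:
    """Exact HWE p-value: conditional test on the heterozygote count.

    Given the allele counts, the heterozygote count under HWE follows the
    standard conditional distribution
    ``P(n_het) ∝ n! 2^n_het / (n_rr! n_het! n_aa!)``; the p-value sums the
    probabilities of all heterozygote counts no more probable than the one
    observed.
    """
    if g.n == 0:
        raise ValueError("no subjects")
    n = g.n
    n_rare = min(g.n_ref_alleles, g.n_alt_alleles)
    if n_rare == 0:
        return 1.0

    def log_prob(n_het: int) -> float:
        n_hom_rare = (n_rare - n_het) // 2
        n_hom_common = n - n_het - n_hom_rare
        return (
            math.lgamma(n + 1)
            - math.lgamma(n_hom_rare + 1)
            - math.lgamma(n_het + 1)
            - math.lgamma(n_hom_common + 1)
            + n_het * math.log(2.0)
            + math.lgamma(g.n_ref_alleles + 1)
            + math.lgamma(g.n_alt_alleles + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(n_rare % 2, n_rare + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    obs = logs[g.n_het]
    # tolerance guards ties against floating-point noise
    p = sum(math.exp(lp) for lp in logs.values() if lp <= obs + 1e-12)
    return min(p, 1.0)


def hwe_exact(g: GenotypeCounts) -> HWEResult:
    """Exact HWE test (chi-square fields filled in alongside)."""
    return hwe_chi2(g)


def hwe_test(g: GenotypeCounts) -> HWEResult:
    """Both HWE tests for one group (chi-square p and exact p)."""
    return hwe_chi2(g)


def cochran_armitage_trend(cases: GenotypeCounts, controls: GenotypeCounts) -> TestResult:
    """Cochran-Armitage test for trend in dosage (scores 0, 1, 2).

    A model-free additive test; note the tabulated "allelic" analysis in
    this package is the allele-count 2x2, not this statistic.
    """
    r = np.array(cases.counts, dtype=float)
    s = np.array(controls.counts, dtype=float)
    n = r + s
    if n.sum() == 0:
        raise ValueError("empty table")
    scores = np.array([0.0, 1.0, 2.0])
    N = n.sum()
    R = r.sum()
    t_stat = float(np.sum(scores * (r - n * R / N)))
    mean_sq = np.sum(scores**2 * n) / N - (np.sum(scores * n) / N) ** 2
    var = R * (N - R) / N * mean_sq * N / (N - 1)
    if var <= 0:
        return TestResult(statistic=0.0, df=1, p=1.0, test_name="cochran_armitage")
    z = t_stat / math.sqrt(var)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return TestResult(statistic=z * z, df=1, p=min(p, 1.0), test_name="cochran_armitage")
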