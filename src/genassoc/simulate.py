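"""Synthetic cohorts with the statistical structure the analysis assumes.

Genotypes are drawn as two independent allele draws at a configured minor
allele frequency, so simulated populations are in Hardy-Weinberg
equilibrium by construction.  Disease status follows a logistic model: the
log odds are a baseline plus a genotype effect (under a chosen inheritance
model), optionally plus binary-exposure main and multiplicative
interaction terms.  Cases and controls are collected by rejection from a
population stream, which keeps the sampling exact at the cost of drawing
more subjects than are kept; the default baseline odds of 0.1 (~9%
prevalence) makes case collection cheap at desk scale.

A two-locus generator draws per-subject haplotype pairs from a configured
haplotype-frequency 4-vector, providing ground truth for the EM and LD
estimators.  All randomness flows from a single seeded NumPy generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .haplotypes import HAPLOTYPE_ORDER
from .io import CohortTable
from .markers import MarkerDef
from .models import GenotypeCounts, InheritanceModel

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_case_control",
    "simulate_case_control_dosages",
    "simulate_two_locus",
    "simulate_fragments",
]

_MAX_POPULATION_DRAWS = 10_000_000


def _genotype_code(dosage: np.ndarray, model: InheritanceModel) -> np.ndarray:
    model = InheritanceModel(model)
    if model is InheritanceModel.DOMINANT:
        return (dosage >= 1).astype(float)
    if model is InheritanceModel.RECESSIVE:
        return (dosage == 2).astype(float)
    if model is InheritanceModel.OVERDOMINANT:
        return (dosage == 1).astype(float)
    if model is InheritanceModel.ALLELIC:
        return dosage.astype(float)  # per-allele (additive) coding
    raise ValueError(
        f"model {model.value!r} has no single-parameter risk coding; "
        "use dominant/recessive/overdominant/allelic"
    )


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic case-control cohort.

    Defaults emulate a candidate-SNP breast-cancer panel: 135 cases and
    112 controls, one biallelic marker at MAF 0.3 with no genotype effect,
    baseline disease odds 0.1.
    """

    maf: float = 0.3
    model: InheritanceModel = InheritanceModel.DOMINANT
    genotype_or: float = 1.0
    baseline_odds: float = 0.1
    n_cases: int = 135
    n_controls: int = 112
    hap_freqs: Optional[Tuple[float, float, float, float]] = None
    exposure_prevalence: Optional[float] = None
    exposure_or: float = 1.0
    interaction_or: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0.0 < self.maf < 1.0):
            raise ValueError("maf must lie in (0, 1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        if self.genotype_or <= 0 or self.baseline_odds <= 0:
            raise ValueError("odds and odds ratios must be positive")
        if self.hap_freqs is not None:
            h = np.asarray(self.hap_freqs, dtype=float)
            if h.shape != (4,) or np.any(h < 0) or abs(h.sum() - 1) > 1e-9:
                raise ValueError("hap_freqs must be a non-negative 4-vector summing to 1")
        if self.exposure_prevalence is not None and not (0 < self.exposure_prevalence < 1):
            raise ValueError("exposure_prevalence must lie in (0, 1)")


def simulate_genotypes(maf: float, n: int, rng) -> np.ndarray:
    """Draw n dosages as two independent allele draws (HWE by construction)."""
    if not (0.0 < maf < 1.0):
        raise ValueError("maf must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    return rng.binomial(2, maf, size=n)


def simulate_case_control_dosages(config: SimulationConfig, rng=None):
    """Rejection-sample case and control dosage vectors from a population stream.

    Returns ``(case_dosages, control_dosages, case_exposure, control_exposure)``;
    the exposure arrays are None unless an exposure is configured.  Raises
    if the requested group sizes are unattainable within 10^7 draws.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    beta0 = math.log(config.baseline_odds)
    beta_g = math.log(config.genotype_or)
    with_exposure = config.exposure_prevalence is not None

    need = {True: config.n_cases, False: config.n_controls}
    got_g = {True: [], False: []}
    got_e = {True: [], False: []}
    drawn = 0
    chunk = max(4096, 2 * (config.n_cases + config.n_controls))
    while (len(got_g[True]) < need[True] or len(got_g[False]) < need[False]):
        if drawn >= _MAX_POPULATION_DRAWS:
            raise RuntimeError(
                f"could not collect {need[True]} cases / {need[False]} controls "
                f"within {_MAX_POPULATION_DRAWS} population draws"
            )
        g = rng.binomial(2, config.maf, size=chunk)
        eta = beta0 + beta_g * _genotype_code(g, config.model)
        if with_exposure:
            e = rng.random(chunk) < config.exposure_prevalence
            eta = eta + math.log(config.exposure_or) * e
            eta = eta + math.log(config.interaction_or) * e * _genotype_code(g, config.model)
        else:
            e = None
        p = 1.0 / (1.0 + np.exp(-eta))
        status = rng.random(chunk) < p
        drawn += chunk
        for st in (True, False):
            short = need[st] - len(got_g[st])
            if short > 0:
                idx = np.nonzero(status == st)[0][:short]
                got_g[st].extend(g[idx].tolist())
                if with_exposure:
                    got_e[st].extend(e[idx].astype(int).tolist())
    case_g = np.array(got_g[True], dtype=int)
    control_g = np.array(got_g[False], dtype=int)
    if with_exposure:
        return case_g, control_g, np.array(got_e[True]), np.array(got_e[False])
    return case_g, control_g, None, None


def _default_marker() -> MarkerDef:
    return MarkerDef(
        marker_id="sim1",
        gene="SIM",
        ref_allele="A",
        alt_allele="B",
        genotype_labels={0: "A/A", 1: "A/B", 2: "B/B"},
    )


def simulate_case_control(config: SimulationConfig, rng=None,
                          marker: Optional[MarkerDef] = None) -> CohortTable:
    """Simulate a full cohort table ready for the association pipeline."""
    marker = marker or _default_marker()
    case_g, control_g, case_e, control_e = simulate_case_control_dosages(config, rng)
    n = config.n_cases + config.n_controls
    ids = [f"S{i:05d}" for i in range(1, n + 1)]
    status = [True] * config.n_cases + [False] * config.n_controls
    pheno = pd.DataFrame({"status": status}, index=pd.Index(ids, name="subject_id"))
    if case_e is not None:
        pheno["exposure"] = np.concatenate([case_e, control_e]).astype(int)
    geno = pd.DataFrame(
        {marker.marker_id: np.concatenate([case_g, control_g])},
        index=pheno.index, dtype="Int64",
    )
    return CohortTable(pheno, geno, {marker.marker_id: marker})


def simulate_two_locus(hap_freqs: Sequence, n: int, rng=None):
    """Draw n subjects as two haplotypes each from a 4-vector of frequencies.

    Returns ``(joint, phased)``: the 3x3 joint dosage count matrix consumed
    by the EM, and the true phased haplotype counts (4-vector in
    :data:`~genassoc.haplotypes.HAPLOTYPE_ORDER`) for oracle use.
    """
    f = np.asarray(hap_freqs, dtype=float)
    if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1) > 1e-9:
        raise ValueError("hap_freqs must be a non-negative 4-vector summing to 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    h1 = rng.choice(4, size=n, p=f)
    h2 = rng.choice(4, size=n, p=f)
    alleles = np.array(HAPLOTYPE_ORDER)
    da = alleles[h1, 0] + alleles[h2, 0]
    db = alleles[h1, 1] + alleles[h2, 1]
    joint = np.zeros((3, 3), dtype=int)
    np.add.at(joint, (da, db), 1)
    phased = np.bincount(np.concatenate([h1, h2]), minlength=4)
    return joint, phased


def simulate_fragments(marker: MarkerDef, dosage: int, rng=None,
                       dropout_prob: float = 1.0) -> list:
    """Emit an RFLP fragment multiset for a genotype, for end-to-end tests.

    Fragments at or below the marker's resolution limit are dropped with
    probability ``dropout_prob`` (default: always dropped, emulating small
    fragments running off the gel).
    """
    if marker.rflp_signatures is None:
        raise ValueError(f"{marker.marker_id} has no RFLP signatures")
    rng = np.random.default_rng(rng)
    out = []
    for f in marker.rflp_signatures[dosage]:
        if f <= marker.min_resolvable_fragment_bp and rng.random() < dropout_prob:
            continue
        out.append(f)
    return out
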