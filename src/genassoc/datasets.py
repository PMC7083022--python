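"""Bundled example dataset: a North-Sardinian breast-cancer SNP panel.

Published contingency counts from a case-control study of five PCR-RFLP
genotyped polymorphisms — MTHFR C677T (rs1801133) and A1298C (rs1801131),
XRCC1 Arg194Trp (rs1799782) and Arg399Gln (rs25487), OGG1 Ser326Cys
(rs1052133) — in 135 breast-cancer cases and 112 healthy women.  The raw
per-subject data were never deposited; what is available, and bundled
here, are the per-group genotype counts, two-locus haplotype counts, and
case-only subgroup counts, which are sufficient inputs for every analysis
in this package.

``study_cohort()`` expands the genotype counts into a per-subject cohort
table.  Only per-marker margins are published, so genotypes are assigned
independently marker by marker: all single-marker analyses reproduce
exactly, but cross-marker joint distributions in the expanded table are
arbitrary.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeTable
from .io import CohortTable
from .markers import MarkerDef
from .models import GenotypeCounts

__all__ = [
    "study_markers",
    "study_genotype_counts",
    "study_cohort",
    "study_haplotypes",
    "study_subgroup_counts",
    "BONFERRONI_FAMILIES",
]

#: Multiple-testing families of the study: 18 descriptive-variable tests,
#: 5 association tests (one per SNP).
BONFERRONI_FAMILIES = {"descriptive": 18, "association": 5}


def study_markers() -> Dict[str, MarkerDef]:
    """The five study markers with their RFLP fragment signatures (bp).

    Sub-resolution control fragments (21-23 bp) are encoded in the
    signatures but optional when matching, via the default 25 bp
    resolution limit.
    """
    defs = [
        MarkerDef(
            marker_id="rs1801133", gene="MTHFR",
            ref_allele="C", alt_allele="T",
            genotype_labels={0: "C/C", 1: "C/T", 2: "T/T"},
            rflp_signatures={0: (201,), 1: (201, 178, 23), 2: (178, 23)},
        ),
        MarkerDef(
            marker_id="rs1801131", gene="MTHFR",
            ref_allele="A", alt_allele="C",
            genotype_labels={0: "A/A", 1: "A/C", 2: "C/C"},
            rflp_signatures={
                0: (56, 31, 30, 28, 18),
                1: (84, 56, 31, 30, 28, 18),
                2: (84, 31, 30, 28, 18),
            },
        ),
        MarkerDef(
            marker_id="rs1799782", gene="XRCC1",
            ref_allele="C", alt_allele="T",  # Arg194Trp
            genotype_labels={0: "C/C", 1: "C/T", 2: "T/T"},
            rflp_signatures={0: (292, 174, 21), 1: (313, 292, 174, 21), 2: (313, 174)},
        ),
        MarkerDef(
            marker_id="rs25487", gene="XRCC1",
            ref_allele="G", alt_allele="A",  # Arg399Gln
            genotype_labels={0: "G/G", 1: "G/A", 2: "A/A"},
            rflp_signatures={0: (374, 241), 1: (615, 374, 241), 2: (615,)},
        ),
        MarkerDef(
            marker_id="rs1052133", gene="OGG1",
            ref_allele="C", alt_allele="G",  # Ser326Cys
            genotype_labels={0: "C/C", 1: "C/G", 2: "G/G"},
            rflp_signatures={0: (213, 21), 1: (213, 164, 49, 21), 2: (164, 49, 21)},
        ),
    ]
    return {m.marker_id: m for m in defs}


# (ref-hom, het, alt-hom) per group; 135 cases, 112 controls.
_GENOTYPE_COUNTS = {
    "rs1801133": {"cases": (53, 60, 22), "controls": (31, 62, 19)},
    "rs1801131": {"cases": (66, 55, 14), "controls": (56, 49, 7)},
    "rs1799782": {"cases": (128, 7, 0), "controls": (102, 10, 0)},
    "rs25487": {"cases": (64, 55, 16), "controls": (53, 43, 16)},
    "rs1052133": {"cases": (87, 46, 2), "controls": (70, 35, 7)},
}


def study_genotype_counts() -> Dict[str, Dict[str, GenotypeCounts]]:
    """Published per-group genotype counts for the five markers."""
    return {
        m: {g: GenotypeCounts(*c) for g, c in groups.items()}
        for m, groups in _GENOTYPE_COUNTS.items()
    }


def study_cohort() -> CohortTable:
    """Expand the published genotype counts into a per-subject cohort.

    Genotypes are laid out deterministically (ref-hom block, then het,
    then alt-hom) independently per marker; see the module docstring for
    what this does and does not preserve.
    """
    markers = study_markers()
    n_cases = sum(_GENOTYPE_COUNTS["rs1801133"]["cases"])
    n_controls = sum(_GENOTYPE_COUNTS["rs1801133"]["controls"])
    ids = [f"CA{i:04d}" for i in range(1, n_cases + 1)] + \
          [f"CO{i:04d}" for i in range(1, n_controls + 1)]
    pheno = pd.DataFrame(
        {"status": [True] * n_cases + [False] * n_controls},
        index=pd.Index(ids, name="subject_id"),
    )
    geno = {}
    for m_id, groups in _GENOTYPE_COUNTS.items():
        col = []
        for grp, n in (("cases", n_cases), ("controls", n_controls)):
            counts = groups[grp]
            if sum(counts) != n:
                raise AssertionError(f"{m_id} {grp}: counts sum to {sum(counts)} != {n}")
            for dosage, k in enumerate(counts):
                col.extend([dosage] * k)
        geno[m_id] = col
    genotypes = pd.DataFrame(geno, index=pheno.index, dtype="Int64")
    return CohortTable(pheno, genotypes, markers)


def study_haplotypes() -> Dict[str, HaplotypeTable]:
    """Published two-locus haplotype counts for the two within-gene pairs.

    MTHFR: rs1801133/rs1801131; XRCC1: rs1799782/rs25487.  Labels are the
    constituent alleles in locus order.  (As published, each group's
    counts total 247 chromosomes; they are consumed verbatim.)
    """
    return {
        "MTHFR": HaplotypeTable(
            labels=("TA", "CC", "CA", "TC"),
            case_counts=(95, 77, 75, 0),
            control_counts=(110, 70, 67, 0),
        ),
        "XRCC1": HaplotypeTable(
            labels=("CG", "CA", "TG", "TA"),
            case_counts=(160, 81, 6, 0),
            control_counts=(153, 83, 11, 0),
        ),
    }


def study_subgroup_counts() -> Dict[str, dict]:
    """Published case-only subgroup genotype counts.

    OGG1 rs1052133 against PgR and Her2 status (only the recessive
    collapse was published: the het column is folded into the ref-hom
    class, which leaves every recessive and allelic-free contrast intact),
    and XRCC1 rs25487 against family history (full genotype counts).
    Group order matches the published orientation: the first-listed class
    (PgR+, Her2+, sporadic) is group 1.
    """
    return {
        "ogg1_pgr": {
            "marker": "rs1052133",
            "groups": ("PgR+", "PgR-"),
            "counts": (GenotypeCounts(90, 0, 0), GenotypeCounts(43, 0, 2)),
        },
        "ogg1_her2": {
            "marker": "rs1052133",
            "groups": ("Her2+", "Her2-"),
            "counts": (GenotypeCounts(40, 0, 2), GenotypeCounts(88, 0, 0)),
        },
        "xrcc1_family_history": {
            "marker": "rs25487",
            "groups": ("sporadic", "familial"),
            "counts": (GenotypeCounts(31, 37, 8), GenotypeCounts(33, 18, 8)),
        },
    }
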