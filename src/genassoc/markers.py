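"""Marker definitions and virtual PCR-RFLP genotype calling.

A biallelic SNP assayed by PCR-RFLP is described by a :class:`MarkerDef`:
its two alleles, display labels for the three genotype classes, and the
restriction-fragment signature (a multiset of fragment lengths in bp) that
each genotype produces on a gel.  :func:`call_genotype_from_fragments` maps
an observed fragment pattern back to a genotype, treating fragments at or
below the gel's resolution limit as optional.  Two markers multiplexed in a
single digest (e.g. the two XRCC1 codons) are handled by partitioning the
joint pattern into per-marker sub-patterns with
:func:`split_multiplex_fragments` before calling each marker separately.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "MISSING",
    "MarkerDef",
    "GenotypeCall",
    "AmbiguousCallError",
    "call_genotype_from_fragments",
    "split_multiplex_fragments",
    "pack_years",
    "binarize_clinical",
    "CLINICAL_SCHEMES",
]

#: Sentinel for an unknown genotype / clinical value.
MISSING = None

DOSAGES = (0, 1, 2)


class AmbiguousCallError(ValueError):
    """Raised when an observed fragment pattern is compatible with two or
    more genotype signatures; the caller never guesses."""


@dataclass(frozen=True)
class MarkerDef:
    """Definition of one biallelic SNP marker.

    Parameters
    ----------
    marker_id : str
        dbSNP-style identifier, e.g. ``"rs1801133"``.
    gene : str
        Gene symbol the marker lies in.
    ref_allele, alt_allele : str
        Single-character allele labels; dosage counts the alt allele.
    genotype_labels : mapping {0, 1, 2} -> str
        Display strings for ref-hom / het / alt-hom, e.g. ``"C/C"``.
    rflp_signatures : mapping {0, 1, 2} -> tuple of int, optional
        Restriction-fragment lengths (bp) produced by each genotype.
    min_resolvable_fragment_bp : int
        Fragments at or below this length may run off the gel and are
        optional when matching an observed pattern.
    """

    marker_id: str
    gene: str
    ref_allele: str
    alt_allele: str
    genotype_labels: Mapping[int, str]
    rflp_signatures: Optional[Mapping[int, tuple]] = None
    min_resolvable_fragment_bp: int = 25

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"{self.marker_id}: ref and alt allele are both {self.ref_allele!r}"
            )
        if set(self.genotype_labels) != set(DOSAGES):
            raise ValueError(f"{self.marker_id}: genotype_labels must cover dosages 0,1,2")
        if len(set(self.genotype_labels.values())) != 3:
            raise ValueError(f"{self.marker_id}: genotype_labels are not unique")
        if self.rflp_signatures is not None:
            if set(self.rflp_signatures) != set(DOSAGES):
                raise ValueError(f"{self.marker_id}: rflp_signatures must cover dosages 0,1,2")
            cores = [
                frozenset(
                    Counter(
                        f for f in self.rflp_signatures[d]
                        if f > self.min_resolvable_fragment_bp
                    ).items()
                )
                for d in DOSAGES
            ]
            if len(set(cores)) != 3:
                raise ValueError(
                    f"{self.marker_id}: RFLP signatures are not distinguishable after "
                    f"dropping fragments <= {self.min_resolvable_fragment_bp} bp"
                )

    # -- genotype string handling -------------------------------------------------

    def dosage_from_cell(self, cell: str) -> int:
        """Parse an ``"X/Y"`` genotype cell into an alt-allele dosage.

        Allele order is irrelevant (``"C/T"`` == ``"T/C"``).  An allele
        character outside ``{ref, alt}`` is an error, never MISSING.
        """
        parts = cell.strip().split("/")
        if len(parts) != 2:
            raise ValueError(f"{self.marker_id}: malformed genotype cell {cell!r}")
        dosage = 0
        for allele in parts:
            if allele == self.alt_allele:
                dosage += 1
            elif allele != self.ref_allele:
                raise ValueError(
                    f"{self.marker_id}: allele {allele!r} in cell {cell!r} is not one of "
                    f"{{{self.ref_allele}, {self.alt_allele}}}"
                )
        return dosage

    def cell_from_dosage(self, dosage) -> str:
        if dosage is MISSING:
            raise ValueError("cannot format MISSING dosage; use the missing token")
        return "/".join(
            [self.ref_allele] * (2 - dosage) + [self.alt_allele] * dosage
        )

    def label(self, dosage: int) -> str:
        return self.genotype_labels[dosage]

    def flipped(self) -> "MarkerDef":
        """The same marker with ref and alt alleles exchanged (dosage d -> 2-d)."""
        relabel = {0: 2, 1: 1, 2: 0}
        return MarkerDef(
            marker_id=self.marker_id,
            gene=self.gene,
            ref_allele=self.alt_allele,
            alt_allele=self.ref_allele,
            genotype_labels={relabel[d]: s for d, s in self.genotype_labels.items()},
            rflp_signatures=(
                None
                if self.rflp_signatures is None
                else {relabel[d]: s for d, s in self.rflp_signatures.items()}
            ),
            min_resolvable_fragment_bp=self.min_resolvable_fragment_bp,
        )

    @property
    def diagnostic_fragments(self) -> frozenset:
        """All fragment lengths that can appear in any of this marker's signatures."""
        if self.rflp_signatures is None:
            return frozenset()
        return frozenset(f for sig in self.rflp_signatures.values() for f in sig)


@dataclass(frozen=True)
class GenotypeCall:
    """One genotype call: alt-allele dosage in {0, 1, 2} or MISSING."""

    marker_id: str
    dosage: Optional[int]

    def __post_init__(self):
        if self.dosage is not MISSING and self.dosage not in DOSAGES:
            raise ValueError(f"dosage must be 0, 1, 2 or MISSING, got {self.dosage!r}")


def call_genotype_from_fragments(marker: MarkerDef, fragments: Iterable[int]) -> GenotypeCall:
    """Call a genotype from an observed multiset of restriction-fragment lengths.

    A signature matches when every fragment longer than
    ``min_resolvable_fragment_bp`` is observed with its full multiplicity,
    shorter (sub-resolution) fragments are present or absent freely, and no
    observed fragment falls outside the signature.  Exactly one match is a
    call; no match returns MISSING with a warning; two or more matches raise
    :class:`AmbiguousCallError` — the caller never guesses.
    """
    if marker.rflp_signatures is None:
        raise ValueError(f"{marker.marker_id} has no RFLP signatures configured")
    observed = Counter(int(f) for f in fragments)
    if any(f <= 0 for f in observed):
        raise ValueError("fragment lengths must be positive integers")

    matches = []
    for dosage in DOSAGES:
        full = Counter(marker.rflp_signatures[dosage])
        required = Counter(
            {f: k for f, k in full.items() if f > marker.min_resolvable_fragment_bp}
        )
        if (observed & full) == observed and (observed & required) == required:
            matches.append(dosage)

    if not matches:
        warnings.warn(
            f"{marker.marker_id}: fragment pattern {sorted(observed.elements(), reverse=True)} "
            f"matches no genotype signature; calling MISSING",
            stacklevel=2,
        )
        return GenotypeCall(marker.marker_id, MISSING)
    if len(matches) > 1:
        names = ", ".join(marker.label(d) for d in matches)
        raise AmbiguousCallError(
            f"{marker.marker_id}: pattern compatible with multiple genotypes: {names}"
        )
    return GenotypeCall(marker.marker_id, matches[0])


def split_multiplex_fragments(fragments: Iterable[int], markers: Iterable[MarkerDef]) -> dict:
    """Partition a joint digest pattern among multiplexed markers.

    Each marker claims the fragments that occur in its own signatures; the
    markers' fragment universes must be disjoint (true for the XRCC1
    codon-194/codon-399 multiplex).  A fragment belonging to no marker is an
    error.  Returns ``{marker_id: [fragments]}``.
    """
    markers = list(markers)
    universes = [m.diagnostic_fragments for m in markers]
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            shared = universes[i] & universes[j]
            if shared:
                raise ValueError(
                    f"markers {markers[i].marker_id} and {markers[j].marker_id} share "
                    f"diagnostic fragments {sorted(shared)}; cannot demultiplex"
                )
    out = {m.marker_id: [] for m in markers}
    for f in fragments:
        f = int(f)
        for m, uni in zip(markers, universes):
            if f in uni:
                out[m.marker_id].append(f)
                break
        else:
            raise ValueError(f"fragment {f} bp belongs to no multiplexed marker")
    return out


def pack_years(years_smoked: float, cigarettes_per_day: float) -> float:
    """Smoking exposure in pack-years: years smoked x cigarettes/day / 20."""
    if years_smoked < 0 or cigarettes_per_day < 0:
        raise ValueError("years_smoked and cigarettes_per_day must be non-negative")
    return years_smoked * cigarettes_per_day / 20.0


# -- clinical binarisation schemes -------------------------------------------------
#
# Each scheme maps a raw clinical value to one of two class labels; the first
# label is the group listed first in reports (group-1 of the 2x2 table).
# Cutpoints are inclusive on the side the label names (Ki67 of exactly 30%
# falls in "<=30%", age of exactly 40 in "<=40").

def _ki67_30(v):
    return "<=30%" if v <= 30 else ">30%"


def _age_dx_40(v):
    return "<=40" if v <= 40 else ">40"


def _bmi_25(v):
    return "<25" if v < 25 else ">=25"


def _passthrough(first, second):
    def f(v):
        if v == first:
            return first
        if v == second:
            return second
        raise ValueError(f"value {v!r} is not one of {first!r}/{second!r}")
    return f


CLINICAL_SCHEMES = {
    # scheme -> (class labels in report order, value -> label)
    "ki67_30": (("<=30%", ">30%"), _ki67_30),
    "age_dx_40": (("<=40", ">40"), _age_dx_40),
    "bmi_25": (("<25", ">=25"), _bmi_25),
    "family_history": (("sporadic", "familial"), _passthrough("sporadic", "familial")),
    "menopause_dx": (("pre", "post"), _passthrough("pre", "post")),
    "er": (("pos", "neg"), _passthrough("pos", "neg")),
    "pgr": (("pos", "neg"), _passthrough("pos", "neg")),
    "her2": (("pos", "neg"), _passthrough("pos", "neg")),
    "lymph_node": (("pos", "neg"), _passthrough("pos", "neg")),
}


def binarize_clinical(value, scheme: str):
    """Assign a clinical value to one of a scheme's two classes.

    MISSING propagates.  Unknown scheme names are an error.  See
    ``CLINICAL_SCHEMES`` for the documented cutpoints (Ki67 at 30%
    inclusive, age at diagnosis at 40 inclusive, BMI at 25, sporadic vs
    familial disease, hormone-receptor status).
    """
    try:
        _, fn = CLINICAL_SCHEMES[scheme]
    except KeyError:
        raise ValueError(
            f"unknown clinical scheme {scheme!r}; known: {sorted(CLINICAL_SCHEMES)}"
        ) from None
    if value is MISSING or (isinstance(value, float) and value != value):
        return MISSING
    return fn(value)


def scheme_classes(scheme: str) -> tuple:
    """The two class labels of a scheme, in report (group-1, group-2) order."""
    try:
        labels, _ = CLINICAL_SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown clinical scheme {scheme!r}") from None
    return labels
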