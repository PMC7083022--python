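"""Orchestration of the full candidate-SNP association analysis.

``run_snp_association`` scans every marker under the configured
inheritance models: per-contrast Pearson chi-square and Woolf odds ratio
(Gart-adjusted on zero cells), with Hardy-Weinberg results attached per
marker and per group, and nominal plus family-wise (Bonferroni)
significance flags.  ``run_subgroup_association`` applies the same
machinery case-only, with a binarised clinical variable standing in for
case/control status.  ``gxe_interaction`` fits the multiplicative
gene-environment logistic model and reports the Wald test of the
interaction term.  Reports are written as TSV (flat, byte-stable) and
JSON (nested by marker), with full-precision numbers alongside
display-rounded columns.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import CohortTable
from .markers import MISSING, binarize_clinical, scheme_classes
from .models import (
    GenotypeCounts,
    HWEResult,
    InheritanceModel,
    ModelTable,
    encode_model,
    hwe_test,
)
from .stats import (
    ORResult,
    Table2x2,
    TestResult,
    bonferroni_threshold,
    odds_ratio_ci,
    pearson_chi2,
    woolf_or_ci,
)

__all__ = [
    "AnalysisConfig",
    "AssociationResult",
    "GxEResult",
    "run_snp_association",
    "run_subgroup_association",
    "gxe_interaction",
    "write_report",
    "results_to_frame",
    "read_report_json",
    "format_or",
    "format_p",
]

ALL_MODELS = tuple(InheritanceModel)


@dataclass
class AnalysisConfig:
    """Configuration of an association run.

    ``families`` maps a family name to its number of tests m; each result
    is assigned a family and flagged significant after correction iff
    p < alpha/m.  ``zero_cell_policy`` selects the Gart-adjusted interval
    ("gart", default) or skipping ("skip") for tables with a zero cell.
    """

    models: Tuple[InheritanceModel, ...] = ALL_MODELS
    alpha: float = 0.05
    families: Dict[str, int] = field(default_factory=lambda: {"association": 5})
    default_family: str = "association"
    zero_cell_policy: str = "gart"
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.zero_cell_policy not in ("gart", "skip"):
            raise ValueError("zero_cell_policy must be 'gart' or 'skip'")
        self.models = tuple(InheritanceModel(m) for m in self.models)
        if self.default_family not in self.families:
            raise ValueError(f"default family {self.default_family!r} not in families")

    def threshold(self, family: str) -> float:
        return bonferroni_threshold(self.alpha, self.families[family])


@dataclass(frozen=True)
class AssociationResult:
    """One tested contrast: marker x model x genotype category."""

    marker_id: str
    model: InheritanceModel
    contrast: str
    table: Table2x2
    or_result: Optional[ORResult]  # None under the 'skip' zero-cell policy
    test_result: TestResult
    bonferroni_family: str
    significant_nominal: bool
    significant_corrected: bool
    hwe_group1: Optional[HWEResult] = None
    hwe_group2: Optional[HWEResult] = None
    group_labels: Tuple[str, str] = ("cases", "controls")


def _analyse_tables(
    marker_id: str,
    model_tables: Sequence[ModelTable],
    config: AnalysisConfig,
    family: str,
    hwe1: Optional[HWEResult],
    hwe2: Optional[HWEResult],
    group_labels: Tuple[str, str],
) -> List[AssociationResult]:
    thresh = config.threshold(family)
    out = []
    for mt in model_tables:
        t = mt.table
        a, b, c, d = t.cells
        if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
            warnings.warn(
                f"{marker_id} {mt.model.value} ({mt.contrast}): degenerate table "
                f"{t.cells}; contrast skipped", stacklevel=3,
            )
            continue
        if t.has_zero_cell() and config.zero_cell_policy == "skip":
            or_res = None
        else:
            or_res = odds_ratio_ci(t)
        try:
            test = pearson_chi2(t.as_array())
        except ValueError:
            # degenerate margin: no variation to test
            test = TestResult(0.0, 1, 1.0, "pearson_chi2")
        out.append(
            AssociationResult(
                marker_id=marker_id,
                model=mt.model,
                contrast=mt.contrast,
                table=t,
                or_result=or_res,
                test_result=test,
                bonferroni_family=family,
                significant_nominal=test.p <= config.alpha,
                significant_corrected=test.p < thresh,
                hwe_group1=hwe1,
                hwe_group2=hwe2,
                group_labels=group_labels,
            )
        )
    return out


def run_snp_association(cohort: CohortTable, config: Optional[AnalysisConfig] = None,
                        family: Optional[str] = None) -> List[AssociationResult]:
    """Scan every marker under every configured inheritance model.

    Complete-case per marker (subjects with a MISSING dosage at that
    marker are dropped).  A marker with an empty group is skipped with a
    warning.  Results are ordered (marker, model, contrast); HWE for both
    groups travels with every result of its marker.
    """
    config = config or AnalysisConfig()
    family = family or config.default_family
    results: List[AssociationResult] = []
    for marker_id in cohort.genotypes.columns:
        cases, controls = cohort.group_counts(marker_id)
        if cases.n == 0 or controls.n == 0:
            warnings.warn(f"{marker_id}: a group has no genotyped subjects; skipped",
                          stacklevel=2)
            continue
        hwe_cases = hwe_test(cases)
        hwe_controls = hwe_test(controls)
        marker = cohort.markers[marker_id]
        for model in config.models:
            tables = encode_model(cases, controls, model, marker=marker)
            results.extend(
                _analyse_tables(marker_id, tables, config, family,
                                hwe_cases, hwe_controls, ("cases", "controls"))
            )
    return results


def run_subgroup_association(
    cases_only: CohortTable,
    variable: str,
    scheme: str,
    config: Optional[AnalysisConfig] = None,
    family: Optional[str] = None,
) -> List[AssociationResult]:
    """Case-only association of genotypes with a binarised clinical variable.

    The scheme's first class plays the role of group 1 ("cases" slot of
    the 2x2); zero cells follow the configured policy (Gart by default).
    A class with zero subjects skips the analysis for that variable.
    """
    config = config or AnalysisConfig()
    family = family or config.default_family
    if not cases_only.phenotypes["status"].astype(bool).all():
        cases_only = cases_only.cases()
    if variable not in cases_only.phenotypes.columns:
        raise ValueError(f"variable {variable!r} not in phenotype table")
    label1, label2 = scheme_classes(scheme)
    classes = cases_only.phenotypes[variable].map(
        lambda v: binarize_clinical(v, scheme) if not pd.isna(v) else MISSING
    )
    mask1 = (classes == label1).values
    mask2 = (classes == label2).values
    if mask1.sum() == 0 or mask2.sum() == 0:
        raise ValueError(
            f"variable {variable!r}: class with zero subjects "
            f"({label1}: {mask1.sum()}, {label2}: {mask2.sum()})"
        )
    results: List[AssociationResult] = []
    for marker_id in cases_only.genotypes.columns:
        g1 = cases_only.genotype_counts(marker_id, mask=mask1)
        g2 = cases_only.genotype_counts(marker_id, mask=mask2)
        if g1.n == 0 or g2.n == 0:
            warnings.warn(f"{marker_id}: a {variable} class has no genotyped subjects; skipped",
                          stacklevel=2)
            continue
        marker = cases_only.markers[marker_id]
        for model in config.models:
            tables = encode_model(g1, g2, model, marker=marker)
            results.extend(
                _analyse_tables(marker_id, tables, config, family,
                                hwe_test(g1), hwe_test(g2), (label1, label2))
            )
    return results


@dataclass(frozen=True)
class GxEResult:
    """Multiplicative gene-environment interaction from a logistic fit."""

    marker_id: str
    exposure: str
    coding: InheritanceModel
    beta_interaction: Optional[float]
    se_interaction: Optional[float]
    p_wald: Optional[float]
    interaction_or: Optional[float]
    separation: bool
    converged: bool
    coefficients: Optional[Dict[str, float]] = None


def _code_genotype(dosages: np.ndarray, coding: InheritanceModel) -> np.ndarray:
    coding = InheritanceModel(coding)
    if coding is InheritanceModel.DOMINANT:
        return (dosages >= 1).astype(float)
    if coding is InheritanceModel.RECESSIVE:
        return (dosages == 2).astype(float)
    if coding is InheritanceModel.ALLELIC:
        return dosages.astype(float)
    raise ValueError("genotype coding must be dominant, recessive or allelic")


def gxe_interaction(cohort: CohortTable, marker_id: str, exposure: str,
                    coding: InheritanceModel = InheritanceModel.DOMINANT) -> GxEResult:
    """Wald test of a multiplicative gene-environment interaction.

    Fits case/control status on intercept + genotype + exposure +
    genotype x exposure by IRLS (log-likelihood tolerance 1e-8, at most 50
    iterations).  The exposure must be binary with both levels present.
    Complete or quasi-complete separation (a fitted probability within
    1e-6 of 0 or 1 with a diverging coefficient) yields a flagged result
    with no p-value.
    """
    import statsmodels.api as sm

    coding = InheritanceModel(coding)
    df = pd.DataFrame({
        "y": cohort.phenotypes["status"].astype(float).values,
        "g": [np.nan if pd.isna(v) else float(v) for v in cohort.genotypes[marker_id]],
        "e": [np.nan if pd.isna(v) else float(v)
              for v in cohort.phenotypes[exposure]],
    }).dropna()
    e_levels = set(df["e"].unique())
    if not e_levels <= {0.0, 1.0}:
        raise ValueError(f"exposure {exposure!r} must be coded 0/1, saw {sorted(e_levels)}")
    if len(e_levels) < 2:
        raise ValueError(f"exposure {exposure!r} is constant")
    g = _code_genotype(df["g"].values, coding)
    X = sm.add_constant(
        pd.DataFrame({"g": g, "e": df["e"].values, "gxe": g * df["e"].values})
    )
    model = sm.GLM(df["y"].values, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(maxiter=50, tol=1e-8, scale=1.0)
    mu = np.asarray(fit.fittedvalues)
    params = {k: float(v) for k, v in fit.params.items()}
    diverged = any(abs(b) > 15 for b in params.values())
    separated = bool(((mu < 1e-6) | (mu > 1 - 1e-6)).any() and diverged)
    if separated:
        return GxEResult(marker_id, exposure, coding, None, None, None, None,
                         separation=True, converged=bool(fit.converged),
                         coefficients=params)
    beta = float(fit.params["gxe"])
    se = float(fit.bse["gxe"])
    from scipy import stats as sps
    p = 2.0 * float(sps.norm.sf(abs(beta / se))) if se > 0 else None
    return GxEResult(marker_id, exposure, coding, beta, se, p, math.exp(beta),
                     separation=False, converged=bool(fit.converged),
                     coefficients=params)


# -- report rendering --------------------------------------------------------------

def format_or(x: Optional[float]) -> str:
    """Display rounding for odds ratios and CI bounds: 2 decimals."""
    return "" if x is None else f"{x:.2f}"


def format_p(p: float) -> str:
    """Display rounding for p-values: 2 significant digits below 0.1,
    2 decimals otherwise (full precision is kept in the numeric columns)."""
    return f"{p:.2g}" if p < 0.1 else f"{p:.2f}"


_TSV_COLUMNS = [
    "marker_id", "model", "contrast", "group1", "group2",
    "a", "b", "c", "d",
    "or", "ci_low", "ci_high", "or_method",
    "chi2", "df", "p",
    "or_display", "ci_display", "p_display",
    "family", "significant_nominal", "significant_corrected",
    "hwe_p_chi2_group1", "hwe_p_chi2_group2",
    "hwe_p_exact_group1", "hwe_p_exact_group2",
]


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flatten association results to a stable-column DataFrame."""
    if not results:
        raise ValueError("no results to report")
    rows = []
    for r in results:
        orr = r.or_result
        rows.append({
            "marker_id": r.marker_id,
            "model": r.model.value,
            "contrast": r.contrast,
            "group1": r.group_labels[0],
            "group2": r.group_labels[1],
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "or": None if orr is None else orr.or_point,
            "ci_low": None if orr is None else orr.ci_low,
            "ci_high": None if orr is None else orr.ci_high,
            "or_method": None if orr is None else orr.method,
            "chi2": r.test_result.statistic,
            "df": r.test_result.df,
            "p": r.test_result.p,
            "or_display": format_or(None if orr is None else orr.or_point),
            "ci_display": "" if orr is None
                          else f"{format_or(orr.ci_low)}-{format_or(orr.ci_high)}",
            "p_display": format_p(r.test_result.p),
            "family": r.bonferroni_family,
            "significant_nominal": r.significant_nominal,
            "significant_corrected": r.significant_corrected,
            "hwe_p_chi2_group1": None if r.hwe_group1 is None else r.hwe_group1.p_chi2,
            "hwe_p_chi2_group2": None if r.hwe_group2 is None else r.hwe_group2.p_chi2,
            "hwe_p_exact_group1": None if r.hwe_group1 is None else r.hwe_group1.p_exact,
            "hwe_p_exact_group2": None if r.hwe_group2 is None else r.hwe_group2.p_exact,
        })
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_report(results: Sequence[AssociationResult], path, fmt: str = "tsv") -> None:
    """Write results as TSV (flat, byte-stable) or JSON (nested by marker)."""
    frame = results_to_frame(results)
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif fmt == "json":
        nested: Dict[str, list] = {}
        for row in frame.to_dict(orient="records"):
            clean = {k: (None if isinstance(v, float) and math.isnan(v) else v)
                     for k, v in row.items()}
            nested.setdefault(row["marker_id"], []).append(clean)
        with open(path, "w") as fh:
            json.dump(nested, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report_json(path) -> pd.DataFrame:
    """Load a JSON report back into the flat results frame."""
    with open(path) as fh:
        nested = json.load(fh)
    rows = [row for marker_rows in nested.values() for row in marker_rows]
    frame = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    return frame.sort_values(["marker_id", "model", "contrast"], kind="stable",
                             ignore_index=True)
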