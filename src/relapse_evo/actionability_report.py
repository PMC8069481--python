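"""Actionability integration, cohort summaries, and paired statistics.

Actionability rules are a local, versioned table (gene, alteration kind,
evidence level) -- no network service is ever consulted.  The paired
comparison implements the Wilcoxon signed-rank test on within-pair
differences with an exact sign-flip null distribution for small n; the
published description of the paired nonparametric test is ambiguous, and the
signed-rank form is the standard paired choice (the output labels it as
such).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FormatError, fmt_float

__all__ = [
    "ClinicalRecord",
    "ActionabilityRecord",
    "read_clinical",
    "default_clinical_table",
    "read_actionability_table",
    "default_actionability_table",
    "default_rules",
    "write_actionability_table",
    "assign_subtype",
    "summarize_clinical",
    "flag_actionable",
    "cohort_actionability_summary",
    "paired_comparison",
    "correlate",
]

_STATUS = {"+", "-", None}


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient row of the cohort characteristics table."""

    patient_id: str
    age: int
    grade: int | None
    er: str | None
    pr: str | None
    her2: str | None
    subtype_label: str | None
    relapse_months: float | None

    def __post_init__(self) -> None:
        for name in ("er", "pr", "her2"):
            if getattr(self, name) not in _STATUS:
                raise FormatError(f"{self.patient_id}: {name} must be '+', '-' or missing")


@dataclass(frozen=True)
class ActionabilityRecord:
    """One biomarker call; HRD-class records carry no clone/CCF/label."""

    sample_id: str
    lesion: str
    biomarker: str  # "OncoKB" | "HRD"
    alteration: str
    clone: str | None
    ccf: float | None
    classification: str | None  # "Trunk" | "Branch" | None

    def __post_init__(self) -> None:
        if self.biomarker == "HRD" and not (
            self.clone is None and self.ccf is None and self.classification is None
        ):
            raise FormatError(
                f"{self.sample_id} ({self.lesion}): HRD records must carry N/A "
                "clone/CCF/classification"
            )


# ---------------------------------------------------------------------------
# fixtures


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "age", "grade", "er", "pr", "her2", "subtype", "relapse_months"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        grade = _opt(row.grade)
        months = _opt(row.relapse_months)
        records.append(
            ClinicalRecord(
                patient_id=str(row.patient_id),
                age=int(row.age),
                grade=int(grade) if grade is not None else None,
                er=_opt(row.er),
                pr=_opt(row.pr),
                her2=_opt(row.her2),
                subtype_label=_opt(row.subtype),
                relapse_months=float(months) if months is not None else None,
            )
        )
    return records


def default_clinical_table() -> list[ClinicalRecord]:
    with resources.as_file(
        resources.files("relapse_evo.data") / "table1_clinical.tsv"
    ) as p:
        return read_clinical(p)


def read_actionability_table(path: str | Path) -> list[ActionabilityRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    records = []
    for row in df.itertuples(index=False):
        clone = None if row.clone == "NA" else row.clone
        ccf = None if row.ccf == "NA" else float(row.ccf)
        classification = None if row.classification == "NA" else row.classification
        records.append(
            ActionabilityRecord(
                sample_id=str(row.sample_id),
                lesion=str(row.lesion),
                biomarker=str(row.biomarker),
                alteration=str(row.alteration),
                clone=clone,
                ccf=ccf,
                classification=classification,
            )
        )
    return records


def default_actionability_table() -> list[ActionabilityRecord]:
    with resources.as_file(
        resources.files("relapse_evo.data") / "table2_actionability.tsv"
    ) as p:
        return read_actionability_table(p)


def default_rules() -> pd.DataFrame:
    from .io_formats import read_rules

    with resources.as_file(
        resources.files("relapse_evo.data") / "oncokb_rules.tsv"
    ) as p:
        return read_rules(p)


def write_actionability_table(records: list[ActionabilityRecord], path: str | Path) -> None:
    lines = ["\t".join(["sample_id", "lesion", "biomarker", "alteration", "clone", "ccf", "classification"])]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.sample_id,
                    r.lesion,
                    r.biomarker,
                    r.alteration,
                    r.clone if r.clone is not None else "NA",
                    fmt_float(r.ccf) if r.ccf is not None else "NA",
                    r.classification if r.classification is not None else "NA",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# clinical summary


def assign_subtype(record: ClinicalRecord) -> str | None:
    """Hormone-receptor/HER2 legend: HR+ means ER+ or PR+.

    Missing HER2, or missing both receptor statuses, yields a missing
    subtype.
    """
    if record.er is None and record.pr is None:
        return None
    if record.her2 is None:
        return None
    hr_positive = record.er == "+" or record.pr == "+"
    if hr_positive:
        return "Luminal A-like" if record.her2 == "-" else "Luminal B-like"
    return "HER2-enriched" if record.her2 == "+" else "Triple negative"


def summarize_clinical(records: list[ClinicalRecord]) -> dict:
    """Cohort summary; missing values leave each denominator.

    Fractions are percentages of all patients (subtypes) or of graded
    patients (grade), rounded to one decimal.
    """
    if not records:
        raise ValueError("no clinical records")
    ages = [r.age for r in records]
    graded = [r.grade for r in records if r.grade is not None]
    months = [r.relapse_months for r in records if r.relapse_months is not None]
    subtype_counts: dict[str, int] = {}
    for r in records:
        label = assign_subtype(r) or "missing"
        subtype_counts[label] = subtype_counts.get(label, 0) + 1
    n = len(records)
    return {
        "n_patients": n,
        "median_age": float(np.median(ages)),
        "age_range": (min(ages), max(ages)),
        "subtype_fractions_pct": {
            k: round(100.0 * v / n, 1) for k, v in sorted(subtype_counts.items())
        },
        "grade2_fraction_pct": (
            round(100.0 * sum(g == 2 for g in graded) / len(graded), 1) if graded else None
        ),
        "n_graded": len(graded),
        "relapse_months_range": (min(months), max(months)) if months else None,
    }


# ---------------------------------------------------------------------------
# actionability


def flag_actionable(
    sample_id: str,
    lesion: str,
    alterations: list[dict],
    rules: pd.DataFrame,
    hrd_phenotype: bool,
    biallelic_brca_gene: str | None = None,
    known_genes: frozenset | None = None,
) -> list[ActionabilityRecord]:
    """One record per rule hit, plus one HRD record when the phenotype holds.

    ``alterations`` entries carry gene, kind (mutation | amplification),
    clone, ccf and classification (from the clone tree).  Rule rows naming a
    gene absent from ``known_genes`` (when provided) trigger a warning, never
    an error.
    """
    if known_genes is not None:
        for gene in sorted(set(rules["gene"]) - set(known_genes)):
            warnings.warn(f"actionability rule references unknown gene {gene!r}")
    rule_keys = set(zip(rules["gene"], rules["alteration"]))
    records = []
    for alt in alterations:
        if (alt["gene"], alt["kind"]) not in rule_keys:
            continue
        records.append(
            ActionabilityRecord(
                sample_id=sample_id,
                lesion=lesion,
                biomarker="OncoKB",
                alteration=f"{alt['gene']} {alt['kind']}",
                clone=alt.get("clone"),
                ccf=alt.get("ccf"),
                classification=alt.get("classification"),
            )
        )
    if hrd_phenotype:
        description = (
            f"Bi-allelic {biallelic_brca_gene}"
            if biallelic_brca_gene
            else "(HRD score >= 42)"
        )
        records.append(
            ActionabilityRecord(
                sample_id=sample_id,
                lesion=lesion,
                biomarker="HRD",
                alteration=description,
                clone=None,
                ccf=None,
                classification=None,
            )
        )
    return records


def cohort_actionability_summary(
    records: list[ActionabilityRecord], n_lesions: int
) -> float:
    """Percentage of lesions carrying at least one record."""
    if n_lesions <= 0:
        raise ValueError("n_lesions must be positive")
    hit = {(r.sample_id, r.lesion) for r in records}
    return 100.0 * len(hit) / n_lesions


# ---------------------------------------------------------------------------
# paired statistics


def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = stats.rankdata(np.abs(diffs))
    return float(ranks[diffs > 0].sum()), ranks


def paired_comparison(
    primary, relapse, alternative: str = "greater"
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on relapse - primary differences.

    ``alternative='greater'`` asks whether relapse values exceed primary.
    Zero differences are dropped; an all-zero difference vector is an error.
    For n <= 15 the null distribution is enumerated exactly over all sign
    assignments (ties in |d| handled by average ranks); larger n falls back
    to the normal approximation.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    primary = np.asarray(primary, dtype=float)
    relapse = np.asarray(relapse, dtype=float)
    if primary.shape != relapse.shape:
        raise ValueError("paired vectors must have equal length")
    if len(primary) < 3:
        raise ValueError("paired comparison requires at least 3 pairs")
    diffs = relapse - primary
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        raise ValueError("all paired differences are zero; p undefined")
    if alternative == "less":
        diffs = -diffs
    n = len(diffs)
    w_obs, ranks = _signed_rank_statistic(diffs)
    if n <= 15:
        hits = 0
        for signs in itertools.product((False, True), repeat=n):
            w = sum(r for r, positive in zip(ranks, signs) if positive)
            if w >= w_obs - 1e-12:
                hits += 1
        p = hits / 2.0**n
    else:
        _, p = stats.wilcoxon(diffs, alternative="greater", method="approx")
    return w_obs, float(p)


def correlate(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value."""
    result = stats.pearsonr(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return float(result.statistic), float(result.pvalue)
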