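"""Bi-allelic alteration classification for homologous-recombination genes.

A gene's allelic status per lesion is derived from six event kinds: germline
LOF, germline VUS, somatic LOF, somatic VUS, somatic LOH of the wild-type
allele, and somatic deep deletion.  Bi-allelic LOF outranks bi-allelic VUS,
which outranks mono-allelic, which outranks no alteration; the ``mechanism``
field records the first enumerated combination that fired.

Conventions chosen where the published rules are silent:

* two somatic LOF hits count as bi-allelic without phasing evidence;
* a compound germline LOF pair stays mono-allelic (no rule covers it);
* germline VUS alone never contributes;
* somatic LOH with no mutation partner counts as mono-allelic loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from .io_formats import FormatError

__all__ = [
    "GeneEvents",
    "HRVariantSet",
    "GeneAllelicStatus",
    "BIALLELIC_LOF",
    "BIALLELIC_VUS",
    "MONOALLELIC",
    "NONE",
    "default_hr_genes",
    "load_hr_genes",
    "classify_gene",
    "classify_lesion",
    "upgrade_putative_lof",
    "shared_events",
    "variant_set_from_table",
]

BIALLELIC_LOF = "biallelic_lof"
BIALLELIC_VUS = "biallelic_vus"
MONOALLELIC = "monoallelic"
NONE = "none"

#: mechanism labels, in priority order of evaluation
LOF_MECHANISMS = {
    "lof_1": "germline LOF + somatic LOH",
    "lof_2": "germline LOF + somatic LOF",
    "lof_3": "somatic LOF + somatic LOH",
    "lof_4": "two somatic LOF",
    "lof_5": "somatic deep deletion",
}
VUS_MECHANISMS = {
    "vus_1": "germline LOF + somatic VUS",
    "vus_2": "somatic LOF + somatic VUS",
    "vus_3": "somatic VUS + somatic LOH",
}


@dataclass(frozen=True)
class GeneEvents:
    """Event tallies for one gene in one lesion."""

    germline_lof: int = 0
    germline_vus: int = 0
    somatic_lof: int = 0
    somatic_vus: int = 0
    somatic_loh: bool = False
    deep_deletion: bool = False


@dataclass
class HRVariantSet:
    """Per-gene HR event tallies for one lesion of one patient."""

    patient_id: str
    lesion: str
    genes: dict = field(default_factory=dict)  # gene -> GeneEvents
    hr_gene_list: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.hr_gene_list:
            off_list = set(self.genes) - set(self.hr_gene_list)
            if off_list:
                raise ValueError(
                    f"{self.patient_id}/{self.lesion}: gene(s) not on the HR list: "
                    f"{sorted(off_list)}"
                )


@dataclass(frozen=True)
class GeneAllelicStatus:
    gene: str
    status: str
    mechanism: str | None
    germline_involved: bool
    putative_lof: bool = False


def default_hr_genes() -> frozenset:
    with resources.as_file(resources.files("relapse_evo.data") / "hr_genes.txt") as p:
        return load_hr_genes(p)


def load_hr_genes(path: str | Path) -> frozenset:
    genes = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(genes) != len(set(genes)):
        raise FormatError(f"{path}: duplicate gene symbols in HR list")
    return frozenset(genes)


def classify_gene(variants: HRVariantSet, gene: str) -> GeneAllelicStatus:
    """Resolve one gene to its highest-priority allelic status.

    Deterministic and independent of event-list order; genes off the
    configured HR list are rejected.
    """
    if variants.hr_gene_list and gene not in variants.hr_gene_list:
        raise ValueError(f"gene {gene!r} is not on the configured HR gene list")
    ev = variants.genes.get(gene, GeneEvents())

    lof_rules = [
        ("lof_1", ev.germline_lof >= 1 and ev.somatic_loh, True),
        ("lof_2", ev.germline_lof >= 1 and ev.somatic_lof >= 1, True),
        ("lof_3", ev.somatic_lof >= 1 and ev.somatic_loh, False),
        ("lof_4", ev.somatic_lof >= 2, False),
        ("lof_5", ev.deep_deletion, False),
    ]
    for mechanism, fired, germline in lof_rules:
        if fired:
            return GeneAllelicStatus(gene, BIALLELIC_LOF, mechanism, germline)

    vus_rules = [
        ("vus_1", ev.germline_lof >= 1 and ev.somatic_vus >= 1, True),
        ("vus_2", ev.somatic_lof >= 1 and ev.somatic_vus >= 1, False),
        ("vus_3", ev.somatic_vus >= 1 and ev.somatic_loh, False),
    ]
    for mechanism, fired, germline in vus_rules:
        if fired:
            return GeneAllelicStatus(gene, BIALLELIC_VUS, mechanism, germline)

    if ev.germline_lof >= 1 or ev.somatic_lof >= 1 or ev.somatic_vus >= 1 or ev.somatic_loh:
        return GeneAllelicStatus(gene, MONOALLELIC, None, ev.germline_lof >= 1)
    return GeneAllelicStatus(gene, NONE, None, False)


def classify_lesion(variants: HRVariantSet) -> dict:
    """Classify every gene with at least one event in the lesion."""
    return {gene: classify_gene(variants, gene) for gene in sorted(variants.genes)}


def upgrade_putative_lof(status_map: dict, hrd_phenotype: bool) -> dict:
    """Annotate bi-allelic VUS genes as putative LOF.

    Fires only when the lesion is HR-deficient and no gene in the map already
    carries a bi-allelic LOF alteration.
    """
    has_lof = any(s.status == BIALLELIC_LOF for s in status_map.values())
    if not hrd_phenotype or has_lof:
        return dict(status_map)
    return {
        gene: replace(s, putative_lof=True) if s.status == BIALLELIC_VUS else s
        for gene, s in status_map.items()
    }


def _is_biallelic(status: GeneAllelicStatus) -> bool:
    return status.status == BIALLELIC_LOF or (
        status.status == BIALLELIC_VUS and status.putative_lof
    )


def shared_events(primary_map: dict, relapse_map: dict) -> dict:
    """Per-gene flags: bi-allelic (LOF or upgraded VUS) in both lesions."""
    genes = set(primary_map) | set(relapse_map)
    return {
        gene: (
            gene in primary_map
            and gene in relapse_map
            and _is_biallelic(primary_map[gene])
            and _is_biallelic(relapse_map[gene])
        )
        for gene in sorted(genes)
    }


def variant_set_from_table(
    df: pd.DataFrame,
    patient_id: str,
    lesion: str,
    hr_gene_list: frozenset | None = None,
) -> HRVariantSet:
    """Build an :class:`HRVariantSet` from a long-format HR variant table.

    For lesion-level classification, germline events recorded for the patient
    apply to both lesions; the table is expected to repeat them per lesion
    (as the bundled simulator does).
    """
    sub = df[(df["patient_id"] == patient_id) & (df["lesion"] == lesion)]
    tallies: dict[str, dict] = {}
    for row in sub.itertuples(index=False):
        t = tallies.setdefault(
            row.gene,
            {
                "germline_lof": 0,
                "germline_vus": 0,
                "somatic_lof": 0,
                "somatic_vus": 0,
                "somatic_loh": False,
                "deep_deletion": False,
            },
        )
        if row.event in ("somatic_loh", "deep_deletion"):
            t[row.event] = True
        else:
            t[row.event] += 1
    return HRVariantSet(
        patient_id=patient_id,
        lesion=lesion,
        genes={g: GeneEvents(**t) for g, t in tallies.items()},
        hr_gene_list=hr_gene_list or frozenset(),
    )
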