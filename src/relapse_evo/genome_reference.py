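"""Genome coordinate model and shared analysis constants.

All scorers consume chromosome coordinates exclusively through this module so
that the whole pipeline shares one convention: coordinates are 1-based, closed
intervals ``[start, end]`` (SEG-file style), and segment length is
``end - start + 1``.  Only autosomes enter scar, instability, and doubling
computations; sex chromosomes are accepted on input and excluded at scoring
time.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ChromosomeSpec",
    "AnalysisConstants",
    "DEFAULT_CONSTANTS",
    "load_assembly",
    "default_assembly",
    "assembly_index",
    "load_constants",
]


class AssemblyError(ValueError):
    """Raised for malformed assembly tables."""


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: length, centromere interval, autosome flag."""

    name: str
    length_bp: int
    centromere_start_bp: int
    centromere_end_bp: int
    is_autosome: bool

    def __post_init__(self) -> None:
        if not (0 < self.centromere_start_bp < self.centromere_end_bp < self.length_bp):
            raise AssemblyError(
                f"chromosome {self.name!r}: centromere "
                f"[{self.centromere_start_bp}, {self.centromere_end_bp}] must lie "
                f"strictly inside (0, {self.length_bp})"
            )


@dataclass(frozen=True)
class AnalysisConstants:
    """Fixed thresholds shared by every analysis stage.

    hrd_loh_min_bp
        minimum span of a loss-of-heterozygosity run to count toward the
        LOH scar score (run must not cover the whole chromosome).
    lst_min_segment_bp / lst_max_gap_bp
        minimum span of each flanking region, and the maximum inter-region
        distance, for a large-scale state transition breakpoint.  The gap
        bound doubles as the segment-merging / run-continuation tolerance.
    hrd_phenotype_threshold
        combined scar score at or above which a lesion is called
        HR-deficient.
    seem_dominant_ccf / minor_surviving_ccf
        cancer-cell-fraction cut-offs for the selective-expansion and
        minor-survivor evolution rules.
    cosine_match_threshold
        minimum cosine similarity for a de novo signature to be reported as
        matching a reference catalog entry.
    wgd_genome_fraction
        fraction of the autosomal genome with major copy number >= 2 that
        must be *exceeded* for a whole-genome-doubling call.
    """

    hrd_loh_min_bp: int = 15_000_000
    lst_min_segment_bp: int = 10_000_000
    lst_max_gap_bp: int = 3_000_000
    hrd_phenotype_threshold: int = 42
    seem_dominant_ccf: float = 0.45
    minor_surviving_ccf: float = 0.15
    cosine_match_threshold: float = 0.70
    wgd_genome_fraction: float = 0.50
    surviving_min_ccf: float = 0.01

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value <= 0:
                raise ValueError(f"constant {f.name} must be strictly positive, got {value}")
        for name in ("seem_dominant_ccf", "minor_surviving_ccf", "surviving_min_ccf"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValueError(f"constant {name} must be in (0, 1), got {value}")


DEFAULT_CONSTANTS = AnalysisConstants()

_ASSEMBLY_COLUMNS = ("chrom", "length", "cen_start", "cen_end", "is_autosome")
_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no"}


def _parse_bool(token: str, where: str) -> bool:
    low = token.strip().lower()
    if low in _TRUTHY:
        return True
    if low in _FALSY:
        return False
    raise AssemblyError(f"{where}: cannot interpret {token!r} as a boolean")


def load_assembly(path: str | Path) -> list[ChromosomeSpec]:
    """Parse a TSV assembly table into validated :class:`ChromosomeSpec` records.

    The table must carry the header ``chrom length cen_start cen_end
    is_autosome``; rows failing any invariant raise :class:`AssemblyError`
    naming the offending row.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise AssemblyError(f"{path}: empty assembly table")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != _ASSEMBLY_COLUMNS:
        raise AssemblyError(
            f"{path}: expected header {list(_ASSEMBLY_COLUMNS)}, got {list(header)}"
        )
    specs: list[ChromosomeSpec] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(_ASSEMBLY_COLUMNS):
            raise AssemblyError(f"{path}:{lineno}: expected {len(_ASSEMBLY_COLUMNS)} columns")
        name = parts[0].strip()
        if name in seen:
            raise AssemblyError(f"{path}:{lineno}: duplicate chromosome {name!r}")
        seen.add(name)
        try:
            length = int(parts[1])
            cen_start = int(parts[2])
            cen_end = int(parts[3])
        except ValueError as exc:
            raise AssemblyError(f"{path}:{lineno}: non-integer coordinate ({exc})") from None
        try:
            spec = ChromosomeSpec(
                name=name,
                length_bp=length,
                centromere_start_bp=cen_start,
                centromere_end_bp=cen_end,
                is_autosome=_parse_bool(parts[4], f"{path}:{lineno}"),
            )
        except AssemblyError as exc:
            raise AssemblyError(f"{path}:{lineno}: {exc}") from None
        specs.append(spec)
    if not any(s.is_autosome for s in specs):
        raise AssemblyError(f"{path}: assembly contains no autosomes")
    return specs


def default_assembly() -> list[ChromosomeSpec]:
    """The bundled hg19 autosome + X table."""
    with resources.as_file(
        resources.files("relapse_evo.data") / "hg19_assembly.tsv"
    ) as p:
        return load_assembly(p)


def assembly_index(specs: list[ChromosomeSpec]) -> Mapping[str, ChromosomeSpec]:
    return {s.name: s for s in specs}


def load_constants(path: str | Path | None = None, **overrides) -> AnalysisConstants:
    """Build :class:`AnalysisConstants`, optionally overriding from a YAML file.

    Keyword overrides win over file values; unknown keys raise ``ValueError``.
    """
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: constants file must be a mapping")
        values.update(loaded)
    values.update(overrides)
    known = {f.name for f in fields(AnalysisConstants)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown constant name(s): {sorted(unknown)}")
    return replace(DEFAULT_CONSTANTS, **values)
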