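"""Genomic scar scores from allele-specific copy-number profiles.

Implements, on merged segment profiles:

* ``hrd_loh`` -- loss-of-heterozygosity events longer than 15 Mb that do not
  cover the whole chromosome;
* ``tai`` -- allelic-imbalance runs reaching a telomere without crossing the
  centromere;
* ``lst`` -- breakpoints between >=10 Mb regions separated by <3 Mb, counted
  per chromosome arm;

plus the combined scar score (unweighted sum), the fraction of the autosomal
genome with non-diploid total copy number, the whole-genome-doubling flag, and
the HR-deficiency phenotype call.

Dialect notes (choices the one-line published definitions leave open):

* LOH means ``minor_cn == 0 and major_cn >= 1``; homozygous deletions
  (``major_cn == 0``) do not count.
* Allelic imbalance means ``major_cn != minor_cn``.
* A "run" is a maximal sequence of same-state segments in which consecutive
  segments are separated by an uncovered gap smaller than ``lst_max_gap_bp``;
  larger gaps break runs.
* "Whole chromosome" means the run spans the physical chromosome, base 1 to
  its full length; telomere anchoring for the imbalance score instead uses
  the chromosome's first/last covered base.
* LST is computed arm-wise: segments are split at the centromere first.
* Uncovered gaps contribute to no score and are excluded from the CIN/WGD
  denominators.
* Only autosomes are scored; ``cell_frac`` never weights a score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .genome_reference import AnalysisConstants, ChromosomeSpec, DEFAULT_CONSTANTS

__all__ = [
    "Segment",
    "SegmentProfile",
    "ScarResult",
    "ProfileError",
    "merge_segments",
    "hrd_loh",
    "tai",
    "lst",
    "hrd_score",
    "cin_fraction",
    "detect_wgd",
    "classify_hrd_phenotype",
    "score_profile",
]


class ProfileError(ValueError):
    """Raised for invalid segment profiles."""


@dataclass(frozen=True)
class Segment:
    """One allele-specific copy-number segment (1-based closed interval)."""

    chrom: str
    start_bp: int
    end_bp: int
    major_cn: int
    minor_cn: int
    cell_frac: float = 1.0

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ProfileError(f"segment {self}: end < start")
        if self.minor_cn < 0 or self.major_cn < 0:
            raise ProfileError(f"segment {self}: negative copy number")
        if self.major_cn < self.minor_cn:
            raise ProfileError(f"segment {self}: major_cn < minor_cn")
        if not (0.0 < self.cell_frac <= 1.0):
            raise ProfileError(f"segment {self}: cell_frac must be in (0, 1]")

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def is_loh(self) -> bool:
        return self.minor_cn == 0 and self.major_cn >= 1

    @property
    def is_imbalanced(self) -> bool:
        return self.major_cn != self.minor_cn

    def allele_state(self) -> tuple[int, int]:
        return (self.major_cn, self.minor_cn)


@dataclass
class SegmentProfile:
    """A sample's segments plus purity/ploidy; sorted and non-overlapping."""

    sample_id: str
    segments: list[Segment]
    purity: float = 1.0
    ploidy: float = 2.0
    lesion: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ProfileError(f"{self.sample_id}: purity must be in (0, 1]")
        if self.ploidy <= 0:
            raise ProfileError(f"{self.sample_id}: ploidy must be positive")
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start_bp))
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and seg.chrom == prev.chrom and seg.start_bp <= prev.end_bp:
                raise ProfileError(
                    f"{self.sample_id}: overlapping segments on {seg.chrom} "
                    f"({prev.start_bp}-{prev.end_bp} and {seg.start_bp}-{seg.end_bp})"
                )
            prev = seg

    def by_chrom(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out


@dataclass(frozen=True)
class ScarResult:
    """Scar components and derived flags for one sample."""

    sample_id: str
    hrd_loh: int
    tai: int
    lst: int
    cin_fraction: float
    wgd: bool
    hrd_phenotype: bool
    lesion: str | None = None

    @property
    def hrd_score(self) -> int:
        return self.hrd_loh + self.tai + self.lst


def _check_chroms(profile: SegmentProfile, assembly: Mapping[str, ChromosomeSpec]) -> None:
    unknown = {s.chrom for s in profile.segments} - set(assembly)
    if unknown:
        raise ProfileError(f"{profile.sample_id}: unknown chromosome(s) {sorted(unknown)}")


def merge_segments(
    profile: SegmentProfile,
    constants: AnalysisConstants = DEFAULT_CONSTANTS,
) -> SegmentProfile:
    """Merge adjacent same-state segments separated by less than the gap bound.

    Idempotent; ``cell_frac`` of a merged segment is the span-weighted mean.
    """
    merged: list[Segment] = []
    for segs in profile.by_chrom().values():
        current = segs[0]
        for seg in segs[1:]:
            gap = seg.start_bp - current.end_bp - 1
            if (
                seg.allele_state() == current.allele_state()
                and gap < constants.lst_max_gap_bp
            ):
                total = current.span_bp + seg.span_bp
                frac = (
                    current.cell_frac * current.span_bp + seg.cell_frac * seg.span_bp
                ) / total
                current = replace(current, end_bp=seg.end_bp, cell_frac=frac)
            else:
                merged.append(current)
                current = seg
        merged.append(current)
    return SegmentProfile(
        sample_id=profile.sample_id,
        segments=merged,
        purity=profile.purity,
        ploidy=profile.ploidy,
        lesion=profile.lesion,
    )


def _runs(
    segments: Sequence[Segment],
    predicate,
    max_gap_bp: int,
) -> list[list[Segment]]:
    """Maximal runs of predicate-true segments with inter-segment gap < max_gap_bp."""
    runs: list[list[Segment]] = []
    current: list[Segment] = []
    for seg in segments:
        if not predicate(seg):
            if current:
                runs.append(current)
                current = []
            continue
        if current and seg.start_bp - current[-1].end_bp - 1 >= max_gap_bp:
            runs.append(current)
            current = []
        current.append(seg)
    if current:
        runs.append(current)
    return runs


def hrd_loh(
    profile: SegmentProfile,
    assembly: Mapping[str, ChromosomeSpec],
    constants: AnalysisConstants = DEFAULT_CONSTANTS,
) -> int:
    """Count LOH runs spanning more than ``hrd_loh_min_bp`` that do not cover
    the chromosome's covered extent (autosomes only)."""
    _check_chroms(profile, assembly)
    merged = merge_segments(profile, constants)
    count = 0
    for chrom, segs in merged.by_chrom().items():
        spec = assembly[chrom]
        if not spec.is_autosome:
            continue
        for run in _runs(segs, lambda s: s.is_loh, constants.lst_max_gap_bp):
            span = run[-1].end_bp - run[0].start_bp + 1
            whole = run[0].start_bp <= 1 and run[-1].end_bp >= spec.length_bp
            if span > constants.hrd_loh_min_bp and not whole:
                count += 1
    return count


def tai(
    profile: SegmentProfile,
    assembly: Mapping[str, ChromosomeSpec],
    constants: AnalysisConstants = DEFAULT_CONSTANTS,
) -> int:
    """Count allelic-imbalance runs anchored at a telomere that do not
    intersect the centromere (autosomes only)."""
    _check_chroms(profile, assembly)
    merged = merge_segments(profile, constants)
    count = 0
    for chrom, segs in merged.by_chrom().items():
        spec = assembly[chrom]
        if not spec.is_autosome:
            continue
        covered_start = segs[0].start_bp
        covered_end = segs[-1].end_bp
        for run in _runs(segs, lambda s: s.is_imbalanced, constants.lst_max_gap_bp):
            lo, hi = run[0].start_bp, run[-1].end_bp
            crosses_cen = lo <= spec.centromere_end_bp and hi >= spec.centromere_start_bp
            if crosses_cen:
                continue
            if lo == covered_start:
                count += 1
            if hi == covered_end:
                count += 1
    return count


def _split_at_centromere(
    segs: Iterable[Segment], spec: ChromosomeSpec
) -> tuple[list[Segment], list[Segment]]:
    """Split segments into p-arm and q-arm pieces, dropping centromeric bp."""
    p_arm: list[Segment] = []
    q_arm: list[Segment] = []
    cs, ce = spec.centromere_start_bp, spec.centromere_end_bp
    for seg in segs:
        if seg.end_bp < cs:
            p_arm.append(seg)
            continue
        if seg.start_bp > ce:
            q_arm.append(seg)
            continue
        if seg.start_bp < cs:
            p_arm.append(replace(seg, end_bp=cs - 1))
        if seg.end_bp > ce:
            q_arm.append(replace(seg, start_bp=ce + 1))
    return p_arm, q_arm


def lst(
    profile: SegmentProfile,
    assembly: Mapping[str, ChromosomeSpec],
    constants: AnalysisConstants = DEFAULT_CONSTANTS,
) -> int:
    """Count arm-wise breakpoints between two >= ``lst_min_segment_bp`` regions
    of different allele state separated by < ``lst_max_gap_bp`` (autosomes)."""
    _check_chroms(profile, assembly)
    merged = merge_segments(profile, constants)
    count = 0
    for chrom, segs in merged.by_chrom().items():
        spec = assembly[chrom]
        if not spec.is_autosome:
            continue
        for arm in _split_at_centromere(segs, spec):
            for left, right in zip(arm, arm[1:]):
                gap = right.start_bp - left.end_bp - 1
                if (
                    left.span_bp >= constants.lst_min_segment_bp
                    and right.span_bp >= constants.lst_min_segment_bp
                    and gap < constants.lst_max_gap_bp
                    and left.allele_state() != right.allele_state()
                ):
                    count += 1
    return count


def hrd_score(
    profile: SegmentProfile,
    assembly: Mapping[str, ChromosomeSpec],
    constants: AnalysisConstants = DEFAULT_CONSTANTS,
) -> int:
    """Unweighted sum of the three scar components."""
    return (
        hrd_loh(profile, assembly, constants)
        + tai(profile, assembly, constants)
        + lst(profile, assembly, constants)
    )


def _autosomal_bp(
    profile: SegmentProfile,
    assembly: Mapping[str, ChromosomeSpec],
    predicate,
) -> tuple[int, int]:
    hit = 0
    total = 0
    for seg in profile.segments:
        if not assembly[seg.chrom].is_autosome:
            continue
        total += seg.span_bp
        if predicate(seg):
            hit += seg.span_bp
    return hit, total


def cin_fraction(
    profile: SegmentProfile,
    assembly: Mapping[str, ChromosomeSpec],
    constants: AnalysisConstants = DEFAULT_CONSTANTS,
) -> float:
    """Fraction of covered autosomal bp whose total copy number differs from 2."""
    _check_chroms(profile, assembly)
    hit, total = _autosomal_bp(profile, assembly, lambda s: s.total_cn != 2)
    return hit / total if total else 0.0


def detect_wgd(
    profile: SegmentProfile,
    assembly: Mapping[str, ChromosomeSpec],
    constants: AnalysisConstants = DEFAULT_CONSTANTS,
) -> bool:
    """True iff strictly more than ``wgd_genome_fraction`` of covered autosomal
    bp has major copy number >= 2."""
    _check_chroms(profile, assembly)
    hit, total = _autosomal_bp(profile, assembly, lambda s: s.major_cn >= 2)
    if total == 0:
        return False
    return hit / total > constants.wgd_genome_fraction


def classify_hrd_phenotype(
    loh: int,
    tai_count: int,
    lst_count: int,
    biallelic_brca: bool,
    constants: AnalysisConstants = DEFAULT_CONSTANTS,
) -> bool:
    """HR-deficient iff scar sum >= threshold or a bi-allelic BRCA1/2 event."""
    return (loh + tai_count + lst_count) >= constants.hrd_phenotype_threshold or bool(
        biallelic_brca
    )


def score_profile(
    profile: SegmentProfile,
    assembly: Mapping[str, ChromosomeSpec],
    constants: AnalysisConstants = DEFAULT_CONSTANTS,
    biallelic_brca: bool = False,
) -> ScarResult:
    """Compute every scar component and derived flag for one sample."""
    loh = hrd_loh(profile, assembly, constants)
    t = tai(profile, assembly, constants)
    l = lst(profile, assembly, constants)
    return ScarResult(
        sample_id=profile.sample_id,
        hrd_loh=loh,
        tai=t,
        lst=l,
        cin_fraction=cin_fraction(profile, assembly, constants),
        wgd=detect_wgd(profile, assembly, constants),
        hrd_phenotype=classify_hrd_phenotype(loh, t, l, biallelic_brca, constants),
        lesion=profile.lesion,
    )
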