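"""Synthetic primary/relapse cohort generator with exact ground truth.

Every downstream stage is testable without external data: planted scar-event
counts are recovered exactly by the scorers, generated clone trees classify
back to their planted evolution model, and mutation catalogs are drawn from
known signature mixtures.

Scar-event planting layout (per chromosome arm, telomere to centromere):
the telomeric block is either a planted allelic-imbalance event or a neutral
baseline block; interior events follow, each isolated by an uncovered gap of
``EVENT_GAP_BP`` (> the run-continuation bound) so no planted event can merge
with, extend, or create breakpoints against its neighbours; the remainder
toward the centromere is filled with baseline.  Telomeric-imbalance events
never touch the centromere, and interior LOH events never reach a telomere or
span a whole chromosome, so the three definitions fire exactly once per
planted event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .genome_reference import ChromosomeSpec, default_assembly
from .io_formats import MutationRecord, TreeDocument, TreeNode
from .mutational_signatures import CONTEXTS_96
from .scar_genomics import Segment, SegmentProfile

__all__ = [
    "SimulationParams",
    "PatientTruth",
    "CohortBundle",
    "CapacityError",
    "fixture_signatures",
    "simulate_profile",
    "simulate_tree",
    "simulate_mutations",
    "simulate_cohort",
    "write_cohort",
    "HR_SCENARIOS",
]

MODELS = ("DNSEM", "HRDEM", "SEEM")

EVENT_GAP_BP = 3_500_000
BASELINE_LEAD_BP = 5_000_000


class CapacityError(ValueError):
    """Requested events do not fit on the assembly."""


# ---------------------------------------------------------------------------
# parameters and ground truth


def _default_scar_ranges() -> dict:
    # (low, high] exclusive per numpy integers; per scar component
    return {
        "DNSEM": {"primary": (0, 3), "relapse": (2, 6)},
        "HRDEM": {"primary": (0, 3), "relapse": (14, 17)},
        "SEEM": {"primary": (0, 3), "relapse": (2, 6)},
    }


def _default_signature_weights() -> dict:
    # (age-like, APOBEC-like, flat) mixing proportions per model per lesion
    return {
        "DNSEM": {"primary": (0.65, 0.15, 0.20), "relapse": (0.30, 0.35, 0.35)},
        "HRDEM": {"primary": (0.60, 0.15, 0.25), "relapse": (0.25, 0.50, 0.25)},
        "SEEM": {"primary": (0.20, 0.55, 0.25), "relapse": (0.10, 0.70, 0.20)},
    }


@dataclass
class SimulationParams:
    """Cohort-level knobs; a fixed seed fixes every emitted byte."""

    n_patients: int = 10
    model_mix: tuple = (0.4, 0.3, 0.3)  # DNSEM, HRDEM, SEEM
    scar_ranges: dict = field(default_factory=_default_scar_ranges)
    signature_weights: dict = field(default_factory=_default_signature_weights)
    burden_range: tuple = (800, 1500)
    relapse_burden_factor: tuple = (1.3, 1.8)
    wgd_probability: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if len(self.model_mix) != 3 or abs(sum(self.model_mix) - 1.0) > 1e-9:
            raise ValueError("model_mix must be three probabilities summing to 1")
        if any(m < 0 for m in self.model_mix):
            raise ValueError("model_mix entries must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "model_mix" in data:
            data["model_mix"] = tuple(data["model_mix"])
        if "burden_range" in data:
            data["burden_range"] = tuple(data["burden_range"])
        if "relapse_burden_factor" in data:
            data["relapse_burden_factor"] = tuple(data["relapse_burden_factor"])
        return cls(**data)


@dataclass
class PatientTruth:
    """Ground-truth ledger for one simulated patient."""

    patient_id: str
    model: str
    scar_counts: dict  # lesion -> (n_loh, n_tai, n_lst)
    wgd: dict  # lesion -> bool
    signature_weights: dict  # lesion -> (age, apobec, flat)
    burdens: dict  # lesion -> int
    hr_scenarios: list  # scenario dicts (see HR_SCENARIOS)
    biallelic_brca: dict  # lesion -> bool

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "model": self.model,
            "scar_counts": {k: list(v) for k, v in self.scar_counts.items()},
            "wgd": self.wgd,
            "signature_weights": {
                k: [round(float(x), 6) for x in v]
                for k, v in self.signature_weights.items()
            },
            "burdens": self.burdens,
            "hr_scenarios": self.hr_scenarios,
            "biallelic_brca": self.biallelic_brca,
        }


@dataclass
class CohortBundle:
    params: SimulationParams
    profiles: dict  # sample id -> SegmentProfile
    trees: dict  # patient id -> TreeDocument
    mutations: list  # MutationRecord
    hr_variants: pd.DataFrame
    truth: list  # PatientTruth


def fixture_signatures() -> pd.DataFrame:
    """The bundled 3-signature reference catalog (age-like, APOBEC-like, flat)."""
    with resources.as_file(
        resources.files("relapse_evo.data") / "signatures_fixture.tsv"
    ) as p:
        return io_formats.read_signature_catalog(p)


# ---------------------------------------------------------------------------
# allele-specific copy-number profiles


def _block_span(block: tuple) -> int:
    if block[0] == "lst":
        return block[1] + block[2]
    return block[0]


@dataclass
class _Arm:
    chrom: str
    start: int
    end: int
    is_p: bool
    blocks: list = field(default_factory=list)  # (span, major, minor), telomere->cen
    has_tai: bool = False

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def used(self) -> int:
        if not self.blocks:
            return 0
        spans = sum(_block_span(b) for b in self.blocks)
        return spans + EVENT_GAP_BP * (len(self.blocks) - 1)

    def fits(self, extra_spans: list) -> bool:
        n_new = len(extra_spans)
        return (
            self.used()
            + sum(extra_spans)
            + EVENT_GAP_BP * (n_new if self.blocks else n_new - 1)
            <= self.size
        )


def _cn(base_major: int, base_minor: int, wgd: bool) -> tuple[int, int]:
    off = 1 if wgd else 0
    return (base_major + off, base_minor + off)


def simulate_profile(
    assembly: list[ChromosomeSpec],
    n_loh: int,
    n_tai: int,
    n_lst: int,
    wgd: bool = False,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
    lesion: str | None = None,
) -> SegmentProfile:
    """Emit a profile whose scar scores are exactly ``(n_loh, n_tai, n_lst)``.

    With ``wgd`` set, the baseline is tetraploid so well over half of the
    covered autosomal genome has major copy number >= 2.
    """
    if min(n_loh, n_tai, n_lst) < 0:
        raise ValueError("event counts must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    autosomes = [s for s in assembly if s.is_autosome]
    arms: list[_Arm] = []
    for spec in autosomes:
        arms.append(_Arm(spec.name, 1, spec.centromere_start_bp - 1, True))
        arms.append(_Arm(spec.name, spec.centromere_end_bp + 1, spec.length_bp, False))

    base = _cn(1, 1, wgd)
    loh_cn = (2 if wgd else 1, 0)  # minor stays 0: copy-number LOH either way
    imb_cn = _cn(2, 1, wgd)

    # telomeric-imbalance events claim the telomeric slot of an arm
    for _ in range(n_tai):
        span = int(rng.integers(8, 15)) * 1_000_000
        candidates = [a for a in arms if not a.has_tai and not a.blocks and a.size >= span]
        if not candidates:
            raise CapacityError("assembly too small for requested telomeric events")
        arm = candidates[int(rng.integers(len(candidates)))]
        arm.blocks.append((span, *imb_cn))
        arm.has_tai = True

    # arms without a telomeric event start with a neutral lead block
    for arm in arms:
        if not arm.has_tai:
            if arm.size < BASELINE_LEAD_BP:
                continue  # tiny arm: leave uncovered
            arm.blocks.insert(0, (BASELINE_LEAD_BP, *base))

    interior = ["loh"] * n_loh + ["lst"] * n_lst
    rng.shuffle(interior)
    for kind in interior:
        if kind == "loh":
            spans = [int(rng.integers(16, 21)) * 1_000_000]
            blocks = [(spans[0], *loh_cn)]
        else:
            s1 = int(rng.integers(10, 14)) * 1_000_000
            s2 = int(rng.integers(10, 14)) * 1_000_000
            spans = [s1 + s2]
            blocks = [("lst", s1, s2)]
        candidates = [a for a in arms if a.blocks and a.fits(spans)]
        if not candidates:
            raise CapacityError(f"assembly too small for requested {kind} events")
        arm = candidates[int(rng.integers(len(candidates)))]
        arm.blocks.extend(blocks)

    # fill the centromere-proximal remainder with baseline where it fits
    for arm in arms:
        if not arm.blocks:
            continue
        free = arm.size - arm.used() - EVENT_GAP_BP
        if free >= 1_000_000:
            arm.blocks.append((free, *base))

    segments: list[Segment] = []
    for arm in arms:
        pos = arm.start if arm.is_p else arm.end
        for block in arm.blocks:
            if block[0] == "lst":
                _, s1, s2 = block
                if arm.is_p:
                    segments.append(Segment(arm.chrom, pos, pos + s1 - 1, *base))
                    segments.append(Segment(arm.chrom, pos + s1, pos + s1 + s2 - 1, *imb_cn))
                    pos += s1 + s2 + EVENT_GAP_BP
                else:
                    segments.append(Segment(arm.chrom, pos - s2 + 1, pos, *imb_cn))
                    segments.append(Segment(arm.chrom, pos - s2 - s1 + 1, pos - s2, *base))
                    pos -= s1 + s2 + EVENT_GAP_BP
            else:
                span, major, minor = block
                if arm.is_p:
                    segments.append(Segment(arm.chrom, pos, pos + span - 1, major, minor))
                    pos += span + EVENT_GAP_BP
                else:
                    segments.append(Segment(arm.chrom, pos - span + 1, pos, major, minor))
                    pos -= span + EVENT_GAP_BP
    return SegmentProfile(sample_id=sample_id, segments=segments, lesion=lesion)


# ---------------------------------------------------------------------------
# clone trees


def _dirichlet_scaled(rng: np.random.Generator, k: int, total: float) -> list[float]:
    parts = rng.dirichlet(np.ones(k)) * total
    return [round(float(p), 4) for p in parts]


def simulate_tree(
    model: str,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    patient_id: str = "sim",
) -> TreeDocument:
    """Emit a clone tree realizing one evolution-model archetype.

    The emitted tree satisfies the corresponding classification rule by
    construction: no surviving subclone (DNSEM); one minor survivor with
    relapse CCF below 0.15 (HRDEM; the HR-deficiency flag comes from the scar
    profile, not the tree); one survivor expanding above 0.45 inclusive
    relapse CCF (SEEM).
    """
    if model not in MODELS:
        raise ValueError(f"unknown evolution model {model!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    nodes: dict[str, TreeNode] = {
        "0": TreeNode("0", None, {"primary": 1.0, "relapse": 1.0}),
        "1": TreeNode("1", "0", {"primary": 1.0, "relapse": 1.0}),
    }
    nid = 2

    def add(parent: str, primary: float, relapse: float) -> str:
        nonlocal nid
        node_id = str(nid)
        nodes[node_id] = TreeNode(
            node_id, parent, {"primary": round(primary, 4), "relapse": round(relapse, 4)}
        )
        nid += 1
        return node_id

    if model == "DNSEM":
        for ccf in _dirichlet_scaled(rng, int(rng.integers(1, 4)), rng.uniform(0.5, 0.9)):
            add("1", ccf, 0.0)
        r0 = rng.uniform(0.5, 0.8)
        rel = add("1", 0.0, r0)
        for ccf in _dirichlet_scaled(
            rng, int(rng.integers(1, 4)), r0 * rng.uniform(0.4, 0.8)
        ):
            add(rel, 0.0, ccf)
    elif model == "HRDEM":
        survivor_p = rng.uniform(0.25, 0.45)
        survivor_r = rng.uniform(0.03, 0.12)
        add("1", survivor_p, survivor_r)
        add("1", rng.uniform(0.15, min(0.3, 0.95 - survivor_p)), 0.0)
        r0 = rng.uniform(0.55, min(0.75, 0.98 - survivor_r))
        dom = add("1", 0.0, r0)
        for ccf in _dirichlet_scaled(
            rng, int(rng.integers(2, 4)), r0 * rng.uniform(0.5, 0.9)
        ):
            add(dom, 0.0, ccf)
    else:  # SEEM
        survivor_p = rng.uniform(0.25, 0.4)
        survivor_r = rng.uniform(0.55, 0.85)
        surv = add("1", survivor_p, survivor_r)
        for ccf in _dirichlet_scaled(
            rng, int(rng.integers(1, 3)), survivor_r * rng.uniform(0.3, 0.8)
        ):
            add(surv, 0.0, ccf)
        add("1", rng.uniform(0.2, min(0.4, 0.95 - survivor_p)), 0.0)
        extra = 1.0 - survivor_r
        if extra > 0.05:
            add("1", 0.0, rng.uniform(0.02, extra - 0.02))

    alterations = [
        {"id": f"{patient_id}_trunk_driver", "node": "1", "gene": "PIK3CA", "kind": "mutation"},
        {"id": f"{patient_id}_branch_driver", "node": "2", "gene": "ERBB2", "kind": "mutation"},
    ]
    return TreeDocument(
        patient_id=patient_id,
        samples=["primary", "relapse"],
        nodes=nodes,
        alterations=alterations,
    )


# ---------------------------------------------------------------------------
# mutation catalogs

_GENE_POOL = (
    "PIK3CA", "TP53", "GATA3", "CTCF", "ERBB2", "AKT1", "PTEN", "NF1",
    "NCOR1", "SPEN", "SF3B1", "CDH1", "MAP3K1", "KMT2C", "ARID1A", "RUNX1",
)


def _context_to_record(
    context: str,
    rng: np.random.Generator,
    sample_id: str,
    lesion: str,
    gene: str,
) -> MutationRecord:
    five, ref, alt, three = context[0], context[2], context[4], context[6]
    if rng.random() < 0.5:  # report on the purine strand to exercise collapsing
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        five, ref, alt, three = comp[three], comp[ref], comp[alt], comp[five]
    return MutationRecord(
        sample_id=sample_id,
        gene=gene,
        variant_class="missense",
        origin="somatic",
        ref=ref,
        alt=alt,
        five_prime=five,
        three_prime=three,
        lesion=lesion,
    )


def simulate_mutations(
    weights,
    burden: int,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
    lesion: str = "primary",
    catalog: pd.DataFrame | None = None,
) -> list[MutationRecord]:
    """Draw ``burden`` SNVs from a mixture of the fixture signature vectors."""
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("signature weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("signature weights must sum to 1")
    if burden < 0:
        raise ValueError("burden must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if catalog is None:
        catalog = fixture_signatures()
    if len(weights) != catalog.shape[1]:
        raise ValueError(
            f"{len(weights)} weights for a {catalog.shape[1]}-signature catalog"
        )
    mix = catalog.to_numpy() @ weights
    mix = mix / mix.sum()
    counts = rng.multinomial(burden, mix)
    records: list[MutationRecord] = []
    for context, count in zip(catalog.index, counts):
        for _ in range(int(count)):
            gene = _GENE_POOL[int(rng.integers(len(_GENE_POOL)))]
            records.append(_context_to_record(context, rng, sample_id, lesion, gene))
    return records


# ---------------------------------------------------------------------------
# HR variant scenarios

#: canonical event bundles covering every enumerated bi-allelic mechanism,
#: plus mono-allelic and progression (second hit at relapse) cases
HR_SCENARIOS = (
    {
        "name": "germline_lof_plus_loh",
        "gene": "BRCA2",
        "events": {"primary": ["germline_lof", "somatic_loh"], "relapse": ["germline_lof", "somatic_loh"]},
        "expected": {"primary": ("biallelic_lof", "lof_1"), "relapse": ("biallelic_lof", "lof_1")},
    },
    {
        "name": "germline_lof_plus_somatic_lof",
        "gene": "ATM",
        "events": {"primary": ["germline_lof", "somatic_lof"], "relapse": ["germline_lof", "somatic_lof"]},
        "expected": {"primary": ("biallelic_lof", "lof_2"), "relapse": ("biallelic_lof", "lof_2")},
    },
    {
        "name": "somatic_lof_plus_loh",
        "gene": "WRN",
        "events": {"primary": ["somatic_lof"], "relapse": ["somatic_lof", "somatic_loh"]},
        "expected": {"primary": ("monoallelic", None), "relapse": ("biallelic_lof", "lof_3")},
    },
    {
        "name": "double_somatic_lof",
        "gene": "BRCA1",
        "events": {"primary": [], "relapse": ["somatic_lof", "somatic_lof"]},
        "expected": {"primary": ("none", None), "relapse": ("biallelic_lof", "lof_4")},
    },
    {
        "name": "deep_deletion",
        "gene": "PALB2",
        "events": {"primary": [], "relapse": ["deep_deletion"]},
        "expected": {"primary": ("none", None), "relapse": ("biallelic_lof", "lof_5")},
    },
    {
        "name": "germline_lof_plus_vus",
        "gene": "FANCM",
        "events": {"primary": ["germline_lof"], "relapse": ["germline_lof", "somatic_vus"]},
        "expected": {"primary": ("monoallelic", None), "relapse": ("biallelic_vus", "vus_1")},
    },
    {
        "name": "somatic_lof_plus_vus",
        "gene": "FANCI",
        "events": {"primary": [], "relapse": ["somatic_lof", "somatic_vus"]},
        "expected": {"primary": ("none", None), "relapse": ("biallelic_vus", "vus_2")},
    },
    {
        "name": "somatic_vus_plus_loh",
        "gene": "MRE11",
        "events": {"primary": ["somatic_vus", "somatic_loh"], "relapse": ["somatic_vus", "somatic_loh"]},
        "expected": {"primary": ("biallelic_vus", "vus_3"), "relapse": ("biallelic_vus", "vus_3")},
    },
    {
        "name": "monoallelic_germline",
        "gene": "CHEK2",
        "events": {"primary": ["germline_lof"], "relapse": ["germline_lof"]},
        "expected": {"primary": ("monoallelic", None), "relapse": ("monoallelic", None)},
    },
    {
        "name": "second_hit_progression",
        "gene": "RAD51C",
        "events": {"primary": ["germline_lof"], "relapse": ["germline_lof", "somatic_loh"]},
        "expected": {"primary": ("monoallelic", None), "relapse": ("biallelic_lof", "lof_1")},
    },
)

_BRCA_GENES = {"BRCA1", "BRCA2"}


# ---------------------------------------------------------------------------
# full cohort


def simulate_cohort(params: SimulationParams) -> CohortBundle:
    """Generate the full cohort bundle deterministically from ``params.seed``.

    Each patient draws from its own RNG stream seeded by (master seed,
    patient index), so per-patient output is independent of cohort size.
    """
    assembly = default_assembly()
    catalog = fixture_signatures()
    master = np.random.default_rng(params.seed)
    model_draws = master.choice(3, size=params.n_patients, p=list(params.model_mix))

    profiles: dict[str, SegmentProfile] = {}
    trees: dict[str, TreeDocument] = {}
    mutations: list[MutationRecord] = []
    hr_rows: list[dict] = []
    truth: list[PatientTruth] = []

    for idx in range(params.n_patients):
        rng = np.random.default_rng([params.seed, idx])
        patient_id = f"SIM{idx + 1:03d}"
        model = MODELS[int(model_draws[idx])]

        scar_counts: dict[str, tuple] = {}
        wgd_flags: dict[str, bool] = {}
        weights: dict[str, tuple] = {}
        burdens: dict[str, int] = {}
        primary_burden = int(rng.integers(*params.burden_range))
        for lesion in ("primary", "relapse"):
            lo, hi = params.scar_ranges[model][lesion]
            counts = tuple(int(rng.integers(lo, hi)) for _ in range(3))
            wgd = bool(rng.random() < params.wgd_probability)
            sample = f"{patient_id}_{lesion}"
            profiles[sample] = simulate_profile(
                assembly, *counts, wgd=wgd, rng=rng, sample_id=sample, lesion=lesion
            )
            scar_counts[lesion] = counts
            wgd_flags[lesion] = wgd
            base = np.asarray(params.signature_weights[model][lesion], dtype=float)
            jitter = rng.uniform(-0.03, 0.03, size=3)
            w = np.clip(base + jitter, 0.01, None)
            w = w / w.sum()
            weights[lesion] = tuple(float(x) for x in w)
            if lesion == "primary":
                burden = primary_burden
            else:
                burden = int(primary_burden * rng.uniform(*params.relapse_burden_factor))
            burdens[lesion] = burden
            mutations.extend(
                simulate_mutations(
                    weights[lesion],
                    burden,
                    rng=rng,
                    sample_id=sample,
                    lesion=lesion,
                    catalog=catalog,
                )
            )

        trees[patient_id] = simulate_tree(model, rng=rng, patient_id=patient_id)

        # HRDEM patients get the BRCA2 second-hit scenario so the bi-allelic
        # route to the HR-deficient phenotype is exercised alongside the scar
        # route; other patients cycle through the remaining scenarios.
        if model == "HRDEM":
            chosen = [HR_SCENARIOS[0], HR_SCENARIOS[idx % (len(HR_SCENARIOS) - 1) + 1]]
        else:
            chosen = [HR_SCENARIOS[idx % (len(HR_SCENARIOS) - 1) + 1]]
        biallelic_brca = {"primary": False, "relapse": False}
        scenario_log = []
        for scenario in chosen:
            for lesion, events in scenario["events"].items():
                for event in events:
                    hr_rows.append(
                        {
                            "patient_id": patient_id,
                            "lesion": lesion,
                            "gene": scenario["gene"],
                            "event": event,
                        }
                    )
                status, _ = scenario["expected"][lesion]
                if scenario["gene"] in _BRCA_GENES and status == "biallelic_lof":
                    biallelic_brca[lesion] = True
            scenario_log.append(
                {
                    "name": scenario["name"],
                    "gene": scenario["gene"],
                    "expected": {k: list(v) for k, v in scenario["expected"].items()},
                }
            )

        truth.append(
            PatientTruth(
                patient_id=patient_id,
                model=model,
                scar_counts=scar_counts,
                wgd=wgd_flags,
                signature_weights=weights,
                burdens=burdens,
                hr_scenarios=scenario_log,
                biallelic_brca=biallelic_brca,
            )
        )

    hr_variants = pd.DataFrame(hr_rows, columns=["patient_id", "lesion", "gene", "event"])
    return CohortBundle(
        params=params,
        profiles=profiles,
        trees=trees,
        mutations=mutations,
        hr_variants=hr_variants,
        truth=truth,
    )


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> None:
    """Write every cohort artifact; byte-identical for identical params."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_segments(bundle.profiles, out / "segments.tsv")
    io_formats.write_mutations(bundle.mutations, out / "mutations.tsv")
    io_formats.write_hr_variants(bundle.hr_variants, out / "hr_variants.tsv")
    trees_dir = out / "trees"
    trees_dir.mkdir(exist_ok=True)
    for patient_id in sorted(bundle.trees):
        io_formats.write_tree(bundle.trees[patient_id], trees_dir / f"{patient_id}.json")
    ledger = [t.to_dict() for t in bundle.truth]
    (out / "truth.json").write_text(json.dumps(ledger, indent=1, sort_keys=True) + "\n")
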