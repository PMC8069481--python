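"""Readers and writers for every on-disk artifact the pipeline touches.

All writers emit byte-stable output for fixed inputs (sorted keys, floats at 6
significant digits) so golden-file tests are meaningful.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .scar_genomics import ProfileError, Segment, SegmentProfile

__all__ = [
    "FormatError",
    "MutationRecord",
    "TreeNode",
    "TreeDocument",
    "VARIANT_CLASSES",
    "LOF_CLASSES",
    "CCF_TOLERANCE",
    "read_segments",
    "write_segments",
    "read_tree",
    "write_tree",
    "read_mutations",
    "write_mutations",
    "read_signature_catalog",
    "read_rules",
    "read_hr_variants",
    "write_hr_variants",
    "fmt_float",
]

VARIANT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice", "start_stop", "silent", "other"}
)
#: variant classes with a clearly disruptive functional impact
LOF_CLASSES = frozenset({"nonsense", "frameshift", "splice", "start_stop"})

ORIGINS = frozenset({"germline", "somatic"})
LESIONS = frozenset({"primary", "relapse"})

#: slack allowed before a child CCF exceeding its parent's is rejected
#: (upstream tree inference is stochastic; hard equality rejects real trees)
CCF_TOLERANCE = 0.02

_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised for malformed input files."""


def fmt_float(x: float) -> str:
    """Canonical float rendering: 6 significant digits, no trailing cruft."""
    return format(float(x), ".6g")


# ---------------------------------------------------------------------------
# mutations


@dataclass(frozen=True)
class MutationRecord:
    """One somatic/germline SNV with its trinucleotide context.

    ``ref``/``alt`` are reference-strand bases; ``five_prime``/``three_prime``
    are the flanking reference bases.  Context collapsing to the pyrimidine
    strand happens downstream when the 96-type catalog is built.
    """

    sample_id: str
    gene: str
    variant_class: str
    origin: str
    ref: str
    alt: str
    five_prime: str
    three_prime: str
    lesion: str

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise FormatError(f"unknown variant_class {self.variant_class!r}")
        if self.origin not in ORIGINS:
            raise FormatError(f"unknown origin {self.origin!r}")
        if self.lesion not in LESIONS:
            raise FormatError(f"unknown lesion {self.lesion!r}")
        for base in (self.ref, self.alt, self.five_prime, self.three_prime):
            if base not in _BASES:
                raise FormatError(f"non-ACGT base {base!r}")
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref})")

    @property
    def is_lof(self) -> bool:
        return self.variant_class in LOF_CLASSES


_MUTATION_COLUMNS = [
    "sample_id",
    "gene",
    "variant_class",
    "origin",
    "ref",
    "alt",
    "five_prime",
    "three_prime",
    "lesion",
]


def read_mutations(path: str | Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(MutationRecord(**{c: getattr(row, c) for c in _MUTATION_COLUMNS}))
        except FormatError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from None
    return records


def write_mutations(records: list[MutationRecord], path: str | Path) -> None:
    lines = ["\t".join(_MUTATION_COLUMNS)]
    for r in records:
        lines.append("\t".join(getattr(r, c) for c in _MUTATION_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# segments

_SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "major_cn", "minor_cn", "cell_frac"]


def read_segments(path: str | Path) -> dict[str, SegmentProfile]:
    """Parse a SEG-like TSV into one profile per sample.

    Validation failures (overlap, major < minor, negative CN) report the
    offending row number.  Optional ``purity``, ``ploidy`` and ``lesion``
    columns are honored when present.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    per_sample: dict[str, list[Segment]] = {}
    meta: dict[str, dict] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            seg = Segment(
                chrom=str(row.chrom),
                start_bp=int(row.start),
                end_bp=int(row.end),
                major_cn=int(row.major_cn),
                minor_cn=int(row.minor_cn),
                cell_frac=float(row.cell_frac),
            )
        except (ProfileError, ValueError) as exc:
            raise FormatError(f"{path}:{i}: {exc}") from None
        sample = str(row.sample)
        per_sample.setdefault(sample, []).append(seg)
        m = meta.setdefault(sample, {})
        if hasattr(row, "purity"):
            m["purity"] = float(row.purity)
        if hasattr(row, "ploidy"):
            m["ploidy"] = float(row.ploidy)
        if hasattr(row, "lesion"):
            m["lesion"] = str(row.lesion)
    profiles: dict[str, SegmentProfile] = {}
    for sample, segs in per_sample.items():
        try:
            profiles[sample] = SegmentProfile(sample_id=sample, segments=segs, **meta[sample])
        except ProfileError as exc:
            raise FormatError(f"{path}: sample {sample}: {exc}") from None
    return profiles


def write_segments(profiles: dict[str, SegmentProfile], path: str | Path) -> None:
    columns = list(_SEGMENT_COLUMNS) + ["purity", "ploidy", "lesion"]
    lines = ["\t".join(columns)]
    for sample in sorted(profiles):
        prof = profiles[sample]
        for seg in prof.segments:
            lines.append(
                "\t".join(
                    [
                        sample,
                        seg.chrom,
                        str(seg.start_bp),
                        str(seg.end_bp),
                        str(seg.major_cn),
                        str(seg.minor_cn),
                        fmt_float(seg.cell_frac),
                        fmt_float(prof.purity),
                        fmt_float(prof.ploidy),
                        prof.lesion or "NA",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# clone trees


@dataclass(frozen=True)
class TreeNode:
    id: str
    parent: str | None
    ccf: dict  # sample label -> inclusive CCF


@dataclass
class TreeDocument:
    """A rooted clone tree with per-sample inclusive CCFs.

    The root is the normal clone; its unique child is the founder clone.
    A node's CCF includes its descendants, so every child's CCF must not
    exceed its parent's beyond :data:`CCF_TOLERANCE`.
    """

    patient_id: str
    samples: list[str]
    nodes: dict[str, TreeNode] = field(default_factory=dict)
    alterations: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise FormatError(
                f"tree {self.patient_id}: expected exactly one root, found {len(roots)}"
            )
        root = roots[0]
        children: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                if node.parent not in self.nodes:
                    raise FormatError(
                        f"tree {self.patient_id}: node {node.id} has unknown parent "
                        f"{node.parent}"
                    )
                children[node.parent].append(node.id)
        # reachability check catches cycles among non-root nodes
        seen: set[str] = set()
        stack = [root.id]
        while stack:
            nid = stack.pop()
            seen.add(nid)
            stack.extend(children[nid])
        if seen != set(self.nodes):
            raise FormatError(f"tree {self.patient_id}: cycle or disconnected nodes")
        if len(children[root.id]) != 1:
            raise FormatError(
                f"tree {self.patient_id}: root must have exactly one (founder) child"
            )
        for node in self.nodes.values():
            for sample in self.samples:
                ccf = node.ccf.get(sample)
                if ccf is None:
                    raise FormatError(
                        f"tree {self.patient_id}: node {node.id} lacks CCF for {sample}"
                    )
                if not (0.0 <= ccf <= 1.0):
                    raise FormatError(
                        f"tree {self.patient_id}: node {node.id} CCF {ccf} outside [0, 1]"
                    )
                if node.parent is not None:
                    parent_ccf = self.nodes[node.parent].ccf[sample]
                    if ccf > parent_ccf + CCF_TOLERANCE:
                        raise FormatError(
                            f"tree {self.patient_id}: node {node.id} CCF {ccf} exceeds "
                            f"parent CCF {parent_ccf} beyond tolerance in {sample}"
                        )
        for alt in self.alterations:
            if alt["node"] not in self.nodes:
                raise FormatError(
                    f"tree {self.patient_id}: alteration {alt.get('id')} assigned to "
                    f"unknown node {alt['node']}"
                )

    @property
    def root(self) -> TreeNode:
        return next(n for n in self.nodes.values() if n.parent is None)

    @property
    def founder(self) -> TreeNode:
        return next(n for n in self.nodes.values() if n.parent == self.root.id)

    def children_of(self, node_id: str) -> list[TreeNode]:
        return sorted(
            (n for n in self.nodes.values() if n.parent == node_id), key=lambda n: n.id
        )

    def descendants_of(self, node_id: str) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [node_id]
        while stack:
            for child in self.children_of(stack.pop()):
                out.append(child)
                stack.append(child.id)
        return out


def tree_to_dict(doc: TreeDocument) -> dict:
    return {
        "patient_id": doc.patient_id,
        "samples": list(doc.samples),
        "nodes": [
            {
                "id": node.id,
                "parent": node.parent,
                "ccf": {s: round(float(node.ccf[s]), 6) for s in doc.samples},
            }
            for node in sorted(doc.nodes.values(), key=lambda n: n.id)
        ],
        "alterations": sorted(doc.alterations, key=lambda a: str(a.get("id"))),
    }


def tree_from_dict(data: dict) -> TreeDocument:
    nodes = {}
    for nd in data["nodes"]:
        node = TreeNode(id=str(nd["id"]), parent=nd["parent"], ccf=dict(nd["ccf"]))
        if node.id in nodes:
            raise FormatError(f"duplicate node id {node.id}")
        nodes[node.id] = node
    return TreeDocument(
        patient_id=str(data["patient_id"]),
        samples=list(data["samples"]),
        nodes=nodes,
        alterations=list(data.get("alterations", [])),
    )


def read_tree(path: str | Path) -> TreeDocument:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from None
    try:
        return tree_from_dict(data)
    except (KeyError, FormatError) as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_tree(doc: TreeDocument, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(tree_to_dict(doc), indent=1, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------------------
# signature catalogs and rule tables


def read_signature_catalog(path: str | Path) -> "pd.DataFrame":
    """Parse a TSV of named 96-element probability vectors.

    Layout: a ``context`` column plus one column per signature.  Vectors are
    renormalized to sum exactly 1 when within 1e-6 of 1, else rejected.
    Returns a DataFrame indexed by context label, one column per signature.
    """
    df = pd.read_csv(path, sep="\t")
    if "context" not in df.columns:
        raise FormatError(f"{path}: missing 'context' column")
    df = df.set_index("context")
    if df.shape[1] == 0:
        raise FormatError(f"{path}: catalog contains no signatures")
    if df.shape[0] != 96:
        raise FormatError(f"{path}: expected 96 context rows, got {df.shape[0]}")
    for name in df.columns:
        vec = df[name].astype(float)
        if (vec < 0).any():
            raise FormatError(f"{path}: signature {name} has negative entries")
        total = float(vec.sum())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise FormatError(
                f"{path}: signature {name} sums to {total}, not within 1e-6 of 1"
            )
        df[name] = vec / total
    return df


def read_rules(path: str | Path) -> "pd.DataFrame":
    """Parse the local actionability rule table (gene, alteration kind, level)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene", "alteration", "level"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    bad = set(df["alteration"]) - {"mutation", "amplification"}
    if bad:
        raise FormatError(f"{path}: unknown alteration kind(s) {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# HR-gene variant tables

_HR_EVENT_TYPES = frozenset(
    {
        "germline_lof",
        "germline_vus",
        "somatic_lof",
        "somatic_vus",
        "somatic_loh",
        "deep_deletion",
    }
)
_HR_COLUMNS = ["patient_id", "lesion", "gene", "event"]


def read_hr_variants(path: str | Path) -> "pd.DataFrame":
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_HR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    bad = set(df["event"]) - _HR_EVENT_TYPES
    if bad:
        raise FormatError(f"{path}: unknown HR event type(s) {sorted(bad)}")
    bad_lesion = set(df["lesion"]) - LESIONS
    if bad_lesion:
        raise FormatError(f"{path}: unknown lesion label(s) {sorted(bad_lesion)}")
    return df


def write_hr_variants(df: "pd.DataFrame", path: str | Path) -> None:
    out = df[_HR_COLUMNS].sort_values(_HR_COLUMNS).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)
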