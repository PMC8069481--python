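"""Tree algebra on consumed clone trees.

Node CCFs are inclusive: a node's cancer cell fraction includes all of its
descendants.  The root is the normal clone and never carries alterations; the
founder clone is the root's unique child.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genome_reference import AnalysisConstants, DEFAULT_CONSTANTS
from .io_formats import TreeDocument

__all__ = [
    "CloneAbundance",
    "EvolutionCall",
    "DiversityRow",
    "DNSEM",
    "HRDEM",
    "SEEM",
    "UNCLASSIFIED",
    "clonal_abundance",
    "shannon_index",
    "gini_simpson",
    "label_trunk_branch",
    "surviving_subclones",
    "classify_evolution_model",
    "diversity_comparison",
]

DNSEM = "DNSEM"
HRDEM = "HRDEM"
SEEM = "SEEM"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class CloneAbundance:
    """Normalized per-clone abundances for one sample."""

    sample: str
    abundances: dict  # node id -> p_i (only clones with p_i > 0 retained)

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if self.abundances and not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"abundances sum to {total}, expected 1")
        if any(p <= 0 for p in self.abundances.values()):
            raise ValueError("retained abundances must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.abundances)

    @property
    def values(self) -> list[float]:
        return [self.abundances[k] for k in sorted(self.abundances)]


@dataclass(frozen=True)
class EvolutionCall:
    patient_id: str
    model: str
    surviving: tuple  # ((node_id, inclusive relapse CCF), ...)
    relapse_hrd: bool


@dataclass(frozen=True)
class DiversityRow:
    patient_id: str
    shannon_primary: float
    shannon_relapse: float
    simpson_primary: float
    simpson_relapse: float
    elevated: bool
    discordant: bool


def clonal_abundance(tree: TreeDocument, sample: str) -> CloneAbundance:
    """Abundance of each clone: its CCF minus the summed CCF of its children.

    The normal (root) clone is excluded; negative residuals (tolerated CCF
    noise) clamp to zero; the result is renormalized over clones with
    positive abundance.
    """
    if sample not in tree.samples:
        raise ValueError(f"sample {sample!r} not present in tree {tree.patient_id}")
    raw: dict[str, float] = {}
    for node in tree.nodes.values():
        if node.parent is None:
            continue
        child_total = sum(c.ccf[sample] for c in tree.children_of(node.id))
        raw[node.id] = max(0.0, node.ccf[sample] - child_total)
    total = sum(raw.values())
    if total <= 0:
        raise ValueError(
            f"tree {tree.patient_id}: all clone abundances are zero in {sample}"
        )
    return CloneAbundance(
        sample=sample, abundances={k: v / total for k, v in raw.items() if v > 0}
    )


def shannon_index(ab: CloneAbundance) -> float:
    """H = -sum(p_i ln p_i); zero-abundance clones contribute nothing."""
    return -sum(p * math.log(p) for p in ab.abundances.values() if p > 0)


def gini_simpson(ab: CloneAbundance) -> float:
    """D = 1 - sum(p_i^2)."""
    return 1.0 - sum(p * p for p in ab.abundances.values())


def label_trunk_branch(tree: TreeDocument, node_id: str) -> str:
    """Trunk for the founder clone, branch for any of its descendants."""
    if node_id not in tree.nodes:
        raise ValueError(f"tree {tree.patient_id}: unknown node {node_id}")
    if node_id == tree.root.id:
        raise ValueError(
            f"tree {tree.patient_id}: the normal (root) clone carries no alterations"
        )
    return "Trunk" if node_id == tree.founder.id else "Branch"


def surviving_subclones(
    tree: TreeDocument,
    primary: str = "primary",
    relapse: str = "relapse",
    constants: AnalysisConstants = DEFAULT_CONSTANTS,
) -> list[tuple]:
    """Subclones (root and founder excluded) detected in both lesions.

    Detection requires inclusive CCF above ``surviving_min_ccf`` in each
    lesion, absorbing upstream sampling noise.  Returns ``(node_id,
    inclusive relapse CCF)`` pairs sorted by node id.
    """
    eps = constants.surviving_min_ccf
    excluded = {tree.root.id, tree.founder.id}
    out = []
    for node in sorted(tree.nodes.values(), key=lambda n: n.id):
        if node.id in excluded:
            continue
        if node.ccf[primary] > eps and node.ccf[relapse] > eps:
            out.append((node.id, node.ccf[relapse]))
    return out


def classify_evolution_model(
    tree: TreeDocument,
    relapse_hrd: bool,
    primary: str = "primary",
    relapse: str = "relapse",
    constants: AnalysisConstants = DEFAULT_CONSTANTS,
) -> EvolutionCall:
    """Total, deterministic model call from surviving-subclone evidence.

    Rule order: a surviving subclone dominant at relapse (inclusive CCF above
    ``seem_dominant_ccf``) wins SEEM; otherwise a minor survivor (below
    ``minor_surviving_ccf``) in an HR-deficient relapse wins HRDEM; otherwise
    no survivor at all means DNSEM; anything else is ``unclassified``.
    """
    surviving = surviving_subclones(tree, primary, relapse, constants)
    model = UNCLASSIFIED
    if any(ccf > constants.seem_dominant_ccf for _, ccf in surviving):
        model = SEEM
    elif relapse_hrd and any(
        ccf < constants.minor_surviving_ccf for _, ccf in surviving
    ):
        model = HRDEM
    elif not surviving:
        model = DNSEM
    return EvolutionCall(
        patient_id=tree.patient_id,
        model=model,
        surviving=tuple(surviving),
        relapse_hrd=bool(relapse_hrd),
    )


def diversity_comparison(
    trees: dict,
    primary: str = "primary",
    relapse: str = "relapse",
) -> list[DiversityRow]:
    """Per-patient diversity indices and the elevated-diversification flag.

    ``elevated`` requires both indices to strictly increase from primary to
    relapse; discordant indices report not-elevated with the discordance flag
    set.
    """
    rows = []
    for patient_id in sorted(trees):
        tree = trees[patient_id]
        ab_p = clonal_abundance(tree, primary)
        ab_r = clonal_abundance(tree, relapse)
        h_p, h_r = shannon_index(ab_p), shannon_index(ab_r)
        d_p, d_r = gini_simpson(ab_p), gini_simpson(ab_r)
        up = (h_r > h_p, d_r > d_p)
        rows.append(
            DiversityRow(
                patient_id=patient_id,
                shannon_primary=h_p,
                shannon_relapse=h_r,
                simpson_primary=d_p,
                simpson_relapse=d_r,
                elevated=all(up),
                discordant=any(up) and not all(up),
            )
        )
    return rows
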