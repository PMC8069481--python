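"""96-context mutation catalogs, NMF signature extraction, catalog matching,
exposure summaries, and the signature-gene regression screen.

Context ordering is fixed: substitution classes C>A, C>G, C>T, T>A, T>C, T>G,
each expanded over 5' base then 3' base in A, C, G, T order, labelled like
``A[C>T]G``.  Records whose reference base is a purine are collapsed to the
pyrimidine strand (reverse complement of ref, alt, and both flanks) before
binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import NMF
from statsmodels.stats.multitest import multipletests

from .io_formats import MutationRecord

__all__ = [
    "SUBSTITUTIONS",
    "CONTEXTS_96",
    "MutationCatalog",
    "SignatureDecomposition",
    "CatalogMatch",
    "collapse_context",
    "build_catalog",
    "nmf_extract",
    "cosine_similarity",
    "match_catalog",
    "exposure_fractions",
    "group_exposure_fractions",
    "signature_gene_screen",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
CONTEXTS_96 = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in _BASES for three in _BASES
)
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class MutationCatalog:
    """Samples x 96 trinucleotide-context count matrix."""

    samples: list[str]
    counts: np.ndarray  # shape (n_samples, 96), non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), 96):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.samples)} samples x 96 contexts"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.samples, columns=list(CONTEXTS_96))


@dataclass
class SignatureDecomposition:
    """NMF factors: signatures sum to 1 per row, exposures absorb magnitude."""

    samples: list[str]
    signatures: np.ndarray  # (rank, 96), rows sum to 1
    exposures: np.ndarray  # (n_samples, rank), >= 0
    reconstruction_error: float
    rank: int
    seed: int


@dataclass(frozen=True)
class CatalogMatch:
    signature_index: int
    reference: str
    similarity: float
    matched: bool


def collapse_context(ref: str, alt: str, five_prime: str, three_prime: str) -> str:
    """Pyrimidine-strand context label for one substitution."""
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five_prime, three_prime = _COMPLEMENT[three_prime], _COMPLEMENT[five_prime]
    label = f"{five_prime}[{ref}>{alt}]{three_prime}"
    if label not in _CONTEXT_INDEX:
        raise ValueError(f"invalid substitution context {label!r}")
    return label


def build_catalog(mutations: list[MutationRecord]) -> MutationCatalog:
    """Bin SNV records into the fixed 96-context order, one row per sample.

    Every record contributes exactly one count, so per-sample totals equal the
    number of records for that sample.
    """
    samples = sorted({m.sample_id for m in mutations})
    index = {s: i for i, s in enumerate(samples)}
    counts = np.zeros((len(samples), 96), dtype=np.int64)
    for m in mutations:
        ctx = collapse_context(m.ref, m.alt, m.five_prime, m.three_prime)
        counts[index[m.sample_id], _CONTEXT_INDEX[ctx]] += 1
    return MutationCatalog(samples=samples, counts=counts)


def nmf_extract(
    catalog: MutationCatalog,
    rank: int,
    seed: int = 0,
    n_restarts: int = 30,
    max_iter: int = 2000,
) -> SignatureDecomposition:
    """De novo signature extraction: best of ``n_restarts`` KL-divergence
    multiplicative-update factorizations, deterministic under a fixed seed."""
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > min(len(catalog.samples), 96):
        raise ValueError(
            f"rank {rank} exceeds min(n_samples={len(catalog.samples)}, 96)"
        )
    x = catalog.counts.astype(float)
    if x.sum() == 0:
        raise ValueError("catalog has no mutations")
    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for rs in restart_seeds:
        model = NMF(
            n_components=rank,
            init="random",
            solver="mu",
            beta_loss="kullback-leibler",
            max_iter=max_iter,
            tol=1e-6,
            random_state=int(rs),
        )
        w = model.fit_transform(x)
        if best is None or model.reconstruction_err_ < best[0]:
            best = (model.reconstruction_err_, w, model.components_)
    err, w, h = best
    scale = h.sum(axis=1)
    scale[scale == 0] = 1.0
    signatures = h / scale[:, None]
    exposures = w * scale[None, :]
    return SignatureDecomposition(
        samples=list(catalog.samples),
        signatures=signatures,
        exposures=exposures,
        reconstruction_error=float(err),
        rank=rank,
        seed=seed,
    )


def cosine_similarity(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


def match_catalog(
    decomp: SignatureDecomposition,
    reference: pd.DataFrame,
    threshold: float = 0.70,
) -> list[CatalogMatch]:
    """Greedy per-signature best hit against a reference catalog.

    ``reference`` is a 96-row DataFrame (context-indexed) with one column per
    named signature; ties break by reference column order.
    """
    if reference.shape[1] == 0:
        raise ValueError("reference catalog is empty")
    ref = reference.reindex(list(CONTEXTS_96))
    if ref.isna().any().any():
        raise ValueError("reference catalog does not cover the 96 fixed contexts")
    matches = []
    for i, sig in enumerate(decomp.signatures):
        sims = [cosine_similarity(sig, ref[name].to_numpy()) for name in ref.columns]
        j = int(np.argmax(sims))
        matches.append(
            CatalogMatch(
                signature_index=i,
                reference=str(ref.columns[j]),
                similarity=sims[j],
                matched=sims[j] > threshold,
            )
        )
    return matches


def exposure_fractions(decomp: SignatureDecomposition) -> pd.DataFrame:
    """Per-sample signature proportions (rows sum to 1)."""
    totals = decomp.exposures.sum(axis=1)
    if (totals == 0).any():
        bad = [s for s, t in zip(decomp.samples, totals) if t == 0]
        raise ValueError(f"sample(s) with zero total exposure: {bad}")
    frac = decomp.exposures / totals[:, None]
    return pd.DataFrame(
        frac,
        index=decomp.samples,
        columns=[f"signature_{i + 1}" for i in range(decomp.rank)],
    )


def group_exposure_fractions(decomp: SignatureDecomposition, groups: dict) -> pd.DataFrame:
    """Exposure-weighted mean signature fractions per sample group.

    ``groups`` maps sample id -> group label.  Pooling is weighted by each
    sample's attributed mutation count, so a group fraction is the group's
    summed exposure share.
    """
    labels = sorted(set(groups.values()))
    rows = []
    for label in labels:
        idx = [i for i, s in enumerate(decomp.samples) if groups.get(s) == label]
        if not idx:
            continue
        pooled = decomp.exposures[idx].sum(axis=0)
        total = pooled.sum()
        if total == 0:
            raise ValueError(f"group {label!r} has zero total exposure")
        rows.append(pooled / total)
    return pd.DataFrame(
        rows, index=labels, columns=[f"signature_{i + 1}" for i in range(decomp.rank)]
    )


def signature_gene_screen(
    exposures: pd.DataFrame,
    gene_indicators: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """OLS slope and p for every (signature, gene) pair, with BH correction.

    ``exposures``: samples x signatures; ``gene_indicators``: samples x genes
    (0/1 mutation presence).  Pairs with a constant exposure or indicator
    vector are skipped and reported in the notice list.  Returns the result
    frame (signature, gene, slope, p_value, q_value, significant) and the
    skip notices; q-values are monotone in p by construction of the step-up.
    """
    if len(exposures) < 3:
        raise ValueError("signature-gene screen requires at least 3 samples")
    if not exposures.index.equals(gene_indicators.index):
        gene_indicators = gene_indicators.reindex(exposures.index)
        if gene_indicators.isna().any().any():
            raise ValueError("exposures and gene indicators cover different samples")
    rows = []
    skipped: list[str] = []
    for sig in exposures.columns:
        y = exposures[sig].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            skipped.append(f"{sig}: constant exposure vector, all pairs skipped")
            continue
        for gene in gene_indicators.columns:
            x = gene_indicators[gene].to_numpy(dtype=float)
            if np.allclose(x, x[0]):
                skipped.append(f"{sig}/{gene}: constant indicator vector")
                continue
            fit = stats.linregress(x, y)
            rows.append((sig, gene, fit.slope, fit.pvalue))
    result = pd.DataFrame(rows, columns=["signature", "gene", "slope", "p_value"])
    if len(result):
        reject, qvals, _, _ = multipletests(result["p_value"], alpha=alpha, method="fdr_bh")
        result["q_value"] = qvals
        result["significant"] = reject
    else:
        result["q_value"] = []
        result["significant"] = []
    return result, skipped
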