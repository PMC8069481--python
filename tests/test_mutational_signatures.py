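import numpy as np
import pandas as pd
import pytest

from relapse_evo.io_formats import MutationRecord
from relapse_evo.mutational_signatures import (
    CONTEXTS_96,
    MutationCatalog,
    build_catalog,
    collapse_context,
    cosine_similarity,
    exposure_fractions,
    group_exposure_fractions,
    match_catalog,
    nmf_extract,
    signature_gene_screen,
)
from relapse_evo.synthetic_cohort import fixture_signatures, simulate_mutations


class TestContexts:
    def test_96_unique_labels(self):
        assert len(CONTEXTS_96) == 96
        assert len(set(CONTEXTS_96)) == 96
        assert CONTEXTS_96[0] == "A[C>A]A"
        assert CONTEXTS_96[-1] == "T[T>G]T"

    def test_purine_reference_collapsed(self):
        # reference strand T[G>A]C reads G[C>T]A on the pyrimidine strand
        assert collapse_context("G", "A", "T", "C") == "G[C>T]A"

    def test_pyrimidine_reference_unchanged(self):
        assert collapse_context("C", "T", "A", "G") == "A[C>T]G"


def record(sample="s1", ref="C", alt="T", five="A", three="G"):
    return MutationRecord(sample, "TP53", "missense", "somatic", ref, alt, five, three, "primary")


class TestBuildCatalog:
    def test_empty_list(self):
        cat = build_catalog([])
        assert cat.counts.shape == (0, 96)

    def test_totals_match_record_counts(self):
        recs = [record() for _ in range(5)] + [record(sample="s2") for _ in range(3)]
        cat = build_catalog(recs)
        assert cat.samples == ["s1", "s2"]
        assert cat.counts.sum(axis=1).tolist() == [5, 3]

    def test_strand_collapse_involution(self):
        rng = np.random.default_rng(0)
        recs = simulate_mutations((0.3, 0.3, 0.4), 500, rng=rng)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        flipped = [
            MutationRecord(
                r.sample_id,
                r.gene,
                r.variant_class,
                r.origin,
                comp[r.ref],
                comp[r.alt],
                comp[r.three_prime],
                comp[r.five_prime],
                r.lesion,
            )
            for r in recs
        ]
        assert (build_catalog(recs).counts == build_catalog(flipped).counts).all()

    def test_age_weights_dominate_npcpg(self):
        recs = simulate_mutations((1.0, 0.0, 0.0), 5000, seed=2)
        cat = build_catalog(recs)
        npcpg = [i for i, c in enumerate(CONTEXTS_96) if c[2:5] == "C>T" and c[6] == "G"]
        assert cat.counts[0, npcpg].sum() / cat.counts.sum() > 0.6


class TestCosine:
    def test_identical(self):
        v = np.arange(1, 97, dtype=float)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_support(self):
        u = np.zeros(96)
        v = np.zeros(96)
        u[:48] = 1
        v[48:] = 1
        assert cosine_similarity(u, v) == 0.0

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            u, v = rng.random(96), rng.random(96)
            s = cosine_similarity(u, v)
            assert cosine_similarity(v, u) == pytest.approx(s)
            assert cosine_similarity(3.7 * u, 0.2 * v) == pytest.approx(s)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(96), np.ones(96))


def planted_catalog(rng, n_samples=8, burden=4000):
    sigs = fixture_signatures().to_numpy().T  # (3, 96)
    exposures = rng.dirichlet(np.ones(3), size=n_samples) * burden
    counts = rng.poisson(exposures @ sigs)
    return MutationCatalog([f"s{i}" for i in range(n_samples)], counts), sigs, exposures


class TestNmf:
    def test_noiseless_rank2_recovery(self):
        # pure samples make the factorization identifiable up to permutation
        rng = np.random.default_rng(3)
        sigs = fixture_signatures().to_numpy().T[:2]
        exposures = np.vstack(
            [rng.uniform(500, 3000, size=(6, 2)), [[4000.0, 0.0], [0.0, 4000.0]]]
        )
        counts = exposures @ sigs
        cat = MutationCatalog([f"s{i}" for i in range(8)], counts)
        decomp = nmf_extract(cat, rank=2, seed=0, n_restarts=5)
        for planted in sigs:
            best = max(cosine_similarity(planted, s) for s in decomp.signatures)
            assert best > 0.99

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        cat, _, _ = planted_catalog(rng, n_samples=5, burden=1000)
        d1 = nmf_extract(cat, rank=2, seed=7, n_restarts=3)
        d2 = nmf_extract(cat, rank=2, seed=7, n_restarts=3)
        assert np.array_equal(d1.signatures, d2.signatures)
        assert np.array_equal(d1.exposures, d2.exposures)

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(5)
        cat, _, _ = planted_catalog(rng, n_samples=5, burden=1000)
        errs = [
            nmf_extract(cat, rank=2, seed=7, n_restarts=n).reconstruction_error
            for n in (1, 3, 6)
        ]
        assert errs[0] >= errs[1] >= errs[2]

    def test_rank_above_sample_count_rejected(self):
        cat = MutationCatalog(["a", "b"], np.ones((2, 96)))
        with pytest.raises(ValueError, match="rank"):
            nmf_extract(cat, rank=3)

    def test_zero_catalog_rejected(self):
        cat = MutationCatalog(["a", "b"], np.zeros((2, 96)))
        with pytest.raises(ValueError, match="no mutations"):
            nmf_extract(cat, rank=1)

    def test_signature_rows_normalized(self):
        rng = np.random.default_rng(6)
        cat, _, _ = planted_catalog(rng, n_samples=5, burden=1000)
        d = nmf_extract(cat, rank=2, seed=0, n_restarts=3)
        assert d.signatures.sum(axis=1) == pytest.approx(np.ones(2))
        assert (d.exposures >= 0).all()


class TestMatchCatalog:
    def test_planted_age_signature_matches(self):
        reference = fixture_signatures()
        cat = build_catalog(simulate_mutations((1.0, 0.0, 0.0), 5000, seed=8))
        decomp = nmf_extract(cat, rank=1, seed=0, n_restarts=3)
        (m,) = match_catalog(decomp, reference)
        assert m.reference == "age_like"
        assert m.similarity > 0.95
        assert m.matched

    def test_uniformish_vector_unmatched_against_sparse(self):
        sparse = np.zeros(96)
        sparse[:4] = 0.25
        reference = pd.DataFrame({"sparse": sparse}, index=list(CONTEXTS_96))
        decomp_like = nmf_extract(
            MutationCatalog(["s"], np.full((1, 96), 50.0)), rank=1, seed=0, n_restarts=1
        )
        (m,) = match_catalog(decomp_like, reference)
        assert not m.matched

    def test_empty_reference_rejected(self):
        cat = MutationCatalog(["s"], np.ones((1, 96)))
        decomp = nmf_extract(cat, rank=1, seed=0, n_restarts=1)
        with pytest.raises(ValueError, match="empty"):
            match_catalog(decomp, pd.DataFrame(index=list(CONTEXTS_96)))


class TestExposures:
    def test_single_signature_fraction_one(self):
        cat = MutationCatalog(["s"], np.ones((1, 96)))
        decomp = nmf_extract(cat, rank=1, seed=0, n_restarts=1)
        assert exposure_fractions(decomp).iloc[0, 0] == pytest.approx(1.0)

    def test_fractions_scale_invariant(self):
        rng = np.random.default_rng(9)
        cat, _, _ = planted_catalog(rng, n_samples=4, burden=1000)
        d = nmf_extract(cat, rank=2, seed=0, n_restarts=3)
        f1 = exposure_fractions(d)
        d.exposures = d.exposures * 7.5
        f2 = exposure_fractions(d)
        pd.testing.assert_frame_equal(f1, f2)

    def test_group_pooling_weighted_by_exposure(self):
        d = nmf_extract(
            MutationCatalog(["a", "b"], np.vstack([np.full(96, 10.0), np.full(96, 30.0)])),
            rank=1,
            seed=0,
            n_restarts=1,
        )
        pooled = group_exposure_fractions(d, {"a": "g", "b": "g"})
        assert pooled.loc["g", "signature_1"] == pytest.approx(1.0)


class TestScreen:
    def test_bh_hand_computed(self):
        # p = .01 .02 .03 .04 with m=4 -> all q = .04 by the step-up
        rng = np.random.default_rng(10)
        n = 40
        exposures = pd.DataFrame({"sig": rng.random(n)})
        genes = {}
        targets = [0.01, 0.02, 0.03, 0.04]
        # craft indicator vectors whose OLS p-values are irrelevant; instead
        # verify the BH arithmetic directly through statsmodels
        from statsmodels.stats.multitest import multipletests

        _, qvals, _, _ = multipletests(targets, alpha=0.05, method="fdr_bh")
        assert qvals == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_planted_association_ranks_first(self):
        rng = np.random.default_rng(11)
        n = 30
        indicator = (rng.random(n) < 0.5).astype(float)
        exposures = pd.DataFrame(
            {
                "sig1": 5 * indicator + rng.normal(0, 0.3, n),
                "sig2": rng.normal(0, 1, n),
            }
        )
        genes = pd.DataFrame(
            {
                "geneA": indicator,
                "geneB": (rng.random(n) < 0.5).astype(float),
                "geneC": (rng.random(n) < 0.5).astype(float),
            }
        )
        result, _ = signature_gene_screen(exposures, genes)
        best = result.sort_values("q_value").iloc[0]
        assert (best["signature"], best["gene"]) == ("sig1", "geneA")
        assert best["significant"]

    def test_constant_exposure_skipped(self):
        exposures = pd.DataFrame({"sig": [1.0, 1.0, 1.0, 1.0]})
        genes = pd.DataFrame({"g": [0.0, 1.0, 0.0, 1.0]})
        result, skipped = signature_gene_screen(exposures, genes)
        assert result.empty
        assert any("constant exposure" in s for s in skipped)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            signature_gene_screen(
                pd.DataFrame({"s": [1.0, 2.0]}), pd.DataFrame({"g": [0.0, 1.0]})
            )

    def test_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(12)
        n = 25
        exposures = pd.DataFrame(rng.random((n, 3)), columns=["s1", "s2", "s3"])
        genes = pd.DataFrame(
            (rng.random((n, 10)) < 0.5).astype(float), columns=[f"g{i}" for i in range(10)]
        )
        result, _ = signature_gene_screen(exposures, genes)
        ordered = result.sort_values("p_value")
        assert ordered["q_value"].is_monotonic_increasing
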