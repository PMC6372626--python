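"""Channel mapping, spectrum building, and NMF signature extraction."""

import numpy as np
import pandas as pd
import pytest

from ubcgenomics import spectra
from ubcgenomics.spectra import CHANNEL_LABELS, MutationSpectrum
from ubcgenomics.types import Genome, SnvCatalog, SnvRecord

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _spectrum(mat, samples=None):
    mat = np.asarray(mat, dtype=float)
    cols = samples or [f"S{i}" for i in range(mat.shape[1])]
    return MutationSpectrum(pd.DataFrame(mat, index=list(CHANNEL_LABELS), columns=cols))


class TestChannelMapping:
    def test_pyrimidine_reference_direct(self):
        genome = Genome.from_strings({"chr1": "AACAA"})
        snv = SnvRecord("S0", "chr1", 3, "C", "T")
        assert CHANNEL_LABELS[spectra.snv_channel(snv, genome)] == "A[C>T]A"

    def test_purine_reference_reverse_complemented(self):
        # G>A in plus-strand context TGA folds to T[C>T]A: revcomp(TGA)=TCA
        genome = Genome.from_strings({"chr1": "ATGAA"})
        snv = SnvRecord("S0", "chr1", 3, "G", "A")
        assert CHANNEL_LABELS[spectra.snv_channel(snv, genome)] == "T[C>T]A"

    @pytest.mark.parametrize("ref,alt", [("C", "A"), ("C", "G"), ("C", "T"),
                                         ("T", "A"), ("T", "C"), ("T", "G")])
    def test_strand_fold_is_involution(self, ref, alt):
        for five in "ACGT":
            for three in "ACGT":
                direct = spectra.channel_index(ref, alt, five, three)
                folded = spectra.channel_index(
                    _COMP[ref], _COMP[alt], _COMP[three], _COMP[five]
                )
                assert direct == folded

    def test_no_context_at_chromosome_edges(self):
        genome = Genome.from_strings({"chr1": "ACGTA"})
        with pytest.raises(spectra.NoContextError):
            spectra.snv_channel(SnvRecord("S0", "chr1", 1, "A", "C"), genome)
        with pytest.raises(spectra.NoContextError):
            spectra.snv_channel(SnvRecord("S0", "chr1", 5, "A", "C"), genome)

    def test_reference_mismatch_detected(self):
        genome = Genome.from_strings({"chr1": "AACAA"})
        with pytest.raises(ValueError, match="mismatch"):
            spectra.snv_channel(SnvRecord("S0", "chr1", 3, "T", "G"), genome)


class TestBuildSpectrum:
    def test_empty_catalog_all_zero(self, small_genome):
        spec = spectra.build_spectrum(SnvCatalog.empty(), small_genome, samples=["S0", "S1"])
        assert spec.matrix.shape == (96, 2) and spec.matrix.sum() == 0

    def test_single_mutation_unit_mass(self):
        genome = Genome.from_strings({"chr1": "AACAA"})
        catalog = SnvCatalog.from_records([SnvRecord("S0", "chr1", 3, "C", "T")])
        spec = spectra.build_spectrum(catalog, genome)
        assert spec.matrix.sum() == 1
        assert spec.counts.loc["A[C>T]A", "S0"] == 1

    def test_edge_mutations_counted_as_skipped(self):
        genome = Genome.from_strings({"chr1": "CACAA"})
        catalog = SnvCatalog.from_records([
            SnvRecord("S0", "chr1", 1, "C", "T"),
            SnvRecord("S0", "chr1", 3, "C", "T"),
        ])
        spec = spectra.build_spectrum(catalog, genome)
        assert spec.n_skipped == 1 and spec.matrix.sum() == 1

    def test_strand_involution_invariance(self, small_genome):
        """Reverse-complementing genome and mutations leaves the spectrum unchanged."""
        rng = np.random.default_rng(1)
        L = len(small_genome.codes("chr1"))
        rows = []
        for _ in range(500):
            pos = int(rng.integers(2, L))
            ref = small_genome.base("chr1", pos)
            alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(0, 3))) % 4]
            rows.append(("S0", "chr1", pos, ref, alt))
        catalog = SnvCatalog(pd.DataFrame(rows, columns=["sample_id", "chrom", "pos",
                                                         "ref", "alt"]))
        rc_genome = small_genome.reverse_complement()
        rc_rows = [
            (s, c, L - p + 1, _COMP[r], _COMP[a]) for s, c, p, r, a in rows
        ]
        rc_catalog = SnvCatalog(pd.DataFrame(rc_rows, columns=catalog.df.columns))
        a = spectra.build_spectrum(catalog, small_genome)
        b = spectra.build_spectrum(rc_catalog, rc_genome)
        assert np.array_equal(a.matrix, b.matrix)


class TestNmf:
    def test_rank_one_spectrum_recovered_exactly(self):
        rng = np.random.default_rng(0)
        s = rng.dirichlet(np.full(96, 0.2))
        exposures = rng.uniform(500, 3000, size=10)
        X = np.round(np.outer(s, exposures))
        sig = spectra.nmf_decompose(_spectrum(X), k=1, n_restarts=3, seed=1)
        w = sig.signatures[:, 0]
        cos = w @ s / np.linalg.norm(w) / np.linalg.norm(s)
        assert cos >= 0.999

    def test_divergence_trace_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(5.0, size=(96, 15)).astype(float)
        sig = spectra.nmf_decompose(_spectrum(X), k=4, n_restarts=2, seed=2)
        assert np.all(np.diff(sig.divergence_trace) <= 1e-8)

    def test_w_columns_normalized_and_product_preserved(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(10.0, size=(96, 12)).astype(float)
        sig = spectra.nmf_decompose(_spectrum(X), k=3, n_restarts=2, seed=2)
        np.testing.assert_allclose(sig.signatures.sum(axis=0), 1.0, atol=1e-9)
        assert spectra.generalized_kl(X, sig.signatures @ sig.exposures) == pytest.approx(
            sig.reconstruction_error, rel=1e-6
        )

    def test_matches_sklearn_nmf_divergence(self):
        """Independent solver cross-check: comparable KL at the same rank."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(5)
        W = rng.dirichlet(np.full(96, 0.1), size=3).T
        H = rng.uniform(100, 1000, size=(3, 20))
        X = rng.poisson(W @ H).astype(float)
        ours = spectra.nmf_decompose(_spectrum(X), k=3, n_restarts=5, seed=6)
        ref = NMF(n_components=3, solver="mu", beta_loss="kullback-leibler",
                  init="random", max_iter=1000, random_state=0, tol=1e-6).fit(X)
        theirs = spectra.generalized_kl(X, ref.transform(X) @ ref.components_)
        assert ours.reconstruction_error <= theirs * 1.05

    def test_three_planted_signatures_recovered(self, three_signatures):
        W = three_signatures.to_numpy()
        rng = np.random.default_rng(7)
        mix = rng.dirichlet(np.ones(3), size=60)
        X = np.stack([rng.multinomial(2000, W @ m) for m in mix], axis=1)
        sig = spectra.nmf_decompose(_spectrum(X), k=3, n_restarts=5, seed=8)
        for i in range(3):
            best = max(
                W[:, i] @ sig.signatures[:, j]
                / np.linalg.norm(W[:, i]) / np.linalg.norm(sig.signatures[:, j])
                for j in range(3)
            )
            assert best >= 0.9

    def test_infeasible_rank_and_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            spectra.nmf_decompose(_spectrum(np.zeros((96, 3))), k=2)
        with pytest.raises(ValueError):
            spectra.nmf_decompose(_spectrum(np.ones((96, 3))), k=4)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        X = rng.poisson(8.0, size=(96, 10)).astype(float)
        a = spectra.nmf_decompose(_spectrum(X), k=2, n_restarts=3, seed=11)
        b = spectra.nmf_decompose(_spectrum(X), k=2, n_restarts=3, seed=11)
        np.testing.assert_array_equal(a.signatures, b.signatures)


class TestRankSelection:
    def test_exact_rank_two_spectrum(self):
        rng = np.random.default_rng(10)
        W = rng.dirichlet(np.full(96, 0.05), size=2).T
        H = rng.uniform(500, 2000, size=(2, 30))
        X = np.round(W @ H)
        chosen, table = spectra.select_rank(_spectrum(X), range(2, 5), n_restarts=5, seed=3)
        row2 = table[table["k"] == 2].iloc[0]
        assert row2["stability"] > 0.9
        # at k >= 2 the model capacity suffices: tiny relative divergence
        assert row2["reconstruction_error"] / X.sum() < 0.05

    def test_degenerate_single_k_range(self):
        rng = np.random.default_rng(12)
        X = rng.poisson(10.0, size=(96, 10)).astype(float)
        chosen, table = spectra.select_rank(_spectrum(X), [3], n_restarts=3, seed=4)
        assert chosen == 3 and list(table["k"]) == [3]

    def test_infeasible_k_dropped_with_warning(self):
        rng = np.random.default_rng(13)
        X = rng.poisson(10.0, size=(96, 4)).astype(float)
        with pytest.warns(UserWarning, match="infeasible"):
            chosen, table = spectra.select_rank(_spectrum(X), range(2, 8), n_restarts=3, seed=5)
        assert table["k"].max() <= 4


class TestReferenceMatching:
    def test_self_similarity_is_one(self):
        v = np.zeros(96)
        v[[3, 10, 50]] = [1, 2, 3]
        assert spectra.cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        u, v = np.zeros(96), np.zeros(96)
        u[:10], v[10:20] = 1, 1
        assert spectra.cosine_similarity(u, v) == 0.0

    def test_closed_form_value(self):
        u, v = np.zeros(96), np.zeros(96)
        u[0] = 1
        v[0] = v[1] = 1 / np.sqrt(2)
        assert spectra.cosine_similarity(u, v) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            spectra.cosine_similarity(np.zeros(96), np.ones(96))

    def test_best_match_and_tie_break(self, three_signatures):
        W = three_signatures.copy()
        ref = pd.concat([three_signatures, three_signatures.iloc[:, [0]]
                        .rename(columns={"Sig1": "Sig1_copy"})], axis=1)
        matches = spectra.match_to_reference(W, ref)
        assert list(matches["best_reference"])[:3] == ["Sig1", "Sig2", "Sig3"]
        assert (matches["cosine_similarity"] > 0.999).all()
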